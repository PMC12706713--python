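"""Vasculogenic-mimicry (VM) quantification and habitat-vasculature regression.

Slide counting protocol: 10 boxes of 550 x 500 um (0.275 mm^2) placed in
viable tumor tissue; discrete-VM and endothelial-vessel counts per box, and
a presence/absence flag for continuous VM per box.  Densities are the mean
box count divided by the box area (vessels/mm^2); continuous-VM positivity
is the fraction of flagged boxes.  When several observers count the same
slide their counts are averaged per box before densities are computed.

The habitat~vasculature analysis regresses each habitat voxel fraction on
(discrete-VM density, endothelial density, continuous-VM positivity) by OLS
and reports standardized betas, t values, adjusted R^2, the overall F and
the Durbin-Watson statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.stattools import durbin_watson

__all__ = [
    "BOX_AREA_MM2",
    "N_BOXES",
    "vm_density",
    "continuous_positivity",
    "average_observers",
    "RegressionReport",
    "HabitatVMRegression",
    "habitat_vm_regression",
]

N_BOXES = 10
BOX_AREA_MM2 = 0.550 * 0.500  # 550 x 500 um


def vm_density(counts, box_area_mm2: float = BOX_AREA_MM2) -> float:
    """Mean box count / box area, in vessels per mm^2."""
    counts = np.asarray(counts, dtype=float)
    if counts.size != N_BOXES:
        raise ValueError(f"expected {N_BOXES} box counts, got {counts.size}")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if box_area_mm2 <= 0:
        raise ValueError("box area must be positive")
    return float(counts.mean()) / box_area_mm2


def continuous_positivity(flags) -> float:
    """Fraction of the 10 counting areas flagged positive for continuous VM."""
    flags = np.asarray(flags, dtype=float)
    if flags.size != N_BOXES:
        raise ValueError(f"expected {N_BOXES} flags, got {flags.size}")
    return float(flags.mean())


def average_observers(sheet: pd.DataFrame) -> pd.DataFrame:
    """Average multi-observer counting sheets per (patient, box).

    Expects long-format columns: patient, box, observer, discrete_vm,
    endothelial, continuous_flag.  Counts and flags are averaged across
    observers (flags become the observer-agreement fraction).
    """
    required = {"patient", "box", "observer", "discrete_vm", "endothelial", "continuous_flag"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"counting sheet missing columns: {sorted(missing)}")
    return (
        sheet.groupby(["patient", "box"], as_index=False)[
            ["discrete_vm", "endothelial", "continuous_flag"]
        ].mean()
    )


def patient_vm_summary(sheet: pd.DataFrame, box_area_mm2: float = BOX_AREA_MM2) -> pd.DataFrame:
    """Per-patient densities and positivity from a (possibly multi-observer) sheet.

    Returns columns: patient, dvm_density, endo_density, cont_positivity,
    cont_positive_any (binary: any area positive).
    """
    mean_sheet = average_observers(sheet) if "observer" in sheet.columns else sheet
    rows = []
    for patient, g in mean_sheet.groupby("patient"):
        g = g.sort_values("box")
        rows.append(
            dict(
                patient=patient,
                dvm_density=vm_density(g["discrete_vm"].to_numpy(), box_area_mm2),
                endo_density=vm_density(g["endothelial"].to_numpy(), box_area_mm2),
                cont_positivity=continuous_positivity(g["continuous_flag"].to_numpy()),
                cont_positive_any=float(g["continuous_flag"].to_numpy().max() > 0),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionReport:
    predictors: list[str]
    std_beta: pd.Series
    t_values: pd.Series
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    durbin_watson: float
    n: int


class HabitatVMRegression:
    """OLS of a habitat fraction on VM/vessel quantities, with report.

    sklearn-style: ``fit(X, y)`` stores ``report_`` and coefficient
    attributes; standardized betas come from refitting on z-scored response
    and predictors (their t statistics equal the raw-model slopes' t).
    """

    def __init__(self):
        pass

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "HabitatVMRegression":
        if params:
            raise ValueError("HabitatVMRegression has no parameters")
        return self

    def fit(self, X: pd.DataFrame, y) -> "HabitatVMRegression":
        X = pd.DataFrame(X).astype(float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n <= p + 1:
            raise ValueError("need n > number of predictors + 1")
        mat = X.to_numpy()
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), mat])) < p + 1:
            raise ValueError("singular design: collinear predictors")
        design = sm.add_constant(X)
        res = sm.OLS(y, design).fit()
        Z = (X - X.mean()) / X.std(ddof=1)
        z = (y - y.mean()) / y.std(ddof=1)
        res_std = sm.OLS(z, sm.add_constant(Z)).fit()
        self.model_ = res
        self.coef_ = res.params[X.columns]
        self.intercept_ = float(res.params["const"])
        self.report_ = RegressionReport(
            predictors=list(X.columns),
            std_beta=res_std.params[X.columns],
            t_values=res.tvalues[X.columns],
            r_squared=float(res.rsquared),
            adj_r_squared=float(res.rsquared_adj),
            f_statistic=float(res.fvalue),
            f_pvalue=float(res.f_pvalue),
            durbin_watson=float(durbin_watson(res.resid)),
            n=n,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X).astype(float)
        return self.intercept_ + X[self.report_.predictors].to_numpy() @ self.coef_.to_numpy()


def habitat_vm_regression(y, X: pd.DataFrame) -> RegressionReport:
    """OLS report for one habitat-fraction response (thin wrapper)."""
    return HabitatVMRegression().fit(X, y).report_
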