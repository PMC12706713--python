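"""Combined diagnostic model: screening, AIC selection, nomogram, calibration, DCA.

The modeling pathway mirrors the standard clinical-prediction workflow for a
binary diagnosis (outcome coded PCNSL = 1):

1. univariable logistic screening of each candidate predictor (keep p < 0.05);
2. backward stepwise elimination from the full multivariable model, removing
   the term whose deletion most decreases AIC until no deletion helps;
3. collinearity diagnostics (tolerance and VIF = 1/tolerance) on the final
   design;
4. a nomogram point scale reconstructing the model probability exactly;
5. calibration: Hosmer-Lemeshow deciles-of-risk test and Harrell's
   optimism-corrected calibration slope/intercept via bootstrap;
6. decision-curve analysis (net benefit against treat-all / treat-none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CohortSplit",
    "FittedLogisticModel",
    "NomogramSpec",
    "CalibrationReport",
    "DcaCurve",
    "split_cohort",
    "fit_logistic",
    "univariable_screen",
    "select_model",
    "build_nomogram",
    "hosmer_lemeshow",
    "calibration_curve",
    "decision_curve",
    "DiagnosticModel",
]

_DIVERGENCE_BOUND = 15.0  # |log-odds coefficient| beyond this flags separation


@dataclass
class CohortSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    ratio: float
    seed: int
    stratified: bool

    @property
    def n_train(self) -> int:
        return int(self.train_idx.size)

    @property
    def n_val(self) -> int:
        return int(self.val_idx.size)


def split_cohort(
    labels,
    ratio: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> CohortSplit:
    """Random train/validation partition with training size = ceil(ratio * n).

    With ``stratify`` the per-class training counts follow largest-remainder
    apportionment of ``ratio * n_class`` so the total is exactly
    ceil(ratio * n) while both classes keep the split ratio.
    """
    labels = np.asarray(labels)
    n = labels.size
    if not 0 < ratio < 1:
        raise ValueError("ratio must lie in (0, 1)")
    if n < 2:
        raise ValueError("need at least two records")
    rng = np.random.default_rng(seed)
    n_train = int(np.ceil(ratio * n))
    if not stratify:
        perm = rng.permutation(n)
        return CohortSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), ratio, seed, False)
    classes, counts = np.unique(labels, return_counts=True)
    quotas = ratio * counts
    base = np.floor(quotas).astype(int)
    short = n_train - base.sum()
    order = np.argsort(-(quotas - base))
    for i in range(int(short)):
        base[order[i % len(classes)]] += 1
    train_parts = []
    val_parts = []
    for cls, take in zip(classes, base):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        train_parts.append(perm[:take])
        val_parts.append(perm[take:])
    return CohortSplit(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(val_parts)),
        ratio,
        seed,
        True,
    )


@dataclass
class FittedLogisticModel:
    """Maximum-likelihood logistic fit with Wald inference and diagnostics.

    ``table`` rows: term, B, SE, OR (= exp(B)), ci_low/ci_high
    (= exp(B -/+ 1.96 SE)), p (Wald), tolerance, VIF.
    """

    terms: list[str]
    table: pd.DataFrame
    intercept: float
    aic: float
    llf: float
    separation_warning: bool = False
    outcome_coding: str = "PCNSL=1"

    @property
    def coefs(self) -> pd.Series:
        return self.table.set_index("term")["B"]

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept)
        for t in self.terms:
            lp = lp + self.coefs[t] * np.asarray(X[t], dtype=float)
        return lp

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _tolerance_vif(X: pd.DataFrame) -> dict[str, tuple[float, float]]:
    out = {}
    cols = list(X.columns)
    for c in cols:
        others = [o for o in cols if o != c]
        if not others:
            out[c] = (1.0, 1.0)
            continue
        design = sm.add_constant(X[others].to_numpy(dtype=float))
        r2 = sm.OLS(X[c].to_numpy(dtype=float), design).fit().rsquared
        tol = max(1.0 - r2, 1e-12)
        out[c] = (tol, 1.0 / tol)
    return out


def fit_logistic(X: pd.DataFrame, y, add_diagnostics: bool = True) -> FittedLogisticModel:
    """Fit a logistic model by IRLS/Newton MLE and report Wald inference.

    Raises on zero-variance predictors; perfect separation is flagged (not
    raised) via diverging-coefficient detection.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need n > number of terms + 1")
    zero_var = [c for c in X.columns if X[c].nunique() < 2]
    if zero_var:
        raise ValueError(f"zero-variance predictors: {zero_var}")

    design = sm.add_constant(X, has_constant="add")
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100, tol=1e-8)
        except Exception:
            # singular Hessian under (quasi-)complete separation: refit with
            # BFGS so a diverging estimate is still reported, and flag it
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, method="bfgs")
            separation = True
    params = res.params
    bse = res.bse
    separation = (
        separation
        or bool(np.any(np.abs(params.values) > _DIVERGENCE_BOUND))
        or not res.mle_retvals.get("converged", True)
    )

    diag = _tolerance_vif(X) if (add_diagnostics and X.shape[1] >= 1) else {}
    rows = []
    for term in X.columns:
        b = float(params[term])
        se = float(bse[term])
        tol, vif = diag.get(term, (np.nan, np.nan))
        # clip exponents so diverging fits report inf-free (huge) ORs
        _e = lambda v: float(np.exp(np.clip(v, -700.0, 700.0)))
        rows.append(
            dict(
                term=term,
                B=b,
                SE=se,
                OR=_e(b),
                ci_low=_e(b - 1.959963984540054 * se),
                ci_high=_e(b + 1.959963984540054 * se),
                p=float(res.pvalues[term]),
                tolerance=tol,
                VIF=vif,
            )
        )
    return FittedLogisticModel(
        terms=list(X.columns),
        table=pd.DataFrame(rows),
        intercept=float(params["const"]),
        aic=float(res.aic),
        llf=float(res.llf),
        separation_warning=separation,
    )


def univariable_screen(X: pd.DataFrame, y, alpha: float = 0.05) -> tuple[list[str], pd.DataFrame]:
    """Per-predictor logistic fits; returns (significant terms, full table)."""
    tables = []
    keep = []
    for c in X.columns:
        m = fit_logistic(X[[c]], y, add_diagnostics=False)
        row = m.table.iloc[0].to_dict()
        tables.append(row)
        if row["p"] < alpha:
            keep.append(c)
    return keep, pd.DataFrame(tables)


def select_model(candidates: list[str], X: pd.DataFrame, y) -> FittedLogisticModel:
    """Backward stepwise AIC elimination from the full candidate model.

    At each step the deletion that most decreases AIC is applied (AIC ties
    broken by removing the larger-Wald-p term); stops when no single deletion
    decreases AIC.  The final model is refit with tolerance/VIF diagnostics.
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    current = list(candidates)
    current_fit = fit_logistic(X[current], y)
    while len(current) > 1:
        trials = []
        for term in current:
            reduced = [t for t in current if t != term]
            fit = fit_logistic(X[reduced], y, add_diagnostics=False)
            wald_p = float(current_fit.table.set_index("term").loc[term, "p"])
            trials.append((fit.aic, -wald_p, term, fit))
        trials.sort(key=lambda t: (t[0], t[1]))
        best_aic, _, term, fit = trials[0]
        if best_aic < current_fit.aic:
            current = [t for t in current if t != term]
            current_fit = fit
        else:
            break
    return fit_logistic(X[current], y)


@dataclass
class NomogramSpec:
    """Point scales reconstructing the logistic model probability.

    Predictor j at value x earns ``100 * |B_j| * (x - ref_j) / scale`` points
    with the reference at the low-risk end of its display range and
    ``scale = max_j |B_j| * range_j``, so the widest-effect predictor spans
    exactly 0-100.  Total points map back to probability through the
    reconstructed linear predictor.
    """

    refs: dict[str, float]
    points_per_unit: dict[str, float]
    scale: float
    intercept_total: float  # model intercept + sum_j B_j * ref_j
    coefs: dict[str, float]

    def points(self, term: str, value) -> np.ndarray:
        v = np.asarray(value, dtype=float)
        sign = 1.0 if self.coefs[term] >= 0 else -1.0
        return self.points_per_unit[term] * sign * (v - self.refs[term])

    def total_points(self, X: pd.DataFrame) -> np.ndarray:
        return sum(self.points(t, X[t]) for t in self.coefs)

    def probability(self, total_points) -> np.ndarray:
        lp = self.intercept_total + np.asarray(total_points, dtype=float) * self.scale / 100.0
        return expit(lp)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.probability(self.total_points(X))


def build_nomogram(model: FittedLogisticModel, ranges: dict[str, tuple[float, float]]) -> NomogramSpec:
    """Construct the nomogram point scales for a fitted model."""
    if not model.terms:
        raise ValueError("model has no predictors")
    widths = {}
    refs = {}
    for t in model.terms:
        lo, hi = ranges[t]
        if not hi > lo:
            raise ValueError(f"zero-width display range for {t!r}")
        b = model.coefs[t]
        widths[t] = abs(b) * (hi - lo)
        refs[t] = lo if b >= 0 else hi  # low-risk end of the range
    scale = max(widths.values())
    ppu = {t: 100.0 * abs(model.coefs[t]) / scale for t in model.terms}
    intercept_total = model.intercept + sum(model.coefs[t] * refs[t] for t in model.terms)
    return NomogramSpec(refs, ppu, scale, float(intercept_total), dict(model.coefs))


def hosmer_lemeshow(probs, outcomes, groups: int = 10) -> tuple[float, int, float]:
    """Hosmer-Lemeshow deciles-of-risk goodness-of-fit test.

    Equal-count bins by predicted probability with ties kept together (bins
    merge when tied probabilities straddle a boundary, reducing df);
    chi2 = sum (O - E)^2 / (E (1 - E/n_g)); df = bins - 2.
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if groups < 3:
        raise ValueError("need at least 3 groups")
    if probs.size < groups:
        raise ValueError("need n >= groups")
    qs = np.quantile(probs, np.linspace(0, 1, groups + 1))
    edges = np.unique(qs)
    bins = np.clip(np.searchsorted(edges, probs, side="right") - 1, 0, len(edges) - 2)
    chi2 = 0.0
    n_bins = 0
    for b in np.unique(bins):
        sel = bins == b
        n_g = sel.sum()
        o = outcomes[sel].sum()
        e = probs[sel].sum()
        if e <= 0 or e >= n_g:
            raise ValueError("degenerate Hosmer-Lemeshow bin (expected count 0 or n)")
        chi2 += (o - e) ** 2 / (e * (1.0 - e / n_g))
        n_bins += 1
    df = n_bins - 2
    p = float(chi2_dist.sf(chi2, df))
    return float(chi2), int(df), p


def _calibration_slope_intercept(lp: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    design = sm.add_constant(lp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=100)
    return float(res.params[1]), float(res.params[0])


@dataclass
class CalibrationReport:
    apparent_slope: float
    apparent_intercept: float
    corrected_slope: float
    corrected_intercept: float
    hl_chi2: float
    hl_df: int
    hl_p: float
    n_resamples_used: int
    curve: pd.DataFrame = field(repr=False)  # per-decile predicted vs observed


def calibration_curve(
    model: FittedLogisticModel,
    X: pd.DataFrame,
    y,
    n_resamples: int = 1000,
    seed: int = 0,
    groups: int = 10,
) -> CalibrationReport:
    """Harrell optimism-corrected calibration of a fitted logistic model.

    Each bootstrap resample refits the model terms, measures the calibration
    slope/intercept of the refit both on the resample (apparent) and on the
    original data (test); the averaged difference is the optimism subtracted
    from the original apparent values.  Single-class resamples are skipped.
    """
    if n_resamples < 1:
        raise ValueError("need at least one bootstrap resample")
    y = np.asarray(y, dtype=float)
    lp = model.linear_predictor(X)
    app_slope, app_int = _calibration_slope_intercept(lp, y)

    rng = np.random.default_rng(seed)
    n = len(y)
    opt_s = []
    opt_i = []
    used = 0
    for _ in range(n_resamples):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if len(np.unique(yb)) < 2:
            continue
        Xb = X.iloc[idx]
        try:
            mb = fit_logistic(Xb[model.terms], yb, add_diagnostics=False)
            s_app, i_app = _calibration_slope_intercept(mb.linear_predictor(Xb), yb)
            s_tst, i_tst = _calibration_slope_intercept(mb.linear_predictor(X), y)
        except Exception:  # separated/singular resample: skip and count
            continue
        opt_s.append(s_app - s_tst)
        opt_i.append(i_app - i_tst)
        used += 1
    if used == 0:
        raise ValueError("no usable bootstrap resamples")
    corr_slope = app_slope - float(np.mean(opt_s))
    corr_int = app_int - float(np.mean(opt_i))

    probs = expit(lp)
    hl_chi2, hl_df, hl_p = hosmer_lemeshow(probs, y, groups=groups)
    order = np.argsort(probs)
    bins = np.array_split(order, groups)
    curve = pd.DataFrame(
        {
            "predicted": [probs[b].mean() for b in bins if len(b)],
            "observed": [y[b].mean() for b in bins if len(b)],
            "n": [len(b) for b in bins if len(b)],
        }
    )
    return CalibrationReport(
        app_slope, app_int, corr_slope, corr_int, hl_chi2, hl_df, hl_p, used, curve
    )


@dataclass
class DcaCurve:
    table: pd.DataFrame  # columns: threshold, nb_model, nb_all, nb_none

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold"].to_numpy()


def decision_curve(probs, outcomes, thresholds=None) -> DcaCurve:
    """Decision-curve analysis: net benefit over a threshold-probability grid.

    NB(p_t) = TP/n - (FP/n) * p_t / (1 - p_t), counting a patient as treated
    when the predicted probability is >= p_t; treat-all and treat-none
    reference curves included.
    """
    probs = np.asarray(probs, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie in (0, 1)")
    if len(np.unique(outcomes)) < 2:
        raise ValueError("both classes must be present")
    n = probs.size
    prevalence = outcomes.mean()
    rows = []
    for pt in thresholds:
        treated = probs >= pt
        tp = float((treated & (outcomes == 1)).sum()) / n
        fp = float((treated & (outcomes == 0)).sum()) / n
        w = pt / (1.0 - pt)
        rows.append(
            dict(
                threshold=float(pt),
                nb_model=tp - fp * w,
                nb_all=prevalence - (1.0 - prevalence) * w,
                nb_none=0.0,
            )
        )
    return DcaCurve(pd.DataFrame(rows))


class DiagnosticModel:
    """sklearn-style classifier: screen, AIC-select, fit, predict.

    ``fit(X, y)`` runs univariable screening at ``screen_alpha`` and backward
    AIC elimination, then refits the selected terms with collinearity
    diagnostics.  ``X`` is a DataFrame of candidate predictors; ``y`` is the
    binary outcome (positive class = 1, conventionally PCNSL).
    """

    def __init__(self, screen_alpha: float = 0.05, direction: str = "backward"):
        self.screen_alpha = screen_alpha
        self.direction = direction

    def get_params(self, deep: bool = True) -> dict:
        return {"screen_alpha": self.screen_alpha, "direction": self.direction}

    def set_params(self, **params) -> "DiagnosticModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y) -> "DiagnosticModel":
        if self.direction != "backward":
            raise ValueError("only backward elimination is implemented")
        X = pd.DataFrame(X).reset_index(drop=True)
        y_arr = np.asarray(y, dtype=float)
        keep_rows = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y_arr))
        Xc = X.loc[keep_rows]
        yc = y_arr[keep_rows]
        keep, table = univariable_screen(Xc, yc, alpha=self.screen_alpha)
        if not keep:
            raise ValueError("no predictor passed univariable screening")
        self.univariable_table_ = table
        self.result_ = select_model(keep, Xc, yc)
        self.selected_features_ = list(self.result_.terms)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        p1 = self.result_.predict_proba(pd.DataFrame(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score(self, X: pd.DataFrame, y) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())
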