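"""End-to-end pipeline driver: preprocess -> habitats -> metrics -> stats -> model -> VM.

Consumes a dataset directory as written by :func:`habitatmri.synthetic.simulate_dataset`
(or equivalently organized real data): ``cohort.csv`` with per-patient
covariates, ``images/<patient>/{t1ce,adc,mask_tumor,mask_edema,mask_reference}.nii.gz``
and optionally ``vm_sheet.csv``.  All outputs (stage CSVs, model JSON,
plots, run manifest) land in the output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grids import InputError, SegmentationMasks, VoxelGrid, load_nifti
from .metrics import compute_metrics
from .model import (
    DiagnosticModel,
    build_nomogram,
    calibration_curve,
    decision_curve,
    split_cohort,
)
from .preprocess import gradient_normalize, resample, resample_mask
from .segmentation import HabitatSegmenter
from .stats import compare_groups, pearson_chi2, roc_youden
from .vm import HabitatVMRegression, patient_vm_summary

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

CONTINUOUS_VARS = [
    "age", "diameter_mm", "f1", "f2", "f3", "ei",
    "radc_mean", "radc_max", "radc_min", "radc_dif",
]
BINARY_VARS = ["male", "headache", "midline"]
MODEL_CANDIDATES = CONTINUOUS_VARS


class PipelineError(RuntimeError):
    """Stage-attributed pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    data_dir: str
    out_dir: str
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    k: int = 3
    cluster_seed: int = 0
    n_restarts: int = 10
    split_ratio: float = 0.7
    split_seed: int = 0
    screen_alpha: float = 0.05
    hl_groups: int = 10
    bootstrap_resamples: int = 1000
    bootstrap_seed: int = 0
    dca_grid: tuple[float, float, float] = (0.01, 0.99, 0.01)  # start, stop, step
    radc_trim: float = 0.005
    make_plots: bool = True

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise PipelineError("config", "split ratio must lie in (0, 1)")
        if any(s <= 0 for s in self.spacing):
            raise PipelineError("config", "spacing must be positive")
        if self.k < 2:
            raise PipelineError("config", "k must be >= 2")
        if not Path(self.data_dir).exists():
            raise PipelineError("config", f"data directory {self.data_dir} not found")


_IMAGE_FILES = ("t1ce.nii.gz", "adc.nii.gz", "mask_tumor.nii.gz",
                "mask_edema.nii.gz", "mask_reference.nii.gz")


def _validate_inputs(cfg: PipelineConfig) -> tuple[pd.DataFrame, dict[str, Path]]:
    data = Path(cfg.data_dir)
    cohort_path = data / "cohort.csv"
    if not cohort_path.exists():
        raise PipelineError("validate", f"missing cohort table {cohort_path}")
    cohort = pd.read_csv(cohort_path)
    patients = {}
    for pid in cohort["patient_id"]:
        pdir = data / "images" / str(pid)
        for fname in _IMAGE_FILES:
            if not (pdir / fname).exists():
                raise PipelineError("validate", f"patient {pid}: missing {fname}")
        patients[str(pid)] = pdir
    return cohort, patients


def _load_patient(pdir: Path, cfg: PipelineConfig):
    t1 = load_nifti(pdir / "t1ce.nii.gz")
    adc = load_nifti(pdir / "adc.nii.gz")
    masks = SegmentationMasks.load(
        pdir / "mask_tumor.nii.gz", pdir / "mask_edema.nii.gz", pdir / "mask_reference.nii.gz"
    )
    if not (t1.aligned_with(adc) and t1.shape == masks.shape):
        raise InputError("volumes and masks are not aligned")
    if not np.allclose(t1.spacing, cfg.spacing):
        t1 = resample(t1, cfg.spacing, "linear")
        adc = resample(adc, cfg.spacing, "linear")
        masks = SegmentationMasks(
            resample_mask(masks.tumor, masks.spacing, cfg.spacing),
            resample_mask(masks.edema, masks.spacing, cfg.spacing),
            resample_mask(masks.reference, masks.spacing, cfg.spacing),
            cfg.spacing,
        )
    return t1, adc, masks


def _group_stats_table(table: pd.DataFrame) -> pd.DataFrame:
    g = table[table["pcnsl"] == 0]
    p = table[table["pcnsl"] == 1]
    rows = []
    for var in CONTINUOUS_VARS:
        res = compare_groups(g[var], p[var])
        rows.append(dict(variable=var, test=res.test, statistic=res.statistic, p=res.p))
    for var in BINARY_VARS:
        tab = [
            [int(g[var].sum()), int((1 - g[var]).sum())],
            [int(p[var].sum()), int((1 - p[var]).sum())],
        ]
        res = pearson_chi2(tab)
        rows.append(dict(variable=var, test=res.test, statistic=res.statistic, p=res.p))
    return pd.DataFrame(rows)


def _roc_table(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    y = table["pcnsl"].to_numpy()
    for var in CONTINUOUS_VARS:
        roc = roc_youden(table[var].to_numpy(), y, direction="auto")
        rows.append(
            dict(variable=var, auc=roc.auc, ci_low=roc.ci_low, ci_high=roc.ci_high,
                 sensitivity=roc.sensitivity, specificity=roc.specificity,
                 cutoff=roc.cutoff, youden_j=roc.youden_j)
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, patients = _validate_inputs(cfg)

    # --- imaging stages -------------------------------------------------
    rows = []
    for pid, pdir in patients.items():
        try:
            t1, adc, masks = _load_patient(pdir, cfg)
            t1n = gradient_normalize(t1)
            seg = HabitatSegmenter(
                k=cfg.k, random_state=cfg.cluster_seed, n_restarts=cfg.n_restarts
            ).fit(t1n, adc, masks.tumor)
            metrics = compute_metrics(adc, masks, trim=cfg.radc_trim)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError("imaging", f"patient {pid}: {exc}") from exc
        fr = seg.fractions_
        rows.append(
            dict(
                patient_id=pid, f1=fr.f1, f2=fr.f2, f3=fr.f3,
                ei=metrics.ei, radc_mean=metrics.radc_mean, radc_max=metrics.radc_max,
                radc_min=metrics.radc_min, radc_dif=metrics.radc_dif,
                diameter_mm=metrics.diameter_mm,
            )
        )
        hab = VoxelGrid(seg.labels_.astype(float), masks.spacing)
        (out / "habitats").mkdir(exist_ok=True)
        hab.save(out / "habitats" / f"{pid}_habitats.nii.gz")
    measured = pd.DataFrame(rows)
    covars = cohort[["patient_id", "diagnosis", "pcnsl", "age", "male", "headache", "midline"]]
    table = covars.merge(measured, on="patient_id")
    table.to_csv(out / "analysis_table.csv", index=False)

    # --- statistics ------------------------------------------------------
    try:
        stats_tbl = _group_stats_table(table)
        roc_tbl = _roc_table(table)
    except Exception as exc:
        raise PipelineError("stats", str(exc)) from exc
    stats_tbl.to_csv(out / "group_stats.csv", index=False)
    roc_tbl.to_csv(out / "roc_univariable.csv", index=False)

    # --- diagnostic model ------------------------------------------------
    try:
        split = split_cohort(table["pcnsl"], cfg.split_ratio, cfg.split_seed)
        train = table.iloc[split.train_idx]
        val = table.iloc[split.val_idx]
        dm = DiagnosticModel(screen_alpha=cfg.screen_alpha).fit(
            train[MODEL_CANDIDATES], train["pcnsl"]
        )
        fitted = dm.result_
        ranges = {
            t: (float(table[t].min()), float(table[t].max())) for t in fitted.terms
        }
        nomogram = build_nomogram(fitted, ranges)
        cal_train = calibration_curve(
            fitted, train[fitted.terms], train["pcnsl"],
            n_resamples=cfg.bootstrap_resamples, seed=cfg.bootstrap_seed,
            groups=cfg.hl_groups,
        )
        probs_train = fitted.predict_proba(train[fitted.terms])
        probs_val = fitted.predict_proba(val[fitted.terms])
        lo, hi, step = cfg.dca_grid
        grid = np.arange(lo, hi + step / 2, step)
        dca_train = decision_curve(probs_train, train["pcnsl"], grid)
        dca_val = decision_curve(probs_val, val["pcnsl"], grid)
        roc_train = roc_youden(probs_train, train["pcnsl"].to_numpy(), ">")
        roc_val = roc_youden(probs_val, val["pcnsl"].to_numpy(), ">")
    except Exception as exc:
        raise PipelineError("model", str(exc)) from exc

    fitted.table.to_csv(out / "model_terms.csv", index=False)
    dm.univariable_table_.to_csv(out / "univariable_logistic.csv", index=False)
    dca_train.table.to_csv(out / "dca_train.csv", index=False)
    dca_val.table.to_csv(out / "dca_validation.csv", index=False)
    cal_train.curve.to_csv(out / "calibration_train.csv", index=False)
    model_summary = {
        "selected_terms": fitted.terms,
        "intercept": fitted.intercept,
        "aic": fitted.aic,
        "train_auc": roc_train.auc,
        "train_auc_ci": [roc_train.ci_low, roc_train.ci_high],
        "val_auc": roc_val.auc,
        "val_auc_ci": [roc_val.ci_low, roc_val.ci_high],
        "hl_train": {"chi2": cal_train.hl_chi2, "df": cal_train.hl_df, "p": cal_train.hl_p},
        "calibration": {
            "apparent_slope": cal_train.apparent_slope,
            "corrected_slope": cal_train.corrected_slope,
            "apparent_intercept": cal_train.apparent_intercept,
            "corrected_intercept": cal_train.corrected_intercept,
        },
        "nomogram": {
            "refs": nomogram.refs,
            "points_per_unit": nomogram.points_per_unit,
            "scale": nomogram.scale,
            "intercept_total": nomogram.intercept_total,
            "coefs": nomogram.coefs,
        },
        "split": {"n_train": split.n_train, "n_val": split.n_val},
    }
    (out / "model_summary.json").write_text(json.dumps(model_summary, indent=2))

    if cfg.make_plots:
        _plots(out, cal_train, dca_train)

    # --- VM --------------------------------------------------------------
    vm_report = None
    vm_path = Path(cfg.data_dir) / "vm_sheet.csv"
    if vm_path.exists():
        try:
            sheet = pd.read_csv(vm_path)
            summary = patient_vm_summary(sheet)
            merged = summary.merge(
                table[["patient_id", "f1", "f2", "f3"]],
                left_on="patient", right_on="patient_id",
            )
            X = merged[["dvm_density", "endo_density", "cont_positivity"]]
            vm_report = {}
            for resp in ("f1", "f2", "f3"):
                rep = HabitatVMRegression().fit(X, merged[resp]).report_
                vm_report[resp] = {
                    "std_beta": rep.std_beta.to_dict(),
                    "t": rep.t_values.to_dict(),
                    "adj_r2": rep.adj_r_squared,
                    "F": rep.f_statistic,
                    "durbin_watson": rep.durbin_watson,
                    "n": rep.n,
                }
            summary.to_csv(out / "vm_summary.csv", index=False)
            (out / "vm_regressions.json").write_text(json.dumps(vm_report, indent=2))
        except Exception as exc:
            raise PipelineError("vm", str(exc)) from exc

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_patients": len(table),
        "selected_terms": fitted.terms,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _plots(out: Path, cal, dca) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].plot([0, 1], [0, 1], "k--", lw=1, label="ideal")
    axes[0].plot(cal.curve["predicted"], cal.curve["observed"], "o-", label="apparent")
    axes[0].set_xlabel("predicted probability")
    axes[0].set_ylabel("observed fraction")
    axes[0].set_title("Calibration (training)")
    axes[0].legend()
    t = dca.table
    axes[1].plot(t["threshold"], t["nb_model"], label="model")
    axes[1].plot(t["threshold"], t["nb_all"], label="treat all")
    axes[1].plot(t["threshold"], t["nb_none"], label="treat none")
    axes[1].set_ylim(-0.1, max(0.6, t["nb_model"].max() + 0.05))
    axes[1].set_xlabel("threshold probability")
    axes[1].set_ylabel("net benefit")
    axes[1].set_title("Decision curve (training)")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(out / "report_plots.png", dpi=110)
    plt.close(fig)
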