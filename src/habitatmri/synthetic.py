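"""Synthetic cohorts, two-channel phantoms and VM counting sheets.

Because the clinical cohort behind this kind of habitat analysis is not
shareable, every downstream stage is exercised on synthetic data with known
ground truth.  The default configuration is calibrated to the published
class-conditional summaries of an atypical-GBM vs PCNSL cohort (n = 125):

* habitat voxel fractions (f1, f2, f3): Dirichlet per class with means
  (39.5%, 52.5%, 8.0%) for GBM and (54.3%, 41.5%, 4.2%) for PCNSL and
  concentrations matched to the reported SDs (14.2% / 17.7% on f1);
* edema index: 1 + LogNormal, medians 2.008 (GBM) and 3.445 (PCNSL);
* rADCmean: LogNormal, medians 1.201 / 0.968; rADCdif likewise, with
  rADCmax/min placed around the mean by a fixed split ratio;
* age: Normal(50.6, 15.0) / Normal(56.9, 12.7); diameter: LogNormal medians
  47.3 / 31.1 mm; sex/headache/midline: Bernoulli at the reported rates.

VM quantities are linear in (f1, f2, f3) and class with truncation at zero
(discrete-VM and endothelial densities) or clipping to [0, 1] (continuous-VM
positivity probability), with signs matching the reported habitat~VM
regressions: discrete VM loads + on f1 and - on f2, endothelial + on f1, and
continuous-VM positivity - on f3.  Magnitudes are calibrated so the n = 19
regressions give standardized betas comparable to the reported ones.

Phantoms realize a ground-truth record as an ellipsoidal tumor partitioned
into three subregions (concentric shells by default: Habitat 1 rim,
Habitat 2 middle, Habitat 3 core; a "speckled" random layout is available
for stress-testing), an edema shell of volume (EI - 1) x tumor volume, and a
reference region whose ADC mean makes the rADCmean target hold.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .grids import SegmentationMasks, VoxelGrid

__all__ = [
    "ClassParams",
    "VMCoupling",
    "PhantomParams",
    "SyntheticConfig",
    "ConfigurationError",
    "SizingError",
    "VMCounts",
    "gen_cohort",
    "render_phantom",
    "gen_vm_counts",
    "make_vm_sheet",
    "default_config",
    "simulate_dataset",
]


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


class SizingError(ValueError):
    """Requested tumor/edema geometry does not fit the phantom grid."""


@dataclass
class ClassParams:
    """Class-conditional generative parameters for one diagnosis."""

    habitat_mean: tuple[float, float, float]
    habitat_concentration: float  # Dirichlet total mass; math.inf = point mass
    ei_median: float
    ei_log_sd: float
    radc_mean_median: float
    radc_mean_log_sd: float
    radc_dif_median: float
    radc_dif_log_sd: float
    age_mean: float
    age_sd: float
    diameter_median_mm: float
    diameter_log_sd: float
    p_male: float
    p_headache: float
    p_midline: float

    def validate(self) -> None:
        f = np.asarray(self.habitat_mean, dtype=float)
        if f.shape != (3,) or not np.isclose(f.sum(), 1.0):
            raise ConfigurationError(f"habitat means must be 3 values summing to 1, got {f}")
        if (f < 0).any():
            raise ConfigurationError("habitat means must be nonnegative")
        if self.habitat_concentration <= 0:
            raise ConfigurationError("Dirichlet concentration must be positive")
        for name in ("ei_log_sd", "radc_mean_log_sd", "radc_dif_log_sd", "age_sd", "diameter_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.ei_median < 1:
            raise ConfigurationError("EI median must be >= 1")
        for name in ("radc_mean_median", "radc_dif_median", "diameter_median_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("p_male", "p_headache", "p_midline"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class VMCoupling:
    """Linear maps from (f1, f2, f3) and class to VM quantities.

    density = max(0, intercept + beta_f . f + beta_class * class + noise);
    continuous-VM positivity probability = clip(linear part, 0, 1).
    """

    dvm_intercept: float = 0.3
    dvm_beta_f: tuple[float, float, float] = (30.0, -20.0, 0.0)
    dvm_beta_class: float = 0.0
    dvm_noise_sd: float = 3.0
    endo_intercept: float = 10.475
    endo_beta_f: tuple[float, float, float] = (35.0, 0.0, 0.0)
    endo_beta_class: float = -9.0
    endo_noise_sd: float = 2.0
    cont_intercept: float = 0.28
    cont_beta_f: tuple[float, float, float] = (0.0, 0.0, -3.0)
    cont_beta_class: float = 0.14

    def validate(self) -> None:
        if self.dvm_noise_sd < 0 or self.endo_noise_sd < 0:
            raise ConfigurationError("VM noise SDs must be nonnegative")


@dataclass
class PhantomParams:
    """Habitat intensity signatures and rendering options.

    T1-CE in raw acquisition units (normalized downstream); ADC in units of
    1e-6 mm^2/s.  Habitat order: (H1 high-T1CE/low-ADC, H2 low/low,
    H3 low/high).
    """

    t1ce_means: tuple[float, float, float] = (200.0, 90.0, 80.0)
    t1ce_noise_sd: float = 10.0
    adc_means: tuple[float, float, float] = (700.0, 750.0, 1600.0)
    adc_noise_sd: float = 60.0
    background_t1ce: float = 70.0
    background_adc: float = 900.0
    edema_t1ce: float = 65.0
    edema_adc: float = 1300.0
    layout: str = "shells"  # or "speckled"
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)

    def validate(self) -> None:
        if self.t1ce_noise_sd < 0 or self.adc_noise_sd < 0:
            raise ConfigurationError("phantom noise SDs must be nonnegative")
        if self.layout not in ("shells", "speckled"):
            raise ConfigurationError("layout must be 'shells' or 'speckled'")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")


@dataclass
class SyntheticConfig:
    n_patients: int = 125
    pcnsl_prevalence: float = 64 / 125
    gbm: ClassParams = field(default_factory=lambda: ClassParams(
        habitat_mean=(0.395, 0.525, 0.080),
        habitat_concentration=10.85,
        ei_median=2.008,
        ei_log_sd=1.386,
        radc_mean_median=1.201,
        radc_mean_log_sd=0.231,
        radc_dif_median=0.624,
        radc_dif_log_sd=0.405,
        age_mean=50.6,
        age_sd=15.0,
        diameter_median_mm=47.3,
        diameter_log_sd=0.406,
        p_male=33 / 61,
        p_headache=30 / 61,
        p_midline=30 / 61,
    ))
    pcnsl: ClassParams = field(default_factory=lambda: ClassParams(
        habitat_mean=(0.543, 0.415, 0.042),
        habitat_concentration=6.92,
        ei_median=3.445,
        ei_log_sd=0.946,
        radc_mean_median=0.968,
        radc_mean_log_sd=0.194,
        radc_dif_median=0.461,
        radc_dif_log_sd=0.408,
        age_mean=56.9,
        age_sd=12.7,
        diameter_median_mm=31.1,
        diameter_log_sd=0.600,
        p_male=30 / 64,
        p_headache=26 / 64,
        p_midline=38 / 64,
    ))
    vm: VMCoupling = field(default_factory=VMCoupling)
    phantom: PhantomParams = field(default_factory=PhantomParams)
    radc_split: float = 0.63  # share of rADCdif above the mean
    severity_coupling: float = 0.5  # within-class latent-factor correlation
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("need at least 2 patients")
        if not 0.0 <= self.pcnsl_prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if self.n_patients >= 10 and self.pcnsl_prevalence in (0.0, 1.0):
            raise ConfigurationError("both classes need nonzero prevalence for n >= 10")
        if not 0.0 < self.radc_split < 1.0:
            raise ConfigurationError("radc_split must lie in (0, 1)")
        if not 0.0 <= self.severity_coupling < 1.0:
            raise ConfigurationError("severity_coupling must lie in [0, 1)")
        self.gbm.validate()
        self.pcnsl.validate()
        self.vm.validate()
        self.phantom.validate()

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["schema_version"] = 1
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        d.pop("schema_version", None)
        cfg = cls(
            n_patients=d["n_patients"],
            pcnsl_prevalence=d["pcnsl_prevalence"],
            gbm=ClassParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["gbm"].items()}),
            pcnsl=ClassParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["pcnsl"].items()}),
            vm=VMCoupling(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["vm"].items()}),
            phantom=PhantomParams(**{k: tuple(v) if isinstance(v, list) else v for k, v in d["phantom"].items()}),
            radc_split=d.get("radc_split", 0.63),
            rng_seed=d.get("rng_seed", 0),
        )
        cfg.validate()
        return cfg


def default_config(**overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(**overrides) if overrides else SyntheticConfig()
    cfg.validate()
    return cfg


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, size: int) -> np.ndarray:
    if log_sd == 0:
        return np.full(size, median)
    return np.exp(rng.normal(math.log(median), log_sd, size))


def gen_cohort(
    config: SyntheticConfig,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns (records, ground_truth) DataFrames, one row each
    per patient, joined on ``patient_id``.

    ``records`` carries what the imaging/clinical pipeline would observe;
    ``ground_truth`` the latent generative values (including VM densities and
    the continuous-VM positivity probability).  Deterministic given the seed
    (``config.rng_seed`` unless overridden).
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    n = config.n_patients
    cls = (rng.random(n) < config.pcnsl_prevalence).astype(int)

    f = np.empty((n, 3))
    ei = np.empty(n)
    radc_mean = np.empty(n)
    radc_dif = np.empty(n)
    age = np.empty(n)
    diameter = np.empty(n)
    male = np.empty(n, dtype=int)
    headache = np.empty(n, dtype=int)
    midline = np.empty(n, dtype=int)

    # One latent "severity" factor per patient couples the imaging markers
    # within class (Gaussian copula): marginals stay exactly as configured,
    # but a habitat-1-rich tumor also tends to have a higher edema index and
    # lower rADC, as in real cohorts, so the predictors are partly redundant.
    from scipy import stats as sps  # local import keeps module load light

    u = rng.normal(0.0, 1.0, n)
    r = math.sqrt(config.severity_coupling)
    q = math.sqrt(1.0 - config.severity_coupling)

    for c, params in ((0, config.gbm), (1, config.pcnsl)):
        sel = cls == c
        m = int(sel.sum())
        if m == 0:
            continue
        mean_f = np.asarray(params.habitat_mean, dtype=float)
        if math.isinf(params.habitat_concentration):
            f[sel] = mean_f
        else:
            alphas = params.habitat_concentration * np.maximum(mean_f, 1e-9)
            # correlate only the habitat-1 gamma component with the latent
            # factor; components stay mutually independent, so (f1, f2, f3)
            # remains exactly Dirichlet
            z1 = r * u[sel] + q * rng.normal(0.0, 1.0, m)
            p1 = np.clip(sps.norm.cdf(z1), 1e-12, 1.0 - 1e-12)
            g1 = sps.gamma.ppf(p1, alphas[0])
            g2 = rng.gamma(alphas[1], size=m)
            g3 = rng.gamma(alphas[2], size=m)
            g = np.column_stack([g1, g2, g3])
            f[sel] = g / g.sum(axis=1, keepdims=True)

        def score(sign: float) -> np.ndarray:
            return sign * r * u[sel] + q * rng.normal(0.0, 1.0, m)

        if params.ei_log_sd == 0 or params.ei_median == 1.0:
            ei[sel] = params.ei_median
        else:
            ei[sel] = 1.0 + np.exp(
                math.log(params.ei_median - 1.0) + params.ei_log_sd * score(+1.0)
            )
        radc_mean[sel] = np.exp(
            math.log(params.radc_mean_median) + params.radc_mean_log_sd * score(-1.0)
        )
        radc_dif[sel] = np.exp(
            math.log(params.radc_dif_median) + params.radc_dif_log_sd * score(-1.0)
        )
        age[sel] = params.age_mean + (rng.normal(0, params.age_sd, m) if params.age_sd > 0 else 0.0)
        diameter[sel] = _lognormal(rng, params.diameter_median_mm, params.diameter_log_sd, m)
        male[sel] = rng.random(m) < params.p_male
        headache[sel] = rng.random(m) < params.p_headache
        midline[sel] = rng.random(m) < params.p_midline

    # keep rADCmin positive: cap the spread below the mean
    low_share = 1.0 - config.radc_split
    radc_dif = np.minimum(radc_dif, (radc_mean - 0.02) / low_share)
    radc_max = radc_mean + config.radc_split * radc_dif
    radc_min = radc_mean - low_share * radc_dif

    vm = config.vm
    bf = np.asarray(vm.dvm_beta_f)
    dvm = vm.dvm_intercept + f @ bf + vm.dvm_beta_class * cls
    dvm = np.maximum(0.0, dvm + (rng.normal(0, vm.dvm_noise_sd, n) if vm.dvm_noise_sd > 0 else 0.0))
    be = np.asarray(vm.endo_beta_f)
    endo = vm.endo_intercept + f @ be + vm.endo_beta_class * cls
    endo = np.maximum(0.0, endo + (rng.normal(0, vm.endo_noise_sd, n) if vm.endo_noise_sd > 0 else 0.0))
    bc = np.asarray(vm.cont_beta_f)
    cont_prob = np.clip(vm.cont_intercept + f @ bc + vm.cont_beta_class * cls, 0.0, 1.0)

    ids = [f"P{i:04d}" for i in range(n)]
    records = pd.DataFrame(
        dict(
            patient_id=ids,
            diagnosis=np.where(cls == 1, "PCNSL", "GBM"),
            pcnsl=cls,
            age=age,
            male=male,
            headache=headache,
            midline=midline,
            diameter_mm=diameter,
            f1=f[:, 0],
            f2=f[:, 1],
            f3=f[:, 2],
            ei=ei,
            radc_mean=radc_mean,
            radc_max=radc_max,
            radc_min=radc_min,
            radc_dif=radc_dif,
        )
    )
    truth = pd.DataFrame(
        dict(
            patient_id=ids,
            pcnsl=cls,
            f1=f[:, 0],
            f2=f[:, 1],
            f3=f[:, 2],
            ei=ei,
            radc_mean_target=radc_mean,
            diameter_mm=diameter,
            dvm_density=dvm,
            endo_density=endo,
            cont_positivity_prob=cont_prob,
        )
    )
    return records, truth


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer counts summing to ``total`` with largest-remainder rounding."""
    quotas = np.asarray(fractions, dtype=float) * total
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for i in range(int(short)):
        base[order[i]] += 1
    return base


def render_phantom(
    f: tuple[float, float, float],
    ei: float,
    radc_mean_target: float,
    diameter_mm: float,
    shape: tuple[int, int, int] | None = None,
    params: PhantomParams | None = None,
    seed: int = 0,
    layout: str | None = None,
) -> tuple[VoxelGrid, VoxelGrid, SegmentationMasks]:
    """Render one two-channel phantom realizing a ground-truth record.

    Returns (t1ce, adc, masks).  The tumor is an ellipsoid with Feret
    diameter ``diameter_mm``; its voxels are split into the three habitats
    with counts given by largest-remainder rounding of ``f``; the edema
    shell holds round((EI - 1) * tumor voxels) voxels; the reference-region
    ADC is set so that rADCmean equals ``radc_mean_target`` for the rendered
    tumor.  With ``shape=None`` a grid just large enough is chosen.
    """
    params = params or PhantomParams()
    params.validate()
    layout = layout or params.layout
    if layout not in ("shells", "speckled"):
        raise ConfigurationError("layout must be 'shells' or 'speckled'")
    f = np.asarray(f, dtype=float)
    if f.shape != (3,) or not np.isclose(f.sum(), 1.0) or (f < 0).any():
        raise ConfigurationError(f"fractions must be nonnegative and sum to 1, got {f}")
    if ei < 1:
        raise ConfigurationError("EI must be >= 1")
    if radc_mean_target <= 0 or diameter_mm <= 0:
        raise ConfigurationError("rADC target and diameter must be positive")

    spacing = np.asarray(params.spacing, dtype=float)
    semi = np.array([diameter_mm / 2.0, 0.85 * diameter_mm / 2.0, 0.80 * diameter_mm / 2.0])
    outer = semi * ei ** (1.0 / 3.0)  # edema outer ellipsoid (same shell shape)
    if shape is None:
        margin = 4.0  # mm on each side
        shape = tuple(int(np.ceil((2 * o + 2 * margin) / s)) + 1 for o, s in zip(outer, spacing))
        # room for the reference box in the corner
        shape = tuple(max(m, 12) for m in shape)

    shape = tuple(int(m) for m in shape)
    rng = np.random.default_rng(seed)
    idx = np.indices(shape, dtype=float)
    coords = idx * spacing[:, None, None, None]
    center = (np.asarray(shape) - 1) * spacing / 2.0
    rel = coords - center[:, None, None, None]
    r = np.sqrt(((rel / semi[:, None, None, None]) ** 2).sum(axis=0))
    tumor = r <= 1.0
    n_t = int(tumor.sum())
    if n_t < 3:
        raise SizingError("tumor does not fit the grid (fewer than 3 voxels inside)")
    # tumor must not touch the grid boundary
    b = np.zeros(shape, dtype=bool)
    b[0, :, :] = b[-1, :, :] = True
    b[:, 0, :] = b[:, -1, :] = True
    b[:, :, 0] = b[:, :, -1] = True
    if np.any(tumor & b):
        raise SizingError("tumor touches the grid boundary; enlarge the grid")

    # reference region: small box in the low corner, away from the lesion
    ref = np.zeros(shape, dtype=bool)
    ref[1:5, 1:5, 1:3] = True
    if np.any(ref & (r <= ei ** (1.0 / 3.0) + 0.2)):
        raise SizingError("reference box overlaps the lesion neighbourhood; enlarge the grid")

    counts = _largest_remainder(f, n_t)
    tumor_idx = np.argwhere(tumor)
    r_t = r[tumor]
    if layout == "shells":
        order = np.argsort(-r_t, kind="stable")  # rim first
    else:
        order = rng.permutation(n_t)
    habitat = np.zeros(shape, dtype=int)
    start = 0
    for h, c in enumerate(counts, start=1):
        sel = tumor_idx[order[start:start + c]]
        habitat[sel[:, 0], sel[:, 1], sel[:, 2]] = h
        start += c

    n_e = int(round((ei - 1.0) * n_t))
    edema = np.zeros(shape, dtype=bool)
    if n_e > 0:
        cand = ~tumor & ~ref & ~b
        cand_idx = np.argwhere(cand)
        cand_r = r[cand]
        if n_e > cand_idx.shape[0]:
            raise SizingError(
                f"edema needs {n_e} voxels but only {cand_idx.shape[0]} are available"
            )
        take = cand_idx[np.argsort(cand_r, kind="stable")[:n_e]]
        edema[take[:, 0], take[:, 1], take[:, 2]] = True

    t1 = np.full(shape, params.background_t1ce)
    adc = np.full(shape, params.background_adc)
    t1[edema] = params.edema_t1ce
    adc[edema] = params.edema_adc
    for h in (1, 2, 3):
        sel = habitat == h
        t1[sel] = params.t1ce_means[h - 1]
        adc[sel] = params.adc_means[h - 1]
    if params.t1ce_noise_sd > 0:
        t1 = t1 + rng.normal(0, params.t1ce_noise_sd, shape)
    if params.adc_noise_sd > 0:
        adc = adc + rng.normal(0, params.adc_noise_sd, shape)

    adc[ref] = float(adc[tumor].mean()) / radc_mean_target

    sp = tuple(spacing)
    return (
        VoxelGrid(t1, sp),
        VoxelGrid(adc, sp),
        SegmentationMasks(tumor, edema, ref, sp),
    )


@dataclass
class VMCounts:
    """Per-slide box counts for one patient (optionally several observers)."""

    dvm_counts: np.ndarray  # (n_observers, 10)
    endo_counts: np.ndarray
    cont_flags: np.ndarray
    box_area_mm2: float = 0.275

    def sheet(self, patient: str) -> pd.DataFrame:
        rows = []
        n_obs, n_box = self.dvm_counts.shape
        for o in range(n_obs):
            for bx in range(n_box):
                rows.append(
                    dict(
                        patient=patient,
                        box=bx + 1,
                        observer=o + 1,
                        discrete_vm=int(self.dvm_counts[o, bx]),
                        endothelial=int(self.endo_counts[o, bx]),
                        continuous_flag=int(self.cont_flags[o, bx]),
                    )
                )
        return pd.DataFrame(rows)


def gen_vm_counts(
    dvm_density: float,
    endo_density: float,
    cont_positivity: float,
    seed: int = 0,
    n_boxes: int = 10,
    n_observers: int = 1,
    box_area_mm2: float = 0.275,
) -> VMCounts:
    """Draw box counts: Poisson with mean density x box area; flags Bernoulli."""
    if dvm_density < 0 or endo_density < 0:
        raise ConfigurationError("densities must be nonnegative")
    if not 0.0 <= cont_positivity <= 1.0:
        raise ConfigurationError("positivity probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = (n_observers, n_boxes)
    return VMCounts(
        dvm_counts=rng.poisson(dvm_density * box_area_mm2, shape),
        endo_counts=rng.poisson(endo_density * box_area_mm2, shape),
        cont_flags=(rng.random(shape) < cont_positivity).astype(int),
        box_area_mm2=box_area_mm2,
    )


def make_vm_sheet(
    truth: pd.DataFrame,
    patients: list[str] | None = None,
    seed: int = 0,
    n_observers: int = 3,
) -> pd.DataFrame:
    """Long-format VM counting sheet for a subset of patients."""
    if patients is None:
        patients = list(truth["patient_id"])
    rng = np.random.default_rng(seed)
    sheets = []
    t = truth.set_index("patient_id")
    for pid in patients:
        row = t.loc[pid]
        vc = gen_vm_counts(
            float(row["dvm_density"]),
            float(row["endo_density"]),
            float(row["cont_positivity_prob"]),
            seed=int(rng.integers(0, 2**31 - 1)),
            n_observers=n_observers,
        )
        sheets.append(vc.sheet(pid))
    return pd.concat(sheets, ignore_index=True)


def simulate_dataset(
    config: SyntheticConfig,
    out_dir: str | Path,
    seed: int | None = None,
    render: bool = True,
    vm_subset: int = 19,
) -> Path:
    """Write a full synthetic dataset: cohort CSV, truth CSV, VM sheet CSV,
    config YAML and (optionally) per-patient NIfTI phantoms."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = config.rng_seed if seed is None else seed
    records, truth = gen_cohort(config, seed=base_seed)
    records.to_csv(out / "cohort.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    config.to_yaml(out / "config.yaml")

    rng = np.random.default_rng(base_seed + 1)
    k = min(vm_subset, len(truth))
    vm_patients = list(rng.choice(truth["patient_id"], size=k, replace=False))
    sheet = make_vm_sheet(truth, vm_patients, seed=base_seed + 2)
    sheet.to_csv(out / "vm_sheet.csv", index=False)

    if render:
        for i, row in truth.iterrows():
            pdir = out / "images" / row["patient_id"]
            pdir.mkdir(parents=True, exist_ok=True)
            t1, adc, masks = render_phantom(
                (row["f1"], row["f2"], row["f3"]),
                float(row["ei"]),
                float(row["radc_mean_target"]),
                float(row["diameter_mm"]),
                params=config.phantom,
                seed=base_seed + 10 + i,
            )
            t1.save(pdir / "t1ce.nii.gz")
            adc.save(pdir / "adc.nii.gz")
            masks.save(pdir)
    return out
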