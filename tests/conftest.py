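import numpy as np
import pytest

from habitatmri.synthetic import PhantomParams, default_config


@pytest.fixture
def noiseless_params() -> PhantomParams:
    return PhantomParams(t1ce_noise_sd=0.0, adc_noise_sd=0.0)


@pytest.fixture
def cohort_config():
    return default_config()


def small_render_config(n_patients: int = 20, seed: int = 0):
    """Cohort config with compact lesions so phantom grids stay small."""
    cfg = default_config()
    cfg.n_patients = n_patients
    cfg.rng_seed = seed
    for cls in (cfg.gbm, cfg.pcnsl):
        cls.diameter_median_mm = 16.0
        cls.diameter_log_sd = 0.1
        cls.ei_median = 1.6
        cls.ei_log_sd = 0.2
    return cfg


def brute_force_kmeans_sse(points: np.ndarray, k: int) -> float:
    """Global K-means optimum by exhaustive enumeration of label assignments.

    Independent oracle for tiny instances (k^n assignments); empty clusters
    are allowed in the enumeration (they can never beat the optimum).
    """
    n = points.shape[0]
    best = np.inf
    for code in range(k**n):
        labels = np.empty(n, dtype=int)
        c = code
        for i in range(n):
            labels[i] = c % k
            c //= k
        sse = 0.0
        for lab in range(k):
            sel = points[labels == lab]
            if len(sel):
                sse += ((sel - sel.mean(axis=0)) ** 2).sum()
        if sse < best:
            best = sse
    return float(best)
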