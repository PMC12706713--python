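# Methods

`habitatmri` implements a tumor-habitat analysis for distinguishing atypical
glioblastoma (GBM, minimal/no necrosis on MRI) from primary CNS lymphoma
(PCNSL) on routine multiparametric MRI, together with a synthetic
cohort/phantom generator that makes every stage testable without patient
data. This note records the models, the defaults and why they were chosen,
and what the synthetic experiments do and do not demonstrate.

## Habitat model

Each tumor voxel carries a two-channel feature (T1-CE, ADC). T1-CE is first
mapped to 0–255 with a gradient-anchored window (below); ADC stays in its
native units (×10⁻⁶ mm²/s). Voxels inside the tumor mask are clustered by
K-means with k = 3 after z-scoring each channel *within the tumor* — the two
channels differ by an order of magnitude in scale, and unscaled ADC would
dominate the Euclidean distance. Clustering is per patient: "high" and "low"
are relative statements about one tumor, so pooling voxels across patients
would mix acquisition scales (a pooled mode exists but is off by default).

Clusters are renamed to habitats by their centroid signature:

* **Habitat 3** (nonviable tissue): maximal mean ADC;
* **Habitat 1** (high-enhancement cellular): of the remaining two, higher
  mean T1-CE;
* **Habitat 2** (low-enhancement cellular): the other.

The fourth conceivable signature (high enhancement with high ADC) gets no
label of its own; if the maximal-ADC centroid also has the strictly maximal
T1-CE the same rule applies and a warning is recorded. Habitat fractions
f1, f2, f3 are voxel counts over the tumor voxel count.

K-means details: k-means++ initialization, 10 restarts (best SSE kept),
fixed seed recorded in the run manifest. On tiny instances (≤ 8 voxels) the
resulting SSE is verified against exhaustive enumeration of all label
assignments in the test suite.

## Preprocessing

Volumes are assumed bias-corrected and co-registered (standard external
steps); the pipeline resamples to 1 × 1 × 3 mm (linear for intensities,
nearest-neighbour for masks, nearest-neighbour extrapolation at the
half-voxel boundary so constant fields stay constant) and validates
grid alignment per patient.

The 0–255 normalization is anchored to the image gradient: within the body
mask, voxels whose central-difference gradient magnitude exceeds its
within-mask mean form the edge set E; the mean μ and SD σ of the *original*
intensities over E define the window [μ − 3σ, μ + 3σ], mapped linearly to
[0, 255] and clipped. Because the gradient of aI + b is a·∇I, E is invariant
under positive affine rescaling and the window rescales with the data, so
the mapping is affine-invariant (verified numerically). The exact windowing
rule used by any particular scanner pipeline is not recoverable from
published descriptions; this concrete rule is a documented design choice,
not a claim about the original. A constant image (window width 0) is a
degenerate-input error; if only the edge voxels are constant the window
falls back to the within-mask range.

## Imaging metrics

* **Edema index**: EI = (tumor voxels + edema voxels) / tumor voxels on the
  resampled grid. EI ≥ 1; EI = 1 means no peritumoral edema.
* **rADC**: tumor ADC statistic divided by the mean ADC of a user-supplied
  reference region (intended: contralateral normal-appearing white matter —
  the conventional "relative ADC" denominator; in phantoms, the generated
  reference box). rADCmean/max/min are the mean and voxelwise extrema;
  rADCdif = rADCmax − rADCmin. Extrema exclude the top/bottom 0.5% of tumor
  voxels by default (single-voxel extrema are acquisition-noise dominated;
  configurable, `trim=0` for raw extrema).
* **Diameter**: 3-D Feret diameter — maximal pairwise distance between tumor
  voxel centers in physical coordinates, computed on the convex hull
  (brute force for degenerate clouds); 0 for a single voxel.

## Group statistics

Conventions: Pearson chi-square on 2×2 tables **without** continuity
correction (this reproduces the published cohort p-values 0.419 / 0.253 /
0.336 from the printed counts; with Yates correction it does not); Welch
t-test by default (both Welch and pooled reproduce the published age
p = 0.013 at three decimals); Shapiro–Wilk at α = 0.05 only gates which test
a summary table reports, never silently overrides an explicit request.
Mann–Whitney and Wilcoxon signed-rank use exact enumeration on midranks for
small samples (combined n ≤ 12; ≤ 15 nonzero pairs) — exact under ties —
and tie-corrected normal approximations otherwise. ROC analysis uses the
Mann–Whitney AUC estimator (ties ½), DeLong 95% CIs (cross-checked against
pROC), and the Youden-optimal cutoff at the midpoint between adjacent
observed scores, ties resolved toward higher sensitivity. Inter-rater
agreement is ICC(2,1) — two-way random effects, absolute agreement, single
measure — from the mean-squares decomposition (cross-checked against
pingouin); a consistency variant ICC(3,1) is available. Medians and
quartiles use the linear-interpolation convention.

## Diagnostic model

Outcome coding: PCNSL = 1, so a positive EI coefficient is PCNSL-ward.
Candidate predictors (age, diameter, f1–f3, EI, four rADC statistics) are
screened univariably (keep p < 0.05), then backward stepwise elimination
from the full model removes whichever deletion most decreases AIC (ties:
drop the larger Wald p) until no deletion helps; habitat fractions enter as
proportions in [0, 1] (hence large ORs for a full 0→1 swing). The final
refit reports B, SE, OR = exp(B), 95% CI = exp(B ± 1.96·SE), Wald p, AIC,
and per-term tolerance/VIF (VIF = 1/tolerance from the OLS R² of each
predictor on the others). Complete cases only. Quasi-separation is flagged
(diverging coefficients / singular Hessian with a BFGS fallback), not
silently accepted. Stepwise direction is backward-only by design; forward
variants were deliberately not implemented.

The **nomogram** assigns predictor j at value x the points
100·|B_j|·(x − ref_j)/max_j(|B_j|·range_j) with the reference at the
low-risk end of its display range, so the widest-effect predictor spans
exactly 0–100 and total points reconstruct the model probability exactly
(round-trip error ≤ 10⁻¹⁰ in tests).

**Calibration**: Hosmer–Lemeshow with deciles-of-risk bins (ties kept
together; bins merge when tied probabilities straddle a boundary, reducing
df = bins − 2), statistic Σ(O−E)²/(E(1−E/n_g)); and Harrell's optimism
correction — each bootstrap resample refits the selected terms, the
calibration slope/intercept difference between resample and original data is
averaged and subtracted from the apparent values (1000 resamples by default;
single-class or separated resamples are skipped and counted). Note the
df = bins − 2 convention presumes the probabilities come from a model fitted
on the same data; with known true probabilities the statistic is
approximately χ²(bins), which matters when simulating nulls.

**Decision curves**: net benefit NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) with
"treat" meaning predicted probability ≥ p_t, against treat-all and
treat-none references on a 0.01-step grid by default.

**Cohort split**: training size is ⌈0.7·n⌉ (125 → 88/37), stratified by
class via largest-remainder apportionment so the total is exact.

## Vasculogenic-mimicry quantification

Counting protocol: 10 boxes of 550 × 500 μm (0.275 mm²) in viable tumor;
discrete-VM and endothelial counts per box, continuous-VM presence flags per
box. Density = mean count / box area (vessels/mm²); continuous-VM positivity
= fraction of flagged boxes (a per-patient any-box-positive binary is also
reported, since "positivity rate" can be read either way). Multi-observer
sheets are averaged per box before densities. The habitat~vasculature
regressions (one per habitat fraction, OLS on discrete-VM density,
endothelial density, continuous positivity) report standardized β, t,
adjusted R², overall F, and Durbin–Watson on residuals in input order.

## Synthetic cohort generator

The generator *is* the study-condition definition: class-conditional
distributions are calibrated to the published 125-patient cohort summaries.

* Habitat fractions: Dirichlet per class; means (0.395, 0.525, 0.080) for
  GBM and (0.543, 0.415, 0.042) for PCNSL (third components from the
  sum-to-one constraint on the reported means/medians), concentrations 10.85
  and 6.92 matched to the reported f1 SDs (14.2% / 17.7%).
* EI: 1 + LogNormal — medians preserved exactly (2.008 / 3.445); log-SDs
  1.386 / 0.946 fitted to the reported quartiles.
* rADCmean and rADCdif: LogNormal, medians 1.201 / 0.968 and 0.624 / 0.461,
  log-SDs from quartiles; rADCmax/min sit at a fixed split (63% of rADCdif
  above the mean, from the reported mean/max/min geometry), with rADCdif
  capped so rADCmin stays positive.
* Age Normal (50.6 ± 15.0 / 56.9 ± 12.7); diameter LogNormal (medians
  47.3 / 31.1 mm); sex/headache/midline Bernoulli at the reported rates;
  PCNSL prevalence 64/125.
* **Within-class severity coupling** (default 0.5): one latent N(0,1) factor
  per patient enters the normal scores of EI (+), rADCmean (−), rADCdif (−)
  and the habitat-1 gamma component (+) via a Gaussian copula. Marginals are
  exactly the configured distributions (the gamma components stay mutually
  independent, so the fractions remain exactly Dirichlet); what changes is
  that the markers become partly redundant within class, as in real tumors
  where one biological axis drives them jointly. The strength was calibrated
  so the selected model's training AUC over simulated 125-patient cohorts
  has a realistic distribution (median ≈ 0.86, central 90% interval
  ≈ [0.77, 0.93]); without coupling the independent signals stack and AUC
  concentrates implausibly around 0.92.
* VM coupling: discrete-VM density = max(0, 0.3 + 30·f1 − 20·f2 + ε),
  endothelial density = max(0, 10.475 + 35·f1 − 9·class + ε), continuous-VM
  positivity probability = clip(0.28 − 3·f3 + 0.14·class, 0, 1) — signs
  chosen to match the reported habitat~VM regressions (+ on f1 for both
  densities, − on f2 for discrete VM, − on f3 for continuous positivity)
  and magnitudes calibrated by simulation so the n = 19 standardized betas
  are comparable to the reported ones (≈ 0.69 for discrete VM on f1, ≈ −0.71
  for continuous positivity on f3) while the group anchors stay near the
  reported values (discrete-VM medians ≈ 2 vs ≈ 9 /mm², endothelial means
  ≈ 24 vs ≈ 21 /mm², positivity ≈ 0.12 vs ≈ 0.31). Box counts are Poisson
  (mean = density × 0.275 mm²), flags Bernoulli, per observer.
* All nonnegative quantities are truncated/clipped (documented
  truncated-normal / clipped-linear sampling).

**Phantoms** realize a record as an ellipsoidal tumor (semi-axes
d/2 × 0.85·d/2 × 0.80·d/2, so the Feret diameter equals d) whose voxels are
split into habitats by largest-remainder rounding of (f1, f2, f3) —
concentric shells by default (Habitat 1 rim, Habitat 2 middle, Habitat 3
core), with a "speckled" random layout for stress-testing, since no spatial
arrangement is asserted to be the true one. The edema shell holds
round((EI−1)·tumor voxels) voxels grown outward; a corner reference box gets
the ADC value that makes rADCmean hit its target exactly. Habitat intensity
signatures: T1-CE (200, 90, 80) raw units with noise SD 10; ADC (700, 750,
1600) ×10⁻⁶ mm²/s with noise SD 60 — chosen as realistic contrasts (tumor
ADC ≈ 0.7–0.8, necrosis ≈ 1.6 ×10⁻³ mm²/s) with noise well below the
habitat separation.

### What the phantoms do and do not emulate

They realize the habitat *composition*, EI, rADCmean and diameter of each
record with the three canonical intensity signatures, and they are exactly
recoverable: the full pipeline (normalize → cluster → fractions → EI →
rADC) returns the generative values to the voxel on noiseless phantoms, and
within 2 percentage points at the default noise. They contain no anatomy
(skull, ventricles), no bias fields, no partial-volume mixing, no motion,
and habitat geometry is schematic. Passing phantom tests therefore
demonstrates the *computational* correctness of the pipeline under the
stated noise model, not segmentation robustness on clinical images.

## Problem sizes used in the test and acceptance runs

Phantom recovery uses 20 tumors of 18 mm diameter at (1, 1, 3) mm spacing;
selection-recovery simulations use 100 runs at n = 500 (4 true + 4 noise
candidates, slopes ±0.8); the Hosmer–Lemeshow null uses 500 fitted-model
runs at n = 5000; VM sign recovery uses 200 cohorts of n = 19 (10 GBM /
9 PCNSL, as in the histology subset); generator calibration uses one
10⁴-patient cohort; the AUC-coverage check uses 200 cohorts of n = 125.

## Known limitations

* **Quarter-separation noise**: at per-channel noise equal to ¼ of the
  habitat contrast, nearest-centroid assignment — Bayes-optimal for equal
  isotropic Gaussians — already misassigns ≈ Φ(−2) ≈ 2.3% of voxels per
  adjacent cluster pair, and K-means' equal-cluster-size bias turns this
  into net fraction shifts of several percentage points for skewed
  compositions. Fraction recovery within ±2 points holds comfortably at the
  default noise (about 1/10 of the separation) but cannot hold at the ¼
  boundary for arbitrary compositions.
* **Vanishing habitats**: k is fixed at 3; when a tumor's true third-habitat
  volume is ≈ 0 the clusterer must split a real habitat, inflating the
  measured f3 by up to tens of percentage points for such patients (mean
  bias ≈ +4 points on full simulated cohorts). This mirrors the method as
  used in practice, where every tumor is forced into three habitats.
* The optimism-corrected calibration slope is noisy below ~100 patients;
  small-cohort corrected slopes well below 1 reflect genuine overfitting of
  the selected model, not a bug.
* Generator covariates beyond the severity factor (age, diameter, sex,
  symptoms) are conditionally independent given class; real cohorts have
  richer dependence.
* The Hosmer–Lemeshow df inference (bins − 2, merged on ties) reproduces
  printed (χ², p) pairs only under the inferred df; published reports rarely
  state the binning.
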