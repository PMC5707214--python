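# Methods

## Problem

(I123)FP-CIT (DaTSCAN) SPECT measures dopamine-transporter density in the
striatum. Clinically a scan is called normal or abnormal (pre-synaptic
dopaminergic deficit, PDD). Two software families make that call:

* **semi-quantification** — compare each regional striatal binding ratio
  (SBR) against a lower cut-off derived from comparison data and flag the
  scan abnormal if any SBR falls below its limit;
* **machine learning** — train a classifier (here a linear or RBF SVM) on
  SBRs, masked voxel intensities, or principal components of those voxels.

`fpcitbench` implements both families behind a shared cross-validation
harness, plus a synthetic cohort/phantom generator so every stage can be
exercised, compared and unit-tested without access to clinical images.

## Synthetic cohort model

Each subject has age, sex, a class label, and four SBRs
(left/right putamen, left/right caudate; "putamen" uptake is understood to
include the adjacent pallidum, as is conventional in this tracer's
literature). The generating model is:

* age ~ Normal(μ_class, σ_class), floored at 1 year;
* healthy mean SBR of region *r* at age *a*: `m_r(a) = b_r + s·a`, with a
  common negative slope `s` (uptake declines with age);
* disease multiplies `m_r(a)` by `1 − d_r(1 + ℓ·A)` where `d_putamen ≥
  d_caudate` (putamen-dominant degeneration), `ℓ = +1` on the left and −1
  on the right, and `A ~ Normal(0, σ_asym)` is drawn once per subject — the
  lateralisation of the deficit, shared across that subject's regions (the
  effective drop is clipped to [0, 1]);
* independent Normal(0, σ_r) measurement noise per region, with the result
  truncated at 10⁻⁶ to keep ratios positive.

Sex is generated (class-specific male fractions) but used by no method; it
is kept for table fidelity.

### Parameters and defaults

| parameter | research preset | clinical preset | units / rationale |
|---|---|---|---|
| n_normal / n_abnormal | 209 / 448 | 113 / 191 | subjects; typical screened-research vs clinical-archive cohort sizes |
| age mean (SD), normal | 60.8 (11.3) | 68.7 (12.4) | years |
| age mean (SD), abnormal | 61.6 (9.8) | 68.7 (13.3) | years |
| SBR intercept, putamen / caudate | 2.8 / 3.3 | same | ratio at age 0; gives ≈2.5 / 3.0 at age 60, the middle of published normal ranges for this tracer |
| age slope | −0.005 | same | ratio/year; ≈ −5 % per decade relative to a ratio of 1, consistent with the reported magnitude of age decline in transporter binding |
| putamen / caudate drop | 0.55 / 0.35 | 0.45 / 0.25 | fraction of the healthy mean lost to disease |
| asymmetry SD | 0.30 | 0.30 | fractional modulation of the drop between hemispheres |
| SBR noise SD | 0.35 | 0.70 | ratio; 0.35 matches the typical spread of normal putamen SBRs; the clinical preset doubles it |

The two presets are designed to bracket task difficulty: the research
preset is a screened, well-calibrated database (large effect, low noise),
the clinical preset a heterogeneous archive (smaller effect, doubled noise,
wider and older age distribution). Effect sizes and noise levels are this
package's own defaults — chosen once for plausibility, not fitted to any
dataset — so absolute accuracies on synthetic cohorts are not estimates of
any published clinical figure; only the *relationships* between methods and
presets are meaningful, and those are what the acceptance suite asserts.

### What the generator does not emulate

Real acquisition physics (collimator blur, scatter, attenuation, camera
calibration differences), registration error, ROI misplacement, diagnostic
label noise, and non-Gaussian biological variation are all absent. Passing
tests therefore demonstrate the correctness and internal consistency of the
classification and validation machinery on data with the assumed
statistical structure — not clinical performance.

## Bayes-rate oracle

`estimate_bayes_rate` brute-forces the best achievable accuracy for a given
parameterisation: subjects are sampled from the generating model (class
priors = cohort proportions) and classified by the exact posterior. The
normal-class likelihood is a product of Gaussians given age; the
abnormal-class likelihood integrates the shared laterality factor out with
Gauss–Hermite quadrature (61 nodes by default; results are stable from ~31
nodes, and the unit suite cross-checks the likelihood against a dense
trapezoid integration). The positive-truncation of sampled SBRs is ignored
in the density: it moves well under 0.1 % of the research-preset mass and
about 3 % of the clinical abnormal-putamen tail, and a ratio clipped toward
zero is classified abnormal by both the exact and the approximate rule, so
the bias is negligible at the tolerances used. Posterior ties (exactly the
zero-effect case) go to the larger prior, then to "normal".

## Phantom volumes

Phantoms are built directly in template space on a cubic grid (64³ default,
3 mm voxels): ellipsoidal putamen and caudate ROIs placed
mirror-symmetrically about the mid-sagittal plane, a cuboidal occipital
reference, and a loose striatal box (the ROI bounding box plus margin).
Registration is assumed perfect. Each striatal ROI is set to
`background·(1 + SBR)` so that `(target − reference)/reference` recovers
the subject's SBR exactly at zero noise; Gaussian noise with SD
`noise_sd·background` is then added voxel-wise and the volume clipped
non-negative. Masks are exported as a bit-field label map (regions nest,
so exclusive integer labels cannot represent them) with a JSON sidecar.

## Semi-quantification conventions

Several details are under-determined in common clinical practice; the
package fixes them as follows (each is either configurable or documented):

* **SD definition** — sample SD (n−1) for mean − k·SD limits.
* **Regression band** — "k standard errors" means k times the residual
  standard error √(RSS/(n−2)) of the normal-population fit of SBR on age,
  i.e. the spread of individuals about the age trend (that is what a
  normal *range* subtracts); the standard error of the predicted mean is
  available via `se_kind="mean"`.
* **Boundary** — an SBR exactly equal to its cut-off is within normal
  limits; the decision rule uses strict `<`.
* **ROC cut-off** — candidates are midpoints between consecutive distinct
  pooled training values plus one sentinel below the minimum and one above
  the maximum; accuracy of "abnormal iff value < c" is maximised and ties
  break toward the smallest candidate (favouring specificity). The
  acceptance suite verifies exact agreement with an exhaustive search over
  every threshold interval.
* **Age matching** — window ±5 years, inclusive. If fewer than 5
  comparators (per class, for two-class ROC variants) are found, the window
  widens symmetrically in 1-year steps (logged) rather than aborting a
  cross-validation run; a hard `max_window` still raises.
* **Method catalogue** — the two ROC variants trained on all data are
  SQ 15/16 and the age-matched ROC variants are SQ 17/18; the "lowest
  putamen/caudate" discriminant is the per-subject minimum of the left and
  right SBR, thresholded directly.

## ML pipeline conventions

* The classifier contract (soft-margin maximum-margin, linear or RBF) is
  fulfilled by scikit-learn's `SVC`; PCA and standardization are likewise
  library-backed. The pipeline logic around them is owned here.
* **PCA is fitted inside each training fold** (inner folds included);
  fitting it on pooled data would leak test information.
* Age is appended as the last feature column of every family, bypasses the
  PCA, and is standardized like any other feature. A switch
  (`standardize_projected`) selects whether standardization happens after
  projection (default) or on the voxel block before it.
* Grid search: C ∈ 2⁻³…2⁸, γ ∈ 2⁻⁸…2³ (×2 steps); γ is dropped for the
  linear kernel. Scored by mean F-score (positive class = abnormal) over a
  stratified 10-fold inner loop, single repetition. Ties break toward
  smaller C, then smaller γ, for determinism. The scaler/PCA are fitted
  once per inner fold and shared across grid points — the fit is identical
  for every (C, γ), so this changes nothing but run time.
* Voxel-feature pipelines allow only the linear kernel: with far more
  voxels than subjects the problem is already ill-posed and a kernel adds
  overfitting risk without capacity benefit.

## Cross-validation harness

Stratified k-fold (default k = 10), repeated (default 10×) with fresh
seeded partitions per repeat; per-repeat seeds derive from the master seed
by a fixed counter scheme recorded in the report header, all below 2³¹.
Within a repeat every method sees identical splits, so method comparisons
are paired. Nested hyperparameter selection runs entirely inside each
outer training split. A method failing on a fold (e.g. comparator
exhaustion on a pathological split) records the cell as missing; summaries
report coverage. Reports are written as a 2-decimal CSV plus a
full-precision JSON twin, and the whole experiment is a pure function of
(config, seed) — byte-identical on re-run.

## Problem sizes used by the test and acceptance suites

Benchmark experiments run at n = 300 subjects per cohort (class ratios
95/205 research-shaped, 112/188 clinical-shaped), k = 10 with 3 repeats,
phantoms on a 32³ grid (the geometry is scale-free plumbing; ROI layout and
all invariants are identical to the 64³ default, which the round-trip
checks use). The research benchmark covers all 18 semi-quantification
methods plus ML1 and ML12 over five generator seeds; the
research-vs-clinical difficulty ordering is checked on a six-method panel
(SQ1, SQ7, SQ13, SQ15, ML1, ML12 — one per cut-off family plus both ML
feature families). Monotonicity properties are checked on 50 seeded
cohorts with a fixed stratified split each.

## Known limitations

* Synthetic SBR noise is Gaussian and independent across regions given the
  laterality factor; real regional uptakes correlate through global
  factors and registration.
* The Bayes oracle ignores the positive-truncation of sampled ratios (see
  above) and assumes the generator's own densities — it is an oracle for
  synthetic data only.
* Statistical significance between methods is deliberately out of scope
  (repeated reuse of the same subjects makes naive tests invalid).
* The voxel feature family reflects phantom geometry, not real striatal
  shape variation, so image-based pipelines are exercised mechanically
  rather than anatomically.
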