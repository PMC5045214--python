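# Methods

`neuromkl` implements a multi-feature discrimination framework for
two-group resting-state neuroimaging cohorts: four regional feature
channels are extracted per subject, selected fold-wise, combined through
a multi-kernel support vector machine, and evaluated by leave-one-out
cross-validation (LOOCV). This note records the model, the numerical
choices, and what the synthetic-data checks do and do not establish.

## Feature channels

All channels are regional: a labelled parcellation (N regions of
interest) reduces voxel maps to length-N vectors per subject.

**ALFF** (amplitude of low-frequency fluctuations). For each voxel's
demeaned series the one-sided amplitude spectrum A_k = 2|X_k|/T is
averaged over DFT bins with 0.01 Hz ≤ f_k ≤ 0.08 Hz. The mean (rather
than the sum) over bins makes the value invariant to series length; the
raw periodogram is used, untapered — a tapered estimate would change
values by a smooth factor that cancels under the global-mean scaling
below. Each subject's map is divided by its global mean (so the masked
mean is exactly 1), then averaged per ROI.

**ReHo** (regional homogeneity). Kendall's coefficient of concordance
over each voxel's K-voxel cluster (K = 7, 19 or 27; default 27):

    W = 12 · Σ_t (R_t − R̄)² / (K²(T³ − T)),

where R_t is the rank-sum across the K series at time point t and ranks
within a series use midranks for ties. W ∈ [0, 1]. W is computed only
where the full cluster lies inside the volume and mask: variable-K
boundary clusters would bias W downward at edges, so boundary voxels
are masked out instead. A cluster in which every series is constant has
no defined concordance and is flagged and masked. ReHo maps are
global-mean scaled and averaged per ROI; an ROI with no interior voxel
yields no ReHo feature and is dropped from that channel's table.

**RFCS** (regional functional correlation strength). ROI mean series are
band-passed (ideal DFT-mask filter with exact band edges — no filter
order to choose), optionally residualized against user-supplied nuisance
covariates (ordinary least squares with intercept), and correlated
pairwise (Pearson). Then

    S(i) = (1/(N−1)) · Σ_{j≠i} |R_ij| ∈ [0, 1].

Band-pass precedes correlation; correlations use filtered series.

**GM** (gray matter). Regional means of the structural map. Smoothing
stages (isotropic Gaussian, FWHM in voxels) exist for both functional
and structural maps but default to off: on desk-scale synthetic grids a
millimetre-specified kernel is ill-posed, and smoothing is a
preprocessing concern, not part of the statistics under test.

## Fold-wise selection

Inside each LOOCV fold, using training rows only:

1. **z-scoring** — each feature is centred and scaled by its training
   mean and population standard deviation (the `StandardScaler`
   convention); the held-out subject is transformed with the same
   statistics. Features with (numerically) zero training variance are
   dropped with a warning.
2. **t filter** — pooled-variance two-sample t-test per feature, keep
   p < α (default 0.05, uncorrected, per the framework's design; no
   multiplicity correction is intended here).
3. **SVM-RFE** — a linear soft-margin SVM (C = 1) is refitted while the
   feature with the smallest squared weight is removed one at a time
   (ties broken by removing the larger column index, for deterministic
   reruns). At every elimination level a leave-one-out accuracy *within
   the training fold* is recorded; the final subset is the smallest
   feature count whose inner accuracy is at least the accuracy with all
   survivors. Training-fold LOO was chosen as the inner accuracy
   because it is the least-biased estimate available at these sample
   sizes without consuming data; plain training accuracy would
   saturate and always select the minimum count.

Selection runs independently per channel; a channel with no t-test
survivors is excluded from that fold's kernel set with a warning.

## Multi-kernel SVM

One linear base kernel per channel is built on the selected features and
scaled to unit mean diagonal, making the learned weights comparable
across channels of different dimensionality. The combined kernel is the
convex combination K = Σ_f β_f K_f with β on the probability simplex,
and the decision function is F(x) = sign(Σ_i y_i α_i K(x_i, x) + b).

Weights are learned by the reduced-gradient scheme (SimpleMKL): starting
from uniform β, alternate (i) a soft-margin SVM solve on the combined
kernel (scikit-learn's libsvm backend, tolerance 1e−7) and (ii) a
descent step on β along the reduced gradient −(∂J/∂β_f − ∂J/∂β_μ)
(μ = largest weight), projected to keep β ≥ 0, with an Armijo
backtracking line search (sufficient-decrease constant 1e−4, halving,
at most 20 backtracks, starting from the largest feasible step).
Stopping: relative objective change < 1e−4, or the duality-gap
criterion max_f s^T K_f s − s^T K(β) s (relative) < 1e−3, or 100 outer
iterations (then the model carries a convergence warning). The
objective is non-increasing by construction of the line search.

Class coding: patient = −1, control = +1 (scores are "control-like"
when positive). A score of exactly 0 predicts control — ties have
measure zero and the rule makes reruns deterministic. Sensitivity and
specificity nonetheless treat patients as the positive class.

## Evaluation

LOOCV: n folds, each holding out one subject; normalization, selection,
kernel construction and MKL fitting all happen inside the fold.
Confusion metrics are computed exactly on integer counts
(sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total). The ROC is built from the decision scores pooled over
all folds (one score per subject) — per-fold ROCs are meaningless at
n = 1 — and AUC equals the Mann–Whitney statistic with ties counting
one half. Feature-frequency tables count, per channel, how many folds
selected each ROI (ties broken by ROI id).

Comparison modes rerun the same folds on every non-empty channel subset
(single channels degenerate to a plain SVM; the per-fold per-channel
selection is computed once and shared, so all modes see the identical
protocol) plus a concatenation mode that stacks all channels into one
long vector and runs its own selection under a single kernel.

Demographic helpers compute both the pooled and the Welch two-sample t
from group summaries, and Pearson's χ² without continuity correction on
2×2 count tables (the uncorrected statistic is the convention the
framework's demographic tables follow).

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
not MRI physics. Per subject and ROI, voxel series are

    x_v(t) = a_r · ( √ρ_r · s_r(t) + √(1−ρ_r) · n_v(t) ),

where s_r is an ROI-shared signal, n_v is voxel-private noise, ρ_r is
the shared-variance fraction (baseline 0.2) and a_r an amplitude factor
(baseline 1). Both s_r and n_v are unit-variance stationary Gaussian
signals band-limited to 0.01–0.08 Hz, built in the DFT domain with
complex-Gaussian coefficients on every in-band bin. Gaussianity is a
deliberate choice: the family is closed under variance-preserving
mixing, so rank- and correlation-based statistics depend only on the
correlation structure, and each injected manipulation moves exactly one
channel. Latent signals couple ROI sets: a member ROI's shared signal
is the variance-preserving mixture √(1−λ)·s_r + √λ·c, re-standardized,
so coupling changes inter-regional correlation without touching
amplitude or within-ROI synchrony. Structural maps are ROI-constant
means plus voxel Gaussian noise — the analysis only ever uses ROI
means.

Injected effects are standardized shifts of the generative parameter,
one Cohen's d unit per between-subject SD of that parameter: amplitude
(SD 0.10), shared fraction (SD 0.05, clipped to [0.02, 0.98]), target
coupling fraction (baseline 0.15, SD 0.20; partner ROIs hold a fixed
0.5 fraction of the latent — the √λ nonlinearity then gives the target
a large correlation response), structural mean (SD = `noise_sd`).
Controls receive no shift; with all effects zero the groups are
generatively identical, and the per-feature t-filter's type-I rate is
nominal (checked at ~1000 null features). Feature-level effect sizes
are attenuated relative to the injected d — estimation noise in W and
in correlation coefficients adds within-group variance, and ReHo
clusters near ROI boundaries mix neighbouring regions — most strongly
for the RFCS and ReHo channels; the simulation-based checks choose
their nominal effect sizes with this attenuation in mind.

The parcellation is a k-d-tree block partition: recursive proportional
splits along the longest axis give contiguous, compact, near-equal
rectangular ROIs — the shape regime a 27-voxel neighbourhood statistic
assumes (thin slab-shaped regions would let every cluster straddle
several ROIs and wash out regional effects).

What the synthetic checks do **not** show: robustness to motion or
physiological artefacts, spatial normalization error, non-Gaussian BOLD
noise, spatially varying smoothness, or realistic anatomical covariance
between channels. Real cohorts share none of the generator's
orthogonality guarantees, so recovered-feature lists on real data need
the usual caution.

## Problem sizes and reproducibility

Simulation-based checks run at desk scale, chosen to keep every check
informative on a single CPU: the headline pipeline uses 21 patients /
28 controls, 30 ROIs on a 12³ grid, 150 time points at TR = 2 s, with
d = 3 effects in two ROIs per channel (a strongly separable regime);
the permutation null re-labels that cohort 20 times; the
complementarity experiment uses 20/20 subjects, 24 ROIs on a 10³ grid,
120 time points, and disjoint d = 2.5 effects in one ROI per channel —
moderate enough that single channels stay well below ceiling (piloted
so the experiment has adequate power to show the combination's
advantage). The permutation-null band is evaluated at the size of a
single LOOCV run (n = 49): fold decisions within a run share training
data, so the pooled-count band would overstate the estimator's
precision; LOOCV null accuracy is also known to sit slightly below
one half, which the single-run band accommodates.

All randomness flows from explicit integer seeds through named
substreams (per-subject generators derive from the cohort seed, so
cohorts are bit-identical across runs); the SVM, RFE and MKL stages are
deterministic given their inputs.

## Known limitations

* The MKL solver targets F ≤ ~10 kernels and a few hundred samples; it
  re-solves an SVM per line-search step and makes no use of warm
  starts.
* SVM-RFE removes one feature per step (a `step` option exists); with
  thousands of surviving features the inner LOO curve becomes the cost
  bottleneck.
* Nuisance regression accepts per-subject covariate matrices but the
  generator does not simulate nuisance structure, so that path is only
  exercised by unit tests.
* The ReHo channel drops boundary ROIs on very coarse grids rather
  than computing a reduced-cluster W.
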