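# Methods

## Overview

`kmcdce` quantifies early contrast kinetics in bilateral breast DCE-MRI
acquired at ultrafast temporal resolution (a few seconds per frame over the
first minute after injection) and derives two families of patient-level
biomarkers:

* **kBPE I/C** — the ipsilateral-to-contralateral ratio of weighted
  cluster-average kinetic parameters of *normal-appearing* parenchyma, a
  bilateral-asymmetry measure motivated by the hypothesis that angiogenic
  factors from a tumor elevate perfusion of the surrounding normal tissue;
* **kT** — weighted cluster-average kinetic parameters of the tumor itself.

These feed logistic models that predict pathologic complete response (pCR)
to neoadjuvant chemotherapy from the pre-treatment exam.

## Enhancement models

For each voxel, percent signal enhancement is computed against the mean of
the precontrast frames:

    PSE(t) = 100 * (S(t) - S_pre) / S_pre .

Voxel curves are fit with the two-parameter empirical uptake model

    PSE(t) = A * alpha * t^2 / (1 + alpha * t^2) ,

where A (percent) is the saturation amplitude and alpha (1/min) the initial
uptake rate; two parameters deliberately under-parameterize noisy
single-voxel data. The product A*alpha — the maximum enhancement-rate
proxy — is the clustering feature. Cluster-averaged curves support a third
parameter, the washout rate beta (1/min, negative for persistent
enhancers):

    PSE_c(t) = A * alpha * t^2 / (1 + alpha * t^2) * exp(-beta * t) ,

and the early-enhancement integral AUC30 = ∫₀^0.5 PSE_c(t) dt (percent*min,
t30 = 0.5 min). When beta = 0 the integral has the closed form
A*(t30 - arctan(sqrt(alpha) t30)/sqrt(alpha)), which the quadrature is
tested against.

**Time origin.** The model forces PSE(0) = 0, so t = 0 must sit at the
bolus-adjacent frame. The source acquisition protocol does not pin this
down; we place the origin at the last precontrast frame and fit only
postcontrast frames. A configurable offset allows bolus-arrival shifts.

**Fitting.** The two-parameter fit is solved by variable projection: for
fixed alpha the amplitude is a closed-form linear least-squares solution
(clipped to [0, 1000]%), reducing the problem to a 1D search over
alpha ∈ [0, 100]/min — a 60-point log-grid bracket followed by bounded
Brent refinement (xatol 1e-12). This is deterministic, has no starting-point
sensitivity, and runs vectorized over a whole volume (the grid stage is one
matrix product). The three-parameter fit uses bounded trust-region least
squares (beta ∈ [-2, 10]/min), initialized from the two-parameter solution
with beta = 0. Non-convergence flags a fit rather than discarding it, but
voxels without a valid fit are excluded from clustering. Voxels whose peak
PSE is below 5% are flagged `low_enhancement`.

## Clustering

Within each region of interest — tumor, ipsilateral parenchyma,
contralateral parenchyma, clustered *separately* — voxels are partitioned
into K = 5 groups by 1D k-means on A*alpha (spatial position is not a
feature). Labels are renumbered ascending by cluster mean. K = 5 balances
within-cluster homogeneity against per-cluster voxel counts.

The initializer is deterministic: centers start at the 10/30/50/70/90th
percentiles of the masked values, so repeated runs are bit-identical with
no seed (a seeded random initializer is available). Lloyd iterations stop
at an assignment fixed point or 300 rounds; nearest-center ties break
toward the lower index; an emptied cluster is re-seeded at the point
farthest from its center. Fewer than K distinct values raises a degeneracy
error naming the region.

Cluster curves average *raw signal* over the cluster's voxels and apply
the PSE definition with the cluster-mean baseline — not an average of
per-voxel PSE — because the enhancement model is nonlinear and the two
operations do not commute.

## Pharmacokinetics

Cluster-mean enhancement is converted to tissue gadolinium concentration
and fit with the extended Tofts model

    C(t) = vp Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^{-(Ktrans/ve)(t-τ)} dτ ,

with Ktrans (1/min) the transfer constant, ve the extravascular
extracellular fraction, vp the plasma fraction, and Kep = Ktrans/ve derived
per cluster after the fit (the identity Kep*ve = Ktrans holds to machine
precision in every emitted fit).

**Concentration conversion.** Default `spgr` mode inverts the spoiled
gradient echo steady-state signal equation: the ratio S(t)/S0 = 1 +
PSE/100 determines E1 = exp(-TR*R1(t)) given the flip angle, and
C = (R1 - 1/T10)/r1. Frames outside the invertible range are clipped and
logged. A `linear` small-enhancement mode (C = PSE/(100 r1 T10)) is the
alternative; outputs record which mode produced them. Defaults: T10 1.4 s
for parenchyma and 1.5 s for tumor at 3 T, relaxivity 5.0 L/(mmol s),
TR 4 ms, flip 10° — all overridable per agent and protocol.

**Population AIF.** Cp(t) defaults to the widely used population form of
two Gaussian bolus terms plus a sigmoid-modulated exponential washout with
its literature parameter vector (mM, minutes), shifted by a configurable
bolus-arrival time (default: the fit origin). The form is a documented
stand-in — the package treats the AIF as pluggable (any parameter vector
of this family via config).

**Forward model and fit.** The convolution uses the exact
exponential-kernel recursion for piecewise-linear Cp, evaluated with
blockwise scaled cumulative sums (numerically safe for any Kep) on a grid
refined 100x relative to the frame spacing; this keeps the absolute error
below 1e-5 mM against converged quadrature. The fit is bounded least
squares over Ktrans ∈ [0, 5], ve ∈ [1e-3, 1], vp ∈ [0, 0.2] from three
deterministic starting points; the lowest-RSS solution wins, ties to the
first start. On noiseless simulations sampled at 5 s over 60 s the fit
recovers Ktrans and vp essentially exactly; ve is weakly identified by a
60 s window (washout barely begins) and is documented to sharpen by more
than an order of magnitude when the window extends to 300 s.

## Patient summaries

Per kinetic parameter p ∈ {A, alpha, A*alpha, beta, AUC30, Ktrans, ve,
Kep, vp}:

* parenchyma, each breast: weighted average of clusters 2-4 with weights
  2, 3, 4 (the extreme clusters are outlier-prone: cluster 1 is barely
  enhancing, cluster 5 collects noise and vessels-adjacent voxels);
* asymmetry: I/C = ipsilateral / contralateral weighted average;
* tumor: weighted average of clusters 3-5 with weights 3, 4, 5 (the lowest
  two clusters have poor SNR; the fastest-enhancing cluster most
  represents viable tumor).

A*alpha is the per-cluster product of fitted A and alpha, and Kep is the
per-cluster ratio Ktrans/ve — composites are formed *before* averaging,
because weighted averaging does not commute with products or ratios. A
missing required cluster makes the affected parameter missing (no
fallback reweighting, which would silently change the estimator). I/C with
a near-zero denominator (|con| < 1e-9) is missing with a warning. Tumor
volume is voxel count times voxel volume, in cm³.

beta and vp I/C are computed and reported even though they are
ill-conditioned (ratios of near-zero quantities); their instability is a
property of the data, not grounds for omission.

## Cohort statistics and prediction

Group comparisons between pCR and non-pCR use a Wilcoxon rank-sum test for
continuous features — exact enumeration when the combined sample is <= 20
and tie-free, normal approximation with tie correction otherwise — and a
Pearson chi-square without continuity correction for categorical ones. No
multiple-testing correction is applied across the comparison battery.

Prediction models are logistic regressions on standardized features
(full-cohort mean/SD, consistent with apparent evaluation) with a small
ridge term (1e-4 on standardized coefficients) so separated designs stay
finite; fitting is damped Newton with a backtracking line search on the
penalized deviance. Seven model families draw candidates from three pools
(clinical covariates; tumor kinetics; kBPE I/C) and their combinations;
within a family every subset of 1-3 features is fit exhaustively
(multi-pool families require at least one feature per constituent pool)
and the subset with the highest apparent ROC AUC wins; ties break to fewer
features, then lexicographic order. The full leaderboard is retained.

ROC AUC is the Mann-Whitney statistic (ties count half). Uncertainty comes
from a patient-level bootstrap (default 1000 resamples, unstratified, with
a stratified option): the *already selected* model is refit on each
resample and scored on it, and the 2.5/97.5 percentiles give the 95% CI.
Selection is not repeated inside the bootstrap — an optimism-prone but
conventional apparent-performance choice, stated openly. Models sharing
resample indices are compared by a z-test on the mean paired AUC
difference (a zero-variance difference is special-cased: p = 1 when the
mean difference is 0, else p = 0). Reported operating points maximize the
Youden index over observed scores (ties to the lowest threshold), with
accuracy evaluated there.

## Synthetic data

No clinical cohort ships with the package; two simulators define the study
conditions.

**Voxel-level phantom.** A rectangular bilateral volume (default 32x64x8
voxels of 1.5x1.5x3 mm) with mirror-symmetric parenchyma slabs of five
kinetic bands each, an ellipsoidal tumor carved into the ipsilateral slab
(its mirror cavity is carved contralaterally too, so the parenchymal
geometry is bilaterally identical), and optional vessel lines. The frame
schedule is 5 precontrast + 18 postcontrast frames at 5 s. Within-band
heterogeneity is a mean-preserving log-normal (sigma 0.15) drawn on the
contralateral side and mirrored; bilateral asymmetry multiplies the
ipsilateral uptake rate by a factor r, so the ground-truth A*alpha I/C is
exactly r. Noise is Gaussian (clipped at zero) or Rician. Two modes:
`signal` (voxels follow the three-parameter enhancement model — exact
truth for the enhancement stages) and `concentration` (voxels follow the
extended Tofts model mapped through the SPGR forward equation — exact
truth for the pharmacokinetic stage); each downstream stage is validated
in its own model family. Parenchymal band amplitudes span 15-60% PSE with
alpha 0.5-2.8/min; tumor bands span 80-200% with alpha 4-20/min and
washout -0.04 to 0.04/min — values chosen once as representative of
parenchymal vs. malignant enhancement at these field strengths.

What the phantom does **not** emulate: anatomically realistic geometry,
coil/B1 inhomogeneity, motion, partial-volume mixing at region borders,
and spatial noise correlation. Passing tests therefore demonstrate
correctness of the estimators under the stated models, not robustness to
those confounds.

**Cohort simulator.** Per-patient feature vectors for 30 non-pCR and 26
pCR patients drawn as independent (default) normals with the published
group means and SDs of the asymmetry and tumor-kinetics features
(log-normal optional), truncated at physical bounds (ratios > 0,
0 < ve <= 1, vp in [0, 0.2]) by rejection; clinical covariates are
Bernoulli draws at the published group frequencies, age a truncated
normal. Features are sampled independently within group — real kinetic
features are correlated, so simulated multi-feature model AUCs run higher
than clinical reality; single-feature discrimination matches the
generating distributions (closed-form Gaussian AUC
Φ(Δμ/√(σ₁²+σ₂²))).

## Numerical and edge-case policy

* All times in minutes internally; conversion at read time only.
* AUC30 quadrature tolerance 1e-8 absolute; closed form used when beta=0.
* Degenerate inputs raise typed errors (`DataError` and subclasses) naming
  the stage/region; silent coercion is never performed.
* Bootstrap resamples with one outcome class are skipped and logged; more
  than 50% degenerate resamples is an error.
* All randomness flows through explicit integer seeds; pipelines are pure
  functions of (inputs, config, seed) and runs are bit-reproducible.

## Known limitations

* The bilateral I/C of cluster-averaged parameters carries ~2-3% noise per
  parameter at 2% Rician signal noise on the default phantom, dominated by
  cluster-composition differences between the independently clustered
  breasts — an inherent property of per-side clustering, visible in the
  symmetry-null simulations.
* ve from a 60 s acquisition window is only weakly identified; Kep inherits
  that uncertainty.
* Apparent (in-sample) AUCs with selection outside the bootstrap are
  optimistic; an honest generalization estimate would need nested
  validation, which is out of scope.
* The population AIF parameter vector is a literature stand-in; absolute
  Ktrans/vp scale with the assumed AIF, though I/C ratios largely cancel
  patient-level AIF scale.
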