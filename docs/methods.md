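# Methods

`dfcsubtype` re-implements, as a tested pipeline, a subtype-discovery
analysis for first-episode drug-naive major depression (FEDN-MDD) built on
dynamic functional connectivity: sliding-window connectivity, group-guided
independent component analysis, per-component network features, an
age-referenced normative model, wrapper feature selection with repeated
k-means, and covariate-adjusted permutation inference. Because the clinical
dataset behind the original analysis is request-only, the package ships a
fully specified synthetic cohort generator with ground truth at every
stage; all quantitative claims in this repository are about what the
pipeline recovers from that generator.

## Pipeline

**Dynamic connectivity.** Each subject's T x m ROI series (default
m = 90 AAL-style regions; the shipped analyses use a reduced m = 30) is
converted to sliding-window Pearson correlations: window length 60 s
(30 volumes at TR = 2 s), step 1 volume, giving W = T - L + 1 windows of
E = m(m-1)/2 upper-triangle edges in lexicographic order. Correlations are
clamped to |r| <= 1 - 1e-7 and Fisher-transformed, z = atanh(r), so all
entries are finite. The window is rectangular by default; a Gaussian taper
(sigma = L/4) is available. "Step 1" is read as one volume (one TR), the
convention of the sliding-window literature.

**Group decomposition.** The healthy-ICA group's window matrices are
stacked, column-centred, reduced to K = 20 dimensions by seeded randomized
SVD, and unmixed by FastICA (logcosh negentropy contrast), treating edges
as samples so the sources are K edge-space connectivity patterns. Because
genuine connectivity components are sparse, each pattern is sparsified at a
relative threshold (loadings below 0.4 of the component's peak are zeroed)
and normalised; this denoising is what makes the patterns usable as
guides. The threshold is a tunable (`sparsify_rel`).

**Guided subject back-reconstruction.** A single subject's data carry far
less information than the group: with a 60 s window, a 210-volume scan has
roughly T/L ≈ 7 effective temporal degrees of freedom, so 20 per-subject
weight regressors are unavoidably collinear and unregularised per-subject
unmixing (or dual regression) is unidentifiable. The guided estimator
therefore treats the group pattern as a structural prior: the subject
pattern for component k is

    p_k = normalise( lambda * r_k + (1 - lambda) * s_k ),

where r_k is the (sparse) group reference and s_k is the subject's mean
Fisher-z connectivity restricted to r_k's active edge set, normalised and
sign-aligned. `lambda_ref` (default 0.5) sets the prior strength; 1.0
returns the references unchanged, 0.0 trusts the subject's own map on the
reference support. The support restriction matters: off-support edges
contribute estimation noise but no component-specific signal at a single
subject's data size, and a scalar readout that integrates all E edges
would otherwise drown individual deviations in noise. Time-varying
component weights are per-window ordinary least squares of the window's
edge vector on the K subject patterns (with intercept).

**Network features.** Each subject is summarised by 2K = 40 numbers. For
each component: (i) the global efficiency of the weighted graph whose
connection weights are the pattern's |loadings| max-normalised to [0, 1],
with edge lengths the reciprocal weights, efficiency = mean inverse
shortest-path length over ordered node pairs (unreachable pairs contribute
0) — scale-free and bounded in [0, 1]; (ii) the fluctuation coefficient,
the mean absolute frame-wise change of the component's weight trajectory.
Negative loadings enter through their magnitude; sign information is
carried by the inference module instead.

**Normative model.** For each feature, 5th/50th/95th percentile curves are
fit on the healthy-base controls as second-order polynomials in age by
pinball-loss minimisation (quantile regression, via iteratively reweighted
least squares), with optional case-resampling bootstrap CIs (default 1000
resamples when requested; the pipeline default is 0 because the intervals
are reported, not consumed). Predictions are monotonically rearranged
across quantile levels so curves never cross. Ten age-decile-stratified
folds give an aggregate model: each fold's curves are fit with that fold
held out; a patient's deviation is

    z = (c_observed - q50(age)) / (q95(age) - q5(age)),

averaged over the ten fold models; controls are scored only by the model
that never saw them. On a Gaussian feature the denominator is 3.29 sigma,
so z = 1 corresponds to a 3.3-SD deviation — "extreme" by construction.

**Subtype discovery.** Forward feature selection wraps plain Lloyd k-means
(k = 2, uniform random point initialisation — deliberately uncareful, so
that run-to-run variability is observable) with mean silhouette as the
criterion. One hundred runs each draw a random 80% patient subsample.
Within a run, the first feature is the silhouette maximiser and each later
candidate is kept only while it beats its own column-permuted twin by a
margin (0.01): permutation preserves a column's marginal but destroys its
alignment with the already-selected structure, giving a selection-bias-free
noise baseline. Redundant informative features are retained (mean
silhouette is nearly dimension-invariant for equally separating features,
which is why a plain improve-or-stop rule would keep exactly one), while
noise features pass only sporadically and never accumulate frequency.
Because a single reordered column is the same 1-D point set, the opening
step is instead gated once per cohort: the mean of the top-3
single-feature silhouettes must exceed the 95th percentile of the same
statistic over 50 Gaussian surrogate matrices (per-column moments
preserved, unimodal by construction). Any 1-D sample splits with a
deceptively high silhouette (~0.55-0.65 for pure Gaussian noise at
n ≈ 100), so without this gate the chance-most-bimodal feature of a null
cohort would be selected persistently. Features selected in more than 80%
of runs are "informative".

Patients are then clustered on the informative features by 100 aligned
k-means runs (Hungarian matching of each run to the first on the confusion
matrix). Per subject, certainty = (modal label count)/100 and the final
label is the argmax (ties to the lower index); subjects below certainty
0.6 are excluded from post hoc analyses (the reference protocol mentions
both 0.6 and 0.8; 0.6 is the default, both are configurable). Quality
indices: silhouette of the retained subjects under the final labels;
centre instability = mean over runs of the summed distances of the run's
aligned centres from the across-run mean centres (the citation defining
this index is not public; this convention is documented as the package's
own); mean stability = mean certainty of retained subjects. Cluster "I"
is the one with the larger mean absolute deviation.

**Inference.** Pseudo two-sample t-tests in the Freedman-Lane scheme:
features are regressed on the covariates (age, sex, education, plus
intercept), residuals are permuted and re-added to the fitted part, and
the pooled-variance two-sample t on the group labels is recomputed each of
n = 5000 permutations; p = (1 + #{|t*| >= |t|})/(1 + n). Tests are
two-sided and thresholded per feature at p < .01, uncorrected, matching
the reference protocol's edge-wise reporting; a Benjamini-Hochberg option
exists but is off by default.

## Synthetic cohort generator

The generator defines the study conditions. Each of K latent components is
a node module — a subset of ROIs sharing a latent signal, the standard
factor model of a resting-state network:

    x(t) = eps(t) + sum_k sqrt(w_k(t)) * b_k * f_k(t),

with unit node noise, i.i.d. module signals and non-negative time-varying
module strengths. The induced covariance I + sum_k w_k(t) b_k b_k^T is
positive definite by construction at any amplitude, so no spectral repair
is ever needed. (An earlier design with arbitrary sparse symmetric edge
patterns required eigenvalue clipping at realistic amplitudes, and the
clipping destroyed the planted linear structure; the factor model removes
the problem at its root and is also the more faithful model of modular
brain networks.) Module size is set so the within-module edge count is
about `sparsity` of the edge space (~9 nodes at m = 30, ~14 at m = 90); a
small core (about a third of the module) carries fixed strong loadings
(0.6-0.9) and the larger periphery carries weaker loadings (0.45-0.7)
scaled by the subject's *density driver*. Static within-module
correlations land in the 0.2-0.5 range typical of resting-state data.
Modules are redrawn until their edge patterns are mutually near-orthogonal
(pairwise |cosine| < 0.3).

Module strengths follow w_k(t) = w0_k exp(s_k(t) + v_k o_k(t)): w0 ~
|N(1.2, 0.25)|; s is moving-average-smoothed white noise (width = half the
analysis window; SD 0.9) — a stationary process, because independent
random walks over a few hundred volumes are spuriously cross-correlated
(|r| up to ~0.97 was observed), which would make the weight design
near-singular and the decomposition unidentifiable; o is a narrowband
oscillation (period 45-105 volumes, amplitude 0.8) scaled by the subject's
*volatility driver* v — the part of the trajectory that survives
window-averaging as frame-wise change, since the consecutive-window
difference of any window-averaged trajectory is (w[t+L] - w[t])/L and a
slow drift alone would leave the fluctuation coefficient noise-dominated.
Lag-1 autocorrelation exceeds 0.5 by construction.

The two drivers per component carry all individual variation: both are
1 + quadratic age trend (coefficients drawn once per bank, linear scale
0.08 over the centred-age range) + N(0, 0.06) population jitter +, for
patients, the subtype's deviation shift. Shifts are specified in z units
of the driver's control quantile range (a shift of 1.5 moves the driver by
1.5 x its 5th-95th percentile control spread). Defaults mirror the
reference cohort: subtype I (16% of patients, deterministic rounding:
round(0.16*91) = 15) carries -4.5 z and subtype II (84%) -0.25 z on 12
features from 10 components (efficiency of components 1-9, fluctuation of
2, 6 and 10); deviations point downward — reduced efficiency and damped
volatility — the direction in which both latent maps are monotone.
Demographics follow the reference cohort's summary statistics (ages
uniform on 18-50, education ~ N(12, 3.3) years, 65% male, FD summaries
near 0.07/0.40 mm); illness duration is lognormal with a shorter-duration
subtype I. With `noise_sd = 0` the joint innovations are exactly whitened
over the series, so the full-series sample covariance equals the analytic
covariance whenever weights are constant.

**What the generator does not emulate.** No hemodynamics, no scanner or
physiological noise beyond i.i.d. Gaussian terms, no spatial structure
beyond node modules, no site effects, and feature deviations enter through
exactly two latent dials per component. Passing the recovery checks
therefore shows that the pipeline's estimators are consistent and
correctly coupled to the constructs they claim to measure — not that real
FEDN-MDD cohorts contain subtypes of this strength or form.

## Numerical choices and resolution limits

* All randomness flows from one root seed through named substreams
  (CRC-32-keyed `SeedSequence` spawns), so every stage is independently
  reproducible and the pipeline is re-entrant from any persisted stage.
* Fisher clamp 1 - 1e-7; quantile non-crossing by pointwise monotone
  rearrangement; forward-selection ties break to the lowest feature index;
  argmax label ties to the lowest label; k-means re-initialises on empty
  clusters (bounded retries).
* The shipped analyses and recovery studies run at reduced size — m = 30
  ROIs, T = 210 volumes, 91 + 91 patients/base controls and 125 ICA
  controls; the planted-recovery study uses K = 5 components at m = 20
  with 20 subjects — sizes chosen so the full suite of studies runs on a
  single CPU in minutes while keeping every estimator in the same regime
  as the full-scale configuration.
* **Weight-trajectory resolution.** A 30-volume window estimates each
  edge's correlation with SD ≈ 1/sqrt(L-3) ≈ 0.19, which propagates to a
  per-window component-weight error of ~0.2 regardless of the estimator;
  overlapping windows make this error low-frequency, so it cannot be
  smoothed away. At physiologically sensible strength fluctuations the
  correlation between recovered and planted weight trajectories therefore
  plateaus near 0.75-0.8. Recovered *patterns* are far more precise
  (matched correlations ≥ 0.94 in the shipped recovery study) because they
  pool all windows.
* **Feature cross-talk.** Per-component deviations partially leak across
  components through shared estimation machinery, so the informative
  features found by selection are subtype-separating but not always the
  planted ones; the subtype partition itself is recovered exactly in the
  shipped studies (ARI 1.0 across ten generator seeds).
* Fluctuation-coefficient features are noisier than efficiency features
  for the same reason as the trajectory limit above; in the shipped
  studies they still contribute to the informative set.

## Open design choices

* FD quality control implements the protocol's printed disjunction
  (mean FD <= 0.5 mm OR max FD <= 2 mm); an `and` variant is available.
* Matching is greedy nearest-neighbour without replacement on standardised
  age/education (Mahalanobis) with exact sex matching when possible, in
  seeded random patient order.
* The normative model is age-only; sex and education enter only the group
  contrasts, mirroring the reference protocol.
* Selection criterion silhouette (Calinski-Harabasz available); the exact
  wrapper objective of the reference analysis is not public, and the
  permutation-gated rule above is this package's own design, chosen so
  that redundant informative features accumulate frequency while pure
  noise cannot — the behaviour the reference analysis reports.
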