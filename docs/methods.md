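# Methods

`delnet` reimplements, end to end and on synthetic data, a resting-state
fMRI functional-network analysis of predisposing delirium risk factors in
an elderly (65+) cohort: per-subject denoising of region-averaged BOLD
time series, Pearson connectivity, spanning-tree backbone metrics,
regional PCC–DLPFC connectivity, and group-level risk-factor regressions
with FDR control. This note records the model, the defaults and why, the
numerical choices, and what the synthetic cohort does and does not show.

## Per-subject chain

Inputs are a regions × volumes BOLD matrix (264 regions in the full
parcellation; TR in seconds), a volumes × 6 rigid-body motion table
(3 rotations in rad, 3 translations in mm), and white-matter / CSF /
global mean signals. The chain is:

1. **Initial-volume deletion** — the first 15 volumes are dropped
   (magnetization stabilisation), from the signal, the motion table and
   the tissue signals alike.
2. **Framewise displacement** — FD[t] = Σ|Δtranslations| + 50 mm ·
   Σ|Δrotations|, FD[0] = 0. The source description cites the 0.2 mm
   scrubbing threshold without printing a formula; we adopt the
   sum-of-absolute-backward-differences convention with a 50 mm rotation
   radius, the standard in the scrubbing literature. In the assembled
   chain FD is computed on the full motion trace and then trimmed to the
   retained volumes, so the first retained volume keeps its physically
   real transition from the last dummy volume (recomputing FD after the
   drop would silently define it as zero and a movement landing exactly
   on the boundary would escape censoring).
3. **Subject motion gate** — subjects with mean relative displacement
   > 0.2 mm (strict) are excluded. Mean relative displacement is a
   realignment-tool output that cannot be recomputed from our inputs; an
   externally supplied value is used when present, otherwise mean FD is
   the documented proxy.
4. **36-parameter nuisance regression** — 9 base regressors (6 motion +
   WM + CSF + global), their backward-difference temporal derivatives
   (first element 0), and the squares of all 18. The published component
   description is internally inconsistent; this 9 + 9 + 18 reading is the
   only one that yields 36. Residuals are computed with an intercept via a
   QR projection (pseudoinverse with a warning when rank deficient), so
   they are orthogonal to every regressor to ~1e−12.
5. **Band-pass 0.01–0.08 Hz** — order-2 Butterworth applied forward and
   backward (zero phase; effective magnitude response is the squared
   Butterworth response). Initial conditions and padding follow the
   standard filtfilt construction (odd extension, step-response initial
   state); the transfer function is fixed by (order, band, TR).
6. **Volume censoring** — volumes whose FD *exceeds* 0.2 mm are masked
   out ("exceeded" read as strict; a volume at exactly 0.2 mm is kept).
   Censoring flips the retained mask only; sample values are never
   altered. The source does not state whether censoring preceded
   regression/filtering; because filtering an irregularly sampled series
   is ill-defined, the default order is regress → filter → censor, with
   censor-first available behind a flag.
7. **Duration gate** — subjects with < 240 s of retained data are
   excluded (strict).

## Connectivity and spanning-tree backbone

Pearson correlations between all region pairs over the retained volumes
(retained volumes are concatenated; a zero-variance region is an error,
not a silent NaN) give a symmetric unit-diagonal matrix. The backbone —
called the MST in this literature, formally a **maximum** spanning tree —
is built by Kruskal's algorithm over the strictly positive correlations:
edges are ranked by weight, the strongest placed first, and any edge that
would close a loop is skipped until all regions are connected by n − 1
edges. Zero and negative correlations are absent edges; if the positive
graph is disconnected the subject is not analyzable under this rule and
the error lists the components. Ties (probability ~0 for continuous
data) break by lexicographic (i, j) order for reproducibility.

Outcomes per subject:

- **global strength** — mean of the n − 1 tree edge weights;
- **diameter** — edges between the two most remote tree nodes, by double
  BFS (exact on trees); lower = more efficiently organized;
- **leaf fraction** — proportion of degree-1 nodes; higher = more
  integrated, star-like. For n ≥ 3, a path attains (n − 1, 2/n) and a
  star (2, (n − 1)/n); metrics are reported unnormalized, with normalized
  variants behind flags.
- **regional PCC–DLPFC connectivity** — member time series of each node
  set are averaged first, then the two averages are Pearson-correlated
  (average-then-correlate, per the source's wording; mean-of-pairwise is
  a sensitivity flag). Default sets (1-based indices into the 264-region
  functional parcellation): PCC {77, 78, 82}, DLPFC left {167, 176},
  DLPFC right {168, 175}, shipped with their MNI centres. At reduced
  simulated region counts, small synthetic stand-in sets on the first
  regions keep the outcome exercised.

## Group statistics

Each outcome is regressed (OLS, intercept, complete cases) on one risk
factor at a time — age, alcohol misuse (AUDIT ≥ 8), MMSE, depression
(GDS ≥ 6), Barthel index, TIA/stroke history, dichotomized ASA status —
adjusted for centre, age (when age is not the determinant), gender and
IQ; and once on all seven factors combined. Slopes are reported as
standardized betas, raw slope × SD(x)/SD(y), binary predictors on the
same convention (the convention of the statistics package the original
analysis used). Log transforms are config-driven with an empty default
(the source does not say which variables were transformed); an optional
Shapiro–Wilk screen only logs recommendations.

Benjamini–Hochberg step-up FDR is applied with the family defaulting to
the set of outcomes per determinant — the only family size under which a
raw p of 0.007 survives at q = 0.05 with five outcomes — and rejection
requires adjusted p strictly below 0.05. Extreme-quintile contrasts cut
at the 20th/80th percentiles (linear-interpolation percentile rule,
boundary values assigned inclusively to the extreme groups) and compare
the groups with Welch's t. Cohort-level summary comparisons use Welch's
t from (mean, SD, n) — the pooled-variance variant is a flag; Welch is
the default because it reproduces the published age comparison (2.30
where pooled gives 2.28) — and Pearson 2×2 chi-square with optional
Yates correction.

## Synthetic cohort

No imaging data were released, so the generator is a first-class module
that emulates the study's inputs:

- **Covariates** match the published included-sample marginals: age
  truncated-normal with lower bound 65, mean 71.2, SD 4.9; IQ 105 ± 12.2;
  MMSE 28.7 ± 1.4 on [24, 30] (lower scores are an exclusion criterion);
  Barthel mean 98.4 on [0, 100]; prevalences — male 63%, Berlin centre
  30%, alcohol 5%, depression 5%, TIA/stroke 24%, ASA-unhealthy 86%.
  Because truncation shifts moments, the truncated-normal location and
  scale are solved numerically so the *realized* mean and SD match the
  targets. Exception: a truncated normal cannot have mean 98.4 and SD 4.8
  under a ceiling of 100 (the real Barthel distribution is a ceiling
  spike plus a long left tail), so Barthel matches the mean only; its
  quintile contrast can degenerate through ties, which the analysis
  handles explicitly.
- **BOLD series** are i.i.d. draws from N(0, C_i): C is block-structured
  (8 modules; within-block r = 0.4, between-block r = 0.1 — typical
  magnitudes for module-resolved functional connectivity), positive
  semidefinite by construction and repaired by eigenvalue clipping plus
  diagonal rescaling if a user-supplied matrix needs it. Shared
  low-frequency sinusoidal WM/CSF/global confounds are added to every
  region with per-subject gains, giving the 36-parameter regression
  something real to remove.
- **Planted effect.** Subject i's correlation is C_i = m_i C + (1 −
  m_i) I, i.e. off-diagonals scaled by a coupling multiplier
  m_i = 1 + s·(γ z_i + √(1 − γ²) η_i), with z_i the standardized planted
  covariate, η_i ~ N(0,1) subject-level coupling noise (deviate clipped
  at ±3.5 SD so m_i stays positive), and s = 0.2 the between-subject SD
  of global coupling. By construction corr(z, m) = γ: γ is the
  *standardized* slope of the covariate on connectivity scaling. The
  coupling spread s = 0.2 (a ~20% coefficient of variation in global
  coupling, in line with empirical FC cohorts) is chosen large enough
  that between-subject coupling variance dominates correlation-estimation
  noise; the standardized effect then survives to the measured outcome
  (mean tree edge weight) with attenuation of roughly 10–20%, so a
  planted γ = 0.18 yields outcome-level β̂ ≈ 0.15 on average. With a
  smaller s the same γ would be attenuated well below its nominal value
  and would no longer mean what the configuration says it means.
- **Motion** is a smooth drift (per-channel sinusoid plus a small clipped
  random walk — the walk breaks an exact collinearity that pure
  sinusoids induce among the 36 regressors) whose worst-case FD is
  bounded below 0.15 mm, plus step-like spikes (persistent position
  jumps of 0.3–0.8 mm on a random translation axis) at per-transition
  probability 0.05 by default. Spike volumes therefore have FD > 0.2 mm
  and non-spike volumes FD ≤ 0.2 mm *by construction*, which is what
  makes the exact-censoring test meaningful.

Everything is keyed on a single integer seed through independent
`SeedSequence` streams (covariates; one stream per subject), so any
subject subset is reproducible and full runs are byte-identical.

## Problem sizes used in tests and the acceptance script

The planted-effect experiments run at n = 222 subjects and 60 regions
(238 volumes, TR 2 s) — the cohort size of the study with the region
count reduced eight-fold, which preserves the estimation problem
(hundreds of tree edges per subject, identical subject-level noise
structure) at desk scale: 100 replicates for effect recovery, 1000 for
null calibration. Brute-force oracles cover all spanning trees at
n ≤ 6 (1000 random graphs), all-pairs BFS diameters, a literal step-up
FDR transcription (10,000 random p-vectors), and closed-form path/star
limits for every n in 3…264.

## What passing does and does not show

The generator draws stationary Gaussian series with an exactly known
correlation target, spike-only motion corruption, and confounds that lie
exactly in the span of the nuisance design. Real BOLD has hemodynamic
autocorrelation, scanner drift, non-Gaussian artefacts, motion that
leaks into the signal itself, and parcellation error — none of which are
modelled. Passing therefore validates the *pipeline machinery* (gates,
filters, estimators, tree algorithms, model fits, FDR) and the
statistical calibration of the full chain under its stated assumptions;
it says nothing about whether the scientific findings would replicate in
new imaging data.

## Known limitations

- The Barthel marginal matches the published mean but not the published
  SD (see above); its distribution is under-dispersed.
- Mean FD is a proxy for the realignment tool's mean relative
  displacement in the subject gate when the latter is not supplied.
- The disconnected-positive-graph rule treats such subjects as errors
  (excluded), matching the all-regions-connected definition; no forest
  fallback is provided.
- Voxel-level spatial preprocessing (registration, segmentation,
  smoothing, slice timing) is out of scope; inputs are region-averaged
  series.
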