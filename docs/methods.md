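# Methods

This note documents the models, defaults, and design choices behind
`visuomap`, and what the synthetic-data tests do and do not establish
about real data.

## Coordinate conventions

All visual-field quantities are in degrees of visual angle (dva) with
the origin at fixation, x rightward, y upward. Grid arrays are indexed
`[iy, ix]` with row 0 at the lowest y (`origin='lower'` when
rendering). The back-projection grid spans −8.5..8.5 dva inclusive at
0.1 dva spacing (171 × 171 centers); searchlight traversal is limited
to center eccentricities ≤ 8.6 dva, so a vertex at 8.49 dva is still
covered by some searchlight. Cells outside the traversal cap are
flagged *untraversed*, which is distinct from a zero value.

## pRF model and fitting

Each pRF is a 2D isotropic Gaussian with center `(x, y)`, size σ and
amplitude β. The Gaussian is **peak-normalized** (value 1 at its
center), not unit-integral; β therefore absorbs all scale. This
changes β's interpretation (it is not an integrated response) but not
the fit quality, and it keeps β comparable across σ.

The forward prediction is the frame-wise overlap (sum over grid
pixels) between the Gaussian and the binary stimulus aperture,
convolved with the canonical double-gamma HRF (peak 6 s, undershoot
16 s, peak:undershoot 6, peak-normalized), resampled to the TR.
Because convolution and the spatial sum are both linear, the aperture
stack is convolved once per session and every candidate prediction is
a single matrix product. The simulated preprocessing linearly detrends
and z-standardizes each series; detrending is likewise a linear
projection, so it is applied to the convolved apertures once, which
makes the fitted model exactly consistent with the preprocessed data.

Fitting: coarse search on a 0.5 dva lattice over ±9 dva with 20
logarithmic σ steps in [0.1, 8] dva, β by least squares at each
candidate (candidate score is the squared correlation, so the search
is a single BLAS pass per σ); then Nelder–Mead refinement of
`(x, y, log σ)` from the best candidate (`xatol 1e-4`, `fatol 1e-10`,
max 400 iterations). The refined fit is kept only if its R² is at
least the coarse R², so refinement can never degrade a fit. R² is
`1 − SS_res/SS_tot` on the standardized series. Fits with `R² ≤ .01`,
`β ≤ 0` or constant input are flagged as artifacts; the
pre-back-projection filter additionally removes `R² ≤ .05` and
eccentricities ≥ 8.5 dva (both thresholds inclusive on the removal
side).

A practical note on null fits: maximizing R² over thousands of grid
candidates inflates the best fit on pure noise to roughly
`2·ln(C_eff)/T` (C_eff = effective number of independent candidates,
T = series length). At a realistic 480-volume mapping run this is
≈ 0.011 — safely below the 0.05 back-projection threshold but not
reliably below 0.01. The tests therefore assert the 0.05 property.

## Surface smoothing

Vertex values are smoothed with a Gaussian kernel of FWHM 3 mm
(σ = FWHM/2.3548) on a flattened synthetic cortical sheet, using
Euclidean distance on the sheet as the geodesic proxy; weights are
truncated at 4σ and renormalized, so a constant field is a fixed
point. Excluded (filtered) vertices contribute no weight and receive
no value. The synthetic sheet places each vertex at
`r_mm = 15·log(1 + ecc)` along its preserved polar angle — a
complex-log retinotopy that keeps visual-field neighbors adjacent in
cortex, which is the only property smoothing relies on. Real cortical
folding, area boundaries and anisotropic magnification are *not*
emulated.

## GLM

Variable-epoch percept regressors are parsed from key-press streams:
display onset to first press is a `pre_first_press` epoch (convolved
like any other epoch), then each inter-press interval carries the
pressed state; repeated presses of the current state merge into the
ongoing epoch. Fixation is modeled implicitly (no baseline
regressor), so "vs fixation" contrasts are single-regressor weights.
Boxcars are built on a 10× oversampled time grid, convolved, and
sampled at volume onsets; zero-duration events (dot-flicker) enter as
unit impulses. The high-pass filter is an orthonormal DCT basis with
`floor(2·T_run/cutoff)` drift columns; the residual-forming projection
is applied identically to data and design (idempotent by
orthonormality). Cutoffs follow the experiment: 128 s (diamond),
185 s (dots and dots-quadrant), 155 s (mapping).

AR(1) handling is a two-pass prewhitening: OLS residuals give one
lag-1 autocorrelation pooled over vertices, both sides are transformed
(`z_t = z_t − ρ z_{t−1}`) and the model refit. This approximates full
restricted-maximum-likelihood AR(1) estimation; it shares the pooled-ρ
assumption but not the ReML variance-component machinery. Degrees of
freedom count the condition, nuisance and drift regressors.

## Searchlight back-projection

Membership uses strict `d < r` (boundary ties are measure-zero). The
per-cell statistic is the one-sample t with sample sd (n−1); cells
with n ≤ 1 are set to 0. A zero sd with n ≥ 2 (possible only in
noise-free synthetic input) returns a signed finite sentinel (1e6)
rather than ±∞, and is only relevant to degenerate tests.

The vertex distance weight is `1 − d/r`: bounded, monotone
decreasing, 1 at the center and 0 at the rim. This is the
implementation of "radius-normalized inverse distance" adopted here —
the unbounded alternative `r/d` is available via
`weight_scheme="reciprocal"` but is not the default because a single
vertex arbitrarily close to a center would dominate every other
contribution. Summary weights of single-vertex cells are set to 0;
normalization divides by the 25th percentile of the traversed-cell
distribution (zero-weight cells included by default; configurable) and
clips at 1. If that percentile is 0 (very sparse input), nonzero cells
map to 1 and zeros stay 0.

Rendering clips t at a figure-specific cap (±25/±15 for the diamond
conventions, ±35/±25 for the dots conventions), maps it through a
diverging colormap, and multiplies each cell's color saturation by its
normalized weight; zero-weight and untraversed cells render as
background.

## RSA and classical MDS

Map dissimilarity is `1 − Spearman ρ` over cells valid (n ≥ 2) and
traversed in *both* maps, with average ranks for ties; at least 3
shared cells are required. Untraversed cells are always excluded.
cMDS is the Torgerson formulation: double-center the *squared*
dissimilarities, eigendecompose, scale the top-k eigenvectors by
√eigenvalue; negative and numerically-zero eigenvalues are truncated
to 0, axes are ordered by decreasing eigenvalue, and each axis sign is
canonicalized (first nonzero coordinate positive) for reproducible
plots.

## Synthetic data: what it emulates, and what it does not

- **pRF populations**: eccentricities drawn as `ecc_max·u^q` (q the
  area's density exponent), uniform polar angle, linear σ–eccentricity
  scaling with lognormal scatter. Defaults (V1: σ = 0.5 + 0.15·ecc,
  V2: 0.7 + 0.2·ecc, V3: 0.9 + 0.25·ecc, VLOC: 1.5 + 0.4·ecc, with
  VLOC the sparsest in the periphery) are illustrative of the
  qualitative V1→VLOC progression, not fitted constants.
- **Percept streams**: dwell times are gamma-distributed (shape 2),
  the standard right-skewed choice for bistable alternation; default
  mean dwell 8 s per state over a 400 s display window. States
  alternate strictly; the pre-first-press latency is drawn like a
  dwell time.
- **Differential betas**: each vertex receives the signed amplitude of
  the region containing its pRF center plus Gaussian noise; the
  default diamond pattern is segments −δ, corners −δ/2, center +δ/2,
  background +δ with δ = 0.5 and noise sd 0.5. Centers outside every
  mask fall back to background.
- **Not emulated**: spatially correlated noise, vertex-to-vertex noise
  correlations induced by smoothing real data, eye movements,
  hemodynamic nonlinearity, per-vertex HRF variation, cortical folding.
  Passing tests therefore establish the *correctness of the analysis
  chain* and its behavior under idealized noise, not the effect sizes
  or spatial autocorrelation structure expected in real recordings.

## Ground truth for end-to-end recovery

The recovery check compares the sign of the noisy back-projected map
to the **noise-free back-projection of the injected effects** (same
searchlight aggregation, zero noise), excluding cells whose noiseless
mean is exactly zero. Near region boundaries a searchlight genuinely
aggregates a mixture of regions, so the region label at the cell
center is not the injected ground truth *of that cell*; the noiseless
aggregate is. Under the default conditions (δ = 0.5, noise 0.5, 4,000
V1-like vertices) sign agreement on well-sampled cells (w ≥ 0.5) is
≈ 97%.

## Null calibration

Calibration of the cell t-statistics is assessed on spatially disjoint
searchlights (centers ≥ 2 dva apart, so no shared vertices), since
neighboring cells share most of their member vertices and are strongly
dependent. With zero injected effect, the fraction of disjoint cells
exceeding the two-sided t critical value at α = 0.05 (per-cell dof
n − 1) is ≈ 4.4% over 30 independent noise draws.

## Problem sizes and determinism

Default analysis sizes — 2,000 vertices for the oracle-equivalence
check, 100 vertices for noiseless pRF recovery, 4,000 vertices for
pattern recovery, 400 per participant for the RSA checks, 30 noise
draws for calibration — were chosen as the smallest sizes at which the
quantities of interest are stable to well within their tolerances.
Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); a fixed seed reproduces outputs exactly,
and the recipe runner records seed, configuration, stage timings and
filter cascades in a JSON manifest.
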