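# Methods

`metfref` implements a statistical pipeline for building and applying
reference ranges for middle ear transfer functions (METFs) measured by
laser Doppler vibrometry (LDV) on the stapes footplate of human
temporal bone (TB) specimens.  This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## The measurement model

An METF is the frequency-domain ratio of stapes output (footplate
displacement or velocity) to sound pressure at the tympanic membrane.
From a two-channel voltage recording the package estimates it as a
calibrated H1 transfer function,

    |H(f_k)| = (a_k / b_k) · |S_xy(f_k)| / S_xx(f_k),

with S_xx, S_yy, S_xy the auto/cross spectra averaged over
`n_averages` rectangular FFT blocks and a_k, b_k per-bin calibration
factors for the LDV and microphone channels (default 1, i.e. simulated
voltages are treated as physical units).  H1 is the standard estimator
when the excitation side is noise-free, which is how the stimulus is
generated here.  No window or overlap is used: excitation tones are
constrained to exact FFT bins (`frequency = m·fs/block_size`), so
rectangular blocks are leakage-free and the estimate is deterministic
given the signals.  The bins *between* tones carry no excitation
energy, which is what makes two quality measures available:

* coherence γ²(f) = |S_xy|²/(S_xx·S_yy) ∈ [0, 1], requiring ≥ 2
  averages (one average gives γ² ≡ 1 identically); and
* adjacent-bin SNR: tone magnitude over the mean magnitude of the six
  nearest non-excited bins (3 below / 3 above; the next-nearest free
  bin is used when a window would collide with another tone).

Three lab gating profiles are provided, with strict inequalities:
`dresden` (γ² > 0.8), `hannover` (SNR > 12 dB), `shanghai` (SNR >
10 dB below 1 kHz, SNR > 20 dB at and above it — the 1 kHz boundary is
assigned to the stricter rule).

Because the LDV beam meets the footplate at an incidence angle θ to
its normal, the measured magnitude is the projection d·cos θ; the
correction adds −20·log10(cos θ) dB (2.58 dB at 42°, 1.25 dB at 30°,
3.01 dB at 45°).  Phase is not modeled anywhere: the analysis operates
on magnitudes only.

## Preprocessing

Acquisition grids vary between labs, so curves are linearly
interpolated onto the audiological grid {125, 250, 500, 1000, 2000,
3000, 4000, 6000} Hz.  The default abscissa is frequency in Hz; a
log10-frequency mode is available (`interp_axis="log_hz"`) because
the choice is genuinely open — results for the audiological targets
differ by fractions of a dB on smooth curves.  Exact source matches
are copied verbatim; targets without valid bracketing points are left
missing — never extrapolated.  A curve is usable at all only if every
grid target in 1000–4000 Hz is supported by valid measurements: an
exact valid match, or valid *nearest* bracketing points (the points
linear interpolation would actually use).  The pipeline order is
fixed: quality gate → interpolation → outlier screening.

## Outlier screening

Per frequency, Tukey fences are set at Q1 − k·IQR and Q3 + k·IQR with
k = 1.75 by default — more lenient than the Gaussian-conventional 1.5
because METF magnitudes are left-skewed, and k = 1.5 would discard an
unreasonable share of genuinely normal specimens.  Quartiles use
linear interpolation of order statistics (numpy's `linear` method,
the common spreadsheet convention); the convention is configurable
because exclusion counts are sensitive to it.  Values exactly on a
fence are kept (flagging is strictly outside).

A curve with any flagged point inside the 500–4000 Hz core band is
discarded entirely — a single outlier there may be the visible part of
a wider peak whose neighbours escaped flagging.  Flags confined to the
edges truncate the curve at the most medial flagged frequency: that
point and everything outward of it are removed, while unflagged points
medial of it survive.

Screening runs twice: pass 1 within each (group, method) cell, for
between-group comparisons; pass 2 on the pooled single-point-LDV
(method "A") data, from which the reference is built, with fences
recomputed from the pooled sample.  By default the two passes are
independent branches (pass 2 pools the raw method-A data); a
`chain_passes` flag feeds pass-1 survivors into pass 2 instead, since
either reading of a branched workflow is defensible.

## Variance decomposition

The crossed random-intercepts model

    y_ijkf = Σ_q β_q z_f^q + u_tb(i) + u_method(j) + u_group(k) + ε,
    u_r ~ N(0, σ²_r),   ε ~ N(0, σ²_ε),

uses a cubic fixed effect in z = standardized log10 frequency
(standardized over the grid to keep the Vandermonde design
well-conditioned; the covariate scale is recorded in the fit object).
Specimen, measurement method and research group are crossed, not
nested: several groups contribute several methods.

Estimation is REML, profiled over β and σ²_ε so the optimization runs
only over the variance ratios γ_r = σ²_r/σ²_ε (Nelder–Mead on log γ,
started from equal ratios, deterministic given the data).  Each
criterion evaluation reduces, via the Woodbury identity, to one
Cholesky factorization of the q×q system I + G^{1/2}Z'Z G^{1/2}
(q = total number of random levels), so designs with hundreds of
specimens fit in about a second.  On small datasets the implementation
agrees with the independent general-purpose REML solver in statsmodels
to three decimals in every variance component (cross-checked in the
test suite).  Variances estimated at the boundary are reported as 0
with a boundary flag, never as an error; random factors observed at a
single level are dropped with a warning and reported 0.
Non-convergence sets `converged=False`, never silently.

Explained variance follows the Nakagawa–Schielzeth decomposition:
R²_marginal = σ²_f / (σ²_f + Σσ²_r + σ²_ε) with σ²_f the population
variance of the fixed-effect predictions over the observed design;
R²_conditional adds Σσ²_r to the numerator.

A practical caveat the test suite quantifies: with only 4 method and
5 group levels, the method/group variance estimates carry ~3–4
degrees of freedom, so a single fit estimates those SDs only to
roughly ±40–50%.  This is an information limit of any estimator at
those level counts, not a solver property; the specimen and residual
SDs (hundreds/thousands of df) recover to a few percent.

## Group comparisons

Between-group differences are tested per frequency with Welch t-tests
(heteroscedasticity is expected between labs) under Holm's step-down
adjustment.  The Holm family is the set of pairwise tests within one
frequency — cross-frequency pooling is not implied when each frequency
is reported separately — with a `holm_family="global"` switch for the
stricter pooled family.  Kurtosis is reported in both conventions
(raw and excess) since "kurtosis < 2" is ambiguous between them.

## Reference construction

Per frequency, the reference carries the sample mean, the 95% t-based
confidence interval of the mean (x̄ ± t_{1−α/2,n−1}·s/√n), and
two-sided normal tolerance intervals x̄ ± k₂(n, p, α)·s for
p ∈ {0.90, 0.95, 0.99} at confidence 1−α = 0.95.  The default k₂ is
Howe's approximation,

    k₂ = z_{(1+p)/2} · √( ν(1 + 1/n) / χ²_{ν;α} ),  ν = n − 1,

with χ²_{ν;α} the lower-α quantile.  The exact factor — solving the
Krishnamoorthy–Mathew integral condition with adaptive quadrature and
Brent root-finding (tolerance 1e−8) — is provided for cross-checking;
at n = 366 the two agree to 0.008%, and at n = 20 Howe's 2.752 sits
0.3% below the exact 2.760, making its empirical confidence about
94.5–95% (within one point of nominal, verified by simulation in the
suite).  Intervals are computed per frequency with no joint
adjustment, and normality of the dB values is assumed (the pooled METF
samples support it: |skewness| and kurtosis below 2, large n).  A
frequency with fewer than 4 values is skipped with a warning.

The builder emits the reference in both unit conventions; since
velocity_dB = displacement_dB + 20·log10(2πf) exactly per frequency,
the second table is the exact affine image of the first.  The
packaged multicenter reference constants satisfy this identity within
0.13 dB (the rounding of values printed to one decimal).  Only the
95% TI proportion is tabulated in the packaged constants; the
validator transparently falls back from an untabulated proportion to
0.95.  The packaged metadata records 366 curves / 2321 points; the
underlying dataset is described in one place as 362 measurements, and
that discrepancy is recorded, not adjudicated.

## Validation of new measurements

Each study curve is checked for containment in the reference TI,
frequency by frequency.  Violations confined to the edges (< 500 Hz or
> 4 kHz) yield `valid_after_truncation` with the offending band listed
for removal; any core-band violation yields `flagged` — flagged curves
are reported, never auto-excluded, because the researcher must judge
whether the cause is pathology, measurement error, or a genuinely
unusual normal ear.  Single-frequency violations are annotated as
possible narrow-band resonances/antiresonances but still counted.

The study mean is compared to the reference mean with an advisory at
|deviation| > 6 dB (the rule-of-thumb bound on a plausible lab
effect), alongside the caveat that a small study's mean falling
outside the reference CI of the mean is expected, not alarming.
Sample-size advisories: strong warning below n = 5, soft warning
below n = 10.

The leverage of one extreme measurement is quantified by a
deterministic surrogate: a study of n−1 typical observations (mean μ,
sample SD σ) plus one observation at the TI edge μ + k₂σ gives

    mean shift = k₂σ/n,
    new SD     = √( σ²(n−2)/(n−1) + (k₂σ)²/n ).

The surrogate treats the edge observation as one *of* the n (it
augments n−1 others), is labeled as a model choice in its output, and
is cross-checked against a Monte-Carlo version (n−1 draws from the
reference normal, ≥10⁴ replicates) that matches its mean shift within
a few percent at n from 3 to 30.

## The synthetic-data generator

`sample_population` draws populations with exactly the variance
structure the analysis assumes: a cubic mean curve in standardized
log10 frequency (by default fitted to the packaged displacement means;
the cubic tracks all 8 means within 2.8 dB, the worst residual sitting
at the 1 kHz resonance a cubic cannot fully follow), crossed random
intercepts with SDs 4.2 dB (specimen), 3.4 dB (method), 1.4 dB
(group), and i.i.d. residual noise.  The residual default of 3.0 dB
is derived, not quoted: the implied total specimen-level SD
√(4.2² + 3.0²) ≈ 5.2 dB reproduces the packaged 95% TI half-width at
1 kHz (≈10.4 dB) divided by the large-n tolerance factor ≈ 2.0.
Optional left skew applies a variance-preserving skew-normal transform
to the residuals only (random intercepts stay Gaussian) — the simplest
structure consistent with per-frequency skew in real data.  Each
entity class (groups, methods, specimens, residuals) has its own RNG
stream spawned from the master seed, so enlarging a population never
perturbs existing draws.

What the generator does **not** emulate: method-specific physics
(footplate rocking modes, µCT-derived volume displacement — methods
differ only by an intercept), frequency-dependent variance and
kurtosis, within-curve correlation of residuals across frequency,
laser speckle dropouts, and nonlinear transmission at high sound
pressure.  Tests passing on generated data therefore demonstrate the
statistical machinery under the stated model, not robustness to every
feature of real measurements.

`make_outlier_fixtures` injects unambiguous screening cases (+30 dB at
2 kHz → discard; −30 dB at 6 kHz / 125 Hz → truncate) into a base
population.  The base is first screened to a fixed point and the
injection re-checked for self-consistency, so chance extremes of the
base never contaminate the expected-verdict manifest.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make their Monte-Carlo
error small relative to the asserted tolerances: 2000 replicates for
TI confidence and Welch type-I rates, 10⁵ points for the Gaussian
fence-flagging rate, 2×10⁴ replicates for the impact cross-check, and
20 seeded replicates of a 5×4×30 crossed design (600 specimens, 4800
points) for LMM parameter recovery.  Every stochastic component takes
an explicit seed; `scripts/acceptance.py` derives all of its streams
from a single `--seed` and recomputes every reported number at run
time.

## Known limitations

* The reference constants are carried at the printed one-decimal
  precision; identities across units hold only within that rounding.
* The 90%/99% TI columns of the packaged reference are not available;
  the validator falls back to the 95% TI.
* Exclusion counts depend on the quantile convention; only the default
  convention is exercised by the shipped tests.
* The exact tolerance factor's quadrature assumes n large enough that
  the X̄ integral is effectively supported on ±8 standard errors;
  below n = 2 nothing is defined.
* The LMM assumes Gaussian random effects and residuals; with strong
  left skew the variance components remain consistent but are no
  longer efficient.
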