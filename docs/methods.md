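# Methods

This note documents the models, conventions and numerical choices behind
`chemoassay`, and what the synthetic phantoms do and do not establish
about real instrument data.

## OCT layer segmentation and outcome measures

**Model.** A B-scan is a 2-D greyscale cross-section, row 0 at the top,
with the biofilm occupying the rows above a known substrate row. Biofilm
material appears in two intensity strata: a brighter *coherent* layer that
stays attached to the substrate, and a dimmer *disrupted* layer that
detaches at an air–liquid interface. Segmentation is 3-class multilevel
Otsu thresholding of the above-substrate histogram: the threshold pair
(t₁ < t₂) maximizing the between-class variance over all ordered pairs of
occupied grey levels, ties broken by the lexicographically smallest pair.
The search over occupied levels is exhaustive (vectorized via prefix sums
for 2 and 3 classes) and is equivalent to a search over the full grey
range, because lowering a threshold to the largest level of its lower
class never changes the partition. Images with more than 256 distinct
levels are re-binned to 256 bins first.

**Heights and outcomes.** Layer thickness per pixel column is the *count*
of same-label pixels above the substrate times the pixel pitch. Counting
is hole-insensitive, which matters because real disrupted strata are
non-contiguous; the alternative (distance from substrate to topmost class
pixel) overestimates whenever a stray bright speckle sits high in the
column. Dissolution is the per cent reduction of the mean coherent
thickness. Disruption is the per cent increase of the mean disrupted
thickness **normalized by the pre-treatment total (coherent + disrupted)
thickness**; normalizing by the pre-treatment disrupted layer alone would
blow up in the common case where that layer starts near zero. Both
normalization choices are conventions of this package and are shared by
the phantom generator, so generator truth and analyzer output are
commensurable by construction.

**Per-image vs shared thresholds.** `segment_layers` thresholds each
image independently (the usual single-image practice).
`analyze_pair` — the pre/post comparison — instead pools the two
above-substrate histograms and applies one threshold pair to both scans,
by default. Reason: 3-class Otsu *must* produce three classes, so on a
post-treatment scan whose coherent stratum has dissolved completely it
will split the disrupted stratum and fabricate coherent pixels, biasing
dissolution downward by tens of points for such samples. Pooling keeps
the stratum definitions fixed across the pair; `shared_thresholds=False`
restores per-image behaviour.

**Degenerate scans.** A scan whose above-substrate region holds fewer
than three distinct grey levels is treated as signal-free and returns an
all-background mask with a warning rather than an error.

**Optics.** `pixel_pitch_um` is assumed already corrected for the
acquisition refraction index (1.33 for hydrated biofilm); the index is
carried as metadata only and no further scaling is applied.

## Stress relaxation and the generalized Maxwell model

**Model.** Under a constant strain ε (default 0.2, established by a 1 s
ramp that is excluded from the record; t = 0 is ramp end), the relaxation
modulus is a four-arm Prony series E(t) = Σᵢ Eᵢ e^(−t/τᵢ) with Eᵢ ≥ 0.
The percentage stress relaxation is R = 100·(σ(0) − σ(D))/σ(0) with
D = 100 s, σ(0) read at the first sample and σ(D) interpolated linearly
between the neighbouring samples. Arms map to constituents by time
constant: free water τ < 0.5 s, bound water 0.5–3 s, EPS 3–100 s,
bacteria > 100 s. Bins are **half-open** [lower, upper) with the slowest
bin unbounded above, so a boundary value (τ = 0.5 s exactly) belongs to
the slower constituent; strict inequalities would leave boundary points
unassigned.

**Fitting.** Variable projection: `least_squares` (trf) optimizes log τ
inside per-bin bounds ([10⁻³, 0.5], [0.5, 3], [3, 100], [100, 10⁴] s —
the finite 10⁴ s surrogate stands in for the unbounded bacteria bin and
also plays the role of a quasi-equilibrium spring), and at every step the
spring constants come from non-negative linear least squares. Multi-start
(default 8): first start at the bin log-midpoints, the rest log-uniform
within bins from a fixed seed; lowest SSE wins. Constrained fitting
guarantees the output is allocatable to the four constituents; an
unconstrained mode (`bins=None`) exists for sensitivity checks and is
only sorted, not binned.

Residuals are evaluated at **all** of the record's sample times up to D.
With uniform sampling and homoscedastic noise this unweighted fit is the
maximum-likelihood estimate. A log-time subset mode (`n_points=N`) is
provided for speed, but de-weighting the dense tail was found to amplify
noise in the ill-conditioned EPS/bacteria split: the Eᵢ ≥ 0 clip then
converts that noise into a systematic upward bias of the bacteria
importance (several percentage points at 1% noise), so subsetting is not
the default.

**Known estimator bias.** When the true EPS time constant sits near the
100 s bin boundary and the EPS arm is small (~10% importance), 1% noise
still lets the fit collapse the EPS arm into the bacteria arm in a
fraction of samples; the group-mean bacteria importance then runs ~2
points high. This is a property of the measurement at that noise level,
not of the calibration, and is left as is.

**Evaporation.** Buffer evaporation appears as a slow baseline drift.
The supported correction subtracts a blank reference trace interpolated
to the record's sample times (exact for any drift shape the blank
captures). When no blank exists, `estimate_tail_drift` offers a
linear-slope estimate over the final 20 s behind an explicit call — it
over-corrects when slow arms are still relaxing, which is why it is not
automatic.

**Relative importance.** pctᵢ = 100·Eᵢ/ΣⱼEⱼ — the arm's share of total
stiffness at t = 0, before any relaxation. The vector sums to 100 by
construction and is scale-invariant (multiplying stress by c scales every
Eᵢ by c).

## Confocal biovolume fractions

Each channel gets one global Otsu threshold (per-slice thresholds are
unstable on sparse slices of shallow stacks); biovolume is foreground
voxel count × voxel volume; fractions are percentages of the summed
biomass. Voxels foreground in several channels count toward each channel
independently — per-channel biovolumes are computed independently, so no
exclusive assignment is imposed. No connectivity filtering or minimum
object size is applied.

**Signal-free channels.** Otsu produces a split even of pure detector
noise (splitting a Gaussian at its mean leaves the class means ~1.6
within-class SDs apart). A channel's split is therefore kept only when
the class-mean separation exceeds 2.0 × the summed within-class SDs;
otherwise the channel is declared empty with a warning. Genuinely stained
channels at the phantom's design SNR ≥ 5 separate by ≥ 5 foreground SDs
and pass this test with a wide margin, so the guard only fires on
(effectively) unstained channels.

## Factorial statistics

Fixed-effects two-way ANOVA with interaction on the time × volume design,
Type III sums of squares with sum-to-zero contrasts (the default factorial
output of the major statistics packages; identical to the classical
decomposition on balanced data). Preconditions are checked explicitly:
≥ 2 occupied levels per factor, no empty cells (named in the error),
positive residual df. Tukey HSD on factors with ≥ 3 levels compares
marginal means with the studentized-range distribution using the
*factorial* residual mean square and df (Tukey–Kramer SE for unequal
sizes); two-level factors are skipped with a notice since the omnibus F
already is that contrast. Simple effects test each factor inside each
level of the other with F = (SS_slice/df_slice)/MS_resid against the
pooled omnibus residual — the standard syntax-driven procedure — rather
than per-slice error terms. An all-constant outcome yields zero SS and
undefined p with a notice. No multiplicity adjustment is applied across
outcomes, and normality/homoscedasticity are not gated, matching common
reporting practice; both are deliberate scope choices.

## Synthetic phantoms

**OCT.** Column-wise layer heights are a nominal mean (250 µm total,
split 80/20 coherent/disrupted by default) plus a smooth zero-mean
roughness profile (Gaussian-filtered white noise, SD = `roughness_um`)
shared between the pre and post scans of a pair (same physical sample).
The post scan scales every coherent column by (1 − dissolution/100) and
shifts the disrupted stratum by disruption/100 × realized pre-treatment
total. Rendering quantizes heights to whole pixels (2 µm pitch), applies
multiplicative log-normal speckle (σ = 0.05, mean-corrected to unity) and
adds a bright substrate band. The phantom does **not** model physical
speckle statistics, depth attenuation, the optical point-spread function
or realistic microcolony morphology — recovery results bound only
quantization and thresholding error, not those physics.

**Relaxation curves.** σ(t) = ε·ΣEᵢe^(−t/τᵢ) + drift·t + Gaussian noise,
sampled at 100 Hz for 100 s, with the matching drift-only blank returned
alongside. Group generation draws per-sample importance vectors and a
log-normal total modulus (median 1 kPa, σ_log = 0.3 — a typical soft
biofilm stiffness scale), sets noise to 1% of initial stress and drift to
−0.1 Pa/s by default.

**A structural constraint: R is not free.** For any Prony series,
R = 100·(1 − Σ pᵢ e^(−D/τᵢ)) with pᵢ the importance fractions — R is pinned
to the slow-arm importances (the fast arms are fully relaxed at D). Group
targets for R and for the importances therefore cannot be drawn
independently; the generator draws the importance vectors, fixes
τ₁ = 0.15 s and τ₂ = 1.2 s (bin log-midpoints; immaterial to R), and
solves the group-level (τ₃, τ₄) so the realized mean R equals the target
(τ₄ preferred near 3000 s, τ₃ absorbing the residual, with fallback
adjustment and a warning when the target is infeasible inside the bins).
Per-sample true R is then *derived*. A consequence worth noting: the
reference group statistics this package ships show R-SDs nearly equal to
the bacteria-importance SDs in both volume groups, which is exactly the
signature of this constraint in real data.

**Calibration modes.** Per-sample truths are drawn
Normal(group mean, between-sample SD) and truncated to their valid ranges
(`calibrate="population"`), or additionally standardized so the *sample*
mean and SD equal the targets exactly (`calibrate="sample"`, iterative
clip-and-standardize; feasible whenever the SD is below the Bhatia–Davis
bound √((m−lo)(hi−m))). Sample calibration is what the end-to-end
recovery tests use: the pipeline's recovered group mean is then compared
against the calibration target without sampling luck in the truth draw.
Dissolution truths live in [0, 100] by default; because published spreads
at short exposures exceed their means (real samples swell), the reference
factories enable `allow_negative_dissolution`, widening the range to
[−100, 100]. Free-water and bacteria importances are drawn jointly with
correlation −0.4 (a stiffer slow arm means proportionally less fast arm),
projected into {f, b ≥ 0.5, f + b ≤ 98}; bound water and EPS split the
remainder in the design's target ratio — their group values are not
separately published, so an even split is used.

**CLSM.** `round(fill × N)` biomass voxels are placed uniformly at random
(no spatial structure, deliberately) and partitioned between channels by
largest-remainder rounding, so channel counts land within one voxel of
target. Background is tight dark noise (SD 2 grey levels), foreground is
wider (SD 8), Poisson-like in spirit; `intensity_snr` is the
foreground/background mean separation in foreground SDs. Real stacks have
correlated speckle, depth-dependent attenuation and a ~60 µm staining
penetration limit, none of which are modelled; recovery results validate
the counting arithmetic and thresholding, not those effects.

**Determinism.** All generators accept a `numpy.random.Generator` or a
seed; `generate_study` derives everything from one `SeedSequence`, and
identical seeds produce byte-identical manifests and TIFFs.

## Problem sizes used in validation

The shipped validation studies use 30 pre/post B-scan pairs
(256 × 420 px) for the OCT recovery group, 20 relaxation curves
(10 001 samples each) per volume group with 8-restart fits, the full
10%-step simplex grid (66 compositions) for confocal recovery, and 2000
null simulations of the 3 × 2 design (n = 10/cell) for the type-I-error
calibration of the ANOVA. These sizes put Monte-Carlo error well inside
the published between-sample spreads while keeping the whole suite at
about a minute of compute.
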