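# Methods

`solegrf` predicts the three-directional ground reaction force (GRF) a foot
exerts on the ground during single stance from the 12 force channels of an
instrumented shoe: four triaxial sensors at the heel, first metatarsal
head, fifth metatarsal head and toe. Two regression models map the
instantaneous 12-channel sensor vector to each GRF component — a stepwise
multiple linear regression (MLR) and a Gaussian process regression (GPR)
with predictive uncertainty — and both are evaluated by leave-one-step-out
cross-validation against force-plate measurements. Because no public
recordings of such a system exist, the package ships a synthetic gait
generator that plays the role of the laboratory: every stage downstream of
it treats its output exactly like raw instrument data.

## The synthetic cohort

A trial is one left-foot strike on a force plate, recorded on three
independent clocks: the sole sensors at 870 Hz, the plate at 1000 Hz, and
heel/toe reflective markers at 200 Hz. Three movements are simulated:
straight walking and two turning strategies with a heading change of
about 20° — a side-step turn and a cross-step turn, whose mediolateral
force signatures are mirror images of each other.

### Waveforms

Shoe-frame GRFs are sums of Gaussian bumps in the stance fraction
s ∈ [0, 1], scaled by body weight m·g and forced to zero at heel contact
and toe-off by a 3%-of-stance cosine taper:

* **Vertical** F_z: loading and push-off peaks of 1.1 BW at s = 0.25 and
  0.75 (width 0.18) minus a midstance valley of 0.4 BW at s = 0.5 (width
  0.12), clipped at zero. The resulting curve is the classic double hump
  with a valley near 0.44 BW.
* **Anteroposterior** F_y: a braking bump of −0.20 BW at s = 0.22 and a
  propulsion bump of +0.20 BW at s = 0.80 (width 0.10).
* **Mediolateral** F_x: a base bump of 0.06 BW at s = 0.35 (width 0.20)
  plus, for turns only, a bump of ±0.08 BW at s = 0.55 (width 0.25) whose
  sign distinguishes side-step from cross-step turning.

All widths, centers and amplitudes are fields of `WaveformParams`. The
peak widths (0.18) were chosen so the midstance valley stays well above
the stance-detection thresholds; narrower peaks would let the vertical
force dip to zero at midstance, splitting the stance phase in two.

Body mass is drawn per participant from N(58.0, 5.4²) kg truncated to
[40, 90] kg. Stance duration is 0.65 s jittered ±10% per step. Heading is
the movement's nominal angle plus N(0, 2°) per trial.

### Variability model

Vertical and anteroposterior amplitudes vary multiplicatively: a
per-participant factor (SD 0.08) times a per-step factor (SD 0.05),
reflecting that a person's loading pattern is consistent across their own
steps and movements.

Mediolateral variability is additive, not multiplicative, because the
calibration targets are absolute: the generator is tuned so that the mean
(over stance) SD of F_x/m reaches, per movement,

| movement   | between-participant (N/kg) | within-participant (N/kg) |
|------------|---------------------------:|--------------------------:|
| straight   | 0.148                      | 0.089                     |
| side-step  | 0.151                      | 0.121                     |
| cross-step | 0.221                      | 0.183                     |

— i.e. cross-step turning, where balance is hardest to keep, is the most
variable movement. Each trial's F_x gains two smooth random curves
(Gaussian bumps at s = 0.45 and 0.55, widths 0.25/0.30): one with a
coefficient drawn per participant **and** movement (how hard someone
pushes sideways in a cross-step turn says little about their
straight-walking mediolateral force), and one drawn per step. Coefficient
SDs solve target = g·sd·mean(shape·taper) exactly, so the cohort-level
statistics land on the table above by construction; an 8-participant ×
10-step cohort reproduces them within ±15% (sampling noise of an
8-participant SD is ~27%).

### Sensor model

Vertical channels share the vertical force through nonnegative
raised-cosine activation windows w_i(s) peaking at s = 0.15 (heel), 0.50
(MT5), 0.55 (MT1) and 0.85 (toe), normalized so Σ_i w_i = 1: with noise
off, the summed vertical channels reproduce F_z to machine precision.
Shear channels mix a vertical-coupled term ρ_i(s)·f_zi (site-specific
piecewise-linear ratio curves, |ρ| ≤ 0.3) with a windowed share of the
shoe-frame shear force. Anteroposterior shear couples at 0.5·w_i at every
site. Mediolateral shear couples site-dependently — 0.2 at the heel, 0 at
both metatarsal sites, 0.5 at the toe. This asymmetry is the generator's
model of the key physical limitation of a four-sensor sole: a single
heel-to-midfoot sensor cannot separate the two turn strategies, whose
mediolateral forces differ mainly in mid-stance sign. It makes F_x the
hardest direction to predict, and makes a model pooled over movements
strictly worse in x than per-movement models — the qualitative structure
the analysis is meant to exhibit. The couplings were calibrated so that
per-movement GPR mediolateral %RMSE falls in the high-single-digit range
(straight/side-step under 10%) while the pooled model is measurably worse.

Per-channel measurement noise is Gaussian with SD = 2% of that channel's
noise-free range. Padding (0.15 s each side) carries sub-threshold
baseline noise only, so stance detection has an unambiguous answer.

The 12→3 map is full-rank at every interior stance fraction
(σ_min/σ_max ≥ 0.03), so the GRF is recoverable from the channels in the
least-squares sense — the property that makes regression meaningful.

### What the generator does *not* emulate

No sensor saturation or hysteresis, no shoe deformation, no double-support
force sharing, no marker dropout, no inter-device clock offset by default
(a config option exists), and the waveform shapes themselves do not vary
between participants beyond amplitude/additive effects. Passing tests on
this cohort therefore demonstrate the correctness and calibration of the
*pipeline*, not field performance on real instrumented-shoe data.

## Preprocessing

Both force streams are low-pass filtered (4th-order Butterworth, 50 Hz
cutoff, forward–backward so the effective response is the squared
magnitude and the lag is zero — conventional for offline gait analysis).
Stance is the longest contiguous run of samples at or above threshold:
15 N on the summed vertical sensor channels, 50 N on the plate vertical
force; equal-length runs reject the trial as ambiguous. The heading angle
φ is the signed angle between the stance-mean toe−heel marker vector and
the walkway axis; plate forces rotate into the shoe frame by

    [F_x, F_y, F_z]ᵀ = [[cos φ, sin φ, 0], [−sin φ, cos φ, 0], [0, 0, 1]]·[F_X, F_Y, F_Z]ᵀ.

Each stream is then linearly interpolated onto 101 equally spaced points
of **its own** stance window (0% = heel contact, 100% = toe-off); cubic
interpolation is a config switch. Cross-device alignment is by stance
fraction, not wall clock, so no synchronization hardware is assumed.
A consequence worth knowing: because the two streams cross *different*
thresholds (15 vs 50 N) inside the steep contact taper, rows 0–3 and
97–100 of features and targets are systematically offset by up to the
threshold gap; the interior rows agree to < 2% of peak, and the full
round trip on noise-free data recovers the generator's shoe-frame curves
to < 0.5% relative RMS. Markers are used unfiltered; filtering precedes
stance detection.

## Models

**MLR** (per direction): F̂ = f·k + b. Predictors are chosen by classical
forward–backward stepwise selection on partial-F p-values (enter < 0.05,
remove > 0.10 — the de-facto defaults of the toolbox family this procedure
comes from; both config-exposed), ties broken toward the lower column
index, with a visited-subset cycle guard. Coefficients come from
QR-based least squares; the intercept is always present and never a
removal candidate. Under a pure-noise response the selection returns the
empty set with probability ≈ 0.95¹² ≈ 0.54.

**GPR** (per direction): F = Hβ + g(f) + ε with H ≡ 1, g a zero-mean GP
with isotropic squared-exponential kernel k(f_i, f_j) =
σf²·exp(−½‖f_i−f_j‖²/σl²), and iid noise variance σ². Features are
z-scored per column and the response centered (both recorded in the
model). β is profiled out in closed form through the Cholesky factor of
K + σ²I at every likelihood evaluation, and (log σf, log σl, log σ) is
optimized by L-BFGS-B with analytic gradients of the profiled log
marginal likelihood (envelope theorem: β̂ may be held fixed when
differentiating). Initialization: σl = mean pairwise distance of a
≤500-row subsample of standardized features, σf = SD of the centered
response, σ² = 0.1 × its variance; random restarts (up to 5) fire only if
an attempt fails, and the returned model never has a likelihood below its
initialization. Cholesky factorizations add adaptive jitter (0, then
10⁻¹⁰×mean-diagonal escalating ×10 to at most 10⁻⁴) only when needed.

Exact dense algebra is used throughout — no inducing points. To keep the
O(n³) cost desk-scale, training sets above a cap (default 400 rows) are
thinned by a deterministic subsample stratified by stance percent; with
101-point curves the rows are highly redundant, and the cap costs little
accuracy while keeping a full cross-validation sweep in minutes on one
CPU.

Predictions report the full posterior mean and covariance; the per-point
variance adds σ² (predictive band for a new *measured* curve; a
latent-only band is a config switch), and the 95% interval is
μ ± 1.96·√variance.

## Evaluation

The cross-validation unit is the step: all 101 rows of one stance leave
together (leaving single rows out would leak the held-out step's
neighboring samples). Every fold refits everything — stepwise selection
for MLR, hyperparameters for GPR. Per held-out step and direction:

* MAE of mass-normalized force, (1/n)Σ|F/m − F̂/m|, in N/kg;
* %RMSE = 100·RMSE/(max − min) of the measured step's curve;
* adjusted R² = 1 − (SS_res/SS_tot)·(n−1)/(n−k−1) with n = 101 and k the
  fold's selected-predictor count (MLR) or 12 (GPR, since all channels
  enter the kernel; config-exposed). Negative values are legal and occur
  for poor fits.

Summaries report mean ± sample SD (n−1) across folds, per movement or
pooled; metrics are computed per fold and then averaged, never pooled
before computation. The cohort variability summary uses: within-
participant SD = SD across one participant's steps at each stance
percent, averaged over percents then participants; between-participant
SD = SD across participant-mean curves at each percent, averaged over
percents. (The estimator has free choices; this is the convention used
everywhere here.)

On the default cohort the pooled 95%-interval coverage of GPR is 87–90%:
slightly below nominal because step-level random effects make residuals
within a held-out step correlated, which an iid noise term cannot
represent. On a cohort without step-level effects (the GP's actual model)
coverage is ~90%. This mild under-coverage is a known limitation of
treating curve-level variation as pointwise noise.

## Problem sizes and seeds

The default experiment is 3 participants × 4 steps × 3 movements = 36
steps (per-movement datasets of 12 steps, a pooled dataset of 36), chosen
as the package's desk-scale standard; the generator scales to the full
8 × 10 × 3 protocol by config. Everything is a pure function of the
master seed: per-trial seeds derive from (master seed, participant,
movement, step) indices, GP restart seeds from the same master seed, so
reruns are byte-identical.

## Known limitations

* The synthetic waveforms are literature-typical shapes, not fits to any
  specific cohort's curves; absolute MAE values are not comparable to
  published tables, while %RMSE and the qualitative orderings are the
  meaningful outputs.
* One isotropic length scale per direction (no automatic relevance
  determination); a single constant basis function.
* The GP's iid-noise assumption understates step-level correlation (see
  coverage above).
* Right-foot strikes, double stance and marker gap-filling are out of
  scope.
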