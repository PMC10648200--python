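"""Synthetic gait-trial generator.

Produces seeded, physiologically shaped multi-rate recordings of single
left-foot force-plate strikes: 12 shoe-sole sensor force channels at 870 Hz,
3 lab-frame force-plate GRF channels at 1000 Hz, and heel/toe marker planar
trajectories at 200 Hz, for straight walking and two turning strategies
(side-step and cross-step, which mirror the mediolateral force signature).

The waveform model is a sum of Gaussian bumps: a double-peaked vertical GRF,
a braking/propulsion anteroposterior GRF, and a movement-dependent
mediolateral GRF whose turning component flips sign between the two turn
types.  Sensor channels are derived from the shoe-frame GRF through
nonnegative site-activation windows (heel early, metatarsals mid, toe late
in stance) plus smooth site-specific shear ratio curves, so the 12-channel
vector determines the 3-channel GRF in the least-squares sense — the premise
that makes downstream regression meaningful.

Between- and within-participant variability of the mass-normalized
mediolateral GRF is calibrated per movement so that the generated cohort
reproduces the ordering (and approximate magnitude) of the variability
observed in real cohorts: cross-step > side-step > straight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

G = 9.81  # m/s^2

SENSOR_FS = 870.0  # Hz, sole-sensor sampling rate
PLATE_FS = 1000.0  # Hz, force-plate sampling rate
MARKER_FS = 200.0  # Hz, motion-capture sampling rate

SENSOR_SITES = ("heel", "mt1", "mt5", "toe")  # i = 1..4

#: Feature column order used everywhere downstream: f_x1..f_x4, f_y1..f_y4, f_z1..f_z4
FEATURE_COLUMNS = tuple(f"f{ax}{i}" for ax in "xyz" for i in range(1, 5))
TARGET_COLUMNS = ("Fx", "Fy", "Fz")


class DomainError(ValueError):
    """Raised when an argument is outside its mathematical domain."""


# ---------------------------------------------------------------------------
# Movement and participant types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovementType:
    """A walking movement: heading change and mediolateral force polarity.

    ``heading_angle`` is the planar angle (degrees) between the shoe's long
    axis and the walkway axis during the plate strike: 0 for straight
    walking, magnitude 20 for both turn types.  ``mediolateral_sign`` sets
    the polarity of the turning component of the mediolateral GRF; it is
    reversed between side-step and cross-step turning.
    """

    label: str
    heading_angle: float  # degrees
    mediolateral_sign: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.mediolateral_sign not in (-1, 1):
            raise DomainError("mediolateral_sign must be +1 or -1")

    @property
    def is_turn(self) -> bool:
        return self.heading_angle != 0.0


STRAIGHT = MovementType("straight", 0.0, +1)
SIDE_STEP = MovementType("side_step", -20.0, +1)
CROSS_STEP = MovementType("cross_step", +20.0, -1)

MOVEMENTS = {m.label: m for m in (STRAIGHT, SIDE_STEP, CROSS_STEP)}


@dataclass(frozen=True)
class ParticipantProfile:
    """Per-participant attributes drawn once per participant.

    ``amplitude_effect`` holds one standard-normal random effect per GRF
    direction (x, y, z).  The y and z effects scale the waveform amplitude
    multiplicatively and are consistent across a participant's movements;
    the x component is only a fallback for standalone trial generation —
    cohort generation draws the mediolateral effect per participant and
    movement (see :func:`generate_dataset`).
    """

    participant_id: str
    body_mass: float  # kg
    amplitude_effect: tuple[float, float, float]  # z-scores per direction
    heading_noise_sd: float = 2.0  # degrees

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise DomainError("body_mass must be positive")


# ---------------------------------------------------------------------------
# Waveform template
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformParams:
    """Parameters of the Gaussian-bump GRF template (all config-exposed).

    Amplitudes are fractions of body weight m·g; centers/widths are stance
    fractions.  The vertical force is two loading/push-off peaks minus a
    midstance valley; anteroposterior is a braking (negative) then
    propulsion (positive) bump; mediolateral is a small baseline bump plus a
    turning bump whose sign is the movement's ``mediolateral_sign``.
    """

    # vertical (z)
    fz_peak_amp: float = 1.1
    fz_peak1_center: float = 0.25
    fz_peak2_center: float = 0.75
    fz_peak_width: float = 0.18
    fz_valley_amp: float = 0.4
    fz_valley_center: float = 0.50
    fz_valley_width: float = 0.12
    # anteroposterior (y)
    fy_amp: float = 0.20
    fy_brake_center: float = 0.22
    fy_prop_center: float = 0.80
    fy_width: float = 0.10
    # mediolateral (x)
    fx_base_amp: float = 0.06
    fx_base_center: float = 0.35
    fx_base_width: float = 0.20
    fx_turn_amp: float = 0.08  # 0 for straight walking
    fx_turn_center: float = 0.55
    fx_turn_width: float = 0.25
    # cosine taper to force zero force at heel contact and toe-off
    taper_frac: float = 0.03
    # sensor site activation windows (raised cosine), one per site
    window_centers: tuple[float, ...] = (0.15, 0.55, 0.50, 0.85)
    window_halfwidths: tuple[float, ...] = (0.45, 0.50, 0.50, 0.45)
    # site shear-to-vertical ratio curves, linear in s: (value at s=0, value at s=1)
    rho_x: tuple[tuple[float, float], ...] = (
        (0.05, 0.00), (-0.05, 0.10), (0.05, -0.05), (0.00, 0.05))
    rho_y: tuple[tuple[float, float], ...] = (
        (-0.20, 0.00), (-0.10, 0.20), (-0.10, 0.15), (0.00, 0.30))
    # fraction of shoe-frame shear force transmitted through each site window;
    # anteroposterior shear is picked up at every site, but mediolateral shear
    # only weakly at the heel and mostly at the toe: a single heel-to-midfoot
    # sensor cannot separate the two turn strategies, which is what degrades
    # pooled-movement mediolateral prediction
    shear_coupling_y: float = 0.5
    shear_coupling_x_sites: tuple[float, ...] = (0.20, 0.0, 0.0, 0.50)


def _bump(s: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Gaussian bump in stance fraction."""
    return np.exp(-0.5 * ((s - center) / width) ** 2)


def _taper(s: np.ndarray, frac: float) -> np.ndarray:
    """Cosine taper: 0 at s=0 and s=1, 1 on [frac, 1-frac]."""
    t = np.ones_like(s)
    lo = s < frac
    hi = s > 1.0 - frac
    t[lo] = 0.5 * (1.0 - np.cos(np.pi * s[lo] / frac))
    t[hi] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - s[hi]) / frac))
    return t


def _fx_bracket(movement: MovementType, s: np.ndarray, p: WaveformParams) -> np.ndarray:
    """Dimensionless mediolateral shape (fraction of body weight), pre-taper."""
    out = p.fx_base_amp * _bump(s, p.fx_base_center, p.fx_base_width)
    if movement.is_turn:
        out = out + movement.mediolateral_sign * p.fx_turn_amp * _bump(
            s, p.fx_turn_center, p.fx_turn_width)
    return out


def grf_template(movement: MovementType,
                 s: float | np.ndarray,
                 mass: float,
                 scale: tuple[float, float, float] = (1.0, 1.0, 1.0),
                 params: WaveformParams | None = None,
                 x_additive: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Evaluate the shoe-frame GRF template at stance fraction(s) ``s``.

    Returns an array of shape (3,) for scalar ``s`` or (n, 3) for vector
    ``s``, columns ordered (Fx, Fy, Fz) in newtons.  Deterministic and
    continuous in ``s``; zero at both stance endpoints by the cosine taper.

    ``x_additive`` carries the trial's mediolateral random-curve
    coefficients (between-participant, within-step) in body-weight units;
    (0, 0) gives the nominal template.
    """
    p = params or WaveformParams()
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if np.any(s_arr < 0.0) or np.any(s_arr > 1.0):
        raise DomainError("stance fraction s must lie in [0, 1]")
    if mass <= 0:
        raise DomainError("mass must be positive")
    mg = mass * G
    taper = _taper(s_arr, p.taper_frac)

    fz_shape = (p.fz_peak_amp * _bump(s_arr, p.fz_peak1_center, p.fz_peak_width)
                + p.fz_peak_amp * _bump(s_arr, p.fz_peak2_center, p.fz_peak_width)
                - p.fz_valley_amp * _bump(s_arr, p.fz_valley_center, p.fz_valley_width))
    fz = np.clip(mg * scale[2] * fz_shape, 0.0, None) * taper

    fy_shape = p.fy_amp * (-_bump(s_arr, p.fy_brake_center, p.fy_width)
                           + _bump(s_arr, p.fy_prop_center, p.fy_width))
    fy = mg * scale[1] * fy_shape * taper

    cb, cw = x_additive
    fx_shape = (scale[0] * _fx_bracket(movement, s_arr, p)
                + cb * _bump(s_arr, *X_BETWEEN_SHAPE)
                + cw * _bump(s_arr, *X_WITHIN_SHAPE))
    fx = mg * fx_shape * taper

    out = np.column_stack([fx, fy, fz])
    return out[0] if np.isscalar(s) or np.ndim(s) == 0 else out


def activation_windows(s: np.ndarray, params: WaveformParams | None = None) -> np.ndarray:
    """Normalized site activation windows w_i(s), shape (n, 4), rows sum to 1.

    Raised-cosine windows peaked at heel → metatarsals → toe across stance;
    the normalization guarantees sum_i w_i(s)·Fz(s) = Fz(s) exactly.
    """
    p = params or WaveformParams()
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    raw = np.empty((s_arr.size, 4))
    for i, (c, h) in enumerate(zip(p.window_centers, p.window_halfwidths)):
        u = np.clip((s_arr - c) / h, -1.0, 1.0)
        raw[:, i] = 0.5 * (1.0 + np.cos(np.pi * u))
    total = raw.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise DomainError("activation windows do not cover all of stance")
    return raw / total


def shear_ratios(s: np.ndarray, table: tuple[tuple[float, float], ...]) -> np.ndarray:
    """Piecewise-linear site shear ratio curves rho_i(s), shape (n, 4)."""
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    out = np.empty((s_arr.size, 4))
    for i, (v0, v1) in enumerate(table):
        out[:, i] = v0 + (v1 - v0) * s_arr
    return out


def sensor_projection(grf: np.ndarray,
                      s: np.ndarray,
                      rng: np.random.Generator | None = None,
                      noise_sd: float = 0.0,
                      params: WaveformParams | None = None) -> np.ndarray:
    """Project shoe-frame GRF samples onto the 12 sensor channels.

    ``grf`` is (n, 3) shoe-frame (Fx, Fy, Fz); ``s`` the matching stance
    fractions.  Vertical channels share the vertical force through the
    activation windows (f_zi = w_i·Fz, so they sum to Fz exactly with noise
    off); shear channels mix a vertical-coupled term rho_i(s)·f_zi with a
    windowed share of the shoe-frame shear force.  Gaussian noise with SD =
    ``noise_sd`` × (per-channel noise-free range) is added per channel.

    Returns (n, 12) in :data:`FEATURE_COLUMNS` order.
    """
    p = params or WaveformParams()
    grf = np.atleast_2d(np.asarray(grf, dtype=float))
    s_arr = np.atleast_1d(np.asarray(s, dtype=float))
    if not np.all(np.isfinite(grf)):
        raise DomainError("grf must be finite")
    w = activation_windows(s_arr, p)
    fz_ch = w * grf[:, 2:3]
    cx = np.asarray(p.shear_coupling_x_sites)[None, :]
    fx_ch = shear_ratios(s_arr, p.rho_x) * fz_ch + grf[:, 0:1] * w * cx
    fy_ch = shear_ratios(s_arr, p.rho_y) * fz_ch + grf[:, 1:2] * w * p.shear_coupling_y
    channels = np.hstack([fx_ch, fy_ch, fz_ch])
    if noise_sd > 0.0:
        if rng is None:
            raise DomainError("rng required when noise_sd > 0")
        rng_ranges = channels.max(axis=0) - channels.min(axis=0)
        channels = channels + rng.normal(0.0, 1.0, channels.shape) * (noise_sd * rng_ranges)
    return channels


# ---------------------------------------------------------------------------
# Variability calibration
# ---------------------------------------------------------------------------

# Calibration targets for the mean (over stance) SD of the mass-normalized
# mediolateral GRF, N/kg: between-participant and within-participant, per
# movement.  These encode the study conditions the generator emulates —
# cross-step turning is the most variable movement, straight walking the
# most repeatable.
X_BETWEEN_SD_TARGET = {"straight": 0.148, "side_step": 0.151, "cross_step": 0.221}
X_WITHIN_SD_TARGET = {"straight": 0.089, "side_step": 0.121, "cross_step": 0.183}

# Smooth unit shapes of the additive mediolateral random curves
# (center, width of a Gaussian bump in stance fraction).  The
# between-participant shape peaks earlier than the step-to-step one.
X_BETWEEN_SHAPE = (0.45, 0.25)
X_WITHIN_SHAPE = (0.55, 0.30)


def _x_shape_norm(shape: tuple[float, float], taper_frac: float,
                  n_grid: int = 2001) -> float:
    """Mean over stance of the tapered unit bump (normalization constant)."""
    s = np.linspace(0.0, 1.0, n_grid)
    return float(np.mean(_bump(s, *shape) * _taper(s, taper_frac)))


def x_additive_sds(params: WaveformParams | None = None) -> tuple[dict, dict]:
    """Per-movement coefficient SDs of the additive mediolateral curves.

    The mediolateral random effects are additive smooth curves
    Fx/m += g·c·φ(s)·taper(s) with c ~ N(0, sd²); sd solves
    target = g·sd·mean(φ·taper), so the cohort-level mean-over-stance SD of
    Fx/m lands exactly on the calibration target for each movement.
    """
    p = params or WaveformParams()
    nb = _x_shape_norm(X_BETWEEN_SHAPE, p.taper_frac)
    nw = _x_shape_norm(X_WITHIN_SHAPE, p.taper_frac)
    between = {m: X_BETWEEN_SD_TARGET[m] / (G * nb) for m in MOVEMENTS}
    within = {m: X_WITHIN_SD_TARGET[m] / (G * nw) for m in MOVEMENTS}
    return between, within


# ---------------------------------------------------------------------------
# Trial generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic cohort; a pure function of its fields.

    Defaults define the package's desk-scale study conditions: 3
    participants × 4 steps per movement × 3 movements = 36 plate strikes.
    """

    n_participants: int = 3
    steps_per_movement: int = 4
    movements: tuple[str, ...] = ("straight", "side_step", "cross_step")
    stance_duration: float = 0.65  # s, nominal
    stance_jitter: float = 0.10  # uniform ±fraction per step
    pad_duration: float = 0.15  # s of sub-threshold baseline each side
    sensor_noise_sd: float = 0.02  # fraction of per-channel range
    within_amplitude_sd_yz: float = 0.05
    between_amplitude_sd_yz: float = 0.08
    x_variability_scale: float = 1.0  # multiplies the additive mediolateral SDs
    heading_noise_sd: float = 2.0  # degrees
    mass_mean: float = 58.0  # kg
    mass_sd: float = 5.4  # kg
    mass_bounds: tuple[float, float] = (40.0, 90.0)
    foot_length: float = 0.25  # m, heel→toe marker distance
    walking_speed: float = 1.2  # m/s outside stance
    waveform: WaveformParams = field(default_factory=WaveformParams)
    clock_offset: float = 0.0  # s, optional inter-device offset for robustness tests
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.steps_per_movement < 1:
            raise DomainError("counts must be >= 1")
        if min(self.sensor_noise_sd, self.within_amplitude_sd_yz,
               self.between_amplitude_sd_yz, self.heading_noise_sd) < 0:
            raise DomainError("noise SDs must be >= 0")
        for m in self.movements:
            if m not in MOVEMENTS:
                raise DomainError(f"unknown movement {m!r}")


@dataclass
class TrialRecording:
    """One gait trial's raw multi-rate streams plus metadata.

    ``sensor`` is (n_s, 12) newtons in :data:`FEATURE_COLUMNS` order at
    ``sensor_fs``; ``forceplate`` is (n_p, 3) lab-frame (F_X, F_Y, F_Z)
    newtons at ``plate_fs``; ``markers`` is (n_m, 4) metres (heelX, heelY,
    toeX, toeY) at ``marker_fs``.  All streams share t=0 at recording start.

    The ``truth_*`` fields are generator-side metadata (true stance timing,
    heading and amplitude scales) used only by tests and diagnostics; the
    preprocessing stage never reads them.
    """

    sensor: np.ndarray
    forceplate: np.ndarray
    markers: np.ndarray
    participant: ParticipantProfile
    movement: MovementType
    seed: int
    step_index: int = 0
    sensor_fs: float = SENSOR_FS
    plate_fs: float = PLATE_FS
    marker_fs: float = MARKER_FS
    truth_heading_deg: float = 0.0
    truth_stance_start: float = 0.0  # s
    truth_stance_duration: float = 0.0  # s
    truth_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    truth_x_additive: tuple[float, float] = (0.0, 0.0)

    def validate(self) -> None:
        if np.any(self.forceplate[:, 2] < 0):
            raise DomainError("F_Z must be nonnegative at every sample")
        if self.sensor.shape[1] != 12 or self.forceplate.shape[1] != 3 \
                or self.markers.shape[1] != 4:
            raise DomainError("stream has wrong channel count")


def _trial_seed(master_seed: int, p_idx: int, m_idx: int, s_idx: int) -> int:
    """Deterministic per-trial seed derived from the master seed and indices."""
    ss = np.random.SeedSequence(entropy=master_seed,
                                spawn_key=(p_idx, m_idx, s_idx))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def draw_participant(config: GeneratorConfig, p_idx: int) -> ParticipantProfile:
    """Draw one participant's profile deterministically from the config."""
    ss = np.random.SeedSequence(entropy=config.master_seed, spawn_key=(p_idx,))
    rng = np.random.default_rng(ss)
    lo, hi = config.mass_bounds
    mass = float(np.clip(rng.normal(config.mass_mean, config.mass_sd), lo, hi))
    effect = tuple(float(v) for v in rng.normal(0.0, 1.0, 3))
    return ParticipantProfile(
        participant_id=f"P{p_idx + 1:02d}",
        body_mass=mass,
        amplitude_effect=effect,
        heading_noise_sd=config.heading_noise_sd,
    )


def _amplitude_scale(profile: ParticipantProfile,
                     config: GeneratorConfig,
                     rng: np.random.Generator) -> tuple[float, float, float]:
    """Multiplicative amplitude scale per direction, clipped positive.

    Applies to the anteroposterior and vertical components (participant
    effect × per-step jitter).  The mediolateral component's variability is
    additive (see :func:`x_additive_sds`), so its multiplicative scale stays
    at 1.
    """
    sd_b = config.between_amplitude_sd_yz
    sd_w = config.within_amplitude_sd_yz
    step_effect = rng.normal(0.0, 1.0, 2)
    scale = [1.0]
    for d in (1, 2):
        part = max(1.0 + profile.amplitude_effect[d] * sd_b, 0.05)
        step = max(1.0 + step_effect[d - 1] * sd_w, 0.05)
        scale.append(part * step)
    return tuple(scale)


def rotation_matrix(phi_deg: float) -> np.ndarray:
    """Lab→shoe rotation about the vertical axis by heading angle phi."""
    phi = math.radians(phi_deg)
    c, sn = math.cos(phi), math.sin(phi)
    return np.array([[c, sn, 0.0], [-sn, c, 0.0], [0.0, 0.0, 1.0]])


def generate_trial(profile: ParticipantProfile,
                   movement: MovementType,
                   config: GeneratorConfig,
                   rng: np.random.Generator,
                   seed: int = 0,
                   step_index: int = 0,
                   x_between_z: float | None = None) -> TrialRecording:
    """Generate one trial: templates sampled on the three native clocks.

    The force-plate stream is expressed in the lab frame by applying the
    inverse heading rotation (preprocessing must undo it); markers advance
    along the heading direction before and after the stance, during which
    the foot is planted with the heel→toe axis oriented at the heading
    angle.  Streams are padded with sub-threshold baseline on both sides.
    """
    p = config.waveform
    duration = config.stance_duration * (
        1.0 + config.stance_jitter * rng.uniform(-1.0, 1.0))
    t0 = config.pad_duration
    t1 = t0 + duration
    total = duration + 2.0 * config.pad_duration
    heading = movement.heading_angle + rng.normal(0.0, profile.heading_noise_sd)
    scale = _amplitude_scale(profile, config, rng)
    between_x, within_x = x_additive_sds(p)
    zb = (profile.amplitude_effect[0] if x_between_z is None else x_between_z)
    x_additive = (zb * between_x[movement.label] * config.x_variability_scale,
                  rng.normal() * within_x[movement.label] * config.x_variability_scale)

    def grid(fs: float, offset: float = 0.0) -> np.ndarray:
        n = int(math.floor((total - offset) * fs)) + 1
        return offset + np.arange(n) / fs

    # --- sensor stream (870 Hz, shoe frame) -------------------------------
    t_s = grid(SENSOR_FS)
    in_stance_s = (t_s >= t0) & (t_s <= t1)
    s_frac = (t_s[in_stance_s] - t0) / duration
    grf_s = grf_template(movement, s_frac, profile.body_mass, scale, p, x_additive)
    sensor = np.zeros((t_s.size, 12))
    sensor[in_stance_s] = sensor_projection(
        grf_s, s_frac, rng, config.sensor_noise_sd, p)
    if config.sensor_noise_sd > 0:
        # sub-threshold baseline wobble outside stance: |sum f_zi| stays < 15 N
        base = rng.normal(0.0, 20.0 * config.sensor_noise_sd,
                          (int((~in_stance_s).sum()), 12))
        sensor[~in_stance_s] = np.clip(base, -3.0, 3.0)

    # --- force-plate stream (1000 Hz, lab frame) ---------------------------
    t_p = grid(PLATE_FS, config.clock_offset)
    in_stance_p = (t_p >= t0) & (t_p <= t1)
    p_frac = (t_p[in_stance_p] - t0) / duration
    grf_p = grf_template(movement, p_frac, profile.body_mass, scale, p, x_additive)
    plate = np.zeros((t_p.size, 3))
    plate[in_stance_p] = grf_p @ rotation_matrix(heading)  # == R^T·F_shoe row-wise
    if config.sensor_noise_sd > 0:
        nout = int((~in_stance_p).sum())
        base_xy = np.clip(rng.normal(0.0, 100.0 * config.sensor_noise_sd, (nout, 2)),
                          -20.0, 20.0)
        base_z = np.clip(np.abs(rng.normal(0.0, 100.0 * config.sensor_noise_sd, nout)),
                         0.0, 40.0)
        plate[~in_stance_p] = np.column_stack([base_xy, base_z])

    # --- marker stream (200 Hz, lab frame) ---------------------------------
    t_m = grid(MARKER_FS, config.clock_offset)
    u = np.array([math.sin(math.radians(heading)), math.cos(math.radians(heading))])
    offset_along = np.where(t_m < t0, config.walking_speed * (t_m - t0),
                            np.where(t_m > t1, config.walking_speed * (t_m - t1), 0.0))
    heel = offset_along[:, None] * u[None, :]
    toe = heel + config.foot_length * u[None, :]
    markers = np.hstack([heel, toe])

    trial = TrialRecording(
        sensor=sensor, forceplate=plate, markers=markers,
        participant=profile, movement=movement, seed=seed,
        step_index=step_index,
        truth_heading_deg=heading, truth_stance_start=t0,
        truth_stance_duration=duration, truth_scale=scale,
        truth_x_additive=x_additive,
    )
    trial.validate()
    return trial


def generate_dataset(config: GeneratorConfig) -> list[TrialRecording]:
    """Generate the full cohort: participants × movements × steps trials.

    Per-participant effects are drawn once per participant; per-step jitter
    per trial.  Trial seeds derive deterministically from
    (master_seed, participant, movement, step), so the dataset is a pure
    function of the config.
    """
    trials: list[TrialRecording] = []
    for p_idx in range(config.n_participants):
        profile = draw_participant(config, p_idx)
        for m_idx, label in enumerate(config.movements):
            movement = MOVEMENTS[label]
            # the mediolateral between-participant effect is drawn per
            # participant AND movement: how hard someone pushes sideways in a
            # cross-step turn says little about their straight-walking
            # mediolateral force
            xeff_ss = np.random.SeedSequence(entropy=config.master_seed,
                                             spawn_key=(p_idx, 1000 + m_idx))
            x_between_z = float(np.random.default_rng(xeff_ss).normal())
            for s_idx in range(config.steps_per_movement):
                seed = _trial_seed(config.master_seed, p_idx, m_idx, s_idx)
                rng = np.random.default_rng(seed)
                trials.append(generate_trial(profile, movement, config, rng,
                                             seed=seed, step_index=s_idx,
                                             x_between_z=x_between_z))
    return trials


def scaled_config(config: GeneratorConfig, **overrides) -> GeneratorConfig:
    """Return a copy of ``config`` with fields replaced (convenience)."""
    return replace(config, **overrides)
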