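"""Raw recordings → aligned, stance-normalized 101-point steps.

The pipeline per trial: low-pass both force streams (4th-order Butterworth,
50 Hz, zero-phase), detect the stance phase independently on each stream
with its own force threshold (15 N on the summed vertical sensor channels,
50 N on the plate vertical), rotate the lab-frame plate forces into the shoe
frame using the heading angle estimated from the heel/toe markers, then
resample every channel onto 101 equally spaced points of its own stance
window (heel contact = 0%, toe-off = 100%).

Alignment across devices is by stance fraction, not wall clock: each stream
is normalized to its own detected stance, which sidesteps inter-device
synchronization entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .synthetic import DomainError, MovementType, TrialRecording

SENSOR_THRESHOLD_N = 15.0  # on sum of the four vertical sensor channels
PLATE_THRESHOLD_N = 50.0   # on the plate vertical force
CUTOFF_HZ = 50.0
FILTER_ORDER = 4
N_POINTS = 101


class StanceDetectionError(RuntimeError):
    """No unambiguous stance phase could be found."""


@dataclass(frozen=True)
class StancePhase:
    """Contiguous supra-threshold run of samples: [start_index, end_index]."""

    start_index: int
    end_index: int
    stream_id: str = ""

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise DomainError("start_index must be <= end_index")

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class AlignedStep:
    """One stance phase resampled to 101 points in the shoe frame.

    ``features`` is 101×12 (columns in :data:`solegrf.synthetic.FEATURE_COLUMNS`
    order), ``targets`` 101×3 (Fx, Fy, Fz).  Row 0 is heel contact, row 100
    toe-off.
    """

    features: np.ndarray
    targets: np.ndarray
    body_mass: float
    movement: MovementType
    participant_id: str
    step_id: int
    heading_angle_used: float  # degrees

    def __post_init__(self) -> None:
        if self.features.shape != (N_POINTS, 12):
            raise DomainError(f"features must be {N_POINTS}x12")
        if self.targets.shape != (N_POINTS, 3):
            raise DomainError(f"targets must be {N_POINTS}x3")


@dataclass
class RegressionDataset:
    """Stacked 101-row step blocks: targets F (n×3), features f (n×12).

    ``row_metadata`` has one row per sample with participant, movement,
    step and stance-percent columns; rows from one step are contiguous and
    ordered by stance percent.
    """

    F: np.ndarray
    f: np.ndarray
    row_metadata: pd.DataFrame

    @property
    def n(self) -> int:
        return self.F.shape[0]

    @property
    def step_keys(self) -> list[tuple]:
        """Unique (participant, movement, step) keys in stacking order."""
        meta = self.row_metadata[["participant", "movement", "step"]]
        seen: dict[tuple, None] = {}
        for key in map(tuple, meta.to_numpy()):
            seen.setdefault(key, None)
        return list(seen)

    def step_rows(self, key: tuple) -> np.ndarray:
        meta = self.row_metadata
        mask = ((meta["participant"] == key[0]) & (meta["movement"] == key[1])
                & (meta["step"] == key[2]))
        return np.flatnonzero(mask.to_numpy())

    def subset(self, row_idx: np.ndarray) -> "RegressionDataset":
        return RegressionDataset(self.F[row_idx], self.f[row_idx],
                                 self.row_metadata.iloc[row_idx].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Signal operations
# ---------------------------------------------------------------------------

def lowpass(series: np.ndarray, fs: float,
            cutoff: float = CUTOFF_HZ, order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; shape-preserving."""
    if fs <= 2.0 * cutoff:
        raise DomainError("cutoff must lie below the Nyquist frequency")
    series = np.asarray(series, dtype=float)
    padlen = 3 * (order * 2 + 1)
    if series.shape[0] <= padlen:
        raise DomainError(
            f"series of length {series.shape[0]} too short for zero-phase "
            f"filtering (needs > {padlen} samples)")
    sos = sp_signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    return sp_signal.sosfiltfilt(sos, series, axis=0)


def detect_stance(thresh_signal: np.ndarray, threshold: float,
                  stream_id: str = "") -> StancePhase:
    """Longest contiguous run of samples with value >= threshold.

    Raises :class:`StanceDetectionError` when no sample reaches the
    threshold or when two equal-length runs tie (ambiguous trial).
    """
    x = np.asarray(thresh_signal, dtype=float)
    above = x >= threshold
    if not above.any():
        raise StanceDetectionError(f"no stance detected ({stream_id or 'stream'}: "
                                   f"no sample >= {threshold} N)")
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, ends = edges[::2], edges[1::2] - 1
    lengths = ends - starts + 1
    best = int(np.argmax(lengths))
    if int((lengths == lengths[best]).sum()) > 1:
        raise StanceDetectionError(
            f"ambiguous stance ({stream_id or 'stream'}): multiple "
            f"equal-length supra-threshold runs")
    return StancePhase(int(starts[best]), int(ends[best]), stream_id)


def heading_angle(markers: np.ndarray, marker_fs: float,
                  window: tuple[float, float]) -> float:
    """Signed heading angle (degrees) of the foot during stance.

    The mean toe−heel planar vector over the marker frames falling inside
    the wall-clock ``window`` (seconds) is compared with the lab +Y axis;
    positive angles rotate toward +X.  Returned in (−180, 180].
    """
    markers = np.asarray(markers, dtype=float)
    t = np.arange(markers.shape[0]) / marker_fs
    mask = (t >= window[0]) & (t <= window[1])
    if int(mask.sum()) < 3:
        raise DomainError("need >= 3 marker frames within the stance window")
    vec = markers[mask, 2:4] - markers[mask, 0:2]  # toe - heel
    mean_vec = vec.mean(axis=0)
    if np.hypot(*mean_vec) < 1e-3:  # < 1 mm
        raise DomainError("heel and toe markers coincide; heading undefined")
    phi = math.degrees(math.atan2(mean_vec[0], mean_vec[1]))
    if phi <= -180.0:
        phi += 360.0
    return phi


def rotate_to_shoe_frame(F_lab: np.ndarray, phi_deg: float) -> np.ndarray:
    """Rotate lab-frame GRFs into the shoe frame about the vertical axis.

    [F_x, F_y, F_z]ᵀ = [[cosφ, sinφ, 0], [−sinφ, cosφ, 0], [0, 0, 1]]·
    [F_X, F_Y, F_Z]ᵀ applied row-wise; the vertical component is unchanged.
    """
    if not np.isfinite(phi_deg):
        raise DomainError("phi must be finite")
    phi = math.radians(phi_deg)
    c, sn = math.cos(phi), math.sin(phi)
    R = np.array([[c, sn, 0.0], [-sn, c, 0.0], [0.0, 0.0, 1.0]])
    return np.atleast_2d(np.asarray(F_lab, dtype=float)) @ R.T


def _resample_101(segment: np.ndarray, kind: str = "linear") -> np.ndarray:
    """Resample a stance segment (m×k) onto 101 equally spaced points."""
    m = segment.shape[0]
    nodes = np.linspace(0.0, m - 1.0, N_POINTS)
    if kind == "linear":
        idx = np.arange(m, dtype=float)
        return np.column_stack([np.interp(nodes, idx, segment[:, j])
                                for j in range(segment.shape[1])])
    if kind == "cubic":
        from scipy.interpolate import CubicSpline
        return CubicSpline(np.arange(m), segment, axis=0)(nodes)
    raise DomainError(f"unknown interpolation kind {kind!r}")


def normalize_step(trial: TrialRecording,
                   cutoff: float = CUTOFF_HZ,
                   sensor_threshold: float = SENSOR_THRESHOLD_N,
                   plate_threshold: float = PLATE_THRESHOLD_N,
                   interpolation: str = "linear") -> AlignedStep:
    """Full per-trial preprocessing: filter → stance → rotate → resample.

    The two force streams are thresholded independently and each normalized
    to its own 0–100% stance window; markers are used unfiltered to estimate
    the heading angle over the plate's stance window.
    """
    sensor_f = lowpass(trial.sensor, trial.sensor_fs, cutoff)
    plate_f = lowpass(trial.forceplate, trial.plate_fs, cutoff)

    fz_sum = sensor_f[:, 8:12].sum(axis=1)  # fz1..fz4 columns
    stance_s = detect_stance(fz_sum, sensor_threshold, "sensor")
    stance_p = detect_stance(plate_f[:, 2], plate_threshold, "forceplate")
    if stance_s.n_samples < 5 or stance_p.n_samples < 5:
        raise StanceDetectionError("stance shorter than 5 samples")

    window = (stance_p.start_index / trial.plate_fs,
              stance_p.end_index / trial.plate_fs)
    phi = heading_angle(trial.markers, trial.marker_fs, window)

    plate_seg = plate_f[stance_p.start_index:stance_p.end_index + 1]
    targets = _resample_101(rotate_to_shoe_frame(plate_seg, phi), interpolation)
    features = _resample_101(
        sensor_f[stance_s.start_index:stance_s.end_index + 1], interpolation)

    return AlignedStep(
        features=features, targets=targets,
        body_mass=trial.participant.body_mass,
        movement=trial.movement,
        participant_id=trial.participant.participant_id,
        step_id=trial.step_index,
        heading_angle_used=phi,
    )


def assemble_dataset(steps: list[AlignedStep]) -> RegressionDataset:
    """Vertically stack aligned steps into one regression dataset."""
    if not steps:
        raise DomainError("need at least one step")
    for st in steps:
        if st.features.shape[1] != 12 or st.targets.shape[1] != 3:
            raise DomainError("inconsistent column counts")
    F = np.vstack([st.targets for st in steps])
    f = np.vstack([st.features for st in steps])
    meta = pd.DataFrame({
        "participant": np.repeat([st.participant_id for st in steps], N_POINTS),
        "movement": np.repeat([st.movement.label for st in steps], N_POINTS),
        "step": np.repeat([st.step_id for st in steps], N_POINTS),
        "pct": np.tile(np.arange(N_POINTS), len(steps)),
        "body_mass": np.repeat([st.body_mass for st in steps], N_POINTS),
    })
    return RegressionDataset(F=F, f=f, row_metadata=meta)


def preprocess_trials(trials: list[TrialRecording], **kwargs) -> list[AlignedStep]:
    """Normalize a list of trials, tagging failures with the trial index."""
    steps = []
    for i, trial in enumerate(trials):
        try:
            steps.append(normalize_step(trial, **kwargs))
        except (StanceDetectionError, DomainError) as exc:
            raise type(exc)(f"trial {i} "
                            f"({trial.participant.participant_id}/"
                            f"{trial.movement.label}/{trial.step_index}): {exc}")
    return steps
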