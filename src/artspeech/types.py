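"""Core data containers shared across the pipeline.

The pipeline manipulates three kinds of objects: timestamped sensor
recordings (:class:`SensorFrameSeries`), rigid head-motion descriptions
(:class:`RigidMotionSeries`, :class:`HeadMotionModel`) and articulatory
parameter spaces (:class:`ArticulatoryModel`, :class:`TrajectoryMatrix`).
Everything is plain numpy held in frozen-ish dataclasses with eager
validation; positions are millimetres, times seconds, angles degrees, and
articulatory scores are expressed in standard-deviation units so that the
inversion box ``[-3, 3]`` means +/- 3 SD for every parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "JAW_SENSORS",
    "UPPER_LIP_SENSORS",
    "LOWER_LIP_SENSORS",
    "LIP_CORNER_SENSORS",
    "LIP_SENSORS",
    "EYEBROW_SENSORS",
    "TONGUE_SENSORS",
    "FACE_MODEL_SENSORS",
    "HEADSET_SENSORS",
    "EMA_RIGID_SENSORS",
    "RIGID_SENSORS",
    "PhoneSegmentation",
    "SensorFrameSeries",
    "RigidMotionSeries",
    "HeadMotionModel",
    "QuantizedFrameSet",
    "ArticulatoryModel",
    "TrajectoryMatrix",
]

SILENCE_LABEL = "_"

# Canonical sensor groups.  Mocap markers track the jaw, lips and eyebrows;
# EMA coils track the tongue (tip / body / dorsum).  The headset markers and
# the nasion/tragus coils are rigid with the skull and used only for head
# motion estimation; they never enter the articulatory model.
JAW_SENSORS = ("jaw_left", "jaw_right", "chin")
UPPER_LIP_SENSORS = ("lip_upper_mid", "lip_upper_left", "lip_upper_right")
LOWER_LIP_SENSORS = ("lip_lower_mid", "lip_lower_left", "lip_lower_right")
LIP_CORNER_SENSORS = ("lip_corner_left", "lip_corner_right")
LIP_SENSORS = UPPER_LIP_SENSORS + LOWER_LIP_SENSORS + LIP_CORNER_SENSORS
EYEBROW_SENSORS = (
    "brow_left_in", "brow_left_mid", "brow_left_out",
    "brow_right_in", "brow_right_mid", "brow_right_out",
)
TONGUE_SENSORS = ("TT", "TB", "TD")
FACE_MODEL_SENSORS = JAW_SENSORS + LIP_SENSORS + EYEBROW_SENSORS + TONGUE_SENSORS
HEADSET_SENSORS = ("headset_1", "headset_2", "headset_3", "headset_4")
EMA_RIGID_SENSORS = ("nasion", "tragus_left", "tragus_right")
RIGID_SENSORS = HEADSET_SENSORS + EMA_RIGID_SENSORS


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class PhoneSegmentation:
    """Ordered (SAMPA label, end time) intervals for one utterance.

    The first interval starts at 0 s by convention; intervals are half-open
    ``[start, end)`` and end times are strictly increasing.  Silence is the
    label ``"_"``.
    """

    utterance_id: str
    labels: list[str]
    end_times: np.ndarray  # seconds, shape (n_phones,)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.end_times = _as_float_array(self.end_times, "end_times").ravel()
        if len(self.labels) == 0:
            raise ValueError("segmentation must contain at least one interval")
        if len(self.labels) != self.end_times.size:
            raise ValueError("labels and end_times must have equal length")
        if any(not lbl for lbl in self.labels):
            raise ValueError("phone labels must be non-empty")
        if self.end_times[0] <= 0:
            raise ValueError("first interval must end after time 0")
        if np.any(np.diff(self.end_times) <= 0):
            raise ValueError("end times must be strictly increasing")

    @property
    def intervals(self) -> list[tuple[str, float]]:
        return list(zip(self.labels, self.end_times.tolist()))

    @property
    def start_times(self) -> np.ndarray:
        return np.concatenate([[0.0], self.end_times[:-1]])

    @property
    def midpoints(self) -> np.ndarray:
        """Temporal midpoint of each phone (the 'stable' portion)."""
        return 0.5 * (self.start_times + self.end_times)

    @property
    def durations(self) -> np.ndarray:
        return self.end_times - self.start_times

    def __len__(self) -> int:
        return len(self.labels)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PhoneSegmentation)
            and self.utterance_id == other.utterance_id
            and self.labels == other.labels
            and np.array_equal(self.end_times, other.end_times)
        )


@dataclass
class SensorFrameSeries:
    """Timestamped 3-D positions of named sensors at a uniform rate.

    ``positions`` is (frames, sensors, 3) in mm; ``mask`` is True where a
    sample is valid (missing data are masked, never NaN-encoded).
    """

    sensor_names: list[str]
    times: np.ndarray          # (F,) seconds
    positions: np.ndarray      # (F, S, 3) mm
    rate: float                # Hz
    mask: np.ndarray | None = None  # (F, S) bool, True = valid

    def __post_init__(self) -> None:
        self.sensor_names = list(self.sensor_names)
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.positions = np.asarray(self.positions, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (frames, sensors, 3)")
        f, s, _ = self.positions.shape
        if len(self.sensor_names) != s:
            raise ValueError("sensor_names length must match positions")
        if self.times.size != f:
            raise ValueError("times length must match frame count")
        if self.mask is None:
            self.mask = np.ones((f, s), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != (f, s):
                raise ValueError("mask must have shape (frames, sensors)")
        if f > 1:
            dt = np.diff(self.times)
            if np.any(np.abs(dt - 1.0 / self.rate) > 1e-9):
                raise ValueError("times must be uniform at the stated rate")
        if not np.all(np.isfinite(self.positions[self.mask])):
            raise ValueError("positions must be finite wherever mask is set")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[1]

    def index_of(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.sensor_names.index(n) for n in names])
        except ValueError as exc:
            raise KeyError(f"unknown sensor in {list(names)}") from exc

    def select(self, names: Sequence[str]) -> "SensorFrameSeries":
        idx = self.index_of(names)
        return SensorFrameSeries(
            sensor_names=[self.sensor_names[i] for i in idx],
            times=self.times,
            positions=self.positions[:, idx],
            rate=self.rate,
            mask=self.mask[:, idx],
        )

    def stacked(self) -> np.ndarray:
        """Frames as (F, 3*S) with sensor-major coordinate order."""
        return self.positions.reshape(self.n_frames, -1)

    def copy(self) -> "SensorFrameSeries":
        return replace(
            self,
            positions=self.positions.copy(),
            mask=self.mask.copy(),
            times=self.times.copy(),
        )


def coordinate_names(sensor_names: Sequence[str]) -> list[str]:
    """Stacked coordinate labels (``jaw_left_x``, ``jaw_left_y``, ...)."""
    return [f"{s}_{ax}" for s in sensor_names for ax in "xyz"]


@dataclass
class RigidMotionSeries:
    """Per-frame rigid head pose: translations (mm) and intrinsic z-y-x
    Euler rotations (degrees) about a single centre of rotation."""

    times: np.ndarray          # (F,)
    translations: np.ndarray   # (F, 3) mm
    rotations: np.ndarray      # (F, 3) degrees (rx, ry, rz)
    center: np.ndarray         # (3,) mm, one centre for the whole recording
    rate: float
    flagged: np.ndarray | None = None  # frames where the fit was interpolated

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float).ravel()
        self.translations = _as_float_array(self.translations, "translations")
        self.rotations = _as_float_array(self.rotations, "rotations")
        self.center = _as_float_array(self.center, "center").ravel()
        f = self.times.size
        if self.translations.shape != (f, 3) or self.rotations.shape != (f, 3):
            raise ValueError("translations/rotations must be (frames, 3)")
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if np.any(self.rotations <= -180.0) or np.any(self.rotations > 180.0):
            raise ValueError("rotations must lie in (-180, 180] degrees")
        if self.flagged is None:
            self.flagged = np.zeros(f, dtype=bool)
        else:
            self.flagged = np.asarray(self.flagged, dtype=bool).ravel()

    @property
    def n_frames(self) -> int:
        return self.times.size

    def as_vectors(self) -> np.ndarray:
        """(F, 6) stacked [Tx, Ty, Tz, Rx, Ry, Rz] vectors."""
        return np.hstack([self.translations, self.rotations])


@dataclass
class HeadMotionModel:
    """PCA model of the 6-dof rigid head motion.

    ``loadings`` columns are scaled by the score standard deviation, so a
    parameter value of 1 means one SD of the observed motion; ``pose(alpha)``
    returns the 6-vector ``mean_motion + loadings @ alpha``.
    """

    sensor_names: list[str]
    mean_shape: np.ndarray       # (S, 3) headset sensors in the head frame
    center: np.ndarray           # (3,) centre of rotation, mm
    mean_motion: np.ndarray      # (6,)
    loadings: np.ndarray         # (6, N)
    explained: np.ndarray        # (N,) fraction of motion variance

    def __post_init__(self) -> None:
        self.sensor_names = list(self.sensor_names)
        self.mean_shape = _as_float_array(self.mean_shape, "mean_shape")
        self.center = _as_float_array(self.center, "center").ravel()
        self.mean_motion = _as_float_array(self.mean_motion, "mean_motion").ravel()
        self.loadings = np.atleast_2d(_as_float_array(self.loadings, "loadings"))
        self.explained = _as_float_array(self.explained, "explained").ravel()
        if self.mean_shape.shape != (len(self.sensor_names), 3):
            raise ValueError("mean_shape must be (n_sensors, 3)")
        if self.mean_motion.shape != (6,) or self.loadings.shape[0] != 6:
            raise ValueError("motion space is 6-dimensional")
        if self.loadings.shape[1] > 6:
            raise ValueError("at most 6 motion components")

    @property
    def n_params(self) -> int:
        return self.loadings.shape[1]

    def pose(self, alpha: np.ndarray) -> np.ndarray:
        alpha = np.asarray(alpha, dtype=float).ravel()
        if alpha.size != self.n_params:
            raise ValueError("alpha dimension mismatch")
        return self.mean_motion + self.loadings @ alpha


@dataclass
class QuantizedFrameSet:
    """Pruned, head-corrected frames ready for model fitting.

    ``frames`` is (n_kept, 3*S) stacked sensor coordinates; ``kept_indices``
    maps back into the source series.
    """

    sensor_names: list[str]
    frames: np.ndarray
    kept_indices: np.ndarray

    def __post_init__(self) -> None:
        self.sensor_names = list(self.sensor_names)
        self.frames = np.atleast_2d(np.asarray(self.frames, dtype=float))
        self.kept_indices = np.asarray(self.kept_indices, dtype=int).ravel()
        if self.frames.size and self.frames.shape[1] != 3 * len(self.sensor_names):
            raise ValueError("frames width must equal 3 * n_sensors")
        if self.frames.shape[0] != self.kept_indices.size:
            raise ValueError("kept_indices must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0] if self.frames.size else 0

    def coords(self, sensors: Sequence[str]) -> np.ndarray:
        """Column indices of the stacked x/y/z coordinates of ``sensors``."""
        base = np.array([self.sensor_names.index(s) for s in sensors])
        return (3 * base[:, None] + np.arange(3)[None, :]).ravel()


@dataclass
class ArticulatoryModel:
    """Linear articulatory model: mean configuration plus per-parameter
    whole-face loading vectors.

    A frame is reconstructed as ``mean + loadings @ alpha`` where ``alpha``
    holds parameter scores in SD units.  ``variance_fractions`` stores the
    percentage of global variance each parameter removed when the model was
    fitted; ``subset_directions`` stores the within-subset principal
    direction of each guided-PCA step (needed to re-score new data), and
    ``scheme_steps`` the (name, sensor subset) extraction recipe.
    """

    parameter_names: list[str]
    sensor_names: list[str]
    mean: np.ndarray                      # (3*S,)
    loadings: np.ndarray                  # (3*S, M) mm per score-SD
    variance_fractions: np.ndarray | None = None   # (M,) percent
    subset_directions: list[np.ndarray] | None = None
    scheme_steps: list[tuple[str, tuple[str, ...]]] | None = None
    sign_convention: np.ndarray | None = None      # (M,) +/- 1

    def __post_init__(self) -> None:
        self.parameter_names = list(self.parameter_names)
        self.sensor_names = list(self.sensor_names)
        self.mean = _as_float_array(self.mean, "mean").ravel()
        self.loadings = np.atleast_2d(_as_float_array(self.loadings, "loadings"))
        d = 3 * len(self.sensor_names)
        if self.mean.shape != (d,):
            raise ValueError("mean must have 3 coordinates per sensor")
        m = len(self.parameter_names)
        if self.loadings.shape != (d, m):
            if m == 0 and self.loadings.size == 0:
                self.loadings = np.zeros((d, 0))
            else:
                raise ValueError("loadings must be (3*n_sensors, n_params)")
        if len(set(self.parameter_names)) != m:
            raise ValueError("parameter names must be unique")
        if self.variance_fractions is not None:
            self.variance_fractions = _as_float_array(
                self.variance_fractions, "variance_fractions"
            ).ravel()
            if self.variance_fractions.shape != (m,):
                raise ValueError("variance_fractions must match parameter count")
            if np.any(self.variance_fractions < -1e-9):
                raise ValueError("variance fractions must be non-negative")
            if self.variance_fractions.sum() > 100.0 + 1e-6:
                raise ValueError("variance fractions cannot exceed 100%")
        if self.sign_convention is None:
            self.sign_convention = np.ones(m)
        else:
            self.sign_convention = _as_float_array(
                self.sign_convention, "sign_convention"
            ).ravel()
            if not np.all(np.isin(self.sign_convention, (-1.0, 1.0))):
                raise ValueError("sign_convention entries must be +/-1")

    @property
    def n_params(self) -> int:
        return len(self.parameter_names)

    @property
    def n_coords(self) -> int:
        return self.mean.size

    def coords(self, sensors: Sequence[str]) -> np.ndarray:
        base = np.array([self.sensor_names.index(s) for s in sensors])
        return (3 * base[:, None] + np.arange(3)[None, :]).ravel()

    def project(self, alpha: np.ndarray) -> np.ndarray:
        """Sensor coordinates for score vector ``alpha`` (mean + loadings@alpha)."""
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape[-1] != self.n_params:
            raise ValueError(
                f"alpha must have {self.n_params} entries, got {alpha.shape[-1]}"
            )
        return self.mean + alpha @ self.loadings.T

    def project_positions(self, alpha: np.ndarray) -> np.ndarray:
        """Like :meth:`project` but reshaped to (..., n_sensors, 3)."""
        flat = self.project(alpha)
        return flat.reshape(*flat.shape[:-1], len(self.sensor_names), 3)


@dataclass
class TrajectoryMatrix:
    """Articulatory parameter values over time: (parameters x frames)."""

    parameter_names: list[str]
    rate: float
    values: np.ndarray  # (M, F), score-SD units

    def __post_init__(self) -> None:
        self.parameter_names = list(self.parameter_names)
        self.values = np.atleast_2d(_as_float_array(self.values, "values"))
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.values.shape[0] != len(self.parameter_names):
            raise ValueError("values must have one row per parameter")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_params(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate

    def slice_frames(self, start: int, end: int) -> "TrajectoryMatrix":
        if not (0 <= start < end <= self.n_frames):
            raise IndexError(f"invalid frame slice [{start}, {end})")
        return TrajectoryMatrix(
            parameter_names=self.parameter_names,
            rate=self.rate,
            values=self.values[:, start:end].copy(),
        )
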