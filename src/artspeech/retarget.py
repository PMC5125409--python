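"""Retargeting avatar key frames to articulatory parameters.

An avatar originally animated by interpolation between stored key frames
is converted to articulatory control in two ways:

* **face**: each selected key frame's displacement from the neutral mesh
  becomes a synthetic articulatory loading, variance-normalized so that an
  activation of 0..+3 spans neutral to three times the (RMS-normalized)
  key-frame pose.  Key frames are extreme poses, so activations are
  one-sided; there is deliberately no jaw-rotation parameter because no
  such key frame exists.
* **tongue**: the avatar's 50-vertex tongue mesh has no speech-related key
  frames, so tongue postures are fitted per quantized EMA sample as the
  bounded linear mixture of the N = 9 tongue key frames that best matches
  the three sensor-associated vertices (weights in [-10, 10]); a
  five-parameter articulatory tongue model (jaw + four tongue parameters)
  is then fitted over the mesh + sensor coordinates with the same guided
  PCA used for the speaker model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .artmodel import AVATAR_TONGUE_SCHEME, ExtractionScheme, fit_guided_pca
from .types import (
    ArticulatoryModel,
    JAW_SENSORS,
    QuantizedFrameSet,
    TONGUE_SENSORS,
)

__all__ = [
    "KeyframeSet",
    "MixtureWeights",
    "TonguePostureDatabase",
    "face_keyframes_to_params",
    "fit_tongue_mixture",
    "build_tongue_posture_db",
    "fit_avatar_tongue_model",
    "align_parameter_signs",
]

TONGUE_WEIGHT_BOUNDS = (-10.0, 10.0)


@dataclass
class KeyframeSet:
    """Avatar key frames: neutral mesh plus named extreme poses.

    ``vertex_correspondence`` maps each EMA sensor name (TT, TB, TD) to the
    mesh vertex it is associated with.
    """

    neutral: np.ndarray                       # (V, 3)
    keyframes: dict[str, np.ndarray]          # name -> (V, 3)
    vertex_correspondence: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.neutral = np.asarray(self.neutral, dtype=float)
        if self.neutral.ndim != 2 or self.neutral.shape[1] != 3:
            raise ValueError("neutral mesh must be (n_vertices, 3)")
        v = self.neutral.shape[0]
        self.keyframes = {
            name: np.asarray(kf, dtype=float) for name, kf in self.keyframes.items()
        }
        for name, kf in self.keyframes.items():
            if kf.shape != (v, 3):
                raise ValueError(
                    f"key frame {name!r} does not share the neutral topology"
                )
        for sensor, idx in self.vertex_correspondence.items():
            if not (0 <= idx < v):
                raise ValueError(f"correspondence for {sensor!r} is out of range")

    @property
    def n_vertices(self) -> int:
        return self.neutral.shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.keyframes)

    def corresponding_vertices(
        self, sensors: tuple[str, ...] = TONGUE_SENSORS
    ) -> np.ndarray:
        try:
            return np.array([self.vertex_correspondence[s] for s in sensors])
        except KeyError as exc:
            raise KeyError(f"no vertex correspondence for sensor {exc}") from exc


@dataclass
class MixtureWeights:
    """Key-frame mixture weights, each bounded to [-10, 10]."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != len(self.names):
            raise ValueError("one weight per key frame required")
        lo, hi = TONGUE_WEIGHT_BOUNDS
        if np.any(self.values < lo - 1e-9) or np.any(self.values > hi + 1e-9):
            raise ValueError("weights exceed the [-10, 10] bounds")


@dataclass
class TonguePostureDatabase:
    """Fitted 50-vertex tongue meshes for a quantized EMA posture set."""

    meshes: np.ndarray         # (n, V, 3)
    weights: np.ndarray        # (n, N)
    residuals: np.ndarray      # (n, 3) per-sensor distance, mm
    sensor_positions: np.ndarray  # (n, 3, 3) the EMA postures (TT, TB, TD)

    @property
    def n_postures(self) -> int:
        return self.meshes.shape[0]

    def residual_summary(self) -> tuple[float, float]:
        """Mean and SD of the sensor-to-vertex distance over all postures."""
        if self.residuals.size == 0:
            return 0.0, 0.0
        return float(self.residuals.mean()), float(self.residuals.std())


def face_keyframes_to_params(keyframes: KeyframeSet) -> ArticulatoryModel:
    """Convert face key frames into one-sided synthetic parameters.

    Each key frame's displacement field from the neutral pose is divided by
    the RMS per-vertex displacement magnitude, so activation ``a`` in
    [0, +3] moves the mesh ``a`` normalized poses away from neutral.  A key
    frame named ``jaw2`` is dropped (no jaw-rotation pose exists in the
    source animation).
    """
    names = []
    cols = []
    for name, kf in keyframes.keyframes.items():
        if name == "jaw2":
            warnings.warn("ignoring key frame 'jaw2'", stacklevel=2)
            continue
        disp = kf - keyframes.neutral
        scale = float(np.sqrt(np.mean(np.sum(disp**2, axis=1))))
        if scale <= 1e-12:
            raise ValueError(f"key frame {name!r} is identical to the neutral pose")
        names.append(name)
        cols.append((disp / scale).ravel())
    if not names:
        raise ValueError("no usable key frames")
    v = keyframes.n_vertices
    return ArticulatoryModel(
        parameter_names=names,
        sensor_names=[f"vertex_{i:03d}" for i in range(v)],
        mean=keyframes.neutral.ravel(),
        loadings=np.column_stack(cols),
    )


def _keyframe_matrix(keyframes: KeyframeSet) -> tuple[np.ndarray, list[str]]:
    """(9 coords x N key frames) matrix of corresponding-vertex positions."""
    idx = keyframes.corresponding_vertices()
    names = keyframes.names
    A = np.column_stack([keyframes.keyframes[n][idx].ravel() for n in names])
    return A, names


def fit_tongue_mixture(
    ema_frame: np.ndarray, keyframes: KeyframeSet
) -> tuple[MixtureWeights, np.ndarray, np.ndarray]:
    """Best bounded mixture of tongue key frames for one EMA posture.

    Minimizes the distance between the weighted key-frame positions at the
    three corresponding vertices and the observed TT/TB/TD sensors, with
    each weight in [-10, 10].  Returns the weights, the fitted 50-vertex
    mesh (the same mixture evaluated on all vertices) and the per-sensor
    residual distances (mm).  A rank-deficient key-frame matrix falls back
    to the minimal-norm ridge solution with a warning.
    """
    obs = np.asarray(ema_frame, dtype=float).reshape(3, 3)
    A, names = _keyframe_matrix(keyframes)
    b = obs.ravel()
    lo, hi = TONGUE_WEIGHT_BOUNDS
    rank = np.linalg.matrix_rank(A, tol=1e-8)
    ridge = 1e-8 if rank < min(A.shape) else 1e-12
    if rank < min(A.shape):
        warnings.warn(
            "rank-deficient key-frame matrix; using minimal-norm solution",
            stacklevel=2,
        )
    n = A.shape[1]
    Areg = np.vstack([A, np.sqrt(ridge) * np.eye(n)])
    breg = np.concatenate([b, np.zeros(n)])
    x = np.linalg.lstsq(Areg, breg, rcond=None)[0]
    if np.any(x < lo) or np.any(x > hi):
        res = optimize.lsq_linear(Areg, breg, bounds=(lo, hi), method="bvls", tol=1e-12)
        x = np.clip(res.x, lo, hi)
    weights = MixtureWeights(names=names, values=x)
    stack = np.stack([keyframes.keyframes[nm] for nm in names])  # (N, V, 3)
    mesh = np.tensordot(x, stack, axes=1)  # (V, 3)
    fitted = (A @ x).reshape(3, 3)
    residual = np.linalg.norm(fitted - obs, axis=1)
    return weights, mesh, residual


def build_tongue_posture_db(
    quantized: QuantizedFrameSet | np.ndarray, keyframes: KeyframeSet
) -> TonguePostureDatabase:
    """Fit a constrained tongue mesh for every quantized EMA posture.

    ``quantized`` is either a pruned frame set containing the TT/TB/TD
    sensors or an (n, 3, 3) array of sensor positions.
    """
    if isinstance(quantized, QuantizedFrameSet):
        if quantized.n_frames == 0:
            postures = np.empty((0, 3, 3))
        else:
            idx = quantized.coords(TONGUE_SENSORS)
            postures = quantized.frames[:, idx].reshape(-1, 3, 3)
    else:
        postures = np.asarray(quantized, dtype=float).reshape(-1, 3, 3)
    n = postures.shape[0]
    v = keyframes.n_vertices
    n_kf = len(keyframes.names)
    meshes = np.zeros((n, v, 3))
    weights = np.zeros((n, n_kf))
    residuals = np.zeros((n, 3))
    for i in range(n):
        w, mesh, res = fit_tongue_mixture(postures[i], keyframes)
        meshes[i] = mesh
        weights[i] = w.values
        residuals[i] = res
    return TonguePostureDatabase(
        meshes=meshes,
        weights=weights,
        residuals=residuals,
        sensor_positions=postures,
    )


def fit_avatar_tongue_model(
    posture_db: TonguePostureDatabase,
    quantized: QuantizedFrameSet,
    scheme: ExtractionScheme = AVATAR_TONGUE_SCHEME,
) -> ArticulatoryModel:
    """Five-parameter articulatory model driving the avatar tongue mesh.

    The fitted meshes are concatenated with the jaw and tongue sensor
    coordinates of the quantized database, and the guided-PCA extraction
    (jaw1, tongue1..tongue4) is run over the joint space, so the resulting
    parameters drive all 50 mesh vertices coherently with the sensors.
    """
    if posture_db.n_postures != quantized.n_frames:
        raise ValueError("posture database and quantized frames are misaligned")
    jaw_idx = quantized.coords(JAW_SENSORS)
    tongue_idx = quantized.coords(TONGUE_SENSORS)
    v = posture_db.meshes.shape[1]
    data = np.hstack(
        [
            quantized.frames[:, jaw_idx],
            quantized.frames[:, tongue_idx],
            posture_db.meshes.reshape(posture_db.n_postures, -1),
        ]
    )
    sensor_names = (
        list(JAW_SENSORS)
        + list(TONGUE_SENSORS)
        + [f"mesh_{i:03d}" for i in range(v)]
    )
    return fit_guided_pca(data, scheme, sensor_names=sensor_names)


def align_parameter_signs(
    speaker_model: ArticulatoryModel,
    avatar_model: ArticulatoryModel,
    sign_table: dict[str, int],
) -> ArticulatoryModel:
    """Flip avatar loadings so speaker trajectories drive it correctly.

    The table maps parameter names to +/-1 (+1 leaves a parameter
    untouched); applying the same table twice is the identity.
    """
    unknown = set(sign_table) - set(avatar_model.parameter_names)
    if unknown:
        raise KeyError(f"sign table names unknown parameters: {sorted(unknown)}")
    for name in sign_table:
        if name not in speaker_model.parameter_names:
            raise KeyError(f"speaker model lacks parameter {name!r}")
    if not all(s in (-1, 1) for s in sign_table.values()):
        raise ValueError("sign table values must be +1 or -1")
    signs = np.array(
        [sign_table.get(n, 1) for n in avatar_model.parameter_names], dtype=float
    )
    return ArticulatoryModel(
        parameter_names=list(avatar_model.parameter_names),
        sensor_names=list(avatar_model.sensor_names),
        mean=avatar_model.mean.copy(),
        loadings=avatar_model.loadings * signs[None, :],
        variance_fractions=(
            None
            if avatar_model.variance_fractions is None
            else avatar_model.variance_fractions.copy()
        ),
        subset_directions=(
            None
            if avatar_model.subset_directions is None
            else [u * s for u, s in zip(avatar_model.subset_directions, signs)]
        ),
        scheme_steps=avatar_model.scheme_steps,
        sign_convention=avatar_model.sign_convention * signs,
    )
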