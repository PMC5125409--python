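"""Stream synchronization, rigid head-motion correction and frame pruning.

The two recording devices run at different rates (EMA at 100 Hz, motion
capture at 60 Hz) on a shared clock.  This module brings everything onto
the 60 Hz mocap clock, estimates the rigid head pose per frame from the
skull-fixed sensors (headset markers, nasion and tragus coils) with an
orthogonal Procrustes / Kabsch fit, removes it, and prunes near-duplicate
frames before model fitting.

Rotations are parameterized as intrinsic z-y-x Euler angles in degrees:
``R = Rz(rz) @ Ry(ry) @ Rx(rx)``.  A frame in head coordinates ``p`` maps to
the world as ``R @ (p - c) + c + t`` with ``c`` the centre of rotation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.spatial.distance import cdist

from .types import (
    HeadMotionModel,
    QuantizedFrameSet,
    RigidMotionSeries,
    SensorFrameSeries,
)

__all__ = [
    "euler_zyx_to_matrix",
    "matrix_to_euler_zyx",
    "kabsch",
    "resample_lowpass",
    "synchronize",
    "estimate_rigid_motion",
    "apply_rigid_motion",
    "remove_rigid_motion",
    "fit_head_motion_model",
    "prune_frames",
]

#: gaps longer than this (seconds) stay masked instead of being interpolated
MAX_FILL_GAP = 0.1


# ---------------------------------------------------------------------------
# rotations and the Kabsch fit
# ---------------------------------------------------------------------------

def euler_zyx_to_matrix(angles_deg: np.ndarray) -> np.ndarray:
    """Rotation matrices for intrinsic z-y-x Euler angles (rx, ry, rz) deg.

    Accepts (..., 3) and returns (..., 3, 3).
    """
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    rx, ry, rz = a[..., 0], a[..., 1], a[..., 2]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    R = np.empty(a.shape[:-1] + (3, 3))
    R[..., 0, 0] = cz * cy
    R[..., 0, 1] = -sz * cx + cz * sy * sx
    R[..., 0, 2] = sz * sx + cz * sy * cx
    R[..., 1, 0] = sz * cy
    R[..., 1, 1] = cz * cx + sz * sy * sx
    R[..., 1, 2] = -cz * sx + sz * sy * cx
    R[..., 2, 0] = -sy
    R[..., 2, 1] = cy * sx
    R[..., 2, 2] = cy * cx
    return R


def matrix_to_euler_zyx(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_zyx_to_matrix` (degrees, (..., 3))."""
    R = np.asarray(R, dtype=float)
    ry = -np.arcsin(np.clip(R[..., 2, 0], -1.0, 1.0))
    rx = np.arctan2(R[..., 2, 1], R[..., 2, 2])
    rz = np.arctan2(R[..., 1, 0], R[..., 0, 0])
    return np.rad2deg(np.stack([rx, ry, rz], axis=-1))


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform mapping point set ``P`` onto ``Q``.

    Returns ``(R, t)`` with ``R @ p + t ~= q``; proper rotation enforced.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


# ---------------------------------------------------------------------------
# resampling and synchronization
# ---------------------------------------------------------------------------

def _fill_gaps(times: np.ndarray, values: np.ndarray, valid: np.ndarray):
    """Linearly interpolate masked samples of a 1-D channel.

    Returns the filled signal and a boolean array marking samples that sit
    inside gaps longer than :data:`MAX_FILL_GAP` (left unreliable).
    """
    filled = values.copy()
    long_gap = np.zeros(values.size, dtype=bool)
    if valid.all():
        return filled, long_gap
    if not valid.any():
        return np.zeros_like(values), np.ones(values.size, dtype=bool)
    filled[~valid] = np.interp(times[~valid], times[valid], values[valid])
    # locate contiguous invalid runs
    idx = np.flatnonzero(~valid)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if times[run[-1]] - times[run[0]] > MAX_FILL_GAP:
            long_gap[run] = True
    return filled, long_gap


def resample_lowpass(
    series: SensorFrameSeries,
    target_rate: float = 60.0,
    cutoff: float = 20.0,
    order: int = 6,
) -> SensorFrameSeries:
    """Low-pass filter a recording and resample it to ``target_rate``.

    A zero-phase Butterworth filter (applied forward-backward, so the
    effective attenuation is twice the design order's) removes content above
    ``cutoff``; the filtered signal is then linearly interpolated onto a
    uniform grid at ``target_rate`` starting at the series' first timestamp.
    Masked gaps are linearly bridged before filtering and re-masked after
    when longer than 100 ms.
    """
    if series.rate <= 2 * cutoff:
        raise ValueError("series rate must exceed twice the cutoff")
    b, a = signal.butter(order, cutoff, fs=series.rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.n_frames <= padlen:
        raise ValueError(
            f"series too short for filtering: need > {padlen} frames, "
            f"got {series.n_frames}"
        )
    n_out = int(round((series.times[-1] - series.times[0]) * target_rate)) + 1
    out_times = series.times[0] + np.arange(n_out) / target_rate
    out_times = out_times[out_times <= series.times[-1] + 1e-9]
    F, S, _ = series.positions.shape
    out_pos = np.zeros((out_times.size, S, 3))
    out_mask = np.ones((out_times.size, S), dtype=bool)
    for s in range(S):
        valid = series.mask[:, s]
        unreliable = np.zeros(F, dtype=bool)
        chans = np.empty((F, 3))
        for ax in range(3):
            filled, long_gap = _fill_gaps(
                series.times, series.positions[:, s, ax], valid
            )
            unreliable |= long_gap
            chans[:, ax] = filled
        if (~valid).all():
            out_mask[:, s] = False
            continue
        smoothed = signal.filtfilt(b, a, chans, axis=0)
        for ax in range(3):
            out_pos[:, s, ax] = np.interp(out_times, series.times, smoothed[:, ax])
        if unreliable.any():
            bad = np.interp(
                out_times, series.times, unreliable.astype(float)
            ) > 0.0
            out_mask[bad, s] = False
    return SensorFrameSeries(
        sensor_names=list(series.sensor_names),
        times=out_times,
        positions=out_pos,
        rate=target_rate,
        mask=out_mask,
    )


def synchronize(
    ema: SensorFrameSeries, mocap: SensorFrameSeries
) -> SensorFrameSeries:
    """Merge the EMA stream onto the mocap clock.

    EMA samples at off-grid times are linearly interpolated between their
    two neighbours; samples exactly on a mocap timestamp pass through
    unchanged.  The output holds all sensors of both streams at the mocap
    rate.  Raises if the time ranges do not overlap or sensor names clash.
    """
    if set(ema.sensor_names) & set(mocap.sensor_names):
        raise ValueError("EMA and mocap streams share sensor names")
    if ema.times[0] > mocap.times[-1] + 1e-9 or mocap.times[0] > ema.times[-1] + 1e-9:
        raise ValueError("EMA and mocap time ranges do not overlap")
    t = mocap.times
    Se, Sm = ema.n_sensors, mocap.n_sensors
    pos = np.zeros((t.size, Sm + Se, 3))
    mask = np.zeros((t.size, Sm + Se), dtype=bool)
    pos[:, :Sm] = mocap.positions
    mask[:, :Sm] = mocap.mask
    in_range = (t >= ema.times[0] - 1e-9) & (t <= ema.times[-1] + 1e-9)
    for s in range(Se):
        for ax in range(3):
            pos[:, Sm + s, ax] = np.interp(t, ema.times, ema.positions[:, s, ax])
        # a target sample is valid when both bracketing EMA samples are valid
        ok = np.interp(t, ema.times, ema.mask[:, s].astype(float)) >= 1.0 - 1e-12
        mask[:, Sm + s] = ok & in_range
    return SensorFrameSeries(
        sensor_names=list(mocap.sensor_names) + list(ema.sensor_names),
        times=t,
        positions=pos,
        rate=mocap.rate,
        mask=mask,
    )


# ---------------------------------------------------------------------------
# rigid head motion
# ---------------------------------------------------------------------------

def _noncollinear(points: np.ndarray) -> bool:
    if points.shape[0] < 3:
        return False
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s.size >= 2 and s[1] > 1e-9 * max(s[0], 1.0)


def estimate_rigid_motion(
    series: SensorFrameSeries,
    rigid_sensors: list[str],
    reference_frame: int = 0,
) -> RigidMotionSeries:
    """Per-frame least-squares rigid pose of the skull-fixed sensors.

    Each frame's rotation and translation is the unweighted Kabsch fit of
    the visible rigid sensors onto their configuration at
    ``reference_frame``.  The centre of rotation is the single point that
    minimizes the residual translation magnitude across all frames (linear
    least squares on ``t_f + (R_f - I) c``).  Frames with fewer than three
    visible, non-collinear rigid sensors are flagged and interpolated from
    their neighbours.
    """
    rigid = series.select(rigid_sensors)
    F = rigid.n_frames
    ref_vis = rigid.mask[reference_frame]
    ref = rigid.positions[reference_frame]
    if not _noncollinear(ref[ref_vis]):
        raise ValueError(
            "reference frame needs >= 3 visible, non-collinear rigid sensors"
        )
    Rs = np.tile(np.eye(3), (F, 1, 1))
    ts = np.zeros((F, 3))
    flagged = np.zeros(F, dtype=bool)
    for f in range(F):
        vis = rigid.mask[f] & ref_vis
        pts = rigid.positions[f, vis]
        if not _noncollinear(pts):
            flagged[f] = True
            continue
        Rs[f], ts[f] = kabsch(ref[vis], pts)
    if flagged.all():
        raise ValueError("no frame has enough visible rigid sensors")
    eulers = matrix_to_euler_zyx(Rs)
    if flagged.any():
        good = np.flatnonzero(~flagged)
        bad = np.flatnonzero(flagged)
        for arr in (ts, eulers):
            for k in range(3):
                arr[bad, k] = np.interp(bad, good, arr[good, k])
        Rs[bad] = euler_zyx_to_matrix(eulers[bad])
    # centre of rotation: minimize sum_f || t_f + (R_f - I) c ||^2
    good = ~flagged
    A = (Rs[good] - np.eye(3)).reshape(-1, 3)
    b = -ts[good].reshape(-1)
    center, *_ = np.linalg.lstsq(A, b, rcond=None)
    tau = ts + np.einsum("fij,j->fi", Rs - np.eye(3), center)
    return RigidMotionSeries(
        times=series.times,
        translations=tau,
        rotations=eulers,
        center=center,
        rate=series.rate,
        flagged=flagged,
    )


def apply_rigid_motion(
    series: SensorFrameSeries, rigid: RigidMotionSeries
) -> SensorFrameSeries:
    """Compose a rigid head motion onto a head-frame recording."""
    _check_times(series, rigid)
    R = euler_zyx_to_matrix(rigid.rotations)
    c = rigid.center
    out = series.copy()
    out.positions = (
        np.einsum("fij,fsj->fsi", R, series.positions - c)
        + c
        + rigid.translations[:, None, :]
    )
    return out


def remove_rigid_motion(
    series: SensorFrameSeries, rigid: RigidMotionSeries
) -> SensorFrameSeries:
    """Undo a rigid head motion, expressing the recording in the head frame.

    Inverse of :func:`apply_rigid_motion`; articulation (inter-sensor
    distances within each frame) is untouched.
    """
    _check_times(series, rigid)
    R = euler_zyx_to_matrix(rigid.rotations)
    c = rigid.center
    out = series.copy()
    shifted = series.positions - c - rigid.translations[:, None, :]
    out.positions = np.einsum("fji,fsj->fsi", R, shifted) + c
    return out


def _check_times(series: SensorFrameSeries, rigid: RigidMotionSeries) -> None:
    if series.n_frames != rigid.n_frames or np.any(
        np.abs(series.times - rigid.times) > 1e-9
    ):
        raise ValueError("series and rigid motion must share timestamps")


def fit_head_motion_model(
    rigid: RigidMotionSeries,
    headset_shape: np.ndarray,
    sensor_names: list[str],
    n_components: int = 6,
) -> HeadMotionModel:
    """PCA of the 6-dof rigid motion vectors.

    Loadings are eigenvectors scaled by the score standard deviation so the
    usual ``[-3, 3]`` box covers +/- 3 SD of observed head motion.
    Rank-deficient motion yields fewer components (with a warning);
    zero-variance motion is an error.
    """
    V = rigid.as_vectors()
    if V.shape[0] < 7:
        raise ValueError("need at least 7 frames to fit a head motion model")
    mean = V.mean(axis=0)
    C = np.cov(V.T, bias=True)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    if total <= 0:
        raise ValueError("rigid motion has zero variance; nothing to model")
    keep = evals > max(1e-12 * total, 0.0)
    n_keep = min(n_components, int(keep.sum()))
    if n_keep < n_components:
        warnings.warn(
            f"rigid motion is rank deficient: keeping {n_keep} of "
            f"{n_components} components",
            stacklevel=2,
        )
    sd = np.sqrt(evals[:n_keep])
    return HeadMotionModel(
        sensor_names=sensor_names,
        mean_shape=np.asarray(headset_shape, dtype=float),
        center=rigid.center,
        mean_motion=mean,
        loadings=evecs[:, :n_keep] * sd,
        explained=evals[:n_keep] / total,
    )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def prune_frames(
    series: SensorFrameSeries | np.ndarray,
    min_dist: float = 1.0,
    sensor_names: list[str] | None = None,
) -> QuantizedFrameSet:
    """Greedy vector quantization of frames (time order, first-come).

    A frame is kept iff its stacked-sensor Euclidean distance to *every*
    previously kept frame is at least ``min_dist`` mm.  Frames with any
    missing sensor are excluded beforehand (the articulatory model is fitted
    on complete frames only).
    """
    if isinstance(series, SensorFrameSeries):
        complete = series.mask.all(axis=1)
        X = series.stacked()[complete]
        src_idx = np.flatnonzero(complete)
        names = list(series.sensor_names)
    else:
        X = np.atleast_2d(np.asarray(series, dtype=float))
        src_idx = np.arange(X.shape[0])
        names = sensor_names or [f"s{i:02d}" for i in range(X.shape[1] // 3)]
    n = X.shape[0]
    if n == 0:
        return QuantizedFrameSet(
            sensor_names=names, frames=np.empty((0, X.shape[1] if X.size else 0)),
            kept_indices=np.empty(0, dtype=int),
        )
    if min_dist <= 0:
        return QuantizedFrameSet(sensor_names=names, frames=X, kept_indices=src_idx)
    thr2 = min_dist * min_dist
    kept: list[int] = []
    block = 1024
    for start in range(0, n, block):
        stop = min(start + block, n)
        cand = np.arange(start, stop)
        if kept:
            d2 = cdist(X[cand], X[kept], "sqeuclidean").min(axis=1)
            cand = cand[d2 >= thr2]
        new: list[int] = []
        for i in cand:
            if new:
                d2 = np.min(np.sum((X[new] - X[i]) ** 2, axis=1))
                if d2 < thr2:
                    continue
            new.append(int(i))
        kept.extend(new)
    kept_arr = np.array(kept, dtype=int)
    return QuantizedFrameSet(
        sensor_names=names, frames=X[kept_arr], kept_indices=src_idx[kept_arr]
    )
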