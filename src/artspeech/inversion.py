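"""Bounded least-squares recovery of articulatory parameter trajectories.

Each frame of a head-corrected recording is 'inverted': the parameter
vector alpha minimizing the Euclidean misfit between the model
reconstruction ``m_Face + alpha @ eigv_Face`` and the observed sensors is
found subject to the box ``[-3, 3]`` per parameter (+/- 3 SD).  Missing
sensors are simply excluded from the objective; the model's inter-sensor
couplings then reconstruct their positions from the fitted alpha.  The
head pose is inverted the same way through the (nonlinear) rigid-motion
forward model.  Trajectories are finally smoothed with a zero-phase
6th-order Butterworth low-pass at 8 Hz.

The face objective is a convex bound-constrained linear least squares:
whenever the unconstrained optimum (tiny-ridge normal equations) already
lies inside the box it is returned directly, otherwise the problem is
handed to a constrained solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .preprocess import euler_zyx_to_matrix
from .types import (
    ArticulatoryModel,
    HeadMotionModel,
    SensorFrameSeries,
    TrajectoryMatrix,
)

__all__ = [
    "InversionResult",
    "invert_face_frame",
    "invert_head_frame",
    "invert_recording",
    "smooth_trajectories",
]

RIDGE = 1e-12  # tie-break toward the smallest-norm solution


@dataclass
class InversionResult:
    """Per-recording inversion output."""

    trajectories: TrajectoryMatrix          # final (smoothed, clipped)
    raw_trajectories: TrajectoryMatrix      # per-frame solutions, unsmoothed
    reconstructed: SensorFrameSeries        # model reconstruction, all sensors
    per_frame_residual: np.ndarray          # mm, mean over sensors per frame
    residual_mean: float                    # mm, over all sensor-frames
    residual_sd: float                      # mm
    flagged_frames: np.ndarray              # frames with too few visible coords


def _bounded_lsq(A: np.ndarray, b: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Box-constrained linear least squares with a tiny ridge tie-break."""
    m = A.shape[1]
    H = A.T @ A + RIDGE * np.eye(m)
    g = A.T @ b
    x = np.linalg.solve(H, g)
    if np.all(x >= lo - 1e-12) and np.all(x <= hi + 1e-12):
        return np.clip(x, lo, hi)
    Areg = np.vstack([A, np.sqrt(RIDGE) * np.eye(m)])
    breg = np.concatenate([b, np.zeros(m)])
    res = optimize.lsq_linear(
        Areg, breg, bounds=(lo, hi), method="bvls", tol=1e-12
    )
    return np.clip(res.x, lo, hi)


def invert_face_frame(
    p3d: np.ndarray,
    model: ArticulatoryModel,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = (-3.0, 3.0),
) -> np.ndarray:
    """Invert one head-corrected frame to parameter scores.

    Parameters
    ----------
    p3d:
        Observed sensor coordinates, stacked (3*S,) or (S, 3), in the
        model's sensor order.
    mask:
        Optional per-sensor visibility (S,); masked sensors are dropped
        from the objective.
    bounds:
        Per-parameter box, default [-3, 3] (score-SD units).
    """
    x = np.asarray(p3d, dtype=float).ravel()
    if x.size != model.n_coords:
        raise ValueError("frame has the wrong number of coordinates")
    if mask is None:
        vis = np.ones(model.n_coords, dtype=bool)
    else:
        vis = np.repeat(np.asarray(mask, dtype=bool), 3)
    if vis.sum() < model.n_params:
        raise ValueError("too few visible coordinates to invert the frame")
    A = model.loadings[vis]
    b = x[vis] - model.mean[vis]
    return _bounded_lsq(A, b, *bounds)


def invert_head_frame(
    p3d_headset: np.ndarray,
    head_model: HeadMotionModel,
    mask: np.ndarray | None = None,
    bounds: tuple[float, float] = (-3.0, 3.0),
) -> np.ndarray:
    """Invert an observed headset frame to rigid-motion scores.

    The forward model poses the mean headset shape by the 6-dof motion
    ``mean_motion + loadings @ alpha`` (rotation about the model centre);
    the optimum is found by bounded trust-region least squares started from
    alpha = 0.
    """
    obs = np.asarray(p3d_headset, dtype=float).reshape(-1, 3)
    if obs.shape[0] != len(head_model.sensor_names):
        raise ValueError("headset frame has the wrong number of sensors")
    vis = (
        np.ones(obs.shape[0], dtype=bool)
        if mask is None
        else np.asarray(mask, dtype=bool)
    )
    if vis.sum() < 3:
        raise ValueError("need at least 3 visible headset sensors")
    shape = head_model.mean_shape
    c = head_model.center

    def forward(alpha: np.ndarray) -> np.ndarray:
        motion = head_model.pose(alpha)
        R = euler_zyx_to_matrix(motion[3:6])
        return (shape - c) @ R.T + c + motion[:3]

    def residual(alpha: np.ndarray) -> np.ndarray:
        return (forward(alpha) - obs)[vis].ravel()

    res = optimize.least_squares(
        residual,
        x0=np.zeros(head_model.n_params),
        bounds=(bounds[0], bounds[1]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(
            f"head inversion did not converge (final residual {res.cost:.3g})"
        )
    return res.x


def invert_recording(
    series: SensorFrameSeries,
    model: ArticulatoryModel,
    bounds: tuple[float, float] = (-3.0, 3.0),
    smooth: bool = True,
    smooth_cutoff: float = 8.0,
    smooth_order: int = 6,
) -> InversionResult:
    """Invert every frame of a synchronized, head-corrected recording.

    Frames with fewer visible coordinates than parameters are flagged and
    their scores linearly interpolated from neighbouring frames.  The
    residual is the Euclidean distance between observed and reconstructed
    sensor positions (visible sensors only), reported per frame and as a
    mean/SD over all sensor-frames.
    """
    obs = series.select(model.sensor_names)
    F = obs.n_frames
    m = model.n_params
    alphas = np.zeros((F, m))
    flagged = np.zeros(F, dtype=bool)
    if F == 0:
        empty = TrajectoryMatrix(
            parameter_names=list(model.parameter_names),
            rate=series.rate,
            values=np.zeros((m, 0)),
        )
        return InversionResult(
            trajectories=empty,
            raw_trajectories=empty,
            reconstructed=obs,
            per_frame_residual=np.zeros(0),
            residual_mean=0.0,
            residual_sd=0.0,
            flagged_frames=flagged,
        )
    X = obs.stacked()
    full = obs.mask.all(axis=1)
    if full.any():
        # complete frames share one unconstrained solve
        H = model.loadings.T @ model.loadings + RIDGE * np.eye(m)
        sol = np.linalg.solve(H, model.loadings.T @ (X[full] - model.mean).T).T
        inside = np.all((sol >= bounds[0]) & (sol <= bounds[1]), axis=1)
        alphas[np.flatnonzero(full)[inside]] = sol[inside]
        for f in np.flatnonzero(full)[~inside]:
            alphas[f] = invert_face_frame(X[f], model, obs.mask[f], bounds)
    for f in np.flatnonzero(~full):
        if 3 * obs.mask[f].sum() < m:
            flagged[f] = True
            continue
        alphas[f] = invert_face_frame(X[f], model, obs.mask[f], bounds)
    if flagged.any():
        good = np.flatnonzero(~flagged)
        if good.size == 0:
            raise ValueError("no frame could be inverted")
        bad = np.flatnonzero(flagged)
        for k in range(m):
            alphas[bad, k] = np.interp(bad, good, alphas[good, k])
    raw = TrajectoryMatrix(
        parameter_names=list(model.parameter_names),
        rate=series.rate,
        values=alphas.T,
    )
    final = smooth_trajectories(raw, smooth_order, smooth_cutoff) if smooth else raw
    recon_flat = model.project(final.values.T)
    recon = SensorFrameSeries(
        sensor_names=list(model.sensor_names),
        times=obs.times,
        positions=recon_flat.reshape(F, -1, 3),
        rate=obs.rate,
    )
    dist = np.linalg.norm(recon.positions - obs.positions, axis=2)  # (F, S)
    per_frame = np.array(
        [d[v].mean() if v.any() else np.nan for d, v in zip(dist, obs.mask)]
    )
    all_vis = dist[obs.mask]
    return InversionResult(
        trajectories=final,
        raw_trajectories=raw,
        reconstructed=recon,
        per_frame_residual=per_frame,
        residual_mean=float(all_vis.mean()) if all_vis.size else 0.0,
        residual_sd=float(all_vis.std()) if all_vis.size else 0.0,
        flagged_frames=flagged,
    )


def smooth_trajectories(
    traj: TrajectoryMatrix,
    order: int = 6,
    cutoff: float = 8.0,
    bounds: tuple[float, float] = (-3.0, 3.0),
) -> TrajectoryMatrix:
    """Zero-phase Butterworth low-pass of the parameter trajectories.

    Applied forward-backward so articulation is not lagged relative to the
    acoustics; values pushed outside the box by the filter are clipped back.
    """
    if traj.rate <= 2 * cutoff:
        raise ValueError("trajectory rate must exceed twice the cutoff")
    b, a = signal.butter(order, cutoff, fs=traj.rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if traj.n_frames <= padlen:
        raise ValueError(
            f"trajectory too short to smooth: need > {padlen} frames, "
            f"got {traj.n_frames}"
        )
    smoothed = signal.filtfilt(b, a, traj.values, axis=1)
    return TrajectoryMatrix(
        parameter_names=list(traj.parameter_names),
        rate=traj.rate,
        values=np.clip(smoothed, bounds[0], bounds[1]),
    )
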