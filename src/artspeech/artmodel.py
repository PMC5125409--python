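"""Guided PCA articulatory model.

Plain PCA on facial data mixes articulators: the first component of raw
face/tongue frames confounds jaw, lip and tongue motion.  Guided PCA
instead extracts one parameter at a time from a designated landmark subset
and subtracts its *whole-face* contribution before the next step:

1. take the first principal direction ``u_k`` of the current residual
   restricted to the step's landmark subset;
2. standardize its scores to unit variance;
3. regress every residual coordinate on the standardized score, giving the
   whole-face loading ``v_k``;
4. subtract ``score * v_k^T`` from the residual.

The variance each step removes, as a percentage of the total variance of
the centred data, is the parameter's share of global variance.  Scores are
in SD units, so the inversion box ``[-3, 3]`` means +/- 3 SD everywhere.

The default ten-step extraction order is jaw opening, four tongue
parameters (front-back and flattening from TB/TD, then vertical and
horizontal tongue-tip from TT), three lip parameters (rounding, lower-lip
closing, upper-lip raising), jaw rotation and eyebrows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import (
    ArticulatoryModel,
    EYEBROW_SENSORS,
    JAW_SENSORS,
    LIP_SENSORS,
    LOWER_LIP_SENSORS,
    QuantizedFrameSet,
    UPPER_LIP_SENSORS,
)

__all__ = [
    "ExtractionScheme",
    "DEFAULT_SCHEME",
    "AVATAR_TONGUE_SCHEME",
    "fit_guided_pca",
    "project_frame",
    "variance_report",
]


@dataclass
class ExtractionScheme:
    """Ordered (parameter name, landmark sensor subset) extraction steps."""

    steps: list[tuple[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        self.steps = [(name, tuple(sensors)) for name, sensors in self.steps]
        names = [name for name, _ in self.steps]
        if len(set(names)) != len(names):
            raise ValueError("parameter names must be unique")
        for name, sensors in self.steps:
            if not sensors:
                raise ValueError(f"step {name!r} has an empty landmark subset")

    @property
    def parameter_names(self) -> list[str]:
        return [name for name, _ in self.steps]

    def __len__(self) -> int:
        return len(self.steps)


DEFAULT_SCHEME = ExtractionScheme(
    steps=[
        ("jaw1", JAW_SENSORS),
        ("tongue1", ("TB", "TD")),
        ("tongue2", ("TB", "TD")),
        ("tongue3", ("TT",)),
        ("tongue4", ("TT",)),
        ("lips1", LIP_SENSORS),
        ("lips2", LOWER_LIP_SENSORS),
        ("lips3", UPPER_LIP_SENSORS),
        ("jaw2", JAW_SENSORS),
        ("eyebrows1", EYEBROW_SENSORS),
    ]
)

#: five-parameter scheme for the avatar tongue model (jaw + tongue only)
AVATAR_TONGUE_SCHEME = ExtractionScheme(
    steps=[
        ("jaw1", JAW_SENSORS),
        ("tongue1", ("TB", "TD")),
        ("tongue2", ("TB", "TD")),
        ("tongue3", ("TT",)),
        ("tongue4", ("TT",)),
    ]
)


def _coord_indices(sensor_names: list[str], sensors: tuple[str, ...]) -> np.ndarray:
    try:
        base = np.array([sensor_names.index(s) for s in sensors])
    except ValueError as exc:
        raise KeyError(f"scheme names unknown sensor among {sensors}") from exc
    return (3 * base[:, None] + np.arange(3)[None, :]).ravel()


def fit_guided_pca(
    frames: QuantizedFrameSet | np.ndarray,
    scheme: ExtractionScheme = DEFAULT_SCHEME,
    sensor_names: list[str] | None = None,
    sign_convention: np.ndarray | None = None,
) -> ArticulatoryModel:
    """Fit the articulatory model by iterative subset PCA + subtraction.

    Parameters
    ----------
    frames:
        Pruned, head-corrected frames, (n, 3*S) stacked.
    scheme:
        Extraction recipe; subsets are sensor names, each contributing its
        x/y/z coordinates.
    sign_convention:
        Optional per-parameter +/-1 flips applied after the canonical sign
        fix (largest-|loading| coordinate of the subset direction positive).
    """
    if isinstance(frames, QuantizedFrameSet):
        X = frames.frames
        sensor_names = list(frames.sensor_names)
    else:
        X = np.atleast_2d(np.asarray(frames, dtype=float))
        if sensor_names is None:
            raise ValueError("sensor_names required when frames is an array")
    n, d = X.shape
    m = len(scheme)
    if n < 2 * m:
        raise ValueError(
            f"need at least {2 * m} frames to fit {m} parameters, got {n}"
        )
    mean = X.mean(axis=0)
    R = X - mean
    total_var = float(np.sum(R * R)) / n
    if total_var <= 0:
        raise ValueError("frames have zero variance")
    signs = (
        np.ones(m) if sign_convention is None else np.asarray(sign_convention, float)
    )
    loadings = np.zeros((d, m))
    fractions = np.zeros(m)
    directions: list[np.ndarray] = []
    for k, (name, sensors) in enumerate(scheme.steps):
        idx = _coord_indices(sensor_names, sensors)
        Rs = R[:, idx]
        if float(np.sum(Rs * Rs)) / n <= 1e-12 * total_var:
            raise ValueError(
                f"zero residual variance on the landmark subset of step {name!r}"
            )
        # first principal direction of the residual restricted to the subset
        _, s, Vt = np.linalg.svd(Rs, full_matrices=False)
        u = Vt[0]
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        u = u * signs[k]
        scores = Rs @ u
        sd = scores.std()
        if sd <= 0:
            raise ValueError(f"degenerate scores in step {name!r}")
        z = scores / sd
        v = R.T @ z / n       # regression of every coordinate on the unit-SD score
        R -= np.outer(z, v)
        loadings[:, k] = v
        fractions[k] = float(v @ v) / total_var * 100.0
        directions.append(u)
    return ArticulatoryModel(
        parameter_names=scheme.parameter_names,
        sensor_names=sensor_names,
        mean=mean,
        loadings=loadings,
        variance_fractions=fractions,
        subset_directions=directions,
        scheme_steps=list(scheme.steps),
        sign_convention=signs,
    )


def project_frame(model: ArticulatoryModel, alpha: np.ndarray) -> np.ndarray:
    """Sensor coordinates ``mean + loadings @ alpha`` (alpha in SD units)."""
    return model.project(alpha)


def variance_report(
    model: ArticulatoryModel, frames: QuantizedFrameSet | np.ndarray
) -> dict[str, float]:
    """Percentage of global variance each parameter accounts for on ``frames``.

    Replays the fitted extraction (stored subset directions, re-scored and
    re-regressed on the given data); on the fitting data this reproduces the
    stored ``variance_fractions``.
    """
    if model.subset_directions is None or model.scheme_steps is None:
        raise ValueError("model lacks stored extraction steps")
    X = frames.frames if isinstance(frames, QuantizedFrameSet) else np.atleast_2d(
        np.asarray(frames, dtype=float)
    )
    n = X.shape[0]
    R = X - X.mean(axis=0)
    total_var = float(np.sum(R * R)) / n
    report: dict[str, float] = {}
    for (name, sensors), u in zip(model.scheme_steps, model.subset_directions):
        idx = _coord_indices(model.sensor_names, sensors)
        scores = R[:, idx] @ u
        sd = scores.std()
        if sd <= 0:
            report[name] = 0.0
            continue
        z = scores / sd
        v = R.T @ z / n
        R -= np.outer(z, v)
        report[name] = float(v @ v) / total_var * 100.0
    return report
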