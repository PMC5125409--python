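"""Readers and writers for every on-disk artifact.

Formats
-------
* phone segmentations: festvox-style ``.lab`` (one ``end_time label`` line
  per interval, ``#`` comment lines ignored) and Praat TextGrid in the long
  text format (first IntervalTier only);
* trajectory tables and sensor recordings: CSV, one row per frame, first
  column ``time``;
* articulatory / head-motion models and diphone dictionaries: versioned
  self-describing JSON containers (arrays as nested float lists, which
  round-trip float64 exactly through ``repr``).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ArticulatoryModel,
    HeadMotionModel,
    PhoneSegmentation,
    QuantizedFrameSet,
    SensorFrameSeries,
    TrajectoryMatrix,
    coordinate_names,
)

__all__ = [
    "ParseError",
    "SchemaError",
    "read_segmentation",
    "write_segmentation",
    "read_trajectory",
    "write_trajectory",
    "read_sensor_series",
    "write_sensor_series",
    "read_frame_set",
    "write_frame_set",
    "save_model",
    "load_model",
    "save_head_model",
    "load_head_model",
    "save_dictionary",
    "load_dictionary",
]

MODEL_SCHEMA = "artspeech.model/1"
HEAD_MODEL_SCHEMA = "artspeech.head-model/1"
DICTIONARY_SCHEMA = "artspeech.diphones/1"


class ParseError(ValueError):
    """A file could not be parsed under the named dialect."""


class SchemaError(ValueError):
    """A JSON container is missing, truncated, or has the wrong schema tag."""


# ---------------------------------------------------------------------------
# phone segmentations
# ---------------------------------------------------------------------------

def read_segmentation(path, dialect: str = "lab") -> PhoneSegmentation:
    """Read a phone segmentation from a ``.lab`` or TextGrid file.

    Parameters
    ----------
    path:
        File to read; the utterance id is the file stem.
    dialect:
        ``"lab"`` or ``"textgrid"``.
    """
    path = Path(path)
    if dialect == "lab":
        labels, ends = _read_lab(path)
    elif dialect == "textgrid":
        labels, ends = _read_textgrid(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not labels:
        raise ParseError(f"{path}: no intervals found")
    return PhoneSegmentation(
        utterance_id=path.stem, labels=labels, end_times=np.array(ends)
    )


def _read_lab(path: Path) -> tuple[list[str], list[float]]:
    labels: list[str] = []
    ends: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'end_time label'")
        try:
            end = float(parts[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad time {parts[0]!r}") from exc
        labels.append(parts[-1])
        ends.append(end)
    if ends and any(b <= a for a, b in zip(ends, ends[1:])):
        raise ParseError(f"{path}: end times are not strictly increasing")
    return labels, ends


def _read_textgrid(path: Path) -> tuple[list[str], list[float]]:
    """Parse the first IntervalTier of a Praat long-format TextGrid."""
    lines = path.read_text().splitlines()
    labels: list[str] = []
    ends: list[float] = []
    in_tier = False
    xmax = xmin = None
    text = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if line.startswith("class") and "IntervalTier" in line:
            if in_tier:
                break  # only the first tier
            in_tier = True
            continue
        if not in_tier:
            continue
        if line.startswith("item ["):
            break  # next tier begins
        if line.startswith("intervals ["):
            xmin = xmax = text = None
        for key in ("xmin", "xmax"):
            if line.startswith(key):
                try:
                    val = float(line.split("=")[1].strip())
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"{path}:{lineno}: bad {key} line") from exc
                if key == "xmin":
                    xmin = val
                else:
                    xmax = val
        if line.startswith("text"):
            try:
                text = line.split("=", 1)[1].strip().strip('"')
            except IndexError as exc:
                raise ParseError(f"{path}:{lineno}: bad text line") from exc
            if xmax is None:
                raise ParseError(f"{path}:{lineno}: text before xmax")
            labels.append(text if text else "_")
            ends.append(xmax)
    if ends and any(b <= a for a, b in zip(ends, ends[1:])):
        raise ParseError(f"{path}: interval times are not monotone")
    return labels, ends


def write_segmentation(seg: PhoneSegmentation, path, dialect: str = "lab") -> Path:
    """Write ``seg`` so that :func:`read_segmentation` recovers it exactly."""
    path = Path(path)
    if dialect == "lab":
        lines = ["# end_time_seconds label"]
        lines += [f"{t!r} {lbl}" for lbl, t in seg.intervals]
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "textgrid":
        path.write_text(_format_textgrid(seg))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


def _format_textgrid(seg: PhoneSegmentation) -> str:
    xmax = float(seg.end_times[-1])
    out = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {xmax!r}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        '        name = "phones"',
        "        xmin = 0",
        f"        xmax = {xmax!r}",
        f"        intervals: size = {len(seg)}",
    ]
    starts = seg.start_times
    for i, (lbl, end) in enumerate(seg.intervals, start=1):
        out += [
            f"        intervals [{i}]:",
            f"            xmin = {float(starts[i - 1])!r}",
            f"            xmax = {float(end)!r}",
            f'            text = "{lbl}"',
        ]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_trajectory(traj: TrajectoryMatrix, path) -> Path:
    """Trajectory as CSV: ``time`` column plus one column per parameter."""
    path = Path(path)
    df = pd.DataFrame(traj.values.T, columns=traj.parameter_names)
    df.insert(0, "time", traj.times)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_trajectory(path) -> TrajectoryMatrix:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ParseError(f"{path}: missing 'time' column")
    times = df["time"].to_numpy()
    if times.size < 2:
        rate = 60.0
    else:
        rate = 1.0 / float(np.median(np.diff(times)))
    names = [c for c in df.columns if c != "time"]
    return TrajectoryMatrix(
        parameter_names=names, rate=rate, values=df[names].to_numpy().T
    )


def write_sensor_series(series: SensorFrameSeries, path) -> Path:
    """Sensor recording as CSV: time, then x/y/z and a validity flag per sensor."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time": series.times}
    for i, name in enumerate(series.sensor_names):
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = series.positions[:, i, j]
        cols[f"{name}_ok"] = series.mask[:, i].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


def read_sensor_series(path, rate: float | None = None) -> SensorFrameSeries:
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ParseError(f"{path}: missing 'time' column")
    times = df["time"].to_numpy()
    names = []
    for c in df.columns:
        if c.endswith("_x"):
            names.append(c[:-2])
    if not names:
        raise ParseError(f"{path}: no sensor columns found")
    f = len(df)
    positions = np.zeros((f, len(names), 3))
    mask = np.ones((f, len(names)), dtype=bool)
    for i, name in enumerate(names):
        for j, ax in enumerate("xyz"):
            positions[:, i, j] = df[f"{name}_{ax}"].to_numpy()
        ok = f"{name}_ok"
        if ok in df.columns:
            mask[:, i] = df[ok].to_numpy().astype(bool)
    if rate is None:
        if times.size < 2:
            raise ParseError(f"{path}: cannot infer rate from a single frame")
        rate = 1.0 / float(np.median(np.diff(times)))
    positions[~mask] = 0.0
    return SensorFrameSeries(
        sensor_names=names, times=times, positions=positions, rate=rate, mask=mask
    )


def write_frame_set(frames: QuantizedFrameSet, path) -> Path:
    """Pruned frame set as CSV: ``frame`` index plus stacked coordinates."""
    path = Path(path)
    df = pd.DataFrame(frames.frames, columns=coordinate_names(frames.sensor_names))
    df.insert(0, "frame", frames.kept_indices)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_frame_set(path) -> QuantizedFrameSet:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise ParseError(f"{path}: missing 'frame' column")
    coord_cols = [c for c in df.columns if c != "frame"]
    names: list[str] = []
    for c in coord_cols:
        if c.endswith("_x"):
            names.append(c[:-2])
    return QuantizedFrameSet(
        sensor_names=names,
        frames=df[coord_cols].to_numpy(),
        kept_indices=df["frame"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# JSON containers
# ---------------------------------------------------------------------------

def _load_json(path, schema: str) -> dict:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise SchemaError(f"{path}: not a readable JSON container: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("schema") != schema:
        raise SchemaError(
            f"{path}: expected schema {schema!r}, found {payload.get('schema')!r}"
            if isinstance(payload, dict)
            else f"{path}: expected a JSON object"
        )
    return payload


def save_model(model: ArticulatoryModel, path) -> Path:
    path = Path(path)
    payload = {
        "schema": MODEL_SCHEMA,
        "parameter_names": model.parameter_names,
        "sensor_names": model.sensor_names,
        "mean": model.mean.tolist(),
        "loadings": model.loadings.tolist(),
        "variance_fractions": (
            None
            if model.variance_fractions is None
            else model.variance_fractions.tolist()
        ),
        "subset_directions": (
            None
            if model.subset_directions is None
            else [u.tolist() for u in model.subset_directions]
        ),
        "scheme_steps": (
            None
            if model.scheme_steps is None
            else [[name, list(sensors)] for name, sensors in model.scheme_steps]
        ),
        "sign_convention": model.sign_convention.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> ArticulatoryModel:
    p = _load_json(path, MODEL_SCHEMA)
    try:
        return ArticulatoryModel(
            parameter_names=p["parameter_names"],
            sensor_names=p["sensor_names"],
            mean=np.array(p["mean"], dtype=float),
            loadings=np.array(p["loadings"], dtype=float).reshape(
                len(p["mean"]), len(p["parameter_names"])
            ),
            variance_fractions=(
                None
                if p.get("variance_fractions") is None
                else np.array(p["variance_fractions"], dtype=float)
            ),
            subset_directions=(
                None
                if p.get("subset_directions") is None
                else [np.array(u, dtype=float) for u in p["subset_directions"]]
            ),
            scheme_steps=(
                None
                if p.get("scheme_steps") is None
                else [(name, tuple(sensors)) for name, sensors in p["scheme_steps"]]
            ),
            sign_convention=(
                None
                if p.get("sign_convention") is None
                else np.array(p["sign_convention"], dtype=float)
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed model container: {exc}") from exc


def save_head_model(model: HeadMotionModel, path) -> Path:
    path = Path(path)
    payload = {
        "schema": HEAD_MODEL_SCHEMA,
        "sensor_names": model.sensor_names,
        "mean_shape": model.mean_shape.tolist(),
        "center": model.center.tolist(),
        "mean_motion": model.mean_motion.tolist(),
        "loadings": model.loadings.tolist(),
        "explained": model.explained.tolist(),
    }
    path.write_text(json.dumps(payload))
    return path


def load_head_model(path) -> HeadMotionModel:
    p = _load_json(path, HEAD_MODEL_SCHEMA)
    try:
        return HeadMotionModel(
            sensor_names=p["sensor_names"],
            mean_shape=np.array(p["mean_shape"], dtype=float),
            center=np.array(p["center"], dtype=float),
            mean_motion=np.array(p["mean_motion"], dtype=float),
            loadings=np.array(p["loadings"], dtype=float).reshape(6, -1),
            explained=np.array(p["explained"], dtype=float),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed head-model container: {exc}") from exc


def save_dictionary(dictionary, path) -> Path:
    """Serialize a :class:`~artspeech.diphones.DiphoneDictionary` to JSON."""
    path = Path(path)
    units = []
    for label in dictionary.labels():
        for u in dictionary.get(label):
            units.append(
                {
                    "label": u.label,
                    "source_utterance": u.source_utterance,
                    "source_start": u.source_start,
                    "source_end": u.source_end,
                    "duration": u.duration,
                    "values": u.values.tolist(),
                }
            )
    payload = {
        "schema": DICTIONARY_SCHEMA,
        "parameter_names": dictionary.parameter_names,
        "rate": dictionary.rate,
        "units": units,
    }
    path.write_text(json.dumps(payload))
    return path


def load_dictionary(path):
    from .diphones import DiphoneDictionary, DiphoneUnit

    p = _load_json(path, DICTIONARY_SCHEMA)
    try:
        dictionary = DiphoneDictionary(
            parameter_names=p["parameter_names"], rate=p["rate"]
        )
        for u in p["units"]:
            dictionary.add(
                DiphoneUnit(
                    label=u["label"],
                    parameter_names=p["parameter_names"],
                    rate=p["rate"],
                    values=np.array(u["values"], dtype=float).reshape(
                        len(p["parameter_names"]), -1
                    ),
                    source_utterance=u["source_utterance"],
                    source_start=u["source_start"],
                    source_end=u["source_end"],
                    duration=u["duration"],
                )
            )
        return dictionary
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: malformed dictionary container: {exc}") from exc
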