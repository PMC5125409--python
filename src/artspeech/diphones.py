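"""Diphone derivation and the multimodal diphone dictionary.

A diphone spans from the stable middle of one phone to the stable middle
of the next, so diphone boundaries sit at phone temporal midpoints.  For a
segmented utterance with an inverted trajectory, each adjacent phone pair
yields one unit: a slice of the 60 Hz articulatory trajectory between the
midpoints, with provenance (utterance, frame range) kept so the
synthesizer can recognize originally contiguous units.

Frame mapping uses ``index = floor(time * rate)`` with half-open
``[start, end)`` slices, so a sentence's own units tile its trajectory
exactly between the first and last midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .types import PhoneSegmentation, TrajectoryMatrix

__all__ = [
    "DiphoneTarget",
    "DiphoneUnit",
    "DiphoneDictionary",
    "phones_to_diphones",
    "extract_diphone_units",
    "build_dictionary",
]


@dataclass
class DiphoneTarget:
    """A requested diphone: two-phone label and target duration (s)."""

    label: str
    target_duration: float
    first_phone: str = ""
    second_phone: str = ""

    def __post_init__(self) -> None:
        if self.target_duration <= 0:
            raise ValueError(f"diphone {self.label!r} has non-positive duration")
        if not self.first_phone or not self.second_phone:
            raise ValueError("diphone needs both phone labels")


@dataclass
class DiphoneUnit:
    """One dictionary unit: a trajectory slice with provenance."""

    label: str
    parameter_names: list[str]
    rate: float
    values: np.ndarray          # (M, T)
    source_utterance: str
    source_start: int           # frame index, half-open [start, end)
    source_end: int
    duration: float             # seconds

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.parameter_names):
            raise ValueError("unit values must have one row per parameter")
        if self.values.shape[1] < 1:
            raise ValueError("unit must have at least one frame")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def first_frame(self) -> np.ndarray:
        return self.values[:, 0]

    @property
    def last_frame(self) -> np.ndarray:
        return self.values[:, -1]

    def is_contiguous_with(self, other: "DiphoneUnit") -> bool:
        """True when ``other`` continues this unit in its source sentence."""
        return (
            self.source_utterance == other.source_utterance
            and self.source_end == other.source_start
        )


@dataclass
class DiphoneDictionary:
    """Diphone label -> list of units, with a shared parameter set and rate."""

    parameter_names: list[str]
    rate: float = 60.0
    units: dict[str, list[DiphoneUnit]] = field(default_factory=dict)

    def add(self, unit: DiphoneUnit) -> None:
        if unit.label not in self.units:
            self.units[unit.label] = []
        if list(unit.parameter_names) != list(self.parameter_names):
            raise ValueError("unit parameter set differs from the dictionary's")
        self.units[unit.label].append(unit)

    def get(self, label: str) -> list[DiphoneUnit]:
        return self.units.get(label, [])

    def labels(self) -> list[str]:
        return sorted(self.units)

    @property
    def n_units(self) -> int:
        return sum(len(v) for v in self.units.values())

    def coverage_report(self) -> dict[str, int]:
        return {label: len(self.units[label]) for label in self.labels()}


def phones_to_diphones(seg: PhoneSegmentation) -> list[DiphoneTarget]:
    """Derive the ordered diphone list of a segmentation.

    One target per adjacent phone pair, spanning midpoint to midpoint; a
    segmentation of n phones yields n - 1 diphones.
    """
    if len(seg) < 2:
        raise ValueError("need at least two phones to form a diphone")
    mids = seg.midpoints
    out = []
    for i in range(len(seg) - 1):
        out.append(
            DiphoneTarget(
                label=seg.labels[i] + seg.labels[i + 1],
                target_duration=float(mids[i + 1] - mids[i]),
                first_phone=seg.labels[i],
                second_phone=seg.labels[i + 1],
            )
        )
    return out


def extract_diphone_units(
    seg: PhoneSegmentation, traj: TrajectoryMatrix
) -> list[DiphoneUnit]:
    """Cut an utterance's trajectory into diphone units at phone midpoints."""
    if traj.duration + 1e-9 < seg.end_times[-1]:
        raise ValueError(
            f"trajectory ({traj.duration:.3f} s) shorter than the "
            f"segmentation ({seg.end_times[-1]:.3f} s)"
        )
    targets = phones_to_diphones(seg)
    mids = seg.midpoints
    frames = np.floor(mids * traj.rate + 1e-9).astype(int)
    units = []
    for i, tgt in enumerate(targets):
        start, end = int(frames[i]), int(frames[i + 1])
        if end <= start:
            raise ValueError(
                f"diphone {tgt.label!r} spans no frame at {traj.rate:g} Hz"
            )
        units.append(
            DiphoneUnit(
                label=tgt.label,
                parameter_names=list(traj.parameter_names),
                rate=traj.rate,
                values=traj.values[:, start:end].copy(),
                source_utterance=seg.utterance_id,
                source_start=start,
                source_end=end,
                duration=(end - start) / traj.rate,
            )
        )
    return units


def build_dictionary(
    corpus: Iterable[tuple[PhoneSegmentation, TrajectoryMatrix]]
) -> DiphoneDictionary:
    """Group the diphone units of a corpus by label.

    Unit lists are kept stable-sorted by (utterance id, start frame), so
    the build is order-independent up to that ordering.
    """
    entries = list(corpus)
    if not entries:
        raise ValueError("corpus is empty")
    first_traj = entries[0][1]
    dictionary = DiphoneDictionary(
        parameter_names=list(first_traj.parameter_names), rate=first_traj.rate
    )
    for seg, traj in entries:
        for unit in extract_diphone_units(seg, traj):
            dictionary.add(unit)
    for label in dictionary.units:
        dictionary.units[label].sort(
            key=lambda u: (u.source_utterance, u.source_start)
        )
    return dictionary
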