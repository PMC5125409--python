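"""Diphone-concatenation synthesis of articulatory trajectories.

Given a phone + duration list and a diphone dictionary the synthesizer
(1) derives the diphone target sequence, (2) builds a trellis of candidate
units per target and selects the cheapest path by dynamic programming —
the boundary cost is the RMS distance between the articulatory parameters
at the junction, and consecutive units that were contiguous in their
source sentence cost nothing — (3) warps each unit to its target duration,
and (4) removes residual concatenation gaps by adding a linear ramp
``delta * i / T`` inside the preceding unit, so the last sample of each
unit coincides with the first sample of the next while the nonlinear
within-unit shape (its second differences) is preserved.

Gap removal runs right-to-left so every ramp targets the already-adjusted
first frame of the following unit; the duplicated boundary sample is
dropped when assembling the final trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .diphones import DiphoneDictionary, DiphoneTarget, DiphoneUnit, phones_to_diphones
from .types import PhoneSegmentation, TrajectoryMatrix

__all__ = [
    "Trellis",
    "SynthesisReport",
    "assemble_target_sequence",
    "build_trellis",
    "select_units",
    "warp_unit_duration",
    "gapless_adjust",
    "gapless_concatenate",
    "synthesize_trajectories",
]

BRIDGE_UTTERANCE = "<bridge>"


@dataclass
class Trellis:
    """Slot-by-candidate lattice over which the best unit path is found."""

    slots: list[DiphoneTarget]
    candidates: list[list[DiphoneUnit]]
    fallback_slots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.slots) != len(self.candidates):
            raise ValueError("one candidate list per slot required")
        for tgt, cands in zip(self.slots, self.candidates):
            if not cands:
                raise ValueError(f"slot {tgt.label!r} has no candidates")


@dataclass
class SynthesisReport:
    selected: list[DiphoneUnit]
    total_cost: float
    boundary_costs: list[float]
    warnings: list[str]


def assemble_target_sequence(
    phones: list[tuple[str, float]]
) -> list[DiphoneTarget]:
    """Diphone targets for a phone (label, duration) list."""
    if len(phones) < 2:
        raise ValueError("need at least two phones to synthesize")
    durations = [d for _, d in phones]
    if any(d <= 0 for d in durations):
        raise ValueError("phone durations must be positive")
    seg = PhoneSegmentation(
        utterance_id="<request>",
        labels=[p for p, _ in phones],
        end_times=np.cumsum(durations),
    )
    return phones_to_diphones(seg)


def _bridge_unit(label: str, parameter_names: list[str], rate: float) -> DiphoneUnit:
    """Placeholder for an uncovered diphone; materialized after selection."""
    m = len(parameter_names)
    return DiphoneUnit(
        label=label,
        parameter_names=parameter_names,
        rate=rate,
        values=np.zeros((m, 2)),
        source_utterance=BRIDGE_UTTERANCE,
        source_start=0,
        source_end=2,
        duration=2 / rate,
    )


def build_trellis(
    targets: list[DiphoneTarget], dictionary: DiphoneDictionary
) -> tuple[Trellis, list[str]]:
    """Candidate lists per target, with graceful fallback.

    Missing labels fall back to (1) any unit sharing the second phone, else
    (2) a two-frame linear bridge between the neighbouring selected units,
    each with a logged warning.
    """
    notes: list[str] = []
    candidates: list[list[DiphoneUnit]] = []
    fallback_slots: list[int] = []
    for i, tgt in enumerate(targets):
        cands = dictionary.get(tgt.label)
        if not cands:
            cands = [
                u
                for lbl in dictionary.labels()
                if lbl.endswith(tgt.second_phone) and lbl != tgt.label
                for u in dictionary.get(lbl)
            ]
            if cands:
                notes.append(
                    f"diphone {tgt.label!r} not in dictionary; using "
                    f"{len(cands)} units sharing the second phone"
                )
            else:
                cands = [
                    _bridge_unit(
                        tgt.label, dictionary.parameter_names, dictionary.rate
                    )
                ]
                notes.append(
                    f"diphone {tgt.label!r} unresolvable; inserting a linear bridge"
                )
            fallback_slots.append(i)
        candidates.append(cands)
    for msg in notes:
        warnings.warn(msg, stacklevel=2)
    return Trellis(slots=list(targets), candidates=candidates,
                   fallback_slots=fallback_slots), notes


def _boundary_cost(prev: DiphoneUnit, nxt: DiphoneUnit) -> float:
    """RMS parameter gap at the junction; zero for contiguous source units."""
    if prev.is_contiguous_with(nxt):
        return 0.0
    if prev.source_utterance == BRIDGE_UTTERANCE or (
        nxt.source_utterance == BRIDGE_UTTERANCE
    ):
        return 0.0
    delta = nxt.first_frame - prev.last_frame
    return float(np.sqrt(np.mean(delta**2)))


def select_units(
    targets: list[DiphoneTarget],
    dictionary: DiphoneDictionary,
    w_sel: float = 0.0,
) -> SynthesisReport:
    """Minimum-cost path through the candidate trellis (Viterbi DP).

    Total cost is the sum of boundary RMS gaps plus an optional per-unit
    duration-mismatch term ``w_sel * |log(unit_duration / target_duration)|``
    (off by default).  Ties break toward the lowest candidate index, so
    reruns are deterministic.
    """
    trellis, notes = build_trellis(targets, dictionary)
    n = len(trellis.slots)
    unit_cost = [
        np.array(
            [
                w_sel * abs(np.log(u.duration / tgt.target_duration))
                if w_sel and u.source_utterance != BRIDGE_UTTERANCE
                else 0.0
                for u in cands
            ]
        )
        for tgt, cands in zip(trellis.slots, trellis.candidates)
    ]
    best = unit_cost[0].copy()
    back: list[np.ndarray] = []
    for i in range(1, n):
        prev_units = trellis.candidates[i - 1]
        cur_units = trellis.candidates[i]
        trans = np.array(
            [[_boundary_cost(p, c) for p in prev_units] for c in cur_units]
        )  # (cur, prev)
        total = trans + best[None, :]
        arg = np.argmin(total, axis=1)  # first minimum = lowest index
        best = total[np.arange(len(cur_units)), arg] + unit_cost[i]
        back.append(arg)
    end = int(np.argmin(best))
    path = [end]
    for arg in reversed(back):
        path.append(int(arg[path[-1]]))
    path.reverse()
    selected = [trellis.candidates[i][j] for i, j in enumerate(path)]
    boundary_costs = [
        _boundary_cost(selected[i], selected[i + 1]) for i in range(n - 1)
    ]
    return SynthesisReport(
        selected=selected,
        total_cost=float(best[end]),
        boundary_costs=boundary_costs,
        warnings=notes,
    )


def warp_unit_duration(
    unit: DiphoneUnit,
    target_duration: float,
    rate: float = 60.0,
    n_frames: int | None = None,
) -> DiphoneUnit:
    """Linearly time-rescale a unit to the target duration.

    The trajectory is resampled by linear interpolation on a stretched time
    axis; first and last frame values are preserved exactly.  The output
    frame count is ``max(1, round(target_duration * rate))`` unless
    ``n_frames`` overrides it.
    """
    if target_duration <= 0:
        raise ValueError("target duration must be positive")
    n = n_frames if n_frames is not None else max(1, round(target_duration * rate))
    t_src = unit.n_frames
    if t_src == 1:
        values = np.repeat(unit.values, n, axis=1)
    elif n == 1:
        values = unit.values[:, :1].copy()
    else:
        pos = np.arange(n) * (t_src - 1) / (n - 1)
        src = np.arange(t_src)
        values = np.vstack([np.interp(pos, src, row) for row in unit.values])
    return DiphoneUnit(
        label=unit.label,
        parameter_names=list(unit.parameter_names),
        rate=rate,
        values=values,
        source_utterance=unit.source_utterance,
        source_start=unit.source_start,
        source_end=unit.source_end,
        duration=n / rate,
    )


def gapless_adjust(units: list[DiphoneUnit]) -> list[np.ndarray]:
    """Per-unit trajectories after gap-removal ramps (no assembly).

    Processing runs right-to-left: for each unit before a non-contiguous
    boundary, ``delta = next_first - last`` is spread as ``delta * i / T``
    over its frames i = 1..T, so its final sample lands exactly on the
    (already adjusted) first sample of the next unit.  Contiguous
    same-source boundaries are left untouched.  Within-unit second
    differences are preserved (the ramp is linear in i).
    """
    if not units:
        raise ValueError("need at least one unit")
    pnames = units[0].parameter_names
    for u in units[1:]:
        if list(u.parameter_names) != list(pnames):
            raise ValueError("units disagree on the parameter set")
    adjusted = [u.values.astype(float).copy() for u in units]
    for j in range(len(units) - 2, -1, -1):
        if units[j].is_contiguous_with(units[j + 1]):
            continue
        delta = adjusted[j + 1][:, 0] - adjusted[j][:, -1]
        T = adjusted[j].shape[1]
        ramp = np.arange(1, T + 1) / T
        adjusted[j] = adjusted[j] + delta[:, None] * ramp[None, :]
    return adjusted


def gapless_concatenate(units: list[DiphoneUnit]) -> TrajectoryMatrix:
    """Concatenate units after gap removal, dropping duplicated boundaries.

    At every non-contiguous boundary the ramp makes the preceding unit's
    final sample coincide with the next unit's first sample (within 1e-9);
    the preceding copy of that sample is dropped during assembly so the
    boundary appears exactly once.
    """
    adjusted = gapless_adjust(units)
    pieces = []
    for j, arr in enumerate(adjusted):
        if j < len(units) - 1 and not units[j].is_contiguous_with(units[j + 1]):
            pieces.append(arr[:, :-1])
        else:
            pieces.append(arr)
    return TrajectoryMatrix(
        parameter_names=list(units[0].parameter_names),
        rate=units[0].rate,
        values=np.hstack(pieces),
    )


def synthesize_trajectories(
    phones: list[tuple[str, float]],
    dictionary: DiphoneDictionary,
    w_sel: float = 0.0,
    bounds: tuple[float, float] = (-3.0, 3.0),
) -> tuple[TrajectoryMatrix, SynthesisReport]:
    """Full synthesis pipeline: assemble, select, warp, concatenate, clip.

    Frame counts per unit come from the cumulative midpoint times, and
    units followed by a ramped boundary are warped one frame long (the
    duplicate is dropped at assembly), so the output length is exactly
    ``round(span * rate)`` frames where span is last minus first phone
    midpoint.
    """
    targets = assemble_target_sequence(phones)
    report = select_units(targets, dictionary, w_sel=w_sel)
    selected = _materialize_bridges(report.selected)
    rate = dictionary.rate
    # frame allocation follows the extraction convention (floor of midpoint
    # times) so a sentence resynthesized from its own units needs no warping
    mids = np.concatenate(
        [[0.0], np.cumsum([t.target_duration for t in targets])]
    )
    durs = [d for _, d in phones]
    mids = mids + durs[0] / 2.0  # absolute phone midpoints
    frame_bounds = np.floor(mids * rate + 1e-9).astype(int)
    warped: list[DiphoneUnit] = []
    for i, unit in enumerate(selected):
        n = int(frame_bounds[i + 1] - frame_bounds[i])
        n = max(n, 1)
        ramped = i < len(selected) - 1 and not unit.is_contiguous_with(
            selected[i + 1]
        )
        warped.append(
            warp_unit_duration(
                unit, targets[i].target_duration, rate, n_frames=n + 1 if ramped else n
            )
        )
    traj = gapless_concatenate(warped)
    traj.values = np.clip(traj.values, bounds[0], bounds[1])
    return traj, report


def _materialize_bridges(selected: list[DiphoneUnit]) -> list[DiphoneUnit]:
    """Replace bridge placeholders by 2-frame ramps between their neighbours."""
    out = list(selected)
    for i, u in enumerate(out):
        if u.source_utterance != BRIDGE_UTTERANCE:
            continue
        left = out[i - 1].last_frame if i > 0 else None
        right = out[i + 1].first_frame if i < len(out) - 1 else None
        if left is None and right is None:
            raise ValueError("cannot bridge a single-slot request")
        if left is None:
            left = right
        if right is None:
            right = left
        out[i] = DiphoneUnit(
            label=u.label,
            parameter_names=list(u.parameter_names),
            rate=u.rate,
            values=np.column_stack([left, right]),
            source_utterance=BRIDGE_UTTERANCE,
            source_start=0,
            source_end=2,
            duration=2 / u.rate,
        )
    return out
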