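"""Unit selection, duration warping and gapless concatenation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from artspeech import synthesis
from artspeech.diphones import DiphoneDictionary, DiphoneTarget, DiphoneUnit
from artspeech.synthesis import (
    assemble_target_sequence,
    gapless_adjust,
    gapless_concatenate,
    select_units,
    synthesize_trajectories,
    warp_unit_duration,
)

P = ["p0", "p1"]


def _unit(label, values, utt="u", start=0, rate=60.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return DiphoneUnit(
        label=label,
        parameter_names=P[: values.shape[0]],
        rate=rate,
        values=values,
        source_utterance=utt,
        source_start=start,
        source_end=start + values.shape[1],
        duration=values.shape[1] / rate,
    )


def _dictionary(units):
    d = DiphoneDictionary(parameter_names=list(units[0].parameter_names), rate=60.0)
    for u in units:
        d.add(u)
    return d


def _exhaustive_best_cost(targets, dictionary, w_sel=0.0):
    """Brute-force minimum path cost over the full trellis."""
    trellis, _ = synthesis.build_trellis(targets, dictionary)
    best = np.inf
    for combo in itertools.product(*[range(len(c)) for c in trellis.candidates]):
        units = [trellis.candidates[i][j] for i, j in enumerate(combo)]
        cost = sum(
            synthesis._boundary_cost(a, b) for a, b in zip(units, units[1:])
        )
        if w_sel:
            cost += sum(
                w_sel * abs(np.log(u.duration / t.target_duration))
                for u, t in zip(units, trellis.slots)
            )
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# target assembly
# ---------------------------------------------------------------------------

def test_welcome_request_assembles_seven_targets():
    phones = [("_", 0.06), ("w", 0.065), ("E", 0.065), ("l", 0.10),
              ("k", 0.095), ("@", 0.125), ("m", 0.185), ("_", 0.2)]
    targets = assemble_target_sequence(phones)
    assert [t.label for t in targets] == ["_w", "wE", "El", "lk", "k@", "@m", "m_"]


def test_two_equal_phones_make_one_midpoint_to_midpoint_target():
    targets = assemble_target_sequence([("a", 0.2), ("b", 0.2)])
    assert len(targets) == 1
    assert targets[0].target_duration == pytest.approx(0.2)


def test_single_phone_request_is_an_error():
    with pytest.raises(ValueError, match="two phones"):
        assemble_target_sequence([("a", 0.5)])


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_single_candidates_are_selected_with_boundary_cost(rng):
    u1 = _unit("ab", rng.normal(size=(2, 5)))
    u2 = _unit("bc", rng.normal(size=(2, 4)), utt="v")
    d = _dictionary([u1, u2])
    targets = [
        DiphoneTarget("ab", 5 / 60, "a", "b"),
        DiphoneTarget("bc", 4 / 60, "b", "c"),
    ]
    rep = select_units(targets, d)
    expected = float(np.sqrt(np.mean((u2.first_frame - u1.last_frame) ** 2)))
    assert rep.total_cost == pytest.approx(expected)
    assert [u.label for u in rep.selected] == ["ab", "bc"]


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    n_slots=st.integers(2, 5),
    n_cands=st.integers(1, 4),
)
def test_dp_matches_exhaustive_enumeration(seed, n_slots, n_cands):
    """Viterbi path cost equals brute force on every trellis shape."""
    rng = np.random.default_rng(seed)
    units = []
    for i in range(n_slots):
        for j in range(n_cands):
            # occasional contiguous pairs across slots exercise zero-cost arcs
            utt = f"u{j}" if rng.random() < 0.5 else f"u{j}{i}"
            units.append(
                _unit(
                    f"l{i}",
                    rng.normal(size=(2, rng.integers(2, 6))),
                    utt=utt,
                    start=10 * i,
                )
            )
    d = _dictionary(units)
    targets = [DiphoneTarget(f"l{i}", 0.08, "l", str(i)) for i in range(n_slots)]
    rep = select_units(targets, d)
    assert rep.total_cost == pytest.approx(
        _exhaustive_best_cost(targets, d), abs=1e-9
    )


def test_contiguous_source_units_cost_nothing(small_corpus):
    """A request covered by one sentence selects its own units at zero cost."""
    sent = small_corpus.sentences[0]
    from artspeech.diphones import build_dictionary

    d = build_dictionary([(sent.segmentation, sent.truth_trajectory)])
    phones = list(zip(sent.segmentation.labels, sent.segmentation.durations))
    targets = assemble_target_sequence(phones)
    rep = select_units(targets, d)
    assert rep.total_cost == 0.0
    for a, b in zip(rep.selected, rep.selected[1:]):
        assert a.is_contiguous_with(b)


def test_unresolvable_target_inserts_a_bridge_with_warning(rng):
    d = _dictionary([_unit("ab", rng.normal(size=(2, 4)))])
    targets = [
        DiphoneTarget("ab", 0.07, "a", "b"),
        DiphoneTarget("zq", 0.07, "z", "q"),
    ]
    with pytest.warns(UserWarning, match="unresolvable"):
        rep = select_units(targets, d)
    assert rep.selected[1].source_utterance == synthesis.BRIDGE_UTTERANCE


# ---------------------------------------------------------------------------
# duration warping
# ---------------------------------------------------------------------------

def test_warp_to_own_duration_is_identity(rng):
    u = _unit("ab", rng.normal(size=(2, 10)))
    w = warp_unit_duration(u, 10 / 60.0)
    np.testing.assert_allclose(w.values, u.values, atol=1e-12)


def test_warp_preserves_linear_ramps_and_endpoints():
    u = _unit("ab", np.linspace(0.0, 1.0, 6)[None, :])
    w = warp_unit_duration(u, 12 / 60.0)
    assert w.n_frames == 12
    np.testing.assert_allclose(w.values[0], np.linspace(0.0, 1.0, 12), atol=1e-12)
    assert w.values[0, 0] == u.values[0, 0]
    assert w.values[0, -1] == u.values[0, -1]


def test_warp_frame_count_arithmetic(rng):
    u = _unit("ab", rng.normal(size=(1, 10)))
    assert warp_unit_duration(u, 0.083).n_frames == 5  # round(0.083*60) = 5


# ---------------------------------------------------------------------------
# gapless concatenation
# ---------------------------------------------------------------------------

def test_ramp_matches_the_hand_computed_example():
    """Flat unit of 4 frames before a 0.4 step becomes [0.1 0.2 0.3 0.4]."""
    u1 = _unit("ab", np.zeros((1, 4)), utt="u1")
    u2 = _unit("bc", np.full((1, 3), 0.4), utt="u2")
    adjusted = gapless_adjust([u1, u2])
    np.testing.assert_allclose(adjusted[0][0], [0.1, 0.2, 0.3, 0.4], atol=1e-12)
    np.testing.assert_allclose(adjusted[1], u2.values)


def test_zero_gap_concatenation_is_plain(rng):
    vals = rng.normal(size=(2, 6))
    u1 = _unit("ab", vals, utt="u", start=0)
    u2 = _unit("bc", rng.normal(size=(2, 5)), utt="u", start=6)  # contiguous
    traj = gapless_concatenate([u1, u2])
    np.testing.assert_array_equal(
        traj.values, np.hstack([u1.values, u2.values])
    )


def _random_units(rng, n_units):
    units = []
    start = 0
    for i in range(n_units):
        T = int(rng.integers(3, 9))
        contiguous = i > 0 and rng.random() < 0.3
        utt = units[-1].source_utterance if contiguous else f"u{i}"
        s = units[-1].source_end if contiguous else start
        units.append(
            _unit(f"d{i}", rng.normal(size=(2, T)), utt=utt, start=s)
        )
        start += 20
    return units


@settings(derandomize=True, max_examples=100, deadline=None)
@given(seed=st.integers(0, 10_000), n_units=st.integers(2, 6))
def test_boundaries_close_and_curvature_survives(seed, n_units):
    """After processing every ramped boundary closes to 1e-9 and the
    within-unit second differences are untouched."""
    rng = np.random.default_rng(seed)
    units = _random_units(rng, n_units)
    adjusted = gapless_adjust(units)
    for j in range(n_units - 1):
        if not units[j].is_contiguous_with(units[j + 1]):
            gap = np.abs(adjusted[j][:, -1] - adjusted[j + 1][:, 0])
            assert gap.max() < 1e-9
    for orig, adj in zip(units, adjusted):
        if orig.n_frames >= 3:
            np.testing.assert_allclose(
                np.diff(adj, 2, axis=1),
                np.diff(orig.values, 2, axis=1),
                atol=1e-9,
            )


def test_concatenation_drops_the_duplicated_boundary_sample(rng):
    u1 = _unit("ab", rng.normal(size=(1, 4)), utt="a")
    u2 = _unit("bc", rng.normal(size=(1, 5)), utt="b")
    traj = gapless_concatenate([u1, u2])
    assert traj.n_frames == 8  # 4 + 5 - 1 duplicated boundary frame
    # the boundary value appears exactly once
    assert traj.values[0, 3] == pytest.approx(u2.values[0, 0], abs=1e-9)


# ---------------------------------------------------------------------------
# full synthesis
# ---------------------------------------------------------------------------

def test_self_resynthesis_reproduces_the_source_trajectory(small_corpus):
    """A sentence synthesized from its own units returns its trajectory."""
    from artspeech.diphones import build_dictionary

    sent = small_corpus.sentences[0]
    truth = sent.truth_trajectory
    d = build_dictionary([(sent.segmentation, truth)])
    phones = list(zip(sent.segmentation.labels, sent.segmentation.durations))
    traj, rep = synthesize_trajectories(phones, d)
    mids = sent.segmentation.midpoints
    f0 = int(np.floor(mids[0] * 60 + 1e-9))
    f1 = int(np.floor(mids[-1] * 60 + 1e-9))
    assert traj.n_frames == f1 - f0
    rmse = np.sqrt(np.mean((traj.values - truth.values[:, f0:f1]) ** 2))
    assert rmse < 1e-6
    assert rep.total_cost == 0.0


def test_cross_sentence_synthesis_is_continuous_and_bounded(small_corpus):
    from artspeech.diphones import build_dictionary

    d = build_dictionary(
        [(s.segmentation, s.truth_trajectory) for s in small_corpus.sentences]
    )
    phones = [("_", 0.2), ("a", 0.15), ("t", 0.12), ("i", 0.15), ("_", 0.2)]
    with pytest.warns(UserWarning):
        traj, rep = synthesize_trajectories(phones, d)
    assert np.all(np.abs(traj.values) <= 3.0)
    mids_span = 0.2 / 2 + 0.15 + 0.12 + 0.15 + 0.2 / 2
    assert abs(traj.n_frames - mids_span * 60) <= 1.0


def test_empty_phone_list_is_an_error(small_corpus):
    from artspeech.diphones import build_dictionary

    sent = small_corpus.sentences[0]
    d = build_dictionary([(sent.segmentation, sent.truth_trajectory)])
    with pytest.raises(ValueError):
        synthesize_trajectories([], d)
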