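"""Resampling, synchronization, rigid-motion and pruning contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from artspeech import preprocess
from artspeech.types import RigidMotionSeries, SensorFrameSeries


def _series(positions, rate, mask=None, names=None):
    positions = np.asarray(positions, dtype=float)
    f, s, _ = positions.shape
    return SensorFrameSeries(
        sensor_names=names or [f"s{i}" for i in range(s)],
        times=np.arange(f) / rate,
        positions=positions,
        rate=rate,
        mask=mask,
    )


def _sine_amplitude(x, times, freq):
    """Least-squares sinusoid amplitude at a known frequency."""
    c = np.cos(2 * np.pi * freq * times)
    s = np.sin(2 * np.pi * freq * times)
    A = np.column_stack([c, s, np.ones_like(times)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(np.hypot(coef[0], coef[1]))


# ---------------------------------------------------------------------------
# resample_lowpass
# ---------------------------------------------------------------------------

def test_resample_preserves_constant_signal_exactly():
    pos = np.tile([[1.0, -2.0, 3.0]], (400, 1))[:, None, :]
    out = preprocess.resample_lowpass(_series(pos, 100.0), 60.0, 20.0)
    assert out.rate == 60.0
    np.testing.assert_allclose(
        out.positions - pos[0, 0][None, None, :], 0.0, atol=1e-9
    )


@pytest.mark.parametrize(
    "freq, lo, hi",
    [
        (5.0, 0.98, 1.02),   # passband: amplitude within 2 %
        (35.0, 0.0, 0.05),   # stopband: amplitude below 5 %
    ],
)
def test_resample_passband_and_stopband(freq, lo, hi):
    t = np.arange(600) / 100.0
    pos = np.zeros((600, 1, 3))
    pos[:, 0, 0] = 10.0 * np.sin(2 * np.pi * freq * t)
    out = preprocess.resample_lowpass(_series(pos, 100.0), 60.0, 20.0)
    mid = (out.times > 1.0) & (out.times < 5.0)
    if freq < 30.0:
        amp = _sine_amplitude(out.positions[mid, 0, 0], out.times[mid], freq)
    else:
        amp = float(np.sqrt(2.0) * out.positions[mid, 0, 0].std())
    assert lo * 10.0 <= amp <= hi * 10.0


def test_resample_rejects_short_series():
    pos = np.zeros((10, 1, 3))
    with pytest.raises(ValueError, match="need >"):
        preprocess.resample_lowpass(_series(pos, 100.0), 60.0, 20.0)


def test_resample_masks_long_gaps_but_fills_short_ones():
    pos = np.zeros((400, 1, 3))
    pos[:, 0, 0] = np.linspace(0, 10, 400)
    mask = np.ones((400, 1), dtype=bool)
    mask[100:103, 0] = False          # 30 ms gap: filled
    mask[200:230, 0] = False          # 290 ms gap: stays masked
    out = preprocess.resample_lowpass(_series(pos, 100.0, mask=mask), 60.0, 20.0)
    t_short = np.abs(out.times - 1.01) < 0.005
    assert out.mask[t_short, 0].all()
    t_long = (out.times > 2.05) & (out.times < 2.2)
    assert not out.mask[t_long, 0].any()


# ---------------------------------------------------------------------------
# synchronize
# ---------------------------------------------------------------------------

def test_synchronize_passes_on_grid_samples_and_interpolates_ramps():
    # EMA at 100 Hz: a linear ramp; mocap at 60 Hz: constants
    t100 = np.arange(100) / 100.0
    ema_pos = np.zeros((100, 1, 3))
    ema_pos[:, 0, 0] = 7.0 * t100
    ema = _series(ema_pos, 100.0, names=["TT"])
    mocap = _series(np.ones((60, 2, 3)), 60.0, names=["a", "b"])
    merged = preprocess.synchronize(ema, mocap)
    assert merged.sensor_names == ["a", "b", "TT"]
    # exact on-grid sample: t = 0.5 exists on both clocks
    i = np.argmin(np.abs(merged.times - 0.5))
    assert merged.positions[i, 2, 0] == pytest.approx(3.5, abs=1e-12)
    # linear signal is interpolated exactly everywhere in range
    np.testing.assert_allclose(
        merged.positions[:, 2, 0], 7.0 * merged.times, atol=1e-9
    )


def test_synchronize_rejects_disjoint_ranges():
    ema = _series(np.zeros((50, 1, 3)), 100.0, names=["TT"])
    mocap = SensorFrameSeries(
        sensor_names=["a"],
        times=10.0 + np.arange(30) / 60.0,
        positions=np.zeros((30, 1, 3)),
        rate=60.0,
    )
    with pytest.raises(ValueError, match="overlap"):
        preprocess.synchronize(ema, mocap)


# ---------------------------------------------------------------------------
# rigid motion
# ---------------------------------------------------------------------------

HEAD_SHAPE = np.array(
    [[0.0, 90.0, 60.0], [-60.0, 80.0, 30.0], [60.0, 80.0, 30.0], [0.0, 100.0, -20.0]]
)


def _full_translation(rigid: RigidMotionSeries) -> np.ndarray:
    """Centre-independent translation t = tau - (R - I) c of each frame."""
    R = preprocess.euler_zyx_to_matrix(rigid.rotations)
    return rigid.translations - np.einsum("fij,j->fi", R - np.eye(3), rigid.center)


def _random_rigid(rng, n, rate=60.0, zero_first=True):
    trans = rng.uniform(-8, 8, size=(n, 3))
    rots = rng.uniform(-12, 12, size=(n, 3))
    if zero_first:
        trans[0] = 0.0
        rots[0] = 0.0
    return RigidMotionSeries(
        times=np.arange(n) / rate,
        translations=trans,
        rotations=rots,
        center=rng.uniform(-50, 50, size=3),
        rate=rate,
    )


def test_identity_motion_estimates_to_zero():
    base = _series(np.tile(HEAD_SHAPE, (20, 1, 1)), 60.0)
    rigid = preprocess.estimate_rigid_motion(base, base.sensor_names)
    np.testing.assert_allclose(_full_translation(rigid), 0.0, atol=1e-9)
    np.testing.assert_allclose(rigid.rotations, 0.0, atol=1e-9)


def test_known_rotation_and_translation_recovered():
    """10 deg about z plus a (5, 0, 0) mm shift comes back within 1e-6."""
    n = 10
    rigid_true = RigidMotionSeries(
        times=np.arange(n) / 60.0,
        translations=np.vstack([np.zeros(3), *[[5.0, 0.0, 0.0]] * (n - 1)]),
        rotations=np.vstack([np.zeros(3), *[[0.0, 0.0, 10.0]] * (n - 1)]),
        center=np.array([0.0, -120.0, -30.0]),
        rate=60.0,
    )
    base = _series(np.tile(HEAD_SHAPE, (n, 1, 1)), 60.0)
    moved = preprocess.apply_rigid_motion(base, rigid_true)
    est = preprocess.estimate_rigid_motion(moved, base.sensor_names)
    np.testing.assert_allclose(est.rotations, rigid_true.rotations, atol=1e-6)
    np.testing.assert_allclose(
        _full_translation(est), _full_translation(rigid_true), atol=1e-6
    )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10_000))
def test_remove_after_apply_is_identity(seed):
    rng = np.random.default_rng(seed)
    base = _series(np.tile(HEAD_SHAPE, (12, 1, 1)), 60.0)
    rigid = _random_rigid(rng, 12, zero_first=False)
    restored = preprocess.remove_rigid_motion(
        preprocess.apply_rigid_motion(base, rigid), rigid
    )
    np.testing.assert_allclose(restored.positions, base.positions, atol=1e-9)


def test_apply_then_estimate_recovers_the_transform(rng):
    """Each frame's full rigid transform is recovered within 1e-6 mm/deg."""
    base = _series(np.tile(HEAD_SHAPE, (30, 1, 1)), 60.0)
    rigid = _random_rigid(rng, 30)
    moved = preprocess.apply_rigid_motion(base, rigid)
    est = preprocess.estimate_rigid_motion(moved, base.sensor_names)
    np.testing.assert_allclose(est.rotations, rigid.rotations, atol=1e-6)
    np.testing.assert_allclose(
        _full_translation(est), _full_translation(rigid), atol=1e-6
    )


def test_headset_static_after_correction(small_corpus):
    """Removing the estimated motion leaves rigid sensors still (noise 0)."""
    sent = small_corpus.sentences[0]
    rigid_names = [s for s in sent.mocap.sensor_names if s.startswith("headset")]
    est = preprocess.estimate_rigid_motion(sent.mocap, rigid_names)
    corrected = preprocess.remove_rigid_motion(sent.mocap, est)
    headset = corrected.select(rigid_names)
    spread = headset.positions.std(axis=0)
    assert spread.max() < 1e-6


def test_planted_sinusoidal_motion_recovered(small_corpus):
    sent = small_corpus.sentences[0]
    rigid_names = [s for s in sent.mocap.sensor_names if s.startswith("headset")]
    est = preprocess.estimate_rigid_motion(sent.mocap, rigid_names)
    np.testing.assert_allclose(
        est.rotations, sent.rigid_motion.rotations, atol=1e-6
    )
    np.testing.assert_allclose(
        _full_translation(est), _full_translation(sent.rigid_motion), atol=1e-6
    )


def test_occluded_frames_are_flagged_and_interpolated(rng):
    base = _series(np.tile(HEAD_SHAPE, (20, 1, 1)), 60.0)
    rigid = _random_rigid(rng, 20)
    moved = preprocess.apply_rigid_motion(base, rigid)
    moved.mask[7, :2] = False  # only 2 visible rigid sensors in frame 7
    est = preprocess.estimate_rigid_motion(moved, base.sensor_names)
    assert est.flagged[7] and not est.flagged[6]
    assert np.isfinite(est.translations[7]).all()


# ---------------------------------------------------------------------------
# head motion model
# ---------------------------------------------------------------------------

def _rigid_from_vectors(V, rate=60.0):
    return RigidMotionSeries(
        times=np.arange(V.shape[0]) / rate,
        translations=V[:, :3],
        rotations=V[:, 3:],
        center=np.zeros(3),
        rate=rate,
    )


def test_tx_only_motion_explains_everything_in_one_component():
    V = np.zeros((50, 6))
    V[:, 0] = np.sin(np.linspace(0, 6, 50))
    with pytest.warns(UserWarning, match="rank deficient"):
        model = preprocess.fit_head_motion_model(
            _rigid_from_vectors(V), HEAD_SHAPE, [f"h{i}" for i in range(4)]
        )
    assert model.explained[0] == pytest.approx(1.0)


def test_two_dominant_components_explain_over_90_percent(rng):
    t = np.arange(600) / 60.0
    V = rng.normal(0, 0.05, size=(600, 6))
    V[:, 0] += 5.0 * np.sin(2 * np.pi * 0.2 * t)
    V[:, 4] += 4.0 * np.sin(2 * np.pi * 0.3 * t + 1.0)
    model = preprocess.fit_head_motion_model(
        _rigid_from_vectors(V), HEAD_SHAPE, [f"h{i}" for i in range(4)]
    )
    assert model.explained[:2].sum() > 0.90


def test_constant_motion_is_a_zero_variance_error():
    V = np.ones((20, 6))
    with pytest.raises(ValueError, match="zero variance"):
        preprocess.fit_head_motion_model(
            _rigid_from_vectors(V), HEAD_SHAPE, [f"h{i}" for i in range(4)]
        )


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def test_identical_frames_prune_to_one():
    X = np.tile(np.arange(6.0), (40, 1))
    q = preprocess.prune_frames(X, 1.0)
    assert q.n_frames == 1
    assert q.kept_indices[0] == 0


def test_two_clusters_prune_to_two(rng):
    a = rng.normal(0, 0.03, size=(30, 6))
    b = rng.normal(0, 0.03, size=(30, 6)) + np.array([5.0, 0, 0, 0, 0, 0])
    X = np.vstack([a, b])
    q = preprocess.prune_frames(X, 1.0)
    assert q.n_frames == 2


def test_zero_min_dist_keeps_everything(rng):
    X = rng.normal(size=(25, 9))
    q = preprocess.prune_frames(X, 0.0)
    assert q.n_frames == 25
    np.testing.assert_array_equal(q.frames, X)


def test_kept_frames_respect_the_distance_floor(rng):
    X = rng.normal(scale=0.8, size=(300, 6))
    q = preprocess.prune_frames(X, 1.0)
    from scipy.spatial.distance import pdist

    assert q.n_frames < 300
    assert pdist(q.frames).min() >= 1.0
    # pruning output is a subset of the input, in original order
    assert np.all(np.diff(q.kept_indices) > 0)


def test_frames_with_missing_sensors_are_excluded(small_corpus):
    sent = small_corpus.sentences[0].mocap.copy()
    sent.mask[5, 0] = False
    q = preprocess.prune_frames(sent, min_dist=0.0)
    assert 5 not in q.kept_indices
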