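"""Ground-truth articulatory models and simulated multimodal corpora.

Downstream stages (synchronization, head-motion correction, guided PCA,
inversion, diphone synthesis) are all tested against corpora generated here
with a *known* articulatory model, known parameter trajectories and known
rigid head motion, mimicking the structure of a real recording session:
EMA coils at 100 Hz, motion-capture markers at 60 Hz on a shared clock,
slow rigid head motion superimposed on articulation, i.i.d. sensor noise,
occasional missing samples, and per-sentence phone segmentations.

Planted variance profile
------------------------
Each articulatory parameter ``k`` receives a whole-face loading vector
``w_k`` whose squared norm is ``fraction_k`` of a chosen global variance,
with unit-variance scores.  Loadings are mutually orthogonal and each one
is confined to (or dominated by) its designated landmark subset, with the
within-subset drivers of parameters extracted later from the same subset
made strictly weaker, so the guided-PCA extraction recovers the planted
loadings exactly in the population limit.  The part of the global variance
not assigned to any parameter is realized as white noise confined to the
orthogonal complement of the planted loadings: its restricted covariance in
any landmark subset is bounded by a single scalar, which keeps every
subset's first principal direction attached to the planted driver.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats
from .artmodel import DEFAULT_SCHEME, ExtractionScheme
from .types import (
    ArticulatoryModel,
    EMA_RIGID_SENSORS,
    FACE_MODEL_SENSORS,
    HEADSET_SENSORS,
    PhoneSegmentation,
    RigidMotionSeries,
    SensorFrameSeries,
    SILENCE_LABEL,
    TONGUE_SENSORS,
    TrajectoryMatrix,
)

__all__ = [
    "DEFAULT_VARIANCE_PROFILE",
    "DEFAULT_FACE_LAYOUT",
    "NECK_CENTER",
    "GroundTruthSpec",
    "GroundTruthModel",
    "SimulatedSentence",
    "SimulatedCorpus",
    "make_ground_truth_model",
    "ground_truth_variance_fractions",
    "sample_frames",
    "phone_target",
    "simulate_sentence",
    "simulate_corpus",
]

#: per-parameter share of global variance (fractions, not percent)
DEFAULT_VARIANCE_PROFILE: list[tuple[str, float]] = [
    ("jaw1", 0.1340),
    ("tongue1", 0.1317),
    ("tongue2", 0.0483),
    ("tongue3", 0.0513),
    ("tongue4", 0.0569),
    ("lips1", 0.1006),
    ("lips2", 0.0093),
    ("lips3", 0.0266),
    ("jaw2", 0.0204),
    ("eyebrows1", 0.0423),
]

#: plausible resting sensor geometry in the head frame (mm); x right, y up,
#: z anterior, origin roughly between the ears
DEFAULT_FACE_LAYOUT: dict[str, tuple[float, float, float]] = {
    "jaw_left": (-25.0, -45.0, 80.0),
    "jaw_right": (25.0, -45.0, 80.0),
    "chin": (0.0, -60.0, 85.0),
    "lip_upper_mid": (0.0, -20.0, 100.0),
    "lip_upper_left": (-15.0, -22.0, 95.0),
    "lip_upper_right": (15.0, -22.0, 95.0),
    "lip_lower_mid": (0.0, -35.0, 100.0),
    "lip_lower_left": (-15.0, -33.0, 95.0),
    "lip_lower_right": (15.0, -33.0, 95.0),
    "lip_corner_left": (-25.0, -28.0, 88.0),
    "lip_corner_right": (25.0, -28.0, 88.0),
    "brow_left_in": (-15.0, 40.0, 95.0),
    "brow_left_mid": (-30.0, 42.0, 88.0),
    "brow_left_out": (-45.0, 40.0, 78.0),
    "brow_right_in": (15.0, 40.0, 95.0),
    "brow_right_mid": (30.0, 42.0, 88.0),
    "brow_right_out": (45.0, 40.0, 78.0),
    "headset_1": (0.0, 90.0, 60.0),
    "headset_2": (-60.0, 80.0, 30.0),
    "headset_3": (60.0, 80.0, 30.0),
    "headset_4": (0.0, 100.0, -20.0),
    "nasion": (0.0, 25.0, 100.0),
    "tragus_left": (-70.0, 0.0, 0.0),
    "tragus_right": (70.0, 0.0, 0.0),
    "TT": (0.0, -30.0, 60.0),
    "TB": (0.0, -25.0, 30.0),
    "TD": (0.0, -20.0, 5.0),
}

#: fixed neck point the rigid head motion rotates about (head frame, mm)
NECK_CENTER = np.array([0.0, -120.0, -30.0])

MOCAP_SENSORS = FACE_MODEL_SENSORS[:17] + HEADSET_SENSORS  # jaw+lips+brows+headset
EMA_SENSORS = TONGUE_SENSORS + EMA_RIGID_SENSORS

_SAMPA_INVENTORY = [
    "p", "b", "t", "d", "k", "g", "m", "n", "N", "f", "v", "s", "z",
    "S", "Z", "l", "r", "w", "j", "h", "i", "e", "a", "o", "u", "@", "E", "I",
]


@dataclass
class GroundTruthSpec:
    """Study conditions for the simulated corpus.

    Defaults mirror a single-speaker multimodal session: 10 s recordings,
    sub-millimetre EMA/mocap noise, a few millimetres / degrees of slow head
    motion, and the ten-parameter variance profile of the articulatory
    model.
    """

    variance_profile: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_VARIANCE_PROFILE)
    )
    noise_sd: float = 0.2               # mm, i.i.d. per sensor coordinate
    head_motion_amplitude: tuple[float, float] = (5.0, 3.0)  # mm, degrees
    missing_rate: float = 0.01          # probability per sensor-frame
    seed: int = 0
    total_variance: float = 100.0       # mm^2, global variance scale
    session_duration: float = 10.0      # s per sentence recording
    ema_rate: float = 100.0
    mocap_rate: float = 60.0

    def __post_init__(self) -> None:
        fracs = np.array([f for _, f in self.variance_profile], dtype=float)
        if fracs.size == 0 or np.any(fracs <= 0):
            raise ValueError("variance fractions must be positive")
        if fracs.sum() > 1.0 + 1e-12:
            raise ValueError("variance fractions must sum to at most 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.total_variance <= 0 or self.session_duration <= 0:
            raise ValueError("total_variance and session_duration must be positive")


@dataclass
class GroundTruthModel:
    """A planted articulatory model plus the unmodelled-variance description.

    ``model`` carries the parameter loadings; the residual (global variance
    not attributed to any parameter) is white noise of variance
    ``nuisance_scale`` per dimension confined to the orthogonal complement
    of ``planted_basis``.
    """

    model: ArticulatoryModel
    planted_basis: np.ndarray    # (D, P) orthonormal: drivers + spill directions
    nuisance_scale: float        # variance per complement dimension
    spec: GroundTruthSpec

    @property
    def n_params(self) -> int:
        return self.model.n_params


def _subset_coords(sensor_names: list[str], sensors: tuple[str, ...]) -> np.ndarray:
    base = np.array([sensor_names.index(s) for s in sensors])
    return (3 * base[:, None] + np.arange(3)[None, :]).ravel()


def make_ground_truth_model(
    spec: GroundTruthSpec,
    scheme: ExtractionScheme = DEFAULT_SCHEME,
    sensor_names: list[str] | None = None,
    mean: np.ndarray | None = None,
) -> GroundTruthModel:
    """Construct the planted articulatory model for ``spec``.

    The loading of each parameter carries exactly its profile fraction of
    the global variance (under unit-variance scores); loadings are mutually
    orthogonal, and within every landmark subset the driver of the earliest
    extraction step strictly dominates later ones so the extraction order is
    well defined.
    """
    names = [n for n, _ in spec.variance_profile]
    steps_by_name = dict(scheme.steps)
    missing = [n for n in names if n not in steps_by_name]
    if missing:
        raise ValueError(f"profile parameters missing from scheme: {missing}")
    steps = [(n, steps_by_name[n]) for n in names]
    if sensor_names is None:
        sensor_names = list(FACE_MODEL_SENSORS)
    d = 3 * len(sensor_names)
    m = len(steps)
    V = spec.total_variance
    fracs = np.array([f for _, f in spec.variance_profile])
    rng = np.random.default_rng([spec.seed, 0x6D6F6465])

    if mean is None:
        if all(s in DEFAULT_FACE_LAYOUT for s in sensor_names):
            mean = np.array(
                [DEFAULT_FACE_LAYOUT[s] for s in sensor_names], dtype=float
            ).ravel()
        else:
            mean = np.zeros(d)
    else:
        mean = np.asarray(mean, dtype=float).ravel()

    # within-subset drivers, mutually orthogonal in the full space
    drivers = np.zeros((d, m))
    subset_dirs: list[np.ndarray] = []
    subset_idx: list[np.ndarray] = []
    for k, (name, sensors) in enumerate(steps):
        idx = _subset_coords(sensor_names, sensors)
        subset_idx.append(idx)
        u = rng.standard_normal(idx.size)
        for j in range(k):
            r = drivers[idx, j]
            nr = r @ r
            if nr > 1e-12:
                u -= (u @ r) / nr * r
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            raise ValueError(f"could not build an independent driver for {name!r}")
        u /= norm
        if u[np.argmax(np.abs(u))] < 0:
            u = -u
        subset_dirs.append(u)
        drivers[idx, k] = u

    # within-subset power: full by default, capped below any earlier step
    # whose subset overlaps so the extraction order is strictly dominant
    b2 = fracs * V
    for k in range(m):
        for j in range(k):
            if np.intersect1d(subset_idx[j], subset_idx[k]).size:
                b2[k] = min(b2[k], 0.75 * b2[j])
    c2 = fracs * V - b2

    # spill directions for capped parameters, orthogonal to everything planted
    basis_cols = [drivers[:, k] for k in range(m)]
    loadings = np.zeros((d, m))
    for k in range(m):
        w = np.sqrt(b2[k]) * drivers[:, k]
        if c2[k] > 1e-12 * V:
            r = rng.standard_normal(d)
            for bvec in basis_cols:
                r -= (r @ bvec) * bvec
            r /= np.linalg.norm(r)
            basis_cols.append(r)
            w = w + np.sqrt(c2[k]) * r
        loadings[:, k] = w

    basis = np.column_stack(basis_cols)
    leftover = 1.0 - fracs.sum()
    n_free = d - basis.shape[1]
    nuisance_scale = leftover * V / n_free if leftover > 1e-12 else 0.0

    model = ArticulatoryModel(
        parameter_names=names,
        sensor_names=sensor_names,
        mean=mean,
        loadings=loadings,
        variance_fractions=fracs * 100.0,
        subset_directions=subset_dirs,
        scheme_steps=steps,
    )
    return GroundTruthModel(
        model=model, planted_basis=basis, nuisance_scale=nuisance_scale, spec=spec
    )


def ground_truth_variance_fractions(gt: GroundTruthModel) -> np.ndarray:
    """Planted fractions recomputed from the loadings by direct accounting.

    Under unit-variance scores the variance carried by parameter ``k`` is
    ``||w_k||^2`` and the unattributed remainder is ``nuisance_scale`` per
    complement dimension; the result is in percent of global variance.
    """
    w2 = np.sum(gt.model.loadings**2, axis=0)
    d = gt.model.loadings.shape[0]
    total = w2.sum() + gt.nuisance_scale * (d - gt.planted_basis.shape[1])
    return w2 / total * 100.0


def sample_frames(
    gt: GroundTruthModel,
    n_frames: int,
    rng: np.random.Generator,
    score_mode: str = "iid",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw head-frame sensor frames from the planted model.

    ``score_mode="iid"`` uses independent standard-normal scores;
    ``"orthonormal"`` orthonormalizes the score matrix so sample variances
    and correlations are exact (useful for exact-recovery checks).  Returns
    ``(frames, scores)`` with frames stacked (n, 3*S).
    """
    m = gt.n_params
    Z = rng.standard_normal((n_frames, m))
    if score_mode == "orthonormal":
        if n_frames <= m:
            raise ValueError("need more frames than parameters for exact scores")
        Z = Z - Z.mean(axis=0)
        Q, _ = np.linalg.qr(Z)
        Z = Q * np.sqrt(n_frames)
    elif score_mode != "iid":
        raise ValueError(f"unknown score_mode {score_mode!r}")
    X = gt.model.mean + Z @ gt.model.loadings.T
    if gt.nuisance_scale > 0:
        G = rng.standard_normal((n_frames, gt.model.loadings.shape[0]))
        G -= (G @ gt.planted_basis) @ gt.planted_basis.T
        X = X + np.sqrt(gt.nuisance_scale) * G
    return X, Z


# ---------------------------------------------------------------------------
# sentence simulation
# ---------------------------------------------------------------------------

def phone_target(label: str, n_params: int, seed: int) -> np.ndarray:
    """Seeded codebook posture for a SAMPA label, in [-2, 2] per parameter.

    Silence maps to the neutral posture (all zeros).  The mapping is a
    deterministic function of (seed, label) only.
    """
    if label == SILENCE_LABEL:
        return np.zeros(n_params)
    rng = np.random.default_rng([seed, zlib.crc32(label.encode())])
    return rng.uniform(-2.0, 2.0, size=n_params)


def _trajectory_function(
    seg: PhoneSegmentation, targets: np.ndarray
) -> "callable":
    """Analytic per-phone posture trajectory with cosine transitions.

    Piecewise constant at each phone's target with a raised-cosine blend of
    length ``min(80 ms, adjacent phone durations)`` centred on every phone
    boundary; smooth, nonlinear in time, and evaluable on any clock.
    """
    ends = seg.end_times
    durs = seg.durations
    bounds = ends[:-1]
    ramps = np.minimum(0.08, np.minimum(durs[:-1], durs[1:]))

    def evaluate(times: np.ndarray) -> np.ndarray:
        t = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(ends, t, side="right"), 0, len(seg) - 1)
        alpha = targets[idx].T.copy()  # (M, T)
        for i, (tb, L) in enumerate(zip(bounds, ramps)):
            if L <= 0:
                continue
            lo, hi = tb - L / 2.0, tb + L / 2.0
            sel = (t >= lo) & (t < hi)
            if not np.any(sel):
                continue
            phase = (t[sel] - lo) / L
            blend = 0.5 * (1.0 - np.cos(np.pi * phase))
            a, b = targets[i][:, None], targets[i + 1][:, None]
            alpha[:, sel] = a + (b - a) * blend
        return alpha

    return evaluate


@dataclass
class SimulatedSentence:
    utterance_id: str
    segmentation: PhoneSegmentation
    ema: SensorFrameSeries             # 100 Hz
    mocap: SensorFrameSeries           # 60 Hz
    truth_trajectory: TrajectoryMatrix  # 60 Hz, in [-3, 3]
    rigid_motion: RigidMotionSeries    # 60 Hz, planted head motion


@dataclass
class SimulatedCorpus:
    sentences: list[SimulatedSentence]
    truth: GroundTruthModel
    manifest: dict | None = None

    def total_mocap_frames(self) -> int:
        return sum(s.mocap.n_frames for s in self.sentences)


def simulate_sentence(
    gt: GroundTruthModel,
    phones: list[tuple[str, float]],
    spec: GroundTruthSpec | None = None,
    utterance_id: str = "utt",
    rng: np.random.Generator | None = None,
) -> SimulatedSentence:
    """Simulate one sentence recording from phone (label, duration) pairs.

    True parameter trajectories interpolate per-phone codebook postures with
    cosine transitions; a slow sinusoidal rigid head motion about the neck
    point is composed on top; the EMA stream is sampled at 100 Hz and the
    mocap stream at 60 Hz on the shared clock; Gaussian noise of
    ``spec.noise_sd`` mm and Bernoulli missing samples are applied last.
    """
    spec = spec or (gt.spec if gt.spec is not None else GroundTruthSpec())
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if not phones:
        raise ValueError("phone list is empty")
    labels = [p for p, _ in phones]
    durations = np.array([d for _, d in phones], dtype=float)
    if np.any(durations <= 0):
        raise ValueError("phone durations must be positive")
    m = gt.n_params
    targets = np.stack([phone_target(lbl, m, spec.seed) for lbl in labels])
    seg = PhoneSegmentation(
        utterance_id=utterance_id, labels=labels, end_times=np.cumsum(durations)
    )
    traj_fn = _trajectory_function(seg, targets)
    total = float(seg.end_times[-1])

    # planted rigid motion, shared by both streams through a common clock
    t60 = np.arange(int(round(total * spec.mocap_rate))) / spec.mocap_rate
    t100 = np.arange(int(round(total * spec.ema_rate))) / spec.ema_rate
    motion_rng = np.random.default_rng(
        [spec.seed, zlib.crc32(utterance_id.encode()), 1]
    )
    # draw sinusoid parameters once, then evaluate on both clocks
    amp_t, amp_r = spec.head_motion_amplitude
    sin_par = [
        (amp_t * motion_rng.uniform(0.4, 1.0), motion_rng.uniform(0.1, 0.35))
        for _ in range(3)
    ] + [
        (amp_r * motion_rng.uniform(0.4, 1.0), motion_rng.uniform(0.1, 0.35))
        for _ in range(3)
    ]

    def rigid_at(times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = [
            a * np.sin(2 * np.pi * f * times) for a, f in sin_par
        ]
        arr = np.stack(cols, axis=1)
        return arr[:, :3], arr[:, 3:]

    noise_rng = np.random.default_rng(
        [spec.seed, zlib.crc32(utterance_id.encode()), 2]
    )

    def build_stream(
        times: np.ndarray, sensor_names: tuple[str, ...], rate: float
    ) -> SensorFrameSeries:
        F, S = times.size, len(sensor_names)
        pos = np.zeros((F, S, 3))
        # articulated sensors come from the model projection, rigid sensors
        # from the static layout
        alpha = traj_fn(times)  # (M, F)
        face = gt.model.project_positions(alpha.T)  # (F, 20, 3)
        face_index = {s: i for i, s in enumerate(gt.model.sensor_names)}
        for si, name in enumerate(sensor_names):
            if name in face_index:
                pos[:, si, :] = face[:, face_index[name], :]
            else:
                pos[:, si, :] = np.array(DEFAULT_FACE_LAYOUT[name])
        trans, rots = rigid_at(times)
        from .preprocess import euler_zyx_to_matrix  # local import, no cycle

        R = euler_zyx_to_matrix(rots)
        pos = (
            np.einsum("fij,fsj->fsi", R, pos - NECK_CENTER)
            + NECK_CENTER
            + trans[:, None, :]
        )
        if spec.noise_sd > 0:
            pos = pos + noise_rng.normal(0.0, spec.noise_sd, size=pos.shape)
        mask = np.ones((F, S), dtype=bool)
        if spec.missing_rate > 0:
            mask = noise_rng.random((F, S)) >= spec.missing_rate
        return SensorFrameSeries(
            sensor_names=list(sensor_names),
            times=times,
            positions=pos,
            rate=rate,
            mask=mask,
        )

    ema = build_stream(t100, EMA_SENSORS, spec.ema_rate)
    mocap = build_stream(t60, MOCAP_SENSORS, spec.mocap_rate)
    alpha60 = np.clip(traj_fn(t60), -3.0, 3.0)
    trans60, rots60 = rigid_at(t60)
    rigid = RigidMotionSeries(
        times=t60,
        translations=trans60,
        rotations=rots60,
        center=NECK_CENTER.copy(),
        rate=spec.mocap_rate,
    )
    return SimulatedSentence(
        utterance_id=utterance_id,
        segmentation=seg,
        ema=ema,
        mocap=mocap,
        truth_trajectory=TrajectoryMatrix(
            parameter_names=list(gt.model.parameter_names),
            rate=spec.mocap_rate,
            values=alpha60,
        ),
        rigid_motion=rigid,
    )


def _random_phone_list(
    spec: GroundTruthSpec, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """Silence-padded random phone sequence filling the session exactly."""
    total = spec.session_duration
    lead = round(rng.uniform(0.25, 0.4), 3)
    tail_min = 0.25
    phones: list[tuple[str, float]] = [(SILENCE_LABEL, lead)]
    used = lead
    while used < total - tail_min - 0.18:
        lbl = _SAMPA_INVENTORY[rng.integers(len(_SAMPA_INVENTORY))]
        dur = round(rng.uniform(0.06, 0.18), 3)
        phones.append((lbl, dur))
        used += dur
    phones.append((SILENCE_LABEL, round(total - used, 9)))
    return phones


def simulate_corpus(
    gt: GroundTruthModel,
    n_sentences: int,
    spec: GroundTruthSpec | None = None,
    out_dir=None,
) -> SimulatedCorpus:
    """Simulate a corpus of ``n_sentences`` fixed-length recording sessions.

    With ``out_dir`` set, writes per-sentence ``.lab`` segmentations,
    EMA/mocap sensor CSVs, true trajectory CSVs and a ``manifest.json``.
    Fully deterministic for a fixed ``spec.seed``.
    """
    if n_sentences < 1:
        raise ValueError("n_sentences must be at least 1")
    spec = spec or gt.spec
    rng = np.random.default_rng([spec.seed, 0x636F7270])
    sentences = []
    manifest_entries = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    for i in range(n_sentences):
        utt = f"utt{i:04d}"
        phones = _random_phone_list(spec, rng)
        sent = simulate_sentence(gt, phones, spec, utterance_id=utt)
        sentences.append(sent)
        if out_path is not None:
            entry = {
                "utterance_id": utt,
                "lab": f"{utt}.lab",
                "ema": f"{utt}_ema.csv",
                "mocap": f"{utt}_mocap.csv",
                "truth": f"{utt}_truth.csv",
            }
            io_formats.write_segmentation(sent.segmentation, out_path / entry["lab"])
            io_formats.write_sensor_series(sent.ema, out_path / entry["ema"])
            io_formats.write_sensor_series(sent.mocap, out_path / entry["mocap"])
            io_formats.write_trajectory(sent.truth_trajectory, out_path / entry["truth"])
            manifest_entries.append(entry)
    manifest = None
    if out_path is not None:
        io_formats.save_model(gt.model, out_path / "truth_model.json")
        manifest = {
            "n_sentences": n_sentences,
            "seed": spec.seed,
            "model": "truth_model.json",
            "sentences": manifest_entries,
        }
        (out_path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return SimulatedCorpus(sentences=sentences, truth=gt, manifest=manifest)
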