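# Methods

This note documents the models, algorithms and numerical choices behind
`artspeech`, and what the synthetic-data experiments do and do not show.

## Data model and units

A recording is a set of named sensors with 3-D positions in millimetres at
a uniform rate on a shared clock: EMA coils (tongue tip/body/dorsum plus
nasion and two tragus references) at 100 Hz and motion-capture markers
(3 jaw, 8 lip, 6 eyebrow, 4 headset) at 60 Hz.  Missing samples are carried
in an explicit boolean mask, never as NaN.  Rotations are intrinsic z-y-x
Euler angles in degrees (`R = Rz Ry Rx`); a head-frame point `p` maps to the
world as `R (p - c) + c + t` with `c` a single centre of rotation for the
whole recording.  Articulatory scores are in standard-deviation units, so
the inversion box `[-3, 3]` means ±3 SD for every parameter.

## Preprocessing

**Resampling.**  The EMA stream is low-pass filtered with a 6th-order
Butterworth at 20 Hz applied forward-backward (zero phase; effective
attenuation is squared, ≈ 42 dB at 30 Hz), then linearly interpolated onto
the 60 Hz mocap clock.  Masked gaps are bridged linearly before filtering;
gaps longer than 100 ms remain masked and are excluded from model fitting.

**Head motion.**  Per frame, the visible rigid sensors are fitted onto
their reference-frame configuration by the unweighted Kabsch algorithm
(proper rotation enforced).  The centre of rotation is the point `c`
minimizing `Σ_f || t_f + (R_f − I) c ||²`, a linear least-squares problem.
Note that when independent translations are present the (c, translation)
decomposition is not unique — any centre yields a valid decomposition with
compensated translations — so recovery tests compare the *full* per-frame
transform (rotation plus centre-independent translation `t = τ − (R−I)c`),
which is identifiable.  Frames with fewer than three visible, non-collinear
rigid sensors are flagged and interpolated from neighbours.  A PCA of the
6-dof motion vectors (loadings scaled by score SD) provides the bounded
head-pose inversion model.

**Pruning.**  Greedy first-come vector quantization in time order: a frame
is kept iff its stacked-coordinate Euclidean distance to *every* previously
kept frame is ≥ 1.0 mm.  Comparing against all kept frames (not only the
previous one) makes the kept set a packing with a guaranteed minimum
separation; greedy scanning keeps the result deterministic and order-stable.
The implementation blocks the scan so the distance computations run as
large matrix products.

## Guided PCA

Plain PCA mixes articulators, so the model is built by iterative subset
extraction.  For each step k with landmark subset S_k:

1. `u_k` = first right singular vector of the residual restricted to S_k
   (sign fixed so the largest-magnitude coordinate is positive);
2. scores standardized to unit variance (population convention, 1/n);
3. whole-face loading `v_k` = regression of every residual coordinate on
   the standardized score (equals the covariance with it);
4. the rank-one contribution is subtracted; the variance removed, divided
   by the total variance of the centred data, is the parameter's share of
   global variance.

Because each loading is removed by regression, the final residual is
orthogonal to every score (checked to 1e-9).  With a single whole-face
step the procedure reduces exactly to the classical first principal
component (`v = sqrt(λ) u`), which is used as an independent oracle in the
tests.  The extraction order follows the parameter list (jaw first — the
tongue rides on the jaw — then tongue, lips, jaw rotation, eyebrows); the
order is configurable through `ExtractionScheme`.  `variance_report`
replays the stored subset directions on new data, so fractions can be
recomputed on held-out frames.

## Inversion

The face objective is convex bound-constrained linear least squares.  A
tiny ridge (1e-12) breaks ties toward the smallest-norm solution; whenever
the regularized normal-equations optimum already lies in the box it is
accepted directly, otherwise the problem goes to a BVLS solver.  Batch
inversion solves all fully-visible frames in one factorization and falls
back per frame only where bounds activate or sensors are missing.  The
head objective is nonlinear through the rotation and is solved by bounded
trust-region least squares from `alpha = 0` (the motion model is built
around the observed mean pose, so the optimum is near the origin and the
problem is benign).  Frames are inverted independently — temporal structure
enters only through the explicit smoothing step, a zero-phase 6th-order
Butterworth at 8 Hz.  Zero-phase filtering was chosen because causal
filtering would lag articulation relative to the audio.  Values pushed out
of the box by the filter are clipped back rather than re-optimized; the
excursions are tiny (the filter is a contraction in the passband) and
clipping keeps the step idempotent.

## Synthetic ground truth

The generator's defaults define the study conditions: 10 s sessions,
EMA at 100 Hz / mocap at 60 Hz on a shared clock, sensor noise
SD 0.2 mm, 1 % missing samples, head motion of a few millimetres /
degrees, and the ten-parameter variance profile (jaw1 13.40 %, tongue1
13.17 %, tongue2 4.83 %, tongue3 5.13 %, tongue4 5.69 %, lips1 10.06 %,
lips2 0.93 %, lips3 2.66 %, jaw2 2.04 %, eyebrows1 4.23 % — 62.14 % of
global variance in total).

**Planted model.**  Each parameter receives a whole-face loading whose
squared norm equals its profile fraction of a global variance scale
(100 mm², giving realistic millimetre-scale facial motion).  Loadings are
mutually orthogonal; each one is dominated by a within-subset driver
direction, with drivers of parameters sharing a subset kept orthogonal and
— where the profile would invert the extraction order (tongue-tip vertical
before the slightly larger horizontal) — the later parameter's
within-subset power is capped at 75 % of the earlier one's, the excess
routed to an orthogonal spill direction.  The 37.86 % of variance not
assigned to any parameter is white noise confined to the orthogonal
complement of the planted directions, with *equal* variance per complement
dimension: its restricted covariance in any landmark subset is then
bounded by that single per-dimension scalar (smaller than the weakest
planted driver), so every subset's first principal direction stays
attached to its planted driver.  Under these conditions the guided-PCA
extraction recovers loadings and fractions exactly in the population
limit, and `sample_frames(..., score_mode="orthonormal")` makes the
recovery exact at finite n for oracle tests.

**Trajectories.**  Each SAMPA label maps to a seeded codebook posture in
[-2, 2] per parameter (silence is neutral); a sentence's true trajectory
holds each posture and blends across boundaries with a raised-cosine ramp
of length min(80 ms, adjacent phone durations).  The blend is evaluated
*analytically* at both 100 Hz and 60 Hz, so the two streams sample exactly
the same continuous-time truth; a discrete low-pass at one rate could not
be replicated at the other.  Head motion is composed on top as slow
(0.1–0.35 Hz) sinusoidal translations/rotations about a fixed neck point,
zero at t = 0 so the first frame is the canonical pose.

**What this does not show.**  The simulated corpus is linear in its
parameters (by construction recoverable), has stationary noise, no
coarticulation beyond the cosine blend, no sensor drift or calibration
error, and a phone-to-posture mapping with no phonetic realism.  Passing
the planted-truth tests therefore demonstrates the correctness of the
*machinery* (synchronization, rigid correction, extraction, bounded
inversion, unit selection, gap removal), not the adequacy of a linear
articulatory model for real speakers.  Residual magnitudes reported on
real recordings depend on the speaker and rig and are not reproduced here.

## Diphones and synthesis

Diphone boundaries sit at phone temporal midpoints (the steadiest part of
a phone); frame mapping is `floor(time × rate)` with half-open slices, so
a sentence's own units tile its trajectory exactly.  Unit selection is
Viterbi dynamic programming with boundary cost = RMS parameter gap at the
junction, zero for units contiguous in their source sentence; ties break
toward the lowest candidate index.  An optional per-unit duration-mismatch
term (`w_sel · |log(unit/target)|`, default 0) is available.  Missing
diphones degrade gracefully: first any unit sharing the second phone, else
a two-frame linear bridge, both with logged warnings.

Duration warping linearly rescales the time axis (endpoints preserved).
Gap removal adds `Δ · i/T` (i = 1..T) inside the preceding unit, processed
right-to-left so every ramp targets the already-adjusted first frame of
the following unit; the duplicated boundary sample is dropped at assembly.
The ramp is linear in the frame index, so within-unit second differences —
the nonlinear shape of the articulation — are unchanged.  In the full
pipeline, per-unit frame counts come from the floored midpoint times and
units before a ramped boundary are warped one frame long, so the output
length is exactly the frame count of the midpoint span and resynthesizing
a sentence from its own units is bit-faithful.

## Avatar retargeting

Face key frames are extreme poses with no physical negative counterpart,
so their activations are one-sided (0..+3): the displacement field from
the neutral mesh is divided by its RMS per-vertex magnitude.  No
jaw-rotation parameter is produced (no such key frame exists in the source
animation).  Tongue retargeting fits, for each quantized EMA posture, the
bounded (±10) linear mixture of the nine tongue key frames minimizing the
misfit at the three sensor-associated mesh vertices — the correspondence
is explicit configuration — and the resulting mesh database, joined with
the jaw and tongue sensor coordinates, is fed through the same guided PCA
with the five-step scheme (jaw1, tongue1..tongue4), matching the speaker
model's parameter subset so speaker trajectories can drive the avatar
directly after per-parameter sign alignment (an involution, applied from
an explicit table).

## Sizes and tolerances used in the test experiments

Planted-recovery experiments use 20,000 i.i.d.-score frames (recovered
global-variance shares match the planted profile to ≲0.15 pp; the tests
assert 0.5 pp), corpus-level checks use 3–4 sentences of 3 s, and oracle
suites use exhaustive enumeration (active-set search up to 3 parameters,
trellis paths up to 5 × 4).  Round-trip identities are asserted at 1e-9
(rigid motion, gap closure) or 1e-12 (serialization); forward-model
inversions at 1e-6.
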