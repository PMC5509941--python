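"""Synthetic stimulus, brain, and session generation with planted ground truth.

Everything the analysis pipeline consumes can be generated here: symbolic
melodies with genre structure, polyphonic chromagrams, a labeled brain whose
regions linearly encode chosen feature kinds, HRF-convolved voxel time
series, and a behavioral genre-confusion matrix. All generators are
deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import HRFParams, condition_regressor
from .music_features import (
    MAJOR_SCALE,
    MINOR_SCALE,
    FeatureMatrix,
    MelodyEvent,
    MelodyTranscription,
    resample_to_frames,
    transcription_to_grid,
)

__all__ = [
    "GENRES",
    "StimulusSpec",
    "default_stimuli",
    "GroundTruthBrain",
    "RegionEncoding",
    "default_brain",
    "SyntheticSession",
    "generate_melody",
    "synthesize_chromagram",
    "generate_session",
    "generate_behavioral_confusions",
]

GENRES = ("Ambient", "Country", "Metal", "RocknRoll", "Symphonic")

#: Per-genre melody-generator parameters: note durations (16th-note slots)
#: and their probabilities, rest probability, random-walk steps (scale
#: degrees), and starting degree. These drive the within-genre statistical
#: similarity of generated melodies.
GENRE_MELODY_PARAMS = {
    "Ambient": dict(durations=(4, 8), dur_p=(0.5, 0.5), rest_p=0.30,
                    steps=(-1, 0, 1), start_degree=7),
    "Country": dict(durations=(2, 4), dur_p=(0.6, 0.4), rest_p=0.15,
                    steps=(-2, -1, 1, 2), start_degree=4),
    "Metal": dict(durations=(1, 2), dur_p=(0.7, 0.3), rest_p=0.05,
                  steps=(-3, -1, 1, 3), start_degree=2),
    "RocknRoll": dict(durations=(1, 2, 4), dur_p=(0.4, 0.4, 0.2), rest_p=0.10,
                      steps=(-2, -1, 1, 2), start_degree=5),
    "Symphonic": dict(durations=(2, 4, 8), dur_p=(0.4, 0.4, 0.2), rest_p=0.10,
                      steps=(-4, -1, 1, 4), start_degree=9),
}

# Keys of the default 25-stimulus set (5 per genre) and genre tempo ranges.
_DEFAULT_KEYS = {
    "Ambient": [(5, "major"), (0, "major"), (0, "major"), (0, "minor"), (11, "major")],
    "Country": [(0, "major"), (9, "major"), (2, "major"), (7, "major"), (2, "major")],
    "Metal": [(1, "major"), (6, "major"), (4, "major"), (7, "major"), (4, "minor")],
    "RocknRoll": [(3, "major"), (5, "major"), (5, "major"), (9, "major"), (4, "major")],
    "Symphonic": [(5, "major"), (10, "minor"), (2, "major"), (5, "major"), (5, "major")],
}
_DEFAULT_TEMPI = {
    "Ambient": (60, 70, 80, 60, 75),
    "Country": (100, 110, 90, 120, 105),
    "Metal": (140, 150, 160, 130, 145),
    "RocknRoll": (150, 140, 130, 160, 150),
    "Symphonic": (80, 100, 90, 110, 120),
}


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus: id, genre, key (tonic pitch class + mode), tempo, duration."""

    stimulus_id: str
    genre: str
    key: int = 0
    mode: str = "major"
    tempo: float = 120.0
    duration: float = 6.0

    def __post_init__(self) -> None:
        if self.genre not in GENRES:
            raise ValueError(f"unknown genre {self.genre!r}")
        if not 0 <= self.key <= 11:
            raise ValueError("key must be a pitch class in [0, 11]")
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def default_stimuli() -> list:
    """The default 25-stimulus set: 5 genres x 5 stimuli."""
    specs = []
    for genre in GENRES:
        for i in range(5):
            key, mode = _DEFAULT_KEYS[genre][i]
            specs.append(
                StimulusSpec(
                    stimulus_id=f"{genre}{i + 1:03d}",
                    genre=genre,
                    key=key,
                    mode=mode,
                    tempo=float(_DEFAULT_TEMPI[genre][i]),
                )
            )
    return specs


@dataclass
class RegionEncoding:
    """How one labeled region responds to stimuli.

    ``weights`` maps the reduced feature vector of ``feature_kind`` linearly
    to per-voxel response amplitudes; ``snr`` is (signal std)/(noise std)
    per voxel (``inf`` for noise-free).
    """

    feature_kind: str  # melody_abs | melody_rel | chroma | none
    weights: np.ndarray = None  # (region voxels, feature dims); None for 'none'
    snr: float = 1.0

    def __post_init__(self) -> None:
        if self.feature_kind not in ("melody_abs", "melody_rel", "chroma", "none"):
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if not np.isfinite(self.weights).all():
                raise ValueError("weights must be finite")


@dataclass
class GroundTruthBrain:
    shape: tuple
    affine: np.ndarray
    region_labels: np.ndarray  # integer volume, 0 = background
    region_encoding: dict  # region id -> RegionEncoding

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels)
        if self.region_labels.shape != tuple(self.shape):
            raise ValueError("region label volume does not match brain shape")
        labels = set(np.unique(self.region_labels)) - {0}
        if labels != set(self.region_encoding):
            raise ValueError("every labeled region needs a region_encoding entry")

    def region_voxels(self, region: int) -> np.ndarray:
        """Flat voxel indices (C order) of one region."""
        return np.flatnonzero(self.region_labels.reshape(-1) == region)


def default_brain(
    feature_dims: dict,
    shape=(24, 24, 24),
    snr: float = 1.0,
    weight_scale: float = 1.0,
    rng_seed: int = 0,
    slab_thickness: int = 2,
    kinds=("melody_abs", "melody_rel", "chroma"),
) -> GroundTruthBrain:
    """Three planted slab regions encoding melody_abs, melody_rel, chroma.

    ``feature_dims`` maps each feature kind to its reduced-vector length.
    Regions are ``slab_thickness``-thick z-slabs covering a third of the x/y
    plane, staggered in x, y, and z so that searchlight halos (sphere radius
    plus scatter fill) of different regions cannot form one connected
    suprathreshold component.
    """
    rng = np.random.default_rng(rng_seed)
    labels = np.zeros(shape, dtype=np.int16)
    nx, ny, nz = shape
    z_starts = [nz // 8, nz // 2 - slab_thickness // 2, 7 * nz // 8 - slab_thickness]
    xy = [
        (slice(nx // 6, nx // 2), slice(ny // 6, ny // 2)),
        (slice(nx // 2, 5 * nx // 6), slice(ny // 2, 5 * ny // 6)),
        (slice(nx // 6, nx // 2), slice(ny // 2, 5 * ny // 6)),
    ]
    encoding = {}
    for r, (z0, (xs, ys), kind) in enumerate(zip(z_starts, xy, kinds), start=1):
        labels[xs, ys, z0 : z0 + slab_thickness] = r
        n_vox = int((labels == r).sum())
        d = feature_dims[kind]
        encoding[r] = RegionEncoding(
            feature_kind=kind,
            weights=rng.standard_normal((n_vox, d)) * weight_scale,
            snr=snr,
        )
    return GroundTruthBrain(
        shape=tuple(shape),
        affine=np.diag([2.0, 2.0, 2.0, 1.0]),
        region_labels=labels,
        region_encoding=encoding,
    )


@dataclass
class SyntheticSession:
    """Simulated multi-run session: 4-D EPI per run plus event tables."""

    epi: np.ndarray  # (runs, T, X, Y, Z)
    events: list  # per-run DataFrame: onset, duration, stimulus_id, genre
    n_runs: int = 8
    volumes_per_run: int = 153
    tr: float = 2.0
    subject_id: str = ""


# ---------------------------------------------------------------------------
# Melody generation
# ---------------------------------------------------------------------------

def generate_melody(spec: StimulusSpec, rng_seed: int) -> MelodyTranscription:
    """Random monophonic melody on a 16th-note grid spanning the stimulus.

    Pitch classes follow a bounded random walk on the scale degrees of
    ``spec.key`` over two octaves; genre sets note-duration and rest
    statistics plus walk step sizes (see :data:`GENRE_MELODY_PARAMS`).
    """
    rng = np.random.default_rng(rng_seed)
    params = GENRE_MELODY_PARAMS[spec.genre]
    scale = MAJOR_SCALE if spec.mode == "major" else MINOR_SCALE
    slot_seconds = 60.0 / spec.tempo / 4.0
    n_slots = int(round(spec.duration / slot_seconds))
    degrees = np.arange(2 * len(scale))  # two octaves of scale degrees

    events = []
    cursor = 0
    degree = params["start_degree"]
    while cursor < n_slots:
        duration = int(rng.choice(params["durations"], p=params["dur_p"]))
        duration = min(duration, n_slots - cursor)
        if rng.random() < params["rest_p"]:
            cursor += duration
            continue
        degree = int(np.clip(degree + rng.choice(params["steps"]), 0, degrees[-1]))
        pc = (scale[degree % len(scale)] + spec.key) % 12
        events.append(MelodyEvent(pitch_class=pc, onset=cursor, duration=duration))
        cursor += duration
    return MelodyTranscription(
        events=events,
        key=spec.key,
        mode=spec.mode,
        tempo=spec.tempo,
        n_slots=n_slots,
    )


# ---------------------------------------------------------------------------
# Chromagram synthesis
# ---------------------------------------------------------------------------

def synthesize_chromagram(
    melody: MelodyTranscription,
    spec: StimulusSpec,
    rng_seed: int,
    chord_level: float = 0.5,
    bass_level: float = 0.3,
    noise_level: float = 0.05,
    envelope_depth: float = 0.3,
    ramp_seconds: float = 0.05,
    rms_target: float = 1.0,
) -> FeatureMatrix:
    """Polyphonic pitch-class-energy matrix emulating an audio chromagram.

    Sum of the melody indicator, triad chord and bass-note energy following
    a I-IV-V progression in ``spec.key``, a multiplicative low-frequency
    amplitude envelope, and additive nonnegative noise. A quarter-sine
    onset/offset ramp of ``ramp_seconds`` is applied, and (if ``rms_target``
    is set) the matrix is rescaled so its RMS entry value matches the target
    exactly -- mirroring RMS-balanced stimulus clips.
    """
    if not melody.events:
        raise ValueError("melody must be nonempty")
    rng = np.random.default_rng(rng_seed)
    mel = resample_to_frames(
        transcription_to_grid(melody), melody.tempo, spec.duration, kind="melody_abs"
    ).values
    n_frames = mel.shape[0]
    out = mel.copy()

    if chord_level > 0 or bass_level > 0:
        scale = MAJOR_SCALE if spec.mode == "major" else MINOR_SCALE
        third = scale[2]  # major/minor third above the chord root
        beat_frames = max(1, int(round((60.0 / spec.tempo) / 0.1)))
        bar_frames = 4 * beat_frames
        roots = rng.choice([0, 5, 7], size=n_frames // bar_frames + 1)
        for t in range(n_frames):
            root = (int(roots[t // bar_frames]) + melody.key) % 12
            for interval, level in ((0, chord_level), (third, chord_level),
                                    (7, chord_level)):
                out[t, (root + interval) % 12] += level
            out[t, root] += bass_level

    if envelope_depth > 0:
        t = np.arange(n_frames) * 0.1
        freq = rng.uniform(0.2, 0.7)
        phase = rng.uniform(0, 2 * np.pi)
        env = 1.0 + envelope_depth * np.sin(2 * np.pi * freq * t + phase)
        out *= env[:, None]

    if noise_level > 0:
        out += noise_level * rng.random((n_frames, 12))

    if ramp_seconds > 0:
        out *= _ramp_gains(n_frames, frame=0.1, ramp=ramp_seconds)[:, None]

    if rms_target is not None:
        rms = np.sqrt(np.mean(out**2))
        if rms > 0:
            out *= rms_target / rms
    return FeatureMatrix(values=out, kind="chroma", stimulus_id=spec.stimulus_id)


def _ramp_gains(n_frames: int, frame: float, ramp: float) -> np.ndarray:
    """Per-frame gain of a quarter-sine onset/offset amplitude ramp."""
    fine = 100
    t = (np.arange(n_frames * fine) + 0.5) * (frame / fine)
    total = n_frames * frame
    gain = np.ones_like(t)
    rising = t < ramp
    gain[rising] = np.sin(0.5 * np.pi * t[rising] / ramp)
    falling = t > total - ramp
    gain[falling] = np.sin(0.5 * np.pi * (total - t[falling]) / ramp)
    return gain.reshape(n_frames, fine).mean(axis=1)


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------

def _draw_run_events(stimuli, rng, volumes: int, tr: float) -> pd.DataFrame:
    """One run's event table: every stimulus once, gaps drawn from {4, 6, 8} s."""
    run_seconds = volumes * tr
    durations = np.array([s.duration for s in stimuli])
    for _ in range(1000):
        order = rng.permutation(len(stimuli))
        gaps = rng.choice([4.0, 6.0, 8.0], size=len(stimuli))
        onsets = np.empty(len(stimuli))
        t = gaps[0]
        for i, j in enumerate(order):
            onsets[i] = t
            t += durations[j] + (gaps[i + 1] if i + 1 < len(stimuli) else 0.0)
        if t <= run_seconds:
            return pd.DataFrame(
                {
                    "onset": onsets,
                    "duration": durations[order],
                    "stimulus_id": [stimuli[j].stimulus_id for j in order],
                    "genre": [stimuli[j].genre for j in order],
                }
            )
    raise RuntimeError("could not fit all trials within the run")


def generate_session(
    brain: GroundTruthBrain,
    stimuli: list,
    features: dict,
    rng_seed: int,
    n_runs: int = 8,
    volumes_per_run: int = 153,
    tr: float = 2.0,
    background_noise: float = 1.0,
    hrf_params: HRFParams = HRFParams(),
    subject_id: str = "",
    dtype=np.float64,
) -> SyntheticSession:
    """Forward model: HRF-convolved event responses with planted weights.

    ``features`` maps feature kind -> {stimulus_id -> reduced vector}. Each
    in-region voxel's response amplitude to stimulus *s* is
    ``weights @ features[kind][s]``; its time series is the amplitude-scaled
    HRF regressor plus white Gaussian noise at the region's SNR (signal std /
    noise std; voxels with zero signal fall back to unit noise). Background
    voxels are pure noise.
    """
    rng = np.random.default_rng(rng_seed)
    shape = tuple(brain.shape)
    n_vox = int(np.prod(shape))
    stim_ids = [s.stimulus_id for s in stimuli]

    # (stimulus x voxel) response amplitudes
    amplitudes = np.zeros((len(stimuli), n_vox))
    snr_per_voxel = np.zeros(n_vox)  # 0 marks background / pure-noise voxels
    for region, enc in brain.region_encoding.items():
        vox = brain.region_voxels(region)
        if enc.feature_kind == "none" or enc.weights is None:
            continue
        kind_feats = features[enc.feature_kind]
        F = np.stack([np.asarray(kind_feats[sid], dtype=float) for sid in stim_ids])
        if F.shape[1] != enc.weights.shape[1]:
            raise ValueError(
                f"region {region}: weight columns ({enc.weights.shape[1]}) do not "
                f"match feature dimensionality ({F.shape[1]})"
            )
        amplitudes[:, vox] = F @ enc.weights.T
        snr_per_voxel[vox] = enc.snr

    events = [
        _draw_run_events(stimuli, rng, volumes_per_run, tr) for _ in range(n_runs)
    ]
    epi = np.empty((n_runs, volumes_per_run, n_vox), dtype=dtype)
    s1 = np.zeros(n_vox)
    s2 = np.zeros(n_vox)
    for r, ev in enumerate(events):
        C = np.column_stack(
            [
                condition_regressor(
                    ev.loc[ev["stimulus_id"] == sid, "onset"].to_numpy(),
                    float(ev.loc[ev["stimulus_id"] == sid, "duration"].iloc[0]),
                    volumes_per_run,
                    tr,
                    hrf_params,
                )
                for sid in stim_ids
            ]
        )
        clean = C @ amplitudes
        epi[r] = clean
        s1 += clean.sum(axis=0)
        s2 += (clean**2).sum(axis=0)

    n_t = n_runs * volumes_per_run
    signal_std = np.sqrt(np.maximum(s2 / n_t - (s1 / n_t) ** 2, 0.0))
    sigma = np.full(n_vox, background_noise)
    planted = snr_per_voxel > 0
    with np.errstate(divide="ignore"):
        sigma[planted] = np.where(
            signal_std[planted] > 0,
            signal_std[planted] / snr_per_voxel[planted],
            1.0,
        )
    sigma[planted & np.isinf(snr_per_voxel)] = 0.0

    sigma = sigma.astype(dtype)
    noise_dtype = np.float32 if dtype == np.float32 else np.float64
    for r in range(n_runs):
        epi[r] += sigma * rng.standard_normal(
            (volumes_per_run, n_vox), dtype=noise_dtype
        )
    epi = epi.reshape(n_runs, volumes_per_run, *shape)
    return SyntheticSession(
        epi=epi,
        events=events,
        n_runs=n_runs,
        volumes_per_run=volumes_per_run,
        tr=tr,
        subject_id=subject_id,
    )


# ---------------------------------------------------------------------------
# Behavioral confusions
# ---------------------------------------------------------------------------

def generate_behavioral_confusions(
    rng_seed: int,
    diagonal: float = 0.864,
    confusion_boosts: dict = None,
    base_weight: float = 1.0,
    noise: float = 0.1,
) -> pd.DataFrame:
    """Row-stochastic 5x5 genre-confusion matrix (true x assigned).

    ``diagonal`` is the probability mass on the correct genre. Off-diagonal
    mass is distributed proportionally to ``base_weight`` plus symmetric
    pair boosts (default: Ambient<->Symphonic strongest, then
    Country<->RocknRoll), with multiplicative seeded jitter.
    """
    if not 0.0 <= diagonal <= 1.0:
        raise ValueError("diagonal mass must be in [0, 1]")
    if confusion_boosts is None:
        confusion_boosts = {
            ("Ambient", "Symphonic"): 4.0,
            ("Country", "RocknRoll"): 2.5,
        }
    rng = np.random.default_rng(rng_seed)
    n = len(GENRES)
    mat = np.zeros((n, n))
    boosts = np.zeros((n, n))
    for (a, b), w in confusion_boosts.items():
        i, j = GENRES.index(a), GENRES.index(b)
        boosts[i, j] = boosts[j, i] = w
    for i in range(n):
        mat[i, i] = diagonal
        off = np.array(
            [0.0 if j == i else base_weight + boosts[i, j] for j in range(n)]
        )
        off = off * (1.0 + noise * rng.uniform(-1, 1, size=n))
        off = np.clip(off, 0.0, None)
        off[i] = 0.0
        if diagonal < 1.0:
            mat[i] += off / off.sum() * (1.0 - diagonal)
    return pd.DataFrame(mat, index=list(GENRES), columns=list(GENRES))


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def stimuli_to_json(stimuli: list) -> str:
    return json.dumps(
        [
            dict(
                stimulus_id=s.stimulus_id,
                genre=s.genre,
                key=s.key,
                mode=s.mode,
                tempo=s.tempo,
                duration=s.duration,
            )
            for s in stimuli
        ],
        indent=2,
    )


def stimuli_from_json(text: str) -> list:
    return [StimulusSpec(**d) for d in json.loads(text)]
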