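"""Stimulus feature construction.

Three per-stimulus representations are supported:

* ``melody_abs`` -- binary pitch-class indicator of the monophonic melody in
  the original key,
* ``melody_rel`` -- the same indicator transposed so the tonic maps to C,
* ``chroma`` -- continuous nonnegative pitch-class energies of the audio.

All three are sampled on a regular 0.1 s frame clock (60 rows for a 6 s
stimulus) over the 12 equal-temperament pitch classes, then reduced by a
truncated SVD fitted on training stimuli only and flattened frame-by-frame
into a single vector per stimulus.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PITCH_CLASS_NAMES",
    "MelodyEvent",
    "MelodyTranscription",
    "FeatureMatrix",
    "ReducedFeatureSet",
    "transcription_to_grid",
    "transpose_to_c",
    "resample_to_frames",
    "audio_to_chromagram",
    "fit_reduce",
    "parse_abc",
    "format_abc",
]

#: Column order of every feature matrix.
PITCH_CLASS_NAMES = ("C", "C#", "D", "D#", "E", "F", "F#", "G", "G#", "A", "A#", "B")

FRAME_SECONDS = 0.1
N_PITCH_CLASSES = 12

MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)
MINOR_SCALE = (0, 2, 3, 5, 7, 8, 10)


@dataclass(frozen=True)
class MelodyEvent:
    """One monophonic note: pitch class, onset and duration in 16th-note slots."""

    pitch_class: int
    onset: int
    duration: int

    def __post_init__(self) -> None:
        if not 0 <= self.pitch_class <= 11:
            raise ValueError(f"pitch_class must be in [0, 11], got {self.pitch_class}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.duration < 1:
            raise ValueError("duration must be >= 1")


@dataclass
class MelodyTranscription:
    """Symbolic monophonic melody on a tempo-invariant 16th-note grid.

    Parameters
    ----------
    events:
        Sorted or unsorted list of :class:`MelodyEvent`; intervals must not
        overlap (monophony).
    key:
        Tonic pitch class, 0 (C) .. 11 (B).
    mode:
        ``"major"`` or ``"minor"``; transposition ignores mode.
    tempo:
        Beats per minute, > 0.
    n_slots:
        Total number of 16th-note slots spanned by the stimulus.
    meter:
        Beats per bar (informational only).
    """

    events: list = field(default_factory=list)
    key: int = 0
    mode: str = "major"
    tempo: float = 120.0
    n_slots: int = 0
    meter: int = 4

    def __post_init__(self) -> None:
        if self.tempo <= 0:
            raise ValueError("tempo must be positive")
        if not 0 <= self.key <= 11:
            raise ValueError("key must be a pitch class in [0, 11]")
        if self.mode not in ("major", "minor"):
            raise ValueError("mode must be 'major' or 'minor'")
        self.validate_monophonic()

    def validate_monophonic(self) -> None:
        occupied = np.zeros(max(self.n_slots, self.max_extent()), dtype=bool)
        for ev in self.events:
            span = slice(ev.onset, ev.onset + ev.duration)
            if occupied[span].any():
                raise ValueError("overlapping events: transcription is not monophonic")
            occupied[span] = True

    def max_extent(self) -> int:
        return max((ev.onset + ev.duration for ev in self.events), default=0)

    @property
    def slot_seconds(self) -> float:
        """Duration of one 16th-note slot in seconds (quarter note = one beat)."""
        return 60.0 / self.tempo / 4.0


@dataclass
class FeatureMatrix:
    """Frames x 12 pitch-class matrix for one stimulus."""

    values: np.ndarray
    kind: str  # melody_abs | melody_rel | chroma
    stimulus_id: str = ""
    frame_seconds: float = FRAME_SECONDS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_PITCH_CLASSES:
            raise ValueError("feature matrix must be frames x 12")
        if self.kind not in ("melody_abs", "melody_rel", "chroma"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind.startswith("melody"):
            v = self.values
            if not np.isin(v, (0.0, 1.0)).all():
                raise ValueError("melody feature matrices must be binary")
            if not np.isin(v.sum(axis=1), (0.0, 1.0)).all():
                raise ValueError("melody rows must have sum 0 (rest) or 1 (one note)")
        elif (self.values < 0).any():
            raise ValueError("chroma features must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        header = ",".join(PITCH_CLASS_NAMES)
        np.savetxt(path, self.values, delimiter=",", header=header, comments="")

    @classmethod
    def from_csv(cls, path, kind: str, stimulus_id: str = "") -> "FeatureMatrix":
        values = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(values=values, kind=kind, stimulus_id=stimulus_id)


@dataclass
class ReducedFeatureSet:
    """SVD-reduced, temporally stacked feature vectors.

    ``basis`` is the 12 x k projection fitted on the pooled (mean-centered)
    frames of the training stimuli; ``vectors`` maps stimulus id to the
    length ``n_frames * k`` stacked projection.
    """

    basis: np.ndarray
    mean: np.ndarray
    variance_explained: float
    vectors: dict
    fitted_on: list
    kind: str

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def save(self, path) -> None:
        np.savez(
            path,
            basis=self.basis,
            mean=self.mean,
            variance_explained=self.variance_explained,
            ids=np.array(sorted(self.vectors), dtype=object),
            vectors=np.stack([self.vectors[i] for i in sorted(self.vectors)]),
            fitted_on=np.array(self.fitted_on, dtype=object),
            kind=self.kind,
        )

    @classmethod
    def load(cls, path) -> "ReducedFeatureSet":
        with np.load(path, allow_pickle=True) as z:
            ids = [str(i) for i in z["ids"]]
            return cls(
                basis=z["basis"],
                mean=z["mean"],
                variance_explained=float(z["variance_explained"]),
                vectors=dict(zip(ids, z["vectors"])),
                fitted_on=[str(i) for i in z["fitted_on"]],
                kind=str(z["kind"]),
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def transcription_to_grid(melody: MelodyTranscription) -> np.ndarray:
    """Binary (slots x 12) indicator: entry (s, p) is 1 iff pitch class *p*
    sounds during slot *s*. Rests are all-zero rows."""
    n_slots = max(melody.n_slots, melody.max_extent())
    grid = np.zeros((n_slots, N_PITCH_CLASSES), dtype=float)
    occupied = np.zeros(n_slots, dtype=bool)
    for ev in melody.events:
        span = slice(ev.onset, ev.onset + ev.duration)
        if occupied[span].any():
            raise ValueError("overlapping events")
        occupied[span] = True
        grid[span, ev.pitch_class] = 1.0
    return grid


def transpose_to_c(grid: np.ndarray, key: int) -> np.ndarray:
    """Rotate columns by ``-key`` (mod 12) so the tonic maps to column 0."""
    grid = np.asarray(grid)
    return np.roll(grid, -int(key) % 12, axis=1)


def resample_to_frames(
    grid: np.ndarray,
    tempo: float,
    duration: float,
    frame: float = FRAME_SECONDS,
    kind: str = "melody_abs",
    stimulus_id: str = "",
) -> FeatureMatrix:
    """Resample a 16th-note slot grid to the regular frame clock.

    Frame ``t`` (center time ``(t + 0.5) * frame``) takes the value of the
    slot active at that time; frames past the end of the grid are zero.
    """
    if tempo <= 0:
        raise ValueError("tempo must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    grid = np.asarray(grid, dtype=float)
    slot_seconds = 60.0 / tempo / 4.0
    n_frames = int(round(duration / frame))
    out = np.zeros((n_frames, N_PITCH_CLASSES), dtype=float)
    for t in range(n_frames):
        center = (t + 0.5) * frame
        slot = int(center / slot_seconds)
        if slot < grid.shape[0]:
            out[t] = grid[slot]
    return FeatureMatrix(values=out, kind=kind, stimulus_id=stimulus_id)


def audio_to_chromagram(
    audio: np.ndarray,
    sample_rate: float = 44100.0,
    frame: float = FRAME_SECONDS,
    n_fft: int = 8192,
    fmin: float = 27.5,
    stimulus_id: str = "",
) -> FeatureMatrix:
    """Pitch-class energy (chromagram) of a waveform on the 0.1 s frame clock.

    Per frame, a Hann-windowed magnitude spectrum is computed around the frame
    center and each spectral bin's energy is folded to its nearest
    equal-temperament pitch class (A4 = 440 Hz reference), accumulated across
    octaves. Stereo input is averaged to mono.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        audio = audio.mean(axis=1)
    if audio.ndim != 1 or audio.size == 0:
        raise ValueError("audio must be a nonempty 1-D or 2-D (samples x channels) array")
    hop = int(round(frame * sample_rate))
    n_frames = int(round(audio.size / sample_rate / frame))
    if n_frames < 1:
        raise ValueError("audio shorter than one frame")

    window = np.hanning(n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    valid = (freqs >= fmin) & (freqs <= sample_rate / 2.0)
    # fold each bin to the nearest equal-temperament pitch class
    pcs = np.full(freqs.size, -1, dtype=int)
    pcs[valid] = np.round(12.0 * np.log2(freqs[valid] / 440.0)).astype(int) % 12
    pcs = (pcs + 9) % 12  # a bin at 440 Hz is pitch class A (9)
    pcs[~valid] = -1

    out = np.zeros((n_frames, N_PITCH_CLASSES), dtype=float)
    half = n_fft // 2
    padded = np.pad(audio, (half, half + n_fft))
    for t in range(n_frames):
        center = int(round((t + 0.5) * hop))
        seg = padded[center : center + n_fft] * window
        power = np.abs(np.fft.rfft(seg)) ** 2
        for pc in range(N_PITCH_CLASSES):
            out[t, pc] = power[pcs == pc].sum()
    return FeatureMatrix(values=out, kind="chroma", stimulus_id=stimulus_id)


def fit_reduce(
    features: dict,
    train_ids: list,
    min_variance: float = 0.95,
) -> ReducedFeatureSet:
    """Fit a truncated SVD on training stimuli and project all stimuli.

    The decomposition is fitted on the pooled frame rows of the training
    stimuli only, mean-centered with the training mean. ``k`` is the smallest
    component count whose cumulative squared-singular-value fraction reaches
    ``min_variance``. Every stimulus (train and test) is projected frame-wise
    and stacked in temporal order into an ``n_frames * k`` vector.
    """
    if not train_ids:
        raise ValueError("train_ids must be nonempty")
    missing = [i for i in train_ids if i not in features]
    if missing:
        raise KeyError(f"training stimuli missing from feature set: {missing}")
    kinds = {features[i].kind for i in features}
    if len(kinds) != 1:
        raise ValueError(f"mixed feature kinds: {sorted(kinds)}")

    pooled = np.vstack([features[i].values for i in train_ids])
    mean = pooled.mean(axis=0)
    centered = pooled - mean
    if not centered.any():
        raise ValueError("degenerate all-zero (constant) training features")

    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, min_variance - 1e-12) + 1)
    basis = vt[:k].T.copy()
    # fix sign: largest-magnitude loading of each component is positive
    for j in range(k):
        col = basis[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            basis[:, j] = -col

    vectors = {
        sid: ((fm.values - mean) @ basis).reshape(-1)
        for sid, fm in features.items()
    }
    return ReducedFeatureSet(
        basis=basis,
        mean=mean,
        variance_explained=float(frac[k - 1]),
        vectors=vectors,
        fitted_on=list(train_ids),
        kind=kinds.pop(),
    )


# ---------------------------------------------------------------------------
# ABC-subset transcription I/O
# ---------------------------------------------------------------------------

_NOTE_RE = re.compile(r"(\^|_)?([A-Ga-gz])(\d*)")
_LETTER_PC = {"C": 0, "D": 2, "E": 4, "F": 5, "G": 7, "A": 9, "B": 11}
_PC_TOKEN = {0: "C", 1: "^C", 2: "D", 3: "^D", 4: "E", 5: "F",
             6: "^F", 7: "G", 8: "^G", 9: "A", 10: "^A", 11: "B"}
_KEY_RE = re.compile(r"^([A-G])(#|b|♯|♭)?(m|min|maj)?$")


def parse_key(text: str) -> tuple:
    """Parse a key token such as ``C``, ``F#``, ``Bbm`` into (pitch_class, mode)."""
    m = _KEY_RE.match(text.strip())
    if not m:
        raise ValueError(f"cannot parse key {text!r}")
    pc = _LETTER_PC[m.group(1)]
    if m.group(2) in ("#", "♯"):
        pc = (pc + 1) % 12
    elif m.group(2) in ("b", "♭"):
        pc = (pc - 1) % 12
    mode = "minor" if m.group(3) in ("m", "min") else "major"
    return pc, mode


def parse_abc(text: str) -> MelodyTranscription:
    """Parse the ABC subset used for melody transcriptions.

    Supported headers: ``K:`` key, ``Q:`` tempo (bpm), ``M:`` meter
    (beats/bar), ``L:`` default note length (must be 1/16). The body is a
    whitespace-separated token stream of notes (letter with optional ``^``/
    ``_`` accidental and an integer multiplier of 16th notes) and ``z`` rests.
    Octave information is discarded: features are pitch-class only.
    """
    key, mode, tempo, meter = 0, "major", 120.0, 4
    body_parts: list = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("%"):
            continue
        if len(line) > 1 and line[1] == ":" and line[0] in "KQMLXT":
            tag, value = line[0], line[2:].strip()
            if tag == "K":
                key, mode = parse_key(value)
            elif tag == "Q":
                tempo = float(value.split("=")[-1])
            elif tag == "M":
                meter = int(value.split("/")[0])
            elif tag == "L" and value not in ("1/16",):
                raise ValueError("only L:1/16 default note lengths are supported")
            continue
        body_parts.append(line)

    events: list = []
    cursor = 0
    body = " ".join(body_parts).replace("|", " ")
    for tok in body.split():
        m = _NOTE_RE.fullmatch(tok)
        if not m:
            raise ValueError(f"cannot parse note token {tok!r}")
        accidental, letter, mult = m.groups()
        duration = int(mult) if mult else 1
        if letter in ("z", "Z"):
            cursor += duration
            continue
        pc = _LETTER_PC[letter.upper()]
        if accidental == "^":
            pc = (pc + 1) % 12
        elif accidental == "_":
            pc = (pc - 1) % 12
        events.append(MelodyEvent(pitch_class=pc, onset=cursor, duration=duration))
        cursor += duration
    return MelodyTranscription(
        events=events, key=key, mode=mode, tempo=tempo, n_slots=cursor, meter=meter
    )


def format_abc(melody: MelodyTranscription) -> str:
    """Serialize a transcription to the ABC subset read by :func:`parse_abc`."""
    key_name = PITCH_CLASS_NAMES[melody.key].replace("#", "#")
    key_tok = key_name + ("m" if melody.mode == "minor" else "")
    lines = [
        f"K:{key_tok}",
        f"Q:1/4={melody.tempo:g}",
        f"M:{melody.meter}/4",
        "L:1/16",
    ]
    toks: list = []
    cursor = 0
    for ev in sorted(melody.events, key=lambda e: e.onset):
        if ev.onset > cursor:
            toks.append(f"z{ev.onset - cursor}")
        toks.append(f"{_PC_TOKEN[ev.pitch_class]}{ev.duration}")
        cursor = ev.onset + ev.duration
    if melody.n_slots > cursor:
        toks.append(f"z{melody.n_slots - cursor}")
    lines.append(" ".join(toks))
    return "\n".join(lines) + "\n"
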