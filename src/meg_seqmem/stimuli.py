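"""Melodic stimuli and their predictability.

Tone sequences are ordered lists of MIDI pitches. An "atonal" counterpart of a
tonal piece is produced by remapping each pitch class by one or two semitones
(applied uniformly across octaves), which preserves rhythm, contour and the
positional recurrence structure of the melody while destroying the tonal
center.

Predictability is quantified per tone by a bounded-order n-gram model with
additive smoothing: the information content of tone ``e_i`` given its context
is ``IC = log2(1 / p(e_i | context))`` (bits), and the entropy of a context is
the expected IC over the alphabet, ``H = sum_e p(e|ctx) * IC(e|ctx)``, bounded
by ``0 <= H <= log2(|A|)``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ToneSequence",
    "PitchMap",
    "NGramModel",
    "PredictabilityProfile",
    "PairedTResult",
    "FIG_PRESET_MAP",
    "make_atonal",
    "random_pitch_map",
    "train_ngram",
    "information_content",
    "entropy",
    "compare_predictability",
    "toy_corpus",
    "excerpts_from_piece",
    "save_sequences_json",
    "load_sequences_json",
]

ROLES = ("piece", "memorized_excerpt", "novel_excerpt")
PIECE_CLASSES = ("tonal", "atonal")


class MappingIncompleteError(KeyError):
    """A pitch class of the source sequence is missing from the pitch map."""


class InvalidMapError(ValueError):
    """A pitch-class displacement falls outside +/-1 or +/-2 semitones."""


@dataclass(frozen=True)
class ToneSequence:
    """An ordered melodic sequence of MIDI pitches (0-127)."""

    pitches: tuple[int, ...]
    tone_duration_ms: int = 250
    role: str = "piece"
    piece_class: str = "tonal"

    def __post_init__(self) -> None:
        object.__setattr__(self, "pitches", tuple(int(p) for p in self.pitches))
        if any(p < 0 or p > 127 for p in self.pitches):
            raise ValueError("MIDI pitches must lie in 0-127")
        if self.tone_duration_ms <= 0:
            raise ValueError("tone_duration_ms must be positive")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")
        if self.piece_class not in PIECE_CLASSES:
            raise ValueError(f"piece_class must be one of {PIECE_CLASSES}")
        if self.role.endswith("excerpt") and len(self.pitches) != 5:
            raise ValueError("excerpt sequences have exactly 5 pitches")

    def __len__(self) -> int:
        return len(self.pitches)

    @property
    def pitch_classes(self) -> set[int]:
        return {p % 12 for p in self.pitches}


@dataclass(frozen=True)
class PitchMap:
    """Pitch-class remapping with every displacement of 1 or 2 semitones.

    The mapping acts on pitch classes (0-11) and is applied uniformly to all
    octaves; displacement is measured on the circle of semitones, so e.g.
    11 -> 0 counts as +1.
    """

    mapping: Mapping[int, int]

    def __post_init__(self) -> None:
        clean = {int(k) % 12: int(v) % 12 for k, v in self.mapping.items()}
        object.__setattr__(self, "mapping", clean)
        for src, dst in clean.items():
            d = (dst - src) % 12
            if d > 6:
                d -= 12
            if abs(d) not in (1, 2):
                raise InvalidMapError(
                    f"pitch class {src} -> {dst} is a {d:+d}-semitone displacement; "
                    "only +/-1 and +/-2 are allowed"
                )
        if len(set(clean.values())) != len(clean):
            raise InvalidMapError("pitch map must be injective on its pitch classes")

    def __call__(self, pitch: int) -> int:
        pc = pitch % 12
        if pc not in self.mapping:
            raise MappingIncompleteError(
                f"pitch class {pc} (pitch {pitch}) not covered by the map"
            )
        dst = self.mapping[pc]
        d = (dst - pc) % 12
        if d > 6:
            d -= 12
        out = pitch + d
        if out < 0 or out > 127:  # fold at the MIDI range edge
            out = pitch - d
        return out

    def inverse(self) -> "PitchMap":
        return PitchMap({v: k for k, v in self.mapping.items()})


#: The three explicit assignments of the published example: C->C#, E->F#, G->F.
FIG_PRESET_MAP: dict[int, int] = {0: 1, 4: 6, 7: 5}


def random_pitch_map(pitch_classes: Iterable[int], rng: np.random.Generator) -> PitchMap:
    """Draw a valid injective +/-1-or-2-semitone map covering ``pitch_classes``.

    Uses rejection sampling over per-class displacement choices; the small
    search space (4 options per class) makes this fast for any realistic set.
    """
    classes = sorted({int(p) % 12 for p in pitch_classes})

    def _assign(i: int, mapping: dict[int, int]) -> dict[int, int] | None:
        if i == len(classes):
            return mapping
        c = classes[i]
        for d in rng.permutation([-2, -1, 1, 2]):
            dst = (c + int(d)) % 12
            if dst not in mapping.values():
                out = _assign(i + 1, {**mapping, c: dst})
                if out is not None:
                    return out
        return None

    mapping = _assign(0, {})
    if mapping is None:  # pragma: no cover — a uniform +1 shift always exists
        raise RuntimeError("could not find an injective pitch map")
    return PitchMap(mapping)


def make_atonal(seq: ToneSequence, pitch_map: PitchMap) -> ToneSequence:
    """Apply a uniform pitch-class remapping, flipping the piece class.

    Length, tone duration, role and the positional recurrence structure are
    preserved: positions holding equal pitches in the source hold equal
    pitches in the result.
    """
    mapped = tuple(pitch_map(p) for p in seq.pitches)
    return replace(seq, pitches=mapped, piece_class="atonal" if seq.piece_class == "tonal" else "tonal")


# ---------------------------------------------------------------------------
# n-gram predictability model


@dataclass
class NGramModel:
    """Bounded-order n-gram over a finite pitch alphabet with additive smoothing.

    ``p(e | ctx) = (count(ctx, e) + gamma) / (count(ctx) + gamma * |A|)``.
    Contexts shorter than ``order`` (at a sequence start) back off to the
    longest available context; the model stores counts for every context
    length up to ``order``.
    """

    order: int
    alphabet: tuple[int, ...]
    smoothing: float = 1.0
    counts: dict[tuple[int, ...], dict[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.smoothing <= 0:
            raise ValueError("smoothing gamma must be > 0")
        self.alphabet = tuple(sorted(set(int(a) for a in self.alphabet)))
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")

    def _observe(self, context: tuple[int, ...], event: int) -> None:
        self.counts.setdefault(context, {})
        self.counts[context][event] = self.counts[context].get(event, 0) + 1

    def context_for(self, history: Sequence[int]) -> tuple[int, ...]:
        """Truncate a history to the model order (longest available context)."""
        h = tuple(int(x) for x in history)
        return h[-self.order:] if self.order else ()

    def prob(self, event: int, history: Sequence[int] = ()) -> float:
        """Smoothed conditional probability of ``event`` given ``history``."""
        ctx = self.context_for(history)
        c = self.counts.get(ctx, {})
        total = sum(c.values())
        return (c.get(event, 0) + self.smoothing) / (total + self.smoothing * len(self.alphabet))

    def distribution(self, history: Sequence[int] = ()) -> np.ndarray:
        """Next-event probabilities over the alphabet (sums to 1)."""
        ctx = self.context_for(history)
        c = self.counts.get(ctx, {})
        total = sum(c.values())
        num = np.array([c.get(e, 0) + self.smoothing for e in self.alphabet], dtype=float)
        return num / (total + self.smoothing * len(self.alphabet))


def train_ngram(
    corpus: Sequence[ToneSequence | Sequence[int]],
    order: int = 2,
    smoothing: float = 1.0,
    alphabet: Iterable[int] | None = None,
) -> NGramModel:
    """Count n-gram statistics over a corpus of tone sequences.

    Every context length 0..order is counted so that truncated contexts at
    sequence starts back off to the longest context seen. Sequences shorter
    than ``order + 1`` contribute their available prefixes only.
    """
    if not corpus:
        raise ValueError("corpus must be non-empty")
    seqs = [tuple(s.pitches) if isinstance(s, ToneSequence) else tuple(int(p) for p in s) for s in corpus]
    if alphabet is None:
        alphabet = sorted(set(itertools.chain.from_iterable(seqs)))
    model = NGramModel(order=order, alphabet=tuple(alphabet), smoothing=smoothing)
    for seq in seqs:
        for i, event in enumerate(seq):
            for n in range(0, order + 1):
                if n <= i:
                    model._observe(seq[i - n:i], event)
    return model


@dataclass(frozen=True)
class PredictabilityProfile:
    """Per-tone information content and per-context entropy, both in bits."""

    ic: tuple[float, ...]
    h: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ic) != len(self.h):
            raise ValueError("ic and h must be aligned per tone")
        if any(x < -1e-12 for x in self.ic):
            raise ValueError("information content must be >= 0")


def information_content(model: NGramModel, seq: ToneSequence | Sequence[int]) -> list[float]:
    """Per-tone IC in bits: ``log2(1 / p(e_i | context_i))``, context truncated
    at the sequence start."""
    pitches = seq.pitches if isinstance(seq, ToneSequence) else tuple(int(p) for p in seq)
    if not pitches:
        raise ValueError("sequence must be non-empty")
    return [math.log2(1.0 / model.prob(e, pitches[:i])) for i, e in enumerate(pitches)]


def entropy(model: NGramModel, context: Sequence[int] = ()) -> float:
    """Entropy of the next-event distribution after ``context``, in bits.

    Expected information content over the alphabet; 0 for a deterministic
    continuation, ``log2(|A|)`` under uniformity. Contexts longer than the
    model order are truncated to the last ``order`` events.
    """
    p = model.distribution(context)
    return float(-(p * np.log2(p)).sum())


def profile(model: NGramModel, seq: ToneSequence | Sequence[int]) -> PredictabilityProfile:
    """IC and H for every tone position of a sequence."""
    pitches = seq.pitches if isinstance(seq, ToneSequence) else tuple(int(p) for p in seq)
    ic = information_content(model, pitches)
    h = [entropy(model, pitches[:i]) for i in range(len(pitches))]
    return PredictabilityProfile(ic=tuple(ic), h=tuple(h))


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def compare_predictability(a: Sequence[float], b: Sequence[float]) -> PairedTResult:
    """Paired t-test on aligned per-tone predictability values.

    Returns a degenerate-flagged result (rather than +/-inf) when the paired
    differences have zero variance.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must be aligned element-wise")
    n = x.size
    if n < 2:
        raise ValueError("need at least two paired observations")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedTResult(t=0.0, df=n - 1, p=1.0, degenerate=True)
        return PairedTResult(t=math.nan, df=n - 1, p=math.nan, degenerate=True)
    res = stats.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


# ---------------------------------------------------------------------------
# built-in toy corpus and excerpt machinery

MAJOR_SCALE = (0, 2, 4, 5, 7, 9, 11)


def toy_corpus(
    n_pieces: int = 20,
    length: int = 64,
    rng: np.random.Generator | int | None = 0,
    tonic: int = 60,
) -> list[ToneSequence]:
    """Diatonic random-walk corpus standing in for a Western training corpus.

    Each piece walks over two octaves of the major scale rooted at ``tonic``
    with small, step-biased moves, giving tonal-looking statistics for the
    n-gram model to learn.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    degrees = [tonic - 12 + off + 12 * octv for octv in range(2) for off in MAJOR_SCALE]
    degrees.append(tonic + 12)
    pieces = []
    steps = np.array([-3, -2, -1, 0, 1, 2, 3])
    w = np.array([0.05, 0.15, 0.25, 0.10, 0.25, 0.15, 0.05])
    for _ in range(n_pieces):
        idx = len(degrees) // 2
        pitches = []
        for _ in range(length):
            idx = int(np.clip(idx + rng.choice(steps, p=w), 0, len(degrees) - 1))
            pitches.append(degrees[idx])
        pieces.append(ToneSequence(tuple(pitches), role="piece", piece_class="tonal"))
    return pieces


def excerpts_from_piece(piece: ToneSequence, n_excerpts: int = 40, bar_length: int = 8,
                        role: str = "memorized_excerpt") -> list[ToneSequence]:
    """First five notes of each bar, as five-tone excerpts (250 ms per tone)."""
    out = []
    for b in range(n_excerpts):
        start = b * bar_length
        chunk = piece.pitches[start:start + 5]
        if len(chunk) < 5:
            break
        out.append(ToneSequence(chunk, tone_duration_ms=piece.tone_duration_ms,
                                role=role, piece_class=piece.piece_class))
    return out


def save_sequences_json(seqs: Sequence[ToneSequence], path: str | Path) -> None:
    payload = [
        {"pitches": list(s.pitches), "tone_duration_ms": s.tone_duration_ms,
         "role": s.role, "piece_class": s.piece_class}
        for s in seqs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_sequences_json(path: str | Path) -> list[ToneSequence]:
    payload = json.loads(Path(path).read_text())
    return [ToneSequence(tuple(d["pitches"]), d.get("tone_duration_ms", 250),
                         d.get("role", "piece"), d.get("piece_class", "tonal"))
            for d in payload]
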