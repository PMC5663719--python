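"""Song models, imitation tasks, and semitone arithmetic.

A *song model* is an ordered motif of syllables played back to a juvenile
zebra finch.  In a serial-tutoring experiment the bird first learns a
*source* model and is then switched to a *target* model that differs in the
pitch of one or two harmonic syllables (by 1-2 semitones) and/or in syllable
order.  The five imitation tasks built by :func:`task_library` are the
standard mismatch geometries used throughout this package:

    task 1    A B C      -> A C+ B           (one pitch shift + permutation)
    task 2    A B C      -> A+ C+ B          (two pitch shifts + permutation)
    task 3    A B C      -> A B- C B+        (two equidistant targets, one in
                                              context, one out of context)
    task 4.1  A B C B+1  -> A B+2 C B-1      (close target in wrong context,
    task 4.2  A B+2 C B-1 -> A B C B+1        far target in right context)
    task 5    A B        -> A B+ A B-        (two equidistant targets, no
                                              sequential bias)

Pitch-variant labels use ASCII superscripts: ``C+``, ``B-``, ``B+2``, ``B-1``.
All pitches are expressed in semitones relative to a per-model reference
frequency (the source syllable's fundamental by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = [
    "SyllableSpec",
    "SongModel",
    "ImitationTask",
    "semitone_offset",
    "apply_shift",
    "task_library",
    "target_bigrams",
]

#: default fundamental of the reference harmonic syllable, Hz (zebra-finch band)
DEFAULT_REFERENCE_FREQ = 600.0


def semitone_offset(f: float, f_ref: float) -> float:
    """Offset of frequency ``f`` from ``f_ref`` in semitones (12*log2(f/f_ref))."""
    if f <= 0 or f_ref <= 0:
        raise ValueError(f"frequencies must be positive, got f={f}, f_ref={f_ref}")
    return 12.0 * math.log2(f / f_ref)


def apply_shift(f: float, s: float) -> float:
    """Shift frequency ``f`` by ``s`` semitones (inverse of :func:`semitone_offset`)."""
    if f <= 0:
        raise ValueError(f"frequency must be positive, got {f}")
    return f * 2.0 ** (s / 12.0)


@dataclass(frozen=True)
class SyllableSpec:
    """One syllable of a song model.

    ``base_pitch`` is in semitones relative to the model's reference
    frequency and is required for harmonic syllables (and calls), absent
    for non-harmonic ones.
    """

    label: str
    kind: str = "harmonic"  # harmonic | nonharmonic | call
    base_pitch: Optional[float] = None
    duration: float = 100.0  # ms

    def __post_init__(self) -> None:
        if self.kind not in ("harmonic", "nonharmonic", "call"):
            raise ValueError(f"unknown syllable kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind in ("harmonic", "call"):
            if self.base_pitch is None or not math.isfinite(self.base_pitch):
                raise ValueError(
                    f"{self.kind} syllable {self.label!r} needs a finite base_pitch"
                )

    @property
    def is_harmonic(self) -> bool:
        return self.kind in ("harmonic", "call")


@dataclass(frozen=True)
class SongModel:
    """An ordered motif of syllables with a reference frequency.

    ``motifs_per_playback`` mirrors the training protocol in which every
    playback contains two consecutive motif renditions, so the motif-wrap
    transition (last syllable back to first) is genuinely performed.
    """

    name: str
    motif: tuple[SyllableSpec, ...]
    reference_freq: float = DEFAULT_REFERENCE_FREQ
    motifs_per_playback: int = 2

    def __post_init__(self) -> None:
        if len(self.motif) < 2:
            raise ValueError("motif must have at least 2 syllables")
        if self.reference_freq <= 0:
            raise ValueError("reference_freq must be positive")
        # repeated labels are allowed (task 5's target performs A twice) but
        # must denote the same syllable type
        by_label: dict[str, SyllableSpec] = {}
        for s in self.motif:
            if s.label in by_label and by_label[s.label] != s:
                raise ValueError(f"conflicting specs for repeated label {s.label!r}")
            by_label[s.label] = s

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.motif)

    def spec(self, label: str) -> SyllableSpec:
        for s in self.motif:
            if s.label == label:
                return s
        raise KeyError(label)

    def harmonic_labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.motif if s.is_harmonic)

    def pitch_of(self, label: str) -> float:
        p = self.spec(label).base_pitch
        if p is None:
            raise ValueError(f"syllable {label!r} has no pitch")
        return p


def target_bigrams(model: SongModel) -> set[tuple[str, str]]:
    """Ordered adjacent label pairs of the motif, including the wrap pair.

    Motifs are performed in repetition (two per playback, several per bout),
    so the last->first transition is part of the song's syntax: for the
    motif ACB the bigram set is {AC, CB, BA}.
    """
    labels = model.labels
    pairs = {(labels[i], labels[i + 1]) for i in range(len(labels) - 1)}
    pairs.add((labels[-1], labels[0]))
    return pairs


@dataclass(frozen=True)
class ImitationTask:
    """A source->target mismatch geometry.

    ``pitch_mismatches`` lists every (source label, target label, semitone
    shift) pair a harmonic source syllable could resolve; in tasks 3 and 5
    one source syllable faces exactly two competing targets.
    ``syntax_mismatch`` is a human-readable description of the ordering
    change.
    """

    task_id: str
    source: SongModel
    target: SongModel
    pitch_mismatches: tuple[tuple[str, str, float], ...]
    syntax_mismatch: str = ""

    def __post_init__(self) -> None:
        for src, tgt, shift in self.pitch_mismatches:
            if shift == 0:
                raise ValueError(f"pitch mismatch {src}->{tgt} has zero shift")
            self.source.spec(src)  # raises KeyError if absent
            self.target.spec(tgt)

    def targets_of(self, source_label: str) -> list[tuple[str, float]]:
        """Competing targets (label, shift) offered to one source syllable."""
        return [(t, s) for (src, t, s) in self.pitch_mismatches if src == source_label]

    def shifted_source_labels(self) -> list[str]:
        seen: list[str] = []
        for src, _, _ in self.pitch_mismatches:
            if src not in seen:
                seen.append(src)
        return seen


def _model(name: str, syls: Iterable[tuple[str, str, Optional[float]]],
           reference_freq: float = DEFAULT_REFERENCE_FREQ) -> SongModel:
    motif = tuple(
        SyllableSpec(label=lab, kind=kind, base_pitch=pitch,
                     duration=120.0 if kind != "call" else 80.0)
        for lab, kind, pitch in syls
    )
    return SongModel(name=name, motif=motif, reference_freq=reference_freq)


def task_library(
    task1_shift: float = 2.0,
    task2_shifts: tuple[float, float] = (2.0, 2.0),
    reference_freq: float = DEFAULT_REFERENCE_FREQ,
) -> dict[str, ImitationTask]:
    """The five imitation tasks, keyed by task id ('1', '2', '3', '4.1', '4.2', '5').

    The sizes of the shifts that varied across experimental birds are
    configurable: task 1 used 1 or 2 semitones (default 2), task 2 varied
    size and direction per bird (default +2/+2 for A and C).
    """
    if task1_shift == 0:
        raise ValueError("task 1 shift must be nonzero")
    s_a, s_c = task2_shifts

    # task 1: ABC -> A C+ B
    src1 = _model("ABC", [("A", "nonharmonic", None), ("B", "nonharmonic", None),
                          ("C", "harmonic", 0.0)], reference_freq)
    tgt1 = _model("AC+B", [("A", "nonharmonic", None), ("C+", "harmonic", task1_shift),
                           ("B", "nonharmonic", None)], reference_freq)
    task1 = ImitationTask("1", src1, tgt1, (("C", "C+", task1_shift),),
                          "permutation ABC -> ACB with C pitch-shifted")

    # task 2: ABC -> A+ C+ B
    src2 = _model("ABC", [("A", "harmonic", 4.0), ("B", "nonharmonic", None),
                          ("C", "harmonic", 0.0)], reference_freq)
    tgt2 = _model("A+C+B", [("A+", "harmonic", 4.0 + s_a), ("C+", "harmonic", s_c),
                            ("B", "nonharmonic", None)], reference_freq)
    task2 = ImitationTask("2", src2, tgt2,
                          (("A", "A+", s_a), ("C", "C+", s_c)),
                          "permutation ABC -> ACB with A and C pitch-shifted")

    # task 3: ABC -> A B- C B+ (two equidistant targets for B)
    src3 = _model("ABC", [("A", "nonharmonic", None), ("B", "harmonic", 0.0),
                          ("C", "nonharmonic", None)], reference_freq)
    tgt3 = _model("AB-CB+", [("A", "nonharmonic", None), ("B-", "harmonic", -2.0),
                             ("C", "nonharmonic", None), ("B+", "harmonic", 2.0)],
                  reference_freq)
    task3 = ImitationTask("3", src3, tgt3,
                          (("B", "B-", -2.0), ("B", "B+", 2.0)),
                          "insertion of a fourth syllable B+ after C")

    # task 4: A B C B+1 <-> A B+2 C B-1 (both directions)
    m_low = _model("ABCB+1", [("A", "nonharmonic", None), ("B", "harmonic", 0.0),
                              ("C", "nonharmonic", None), ("B+1", "harmonic", 1.0)],
                   reference_freq)
    m_high = _model("AB+2CB-1", [("A", "nonharmonic", None), ("B+2", "harmonic", 2.0),
                                 ("C", "nonharmonic", None), ("B-1", "harmonic", -1.0)],
                    reference_freq)
    mm41 = (("B", "B+2", 2.0), ("B", "B-1", -1.0),
            ("B+1", "B+2", 1.0), ("B+1", "B-1", -2.0))
    task41 = ImitationTask("4.1", m_low, m_high, mm41,
                           "close (1 st) targets swap sequential positions")
    mm42 = (("B+2", "B", -2.0), ("B+2", "B+1", -1.0),
            ("B-1", "B", 1.0), ("B-1", "B+1", 2.0))
    task42 = ImitationTask("4.2", m_high, m_low, mm42,
                           "close (1 st) targets swap sequential positions")

    # task 5: AB -> A B+ A B- (two equidistant targets, no sequential bias)
    src5 = _model("AB", [("A", "nonharmonic", None), ("B", "harmonic", 0.0)],
                  reference_freq)
    tgt5 = _model("AB+AB-", [("A", "nonharmonic", None), ("B+", "harmonic", 2.0),
                             ("A", "nonharmonic", None), ("B-", "harmonic", -2.0)],
                  reference_freq)
    task5 = ImitationTask("5", src5, tgt5,
                          (("B", "B+", 2.0), ("B", "B-", -2.0)),
                          "motif doubled with B split into B+ and B-")

    return {"1": task1, "2": task2, "3": task3, "4.1": task41, "4.2": task42,
            "5": task5}


# ---------------------------------------------------------------------------
# serialization

def _spec_to_dict(s: SyllableSpec) -> dict:
    return asdict(s)


def model_to_dict(m: SongModel) -> dict:
    return {
        "name": m.name,
        "reference_freq": m.reference_freq,
        "motifs_per_playback": m.motifs_per_playback,
        "motif": [_spec_to_dict(s) for s in m.motif],
    }


def model_from_dict(d: dict) -> SongModel:
    motif = tuple(SyllableSpec(**s) for s in d["motif"])
    return SongModel(name=d["name"], motif=motif,
                     reference_freq=d.get("reference_freq", DEFAULT_REFERENCE_FREQ),
                     motifs_per_playback=d.get("motifs_per_playback", 2))


def task_to_dict(t: ImitationTask) -> dict:
    return {
        "task_id": t.task_id,
        "source": model_to_dict(t.source),
        "target": model_to_dict(t.target),
        "pitch_mismatches": [list(pm) for pm in t.pitch_mismatches],
        "syntax_mismatch": t.syntax_mismatch,
    }


def task_from_dict(d: dict) -> ImitationTask:
    return ImitationTask(
        task_id=str(d["task_id"]),
        source=model_from_dict(d["source"]),
        target=model_from_dict(d["target"]),
        pitch_mismatches=tuple(tuple(pm) for pm in d["pitch_mismatches"]),
        syntax_mismatch=d.get("syntax_mismatch", ""),
    )


def save_task(t: ImitationTask, path: str | Path) -> None:
    path = Path(path)
    d = task_to_dict(t)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_task(path: str | Path) -> ImitationTask:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return task_from_dict(d)
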