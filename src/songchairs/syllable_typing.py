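"""Syllable-type labelling of renditions.

Types are assigned by a nearest-neighbour classifier over fixed-shape
70 ms log-power spectrogram segments, mirroring manual spectrogram-based
clustering.  Spectrally close types that the classifier lumps together
(e.g. two pitch variants one semitone apart) can be pulled apart by their
sequential context with :func:`refine_by_context`.

Templates are seeded from ground truth on synthetic data; for real data a
curated template store (matrix files + JSON manifest) can be supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy.signal import stft

__all__ = [
    "TypeTemplate",
    "spectrogram_segment",
    "knn_classify",
    "refine_by_context",
    "percent_clustered",
    "label_renditions",
    "templates_from_dataset",
    "save_templates",
    "load_templates",
]

SEGMENT_MS = 70.0
NPERSEG = 256
NOVERLAP = 192


@dataclass
class TypeTemplate:
    """Reference spectrogram segments for one syllable type."""

    label: str
    segments: list[np.ndarray]
    source: str = "seeded-from-truth"  # or "user-curated"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"template {self.label!r} needs at least one segment")
        shapes = {s.shape for s in self.segments}
        if len(shapes) != 1:
            raise ValueError(f"template {self.label!r} segments differ in shape")


def spectrogram_segment(signal: np.ndarray, sr: float,
                        center_ms: Optional[float] = None) -> np.ndarray:
    """Fixed-shape log-power STFT segment of 70 ms centered on ``center_ms``
    (the rendition midpoint by default); shorter audio is zero-padded."""
    x = np.asarray(signal, dtype=float).ravel()
    rms = np.sqrt(np.mean(x ** 2)) if x.size else 0.0
    if rms > 0:
        x = x / rms  # recording level must not affect type distances
    n = int(SEGMENT_MS * sr / 1000.0)
    if center_ms is None:
        center_ms = (x.size / sr) * 500.0
    c = int(center_ms * sr / 1000.0)
    i0 = c - n // 2
    seg = np.zeros(n)
    lo, hi = max(0, i0), min(x.size, i0 + n)
    if hi > lo:
        seg[lo - i0:hi - i0] = x[lo:hi]
    _, _, Z = stft(seg, fs=sr, nperseg=NPERSEG, noverlap=NOVERLAP,
                   boundary=None, padded=True)
    return 10.0 * np.log10(np.abs(Z) ** 2 + 1e-12)


def knn_classify(segment: np.ndarray, templates: list[TypeTemplate],
                 k: int = 5) -> str:
    """Majority label among the k nearest template segments (Euclidean on
    flattened dB matrices); ties broken by smallest mean distance, then by
    template label order."""
    if not templates:
        raise ValueError("no templates configured")
    if k < 1 or k % 2 == 0:
        raise ValueError("k must be a positive odd number")
    v = segment.ravel()
    dists: list[tuple[float, int, str]] = []
    for order, t in enumerate(templates):
        for s in t.segments:
            dists.append((float(np.linalg.norm(v - s.ravel())), order, t.label))
    dists.sort(key=lambda d: (d[0], d[1]))
    top = dists[:min(k, len(dists))]
    tally: dict[str, list[float]] = {}
    order_of: dict[str, int] = {}
    for d, order, lab in top:
        tally.setdefault(lab, []).append(d)
        order_of.setdefault(lab, order)
    best = sorted(tally.items(),
                  key=lambda kv: (-len(kv[1]), float(np.mean(kv[1])),
                                  order_of[kv[0]]))
    return best[0][0]


def percent_clustered(labels: Iterable[Optional[str]]) -> float:
    """Percentage of renditions carrying a type label."""
    labs = list(labels)
    if not labs:
        raise ValueError("no renditions: percent clustered undefined")
    n_lab = sum(1 for l in labs if l is not None and l == l and l != "")
    return 100.0 * n_lab / len(labs)


def refine_by_context(df: pd.DataFrame, pair: tuple[str, str],
                      context_rules: dict[str, dict[str, Optional[str]]],
                      expected_pitch: Optional[dict[str, float]] = None
                      ) -> pd.DataFrame:
    """Re-split a lumped pair of labels by sequential context.

    ``context_rules`` maps each label of the confusable ``pair`` to
    ``{"preceding": label-or-None, "following": label-or-None}``.  Every
    rendition currently labelled with either member of the pair is
    re-assigned to the member whose expected predecessor (or, failing
    that, successor) matches the rendition's observed neighbors in its
    bout.  Renditions matching neither context fall back to the nearest
    ``expected_pitch`` when given, else keep their label.  Adds/updates a
    ``label_refined`` column; idempotent on already-separated data.
    """
    l1, l2 = pair
    for lab in pair:
        if lab not in context_rules:
            raise ValueError(f"no context rule for {lab!r}")
    out = df.copy()
    base = out["label_refined"] if "label_refined" in out else out["label"]
    out["label_refined"] = base.copy()
    song = out.sort_values(["day", "bout_id", "position_in_bout"], kind="stable")
    grp = song.groupby(["day", "bout_id"])["label_refined"]
    pred = grp.shift(1)
    succ = grp.shift(-1)
    lumped = song["label_refined"].isin(pair)
    for idx in song.index[lumped]:
        p, s = pred.loc[idx], succ.loc[idx]
        assigned = None
        for lab in (l1, l2):
            want = context_rules[lab].get("preceding")
            if want is not None and p == want:
                assigned = lab
                break
        if assigned is None:
            for lab in (l1, l2):
                want = context_rules[lab].get("following")
                if want is not None and s == want:
                    assigned = lab
                    break
        if assigned is None and expected_pitch is not None:
            hz_col = "median_pitch_hz" if "median_pitch_hz" in song.columns else None
            if hz_col and pd.notna(song.at[idx, hz_col]):
                hz = song.at[idx, hz_col]
                assigned = min(pair, key=lambda l: abs(hz - expected_pitch[l]))
        if assigned is not None:
            out.at[idx, "label_refined"] = assigned
    return out


# ---------------------------------------------------------------------------
# template stores and dataset labelling


def templates_from_dataset(waves: dict[str, list[np.ndarray]], sr: float,
                           source: str = "seeded-from-truth"
                           ) -> list[TypeTemplate]:
    """Build templates from example waveforms per label."""
    return [
        TypeTemplate(label=lab,
                     segments=[spectrogram_segment(w, sr) for w in ws],
                     source=source)
        for lab, ws in sorted(waves.items())
    ]


def label_renditions(df: pd.DataFrame, signal_of_day, sr: float,
                     templates: list[TypeTemplate], k: int = 5) -> pd.DataFrame:
    """KNN-label every rendition row of an annotation-like table.

    ``signal_of_day`` maps a day index to that day's waveform; onsets and
    offsets in ``df`` index into it.  Returns a copy with a ``label``
    column (existing labels are overwritten: this is the measured path).
    """
    out = df.copy()
    labels = []
    cache: dict[int, np.ndarray] = {}
    for row in out.itertuples(index=False):
        day = int(row.day)
        if day not in cache:
            cache[day] = np.asarray(signal_of_day(day), dtype=float)
        x = cache[day]
        i0 = int(row.onset_ms * sr / 1000.0)
        i1 = int(row.offset_ms * sr / 1000.0)
        seg = spectrogram_segment(x[i0:i1], sr)
        labels.append(knn_classify(seg, templates, k=k))
    out["label"] = labels
    return out


def save_templates(templates: list[TypeTemplate], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for t in templates:
        files = []
        for i, s in enumerate(t.segments):
            fname = f"{t.label}_{i}.txt"
            np.savetxt(directory / fname, s)
            files.append(fname)
        manifest.append({"label": t.label, "source": t.source, "files": files})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_templates(directory: str | Path) -> list[TypeTemplate]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    return [
        TypeTemplate(label=m["label"],
                     segments=[np.loadtxt(directory / f) for f in m["files"]],
                     source=m.get("source", "user-curated"))
        for m in manifest
    ]
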