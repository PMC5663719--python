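"""Error-correction metrics over developmental rendition streams.

All functions operate on a tidy annotation table (one row per rendition;
see :data:`songchairs.synthetic_data.ANNOTATION_COLUMNS`) carrying either
ground-truth f0 (``true_f0_hz``) or measured pitch (``median_pitch_hz``).

Conventions:

* The fraction of pitch correction is 0 at the source pitch and 1 at the
  target pitch, unclamped (birds over- and undershoot).
* Syntax is scored on the focal (pitch-shifted) syllable's neighbors: the
  *converging* transition is the preceding syllable, the *diverging*
  transition the following one; the overall fraction is their mean.  The
  bidirectional shift scale subtracts the fraction of explicitly
  incorrect (away-from-target) transitions, so +1 means 100% correct
  transitions and -1 means 100% incorrect transitions.
* Day-level values are medians over that day's renditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .song_tasks import ImitationTask, semitone_offset, target_bigrams

__all__ = [
    "PitchCorrection",
    "SyntaxCorrection",
    "pitch_semitones",
    "daily_pitch_medians",
    "fraction_pitch_corrected",
    "rendition_pitch_fraction",
    "syntax_spec_for_task",
    "syntax_fractions",
    "rendition_syntax_indicators",
    "syntax_shift_scale",
    "binned_series",
    "pitch_vs_syntax_curve",
    "endpoint_summary",
    "cohort_percentages",
    "null_call_probability",
    "vacancy_histogram",
]


@dataclass
class PitchCorrection:
    source_pitch: float  # semitones
    target_pitch: float
    series: pd.Series = field(default_factory=pd.Series)  # per day or per bin

    def __post_init__(self) -> None:
        if self.target_pitch == self.source_pitch:
            raise ValueError("source and target pitch must differ")


@dataclass
class SyntaxCorrection:
    """Scoring rule for one focal syllable's transitions.

    ``focal_labels``: labels counted as renditions of the focal syllable
    (its developmental lineage).  ``converging_target`` / ``diverging_target``:
    the predecessor / successor label demanded by the target song.
    ``incorrect_set``: bigrams (over lineage labels) scored as
    away-from-target; must be disjoint from the target bigrams
    {(converging, focal), (focal, diverging)}.
    """

    focal_labels: frozenset[str]
    converging_target: str
    diverging_target: str
    incorrect_set: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        correct = {(self.converging_target, f) for f in self.focal_labels}
        correct |= {(f, self.diverging_target) for f in self.focal_labels}
        if self.incorrect_set & correct:
            raise ValueError("incorrect_set overlaps the target bigrams")


def pitch_semitones(df: pd.DataFrame, reference_freq: float,
                    column: Optional[str] = None) -> pd.Series:
    """Rendition pitch in semitones relative to ``reference_freq``.

    Uses ``median_pitch_hz`` when present (measured path), else
    ``true_f0_hz`` (annotation-only path), unless ``column`` pins one.
    """
    if column is None:
        column = "median_pitch_hz" if "median_pitch_hz" in df.columns else "true_f0_hz"
    hz = pd.to_numeric(df[column], errors="coerce")
    out = pd.Series(np.nan, index=df.index, dtype=float)
    ok = hz > 0
    out[ok] = 12.0 * np.log2(hz[ok] / reference_freq)
    return out


def daily_pitch_medians(df: pd.DataFrame, focal_labels: Iterable[str],
                        reference_freq: float,
                        column: Optional[str] = None) -> pd.Series:
    """Per-day median pitch (semitones) of the focal syllable's renditions."""
    focal = df[df["label"].isin(set(focal_labels))].copy()
    focal["st"] = pitch_semitones(focal, reference_freq, column)
    return focal.groupby("day")["st"].median()


def fraction_pitch_corrected(day_medians: pd.Series | Sequence[float],
                             source: float, target: float) -> pd.Series:
    """(p - source) / (target - source), unclamped."""
    if target == source:
        raise ValueError("source and target pitch must differ")
    p = pd.Series(day_medians, dtype=float)
    return (p - source) / (target - source)


def rendition_pitch_fraction(df: pd.DataFrame, focal_labels: Iterable[str],
                             reference_freq: float, source: float,
                             target: float,
                             column: Optional[str] = None) -> pd.Series:
    """Per-rendition pitch-correction fraction, time-ordered."""
    focal = df[df["label"].isin(set(focal_labels))]
    focal = focal.sort_values(["day", "onset_ms"], kind="stable")
    st = pitch_semitones(focal, reference_freq, column)
    return ((st - source) / (target - source)).reset_index(drop=True)


# ---------------------------------------------------------------------------
# syntax


def syntax_spec_for_task(task: ImitationTask, focal_source_label: str,
                         chosen_target_label: str) -> SyntaxCorrection:
    """Build the syntax scoring rule for a focal syllable and its chosen target.

    The converging/diverging targets are the chosen target syllable's
    neighbors in the target motif (with wrap), expressed as source-lineage
    labels where applicable.  Source-motif neighbors of the focal syllable
    that are *not* the target neighbors become the incorrect set — keeping
    them while sounding like the chosen target moves the song away from
    the target syntax.
    """
    tgt_labels = list(task.target.labels)
    try:
        j = tgt_labels.index(chosen_target_label)
    except ValueError:
        raise KeyError(chosen_target_label)
    conv = tgt_labels[(j - 1) % len(tgt_labels)]
    div = tgt_labels[(j + 1) % len(tgt_labels)]
    # map target neighbor labels back to source lineage labels when the
    # neighbor is itself a pitch variant of a source syllable
    back = {t: s for (s, t, _) in task.pitch_mismatches}
    conv = back.get(conv, conv)
    div = back.get(div, div)
    src_labels = list(task.source.labels)
    i = src_labels.index(focal_source_label)
    src_conv = src_labels[(i - 1) % len(src_labels)]
    src_div = src_labels[(i + 1) % len(src_labels)]
    # a retained source-context transition is *incorrect* (anti-target)
    # only when that context belongs to a competing, unchosen target
    # variant of the focal syllable in the target motif: performing it
    # while sounding like the chosen target collides with the competitor's
    # slot (e.g. keeping A.B and B.C while B sounds like B+ in the task
    # where the target demands A.B- and B-.C)
    competitors = {t for (t, _) in task.targets_of(focal_source_label)
                   if t != chosen_target_label}
    tb = target_bigrams(task.target)
    fwd: dict[str, set[str]] = {}
    for s, t, _ in task.pitch_mismatches:
        fwd.setdefault(s, set()).add(t)
    incorrect: set[tuple[str, str]] = set()
    if src_conv != conv:
        conv_forms = fwd.get(src_conv, {src_conv}) | {src_conv}
        if any((a, c) in tb for a in conv_forms for c in competitors):
            incorrect.add((src_conv, focal_source_label))
    if src_div != div:
        div_forms = fwd.get(src_div, {src_div}) | {src_div}
        if any((c, b) in tb for c in competitors for b in div_forms):
            incorrect.add((focal_source_label, src_div))
    return SyntaxCorrection(focal_labels=frozenset({focal_source_label}),
                            converging_target=conv, diverging_target=div,
                            incorrect_set=frozenset(incorrect))


def _neighbor_frame(df: pd.DataFrame, spec: SyntaxCorrection) -> pd.DataFrame:
    """Focal renditions with predecessor/successor labels within their bout."""
    song = df[~df["is_call"].astype(bool)] if "is_call" in df.columns else df
    song = song.sort_values(["day", "bout_id", "position_in_bout"], kind="stable")
    grp = song.groupby(["day", "bout_id"])["label"]
    pred = grp.shift(1)
    succ = grp.shift(-1)
    focal = song["label"].isin(spec.focal_labels)
    out = song.loc[focal, ["day", "bout_id", "onset_ms", "label"]].copy()
    out["pred"] = pred[focal]
    out["succ"] = succ[focal]
    return out


def _daily_syntax(nbr: pd.DataFrame, spec: SyntaxCorrection,
                  against: Optional[frozenset[tuple[str, str]]] = None
                  ) -> pd.DataFrame:
    """Per-day converging/diverging/overall fractions.

    With ``against`` given, scores membership of the (neighbor, focal)
    bigram in that set instead of agreement with the target neighbors.
    Bout-initial (-final) renditions lack a predecessor (successor) and
    are excluded from the converging (diverging) fraction.
    """
    rows = []
    for day, g in nbr.groupby("day"):
        if against is None:
            conv_hits = (g["pred"] == spec.converging_target)
            div_hits = (g["succ"] == spec.diverging_target)
        else:
            conv_hits = [
                (p, f) in against for p, f in zip(g["pred"], g["label"])]
            div_hits = [
                (f, s) in against for f, s in zip(g["label"], g["succ"])]
            conv_hits = pd.Series(conv_hits, index=g.index)
            div_hits = pd.Series(div_hits, index=g.index)
        conv_n = g["pred"].notna().sum()
        div_n = g["succ"].notna().sum()
        conv = float(conv_hits[g["pred"].notna()].mean()) if conv_n else np.nan
        div = float(div_hits[g["succ"].notna()].mean()) if div_n else np.nan
        overall = np.nanmean([conv, div]) if not (math.isnan(conv) and math.isnan(div)) else np.nan
        rows.append({"day": day, "converging": conv, "diverging": div,
                     "overall": overall})
    return pd.DataFrame(rows).set_index("day") if rows else pd.DataFrame(
        columns=["converging", "diverging", "overall"])


def syntax_fractions(df: pd.DataFrame, spec: SyntaxCorrection) -> pd.DataFrame:
    """Per-day (converging, diverging, overall) fractions of target syntax.

    Days without focal renditions are absent from the index (not zero).
    """
    nbr = _neighbor_frame(df, spec)
    return _daily_syntax(nbr, spec)


def syntax_shift_scale(df: pd.DataFrame, spec: SyntaxCorrection) -> pd.Series:
    """Per-day (correct fraction) - (incorrect fraction), in [-1, 1]."""
    nbr = _neighbor_frame(df, spec)
    correct = _daily_syntax(nbr, spec)["overall"]
    if not spec.incorrect_set:
        return correct
    incorrect = _daily_syntax(nbr, spec, against=spec.incorrect_set)["overall"]
    return correct - incorrect


def rendition_syntax_indicators(df: pd.DataFrame,
                                spec: SyntaxCorrection) -> pd.Series:
    """Per-focal-rendition target-syntax score in {0, 0.5, 1}, time-ordered.

    Mean of the converging and diverging indicators; edge renditions use
    only the side that exists.
    """
    nbr = _neighbor_frame(df, spec).sort_values(["day", "onset_ms"], kind="stable")
    conv = (nbr["pred"] == spec.converging_target).where(nbr["pred"].notna())
    div = (nbr["succ"] == spec.diverging_target).where(nbr["succ"].notna())
    both = pd.concat([conv.astype(float), div.astype(float)], axis=1)
    return both.mean(axis=1, skipna=True).reset_index(drop=True)


# ---------------------------------------------------------------------------
# binning and curves


def binned_series(samples: Sequence[float], bin: int = 30, overlap: int = 25,
                  stat: str = "median") -> np.ndarray:
    """Sliding-window summaries: windows of ``bin`` samples advancing by
    ``bin - overlap``; a series of N samples yields
    floor((N - bin)/(bin - overlap)) + 1 windows (0 when N < bin)."""
    if not bin > overlap >= 0:
        raise ValueError("need bin > overlap >= 0")
    x = np.asarray(samples, dtype=float)
    step = bin - overlap
    if x.size < bin:
        return np.empty(0)
    starts = np.arange(0, x.size - bin + 1, step)
    fn = np.nanmedian if stat == "median" else np.nanmean
    return np.array([fn(x[s:s + bin]) for s in starts])


def pitch_vs_syntax_curve(pitch_bins: Sequence[float],
                          syntax_bins: Sequence[float],
                          window: tuple[float, float] = (0.45, 0.55)
                          ) -> tuple[pd.DataFrame, Optional[float]]:
    """Paired (pitch, syntax) bins plus the mean syntax correction over bins
    whose pitch correction falls in ``window`` (None if no bin does)."""
    p = np.asarray(pitch_bins, dtype=float)
    s = np.asarray(syntax_bins, dtype=float)
    if p.size != s.size:
        raise ValueError("pitch and syntax bins must be paired")
    pairs = pd.DataFrame({"pitch": p, "syntax": s})
    sel = (p >= window[0]) & (p <= window[1])
    summary = float(np.nanmean(s[sel])) if sel.any() else None
    return pairs, summary


def endpoint_summary(df: pd.DataFrame, focal_labels: Iterable[str],
                     reference_freq: float, source: float, target: float,
                     spec: Optional[SyntaxCorrection] = None,
                     last_n_days: int = 3,
                     column: Optional[str] = None) -> dict[str, float]:
    """Pitch and syntax correction over the final ``last_n_days`` pooled.

    Returns pitch_correction (median-rendition based), and when a syntax
    spec is given, syntax_correction (overall target fraction) and
    syntax_shift (correct - incorrect)."""
    if df.empty:
        raise ValueError("empty trajectory")
    days = sorted(df["day"].unique())[-last_n_days:]
    tail = df[df["day"].isin(days)]
    focal = tail[tail["label"].isin(set(focal_labels))]
    st = pitch_semitones(focal, reference_freq, column)
    med = float(np.nanmedian(st)) if len(st) else np.nan
    out = {"pitch_correction": (med - source) / (target - source)}
    if spec is not None:
        nbr = _neighbor_frame(tail, spec)
        daily = _daily_syntax(nbr, spec)
        out["syntax_correction"] = float(np.nanmean(daily["overall"])) if len(daily) else np.nan
        if spec.incorrect_set:
            inc = _daily_syntax(nbr, spec, against=spec.incorrect_set)
            out["syntax_shift"] = out["syntax_correction"] - (
                float(np.nanmean(inc["overall"])) if len(inc) else 0.0)
        else:
            out["syntax_shift"] = out["syntax_correction"]
    return out


# ---------------------------------------------------------------------------
# cohort summaries


def cohort_percentages(outcomes: Sequence[bool]) -> tuple[int, int, int]:
    """(percent, count, n): integer percent of True flags, rounding half away
    from zero (20/26 -> 77, 4/26 -> 15)."""
    n = len(outcomes)
    if n < 1:
        raise ValueError("need at least one outcome")
    count = int(sum(bool(o) for o in outcomes))
    pct = int(math.floor(100.0 * count / n + 0.5))
    return pct, count, n


def null_call_probability(n_birds: int) -> float:
    """(1/2)^n: probability that every bird's recruited call lands on the
    vacant (rather than the occupied) target under independent fair choice."""
    if n_birds < 0:
        raise ValueError("n_birds must be nonnegative")
    return 0.5 ** n_birds


def vacancy_histogram(df: pd.DataFrame, focal_labels: Iterable[str],
                      recruited_call: Optional[str], reference_freq: float,
                      source_pitch: float, direction: float,
                      window: float = 6.0, bin_width: float = 0.5,
                      column: Optional[str] = None
                      ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Signed semitone distance-from-source histograms at endpoint.

    Three histograms over harmonic renditions within ``window`` semitones
    of the source pitch: ``focal`` (descendants of the focal syllable),
    ``call`` (the recruited call, empty if None), ``other`` (all remaining
    harmonic vocalizations).  Distances are signed positive in the focal
    syllable's shift ``direction`` (sign of its endpoint shift), so a
    direction flip mirrors the histograms.
    """
    if direction == 0:
        raise ValueError("direction must be nonzero")
    sign = 1.0 if direction > 0 else -1.0
    st = pitch_semitones(df, reference_freq, column)
    dist = sign * (st - source_pitch)
    ok = dist.notna() & (dist.abs() <= window)
    edges = np.arange(-window, window + bin_width / 2, bin_width)
    focal_set = set(focal_labels)
    groups = {
        "focal": ok & df["label"].isin(focal_set),
        "call": ok & (df["label"] == recruited_call) if recruited_call else ok & False,
        "other": ok & ~df["label"].isin(focal_set | ({recruited_call} if recruited_call else set())),
    }
    out = {}
    for name, mask in groups.items():
        counts, _ = np.histogram(dist[mask].to_numpy(), bins=edges)
        out[name] = (edges, counts)
    return out
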