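"""Millisecond-scale acoustic analysis of song recordings.

Implements the feature-extraction stage of the pipeline: a YIN
fundamental-frequency tracker evaluated every millisecond, Wiener entropy,
amplitude-threshold syllable segmentation, bout grouping by inter-syllable
stop duration, and per-rendition summaries (median pitch with the leading
aperiodic run of distance-call-like onsets excluded).

The YIN tracker is the cumulative-mean-normalized difference function
(CMNDF) variant: for each analysis frame the difference function
``d(tau)`` is normalized by its running mean, the first lag dipping below
an aperiodicity threshold is refined to the local minimum, and the period
is interpolated parabolically.  Frames whose CMNDF minimum stays above the
threshold are flagged aperiodic and carry no f0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "FrameFeatures",
    "RenditionRecord",
    "yin_f0",
    "wiener_entropy",
    "segment_syllables",
    "group_bouts",
    "median_pitch",
    "log_power_envelope",
    "analyze_waveform",
]

DEFAULT_FMIN = 300.0
DEFAULT_FMAX = 4000.0
DEFAULT_WINDOW_MS = 25.0
DEFAULT_HOP_MS = 1.0
APERIODICITY_THRESHOLD = 0.2
ENTROPY_FLOOR = -15.0
BOUT_STOP_MS = 175.0  # typical endpoint-song stop duration band is 150-200 ms


@dataclass
class FrameFeatures:
    """Per-frame acoustic measurements (times in ms)."""

    time: np.ndarray
    f0: np.ndarray  # Hz, NaN where aperiodic
    aperiodicity: np.ndarray  # [0, 1], CMNDF depth at the chosen lag
    log_power: Optional[np.ndarray] = None  # dB
    wiener: Optional[np.ndarray] = None

    @property
    def voiced(self) -> np.ndarray:
        return np.isfinite(self.f0)

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class RenditionRecord:
    """One performed syllable or call."""

    day: int
    bout_id: int
    position: int
    label: str
    onset: float  # ms
    offset: float
    median_pitch: Optional[float] = None  # Hz
    median_entropy: Optional[float] = None
    is_call: bool = False

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must exceed onset")


def yin_f0(signal: np.ndarray, sr: float,
           fmin: float = DEFAULT_FMIN, fmax: float = DEFAULT_FMAX,
           hop_ms: float = DEFAULT_HOP_MS,
           window_ms: float = DEFAULT_WINDOW_MS,
           threshold: float = APERIODICITY_THRESHOLD) -> FrameFeatures:
    """Track f0 with the CMNDF estimator, one frame per ``hop_ms``.

    Returns empty features when the signal is shorter than one analysis
    window plus the longest candidate period.
    """
    if not (0 < fmin < fmax < sr / 2):
        raise ValueError("need 0 < fmin < fmax < sr/2")
    x = np.asarray(signal, dtype=float).ravel()
    w = int(round(window_ms * sr / 1000.0))
    hop = max(1, int(round(hop_ms * sr / 1000.0)))
    tau_min = max(2, int(sr / fmax))
    tau_max = int(np.ceil(sr / fmin))
    frame_len = w + tau_max
    if x.size < frame_len:
        z = np.empty(0)
        return FrameFeatures(time=z, f0=z.copy(), aperiodicity=z.copy())

    n_frames = 1 + (x.size - frame_len) // hop
    starts = hop * np.arange(n_frames)
    frames = x[starts[:, None] + np.arange(frame_len)[None, :]]

    # difference function d(tau) = e0 + e_tau - 2*corr(tau), via FFT
    nfft = next_fast_len(2 * frame_len)
    head = np.zeros((n_frames, frame_len))
    head[:, :w] = frames[:, :w]
    F_all = rfft(frames, nfft, axis=1)
    F_head = rfft(head, nfft, axis=1)
    corr = irfft(np.conj(F_head) * F_all, nfft, axis=1)[:, : tau_max + 1]
    csum = np.cumsum(frames * frames, axis=1)
    e0 = csum[:, w - 1][:, None]
    e_tau = np.empty((n_frames, tau_max + 1))
    e_tau[:, 0] = csum[:, w - 1]
    idx = np.arange(1, tau_max + 1)
    e_tau[:, 1:] = csum[:, idx + w - 1] - csum[:, idx - 1]
    d = np.maximum(e0 + e_tau - 2.0 * corr, 0.0)

    # cumulative-mean normalization
    dn = np.ones_like(d)
    run = np.cumsum(d[:, 1:], axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dn[:, 1:] = d[:, 1:] * idx[None, :] / np.where(run > 0, run, np.inf)

    # first lag below threshold, descended to its local minimum
    below = dn < threshold
    below[:, :tau_min] = False
    voiced = below.any(axis=1)
    tau = np.where(voiced, np.argmax(below, axis=1),
                   np.argmin(dn[:, tau_min:], axis=1) + tau_min)
    rows = np.arange(n_frames)
    for _ in range(tau_max):
        nxt = np.minimum(tau + 1, tau_max)
        better = (nxt > tau) & (dn[rows, nxt] < dn[rows, tau])
        if not better.any():
            break
        tau = np.where(better, nxt, tau)

    ap = np.clip(dn[rows, tau], 0.0, 1.0)
    # parabolic interpolation of the CMNDF minimum
    t0 = np.clip(tau, tau_min, tau_max)
    tm = np.clip(t0 - 1, 0, tau_max)
    tp = np.clip(t0 + 1, 0, tau_max)
    a = dn[rows, tm]
    b = dn[rows, t0]
    c = dn[rows, tp]
    denom = a - 2 * b + c
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (a - c) / np.where(denom == 0, 1, denom), 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    period = t0 + np.where((tm < t0) & (tp > t0), shift, 0.0)
    f0 = np.where(voiced & (period > 0), sr / np.maximum(period, 1e-9), np.nan)
    # center time of the correlation window
    time = (starts + w / 2.0) * 1000.0 / sr
    return FrameFeatures(time=time, f0=f0, aperiodicity=ap)


def wiener_entropy(power_spectrum: Sequence[float],
                   floor: float = ENTROPY_FLOOR) -> float:
    """log(geometric mean / arithmetic mean) of spectral power, in (floor, 0].

    0 for a flat (noise-like) spectrum; strongly negative for tonal (line)
    spectra, clamped at ``floor`` when any bin is zero.
    """
    p = np.asarray(power_spectrum, dtype=float).ravel()
    if p.size == 0 or (p < 0).any():
        raise ValueError("power spectrum must be nonnegative and nonempty")
    am = p.mean()
    if am == 0:
        raise ValueError("all-zero spectrum: Wiener entropy undefined")
    if (p == 0).any():
        return floor
    h = float(np.mean(np.log(p)) - np.log(am))
    return min(0.0, max(h, floor))


def log_power_envelope(signal: np.ndarray, sr: float,
                       window_ms: float = 10.0,
                       hop_ms: float = DEFAULT_HOP_MS
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame log power in dB (moving RMS), returns (times_ms, dB)."""
    x = np.asarray(signal, dtype=float).ravel()
    w = int(round(window_ms * sr / 1000.0))
    hop = max(1, int(round(hop_ms * sr / 1000.0)))
    if x.size < w:
        return np.empty(0), np.empty(0)
    c = np.concatenate([[0.0], np.cumsum(x * x)])
    starts = np.arange(0, x.size - w + 1, hop)
    power = (c[starts + w] - c[starts]) / w
    db = 10.0 * np.log10(np.maximum(power, 1e-20))
    times = (starts + w / 2.0) * 1000.0 / sr
    return times, db


def segment_syllables(times: np.ndarray, log_power: np.ndarray,
                      power_threshold: float = -45.0,
                      min_dur: float = 20.0,
                      min_gap: float = 5.0) -> list[tuple[float, float]]:
    """Maximal above-threshold runs as (onset, offset) in ms.

    Gaps shorter than ``min_gap`` are merged, runs shorter than
    ``min_dur`` discarded.
    """
    if min_dur <= 0 or min_gap < 0:
        raise ValueError("min_dur must be positive and min_gap nonnegative")
    t = np.asarray(times, dtype=float)
    above = np.asarray(log_power) > power_threshold
    if t.size == 0 or not above.any():
        return []
    edges = np.diff(above.astype(int))
    onsets = list(np.flatnonzero(edges == 1) + 1)
    offsets = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        onsets.insert(0, 0)
    if above[-1]:
        offsets.append(above.size)
    segs = [(t[i], t[j - 1]) for i, j in zip(onsets, offsets)]
    merged: list[tuple[float, float]] = []
    for on, off in segs:
        if merged and on - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    return [(on, off) for on, off in merged if off - on >= min_dur]


def group_bouts(onsets: Sequence[float], offsets: Sequence[float],
                stop_threshold: float = BOUT_STOP_MS) -> np.ndarray:
    """Assign 0-based bout ids: a stop (offset_i -> onset_{i+1}) of at least
    ``stop_threshold`` ms starts a new bout.  Input must be time-sorted."""
    on = np.asarray(onsets, dtype=float)
    off = np.asarray(offsets, dtype=float)
    if on.size != off.size:
        raise ValueError("onsets and offsets must have equal length")
    if on.size == 0:
        return np.empty(0, dtype=int)
    if (np.diff(on) < 0).any():
        raise ValueError("renditions must be time-sorted")
    gaps = on[1:] - off[:-1]
    return np.concatenate([[0], np.cumsum(gaps >= stop_threshold)]).astype(int)


def median_pitch(features: FrameFeatures,
                 min_voiced_fraction: float = 0.5) -> Optional[float]:
    """Median f0 of a rendition's voiced frames, in Hz.

    The leading contiguous aperiodic run (the noisy onset characteristic
    of distance calls) is excluded first; the median is taken over the
    remaining voiced frames and is absent (None) if fewer than
    ``min_voiced_fraction`` of the remaining frames are voiced.
    """
    voiced = features.voiced
    if voiced.size == 0:
        return None
    first = int(np.argmax(voiced)) if voiced.any() else voiced.size
    rest = voiced[first:]
    if rest.size == 0 or rest.mean() < min_voiced_fraction:
        return None
    return float(np.nanmedian(features.f0[first:]))


def _rendition_entropy(seg: np.ndarray, sr: float) -> Optional[float]:
    if seg.size < 64:
        return None
    nper = min(512, seg.size)
    spec = np.abs(rfft(seg[:nper] * np.hanning(nper))) ** 2
    try:
        return wiener_entropy(spec + 1e-12)
    except ValueError:
        return None


def analyze_waveform(signal: np.ndarray, sr: float, day: int = 0,
                     segments: Optional[list[tuple[float, float]]] = None,
                     power_threshold: float = -45.0,
                     stop_threshold: float = BOUT_STOP_MS,
                     fmin: float = DEFAULT_FMIN, fmax: float = DEFAULT_FMAX,
                     bout_id_offset: int = 0) -> pd.DataFrame:
    """Segment (unless boundaries are supplied), track pitch, and summarize.

    Returns one row per rendition with columns day, bout_id, position_in_bout,
    onset_ms, offset_ms, median_pitch_hz, median_entropy.  Labels are not
    assigned here; see :mod:`songchairs.syllable_typing`.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if segments is None:
        t, db = log_power_envelope(x, sr)
        segments = segment_syllables(t, db, power_threshold=power_threshold)
    rows = []
    pad = int(0.005 * sr)
    for on, off in segments:
        i0 = max(0, int(on * sr / 1000.0) - pad)
        i1 = min(x.size, int(off * sr / 1000.0) + pad)
        seg = x[i0:i1]
        feats = yin_f0(seg, sr, fmin=fmin, fmax=fmax)
        mp = median_pitch(feats) if len(feats) else None
        rows.append({"day": day, "onset_ms": on, "offset_ms": off,
                     "median_pitch_hz": mp,
                     "median_entropy": _rendition_entropy(seg, sr)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["day", "bout_id", "position_in_bout",
                                     "onset_ms", "offset_ms",
                                     "median_pitch_hz", "median_entropy"])
    bouts = group_bouts(df["onset_ms"].to_numpy(), df["offset_ms"].to_numpy(),
                        stop_threshold=stop_threshold)
    df["bout_id"] = bouts + bout_id_offset
    df["position_in_bout"] = df.groupby("bout_id").cumcount()
    return df[["day", "bout_id", "position_in_bout", "onset_ms", "offset_ms",
               "median_pitch_hz", "median_entropy"]]
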