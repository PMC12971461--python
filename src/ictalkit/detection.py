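"""RMS-threshold seizure detection and seizure-burden summaries.

An epoch is flagged ictal-like when its RMS amplitude is strictly greater
than three times the per-channel baseline RMS (the detection ratio is
configurable; 3 is the operating default).  Flagged sliding windows are
merged into events per channel, short events discarded, and simultaneous
multi-channel detections fused into one event carrying all channels.
Burden is summarized as 4-h binned counts, mean event duration, onset
latency, and the trapezoidal area under the binned count curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from .errors import ParameterError
from .io_preprocess import Recording

__all__ = [
    "BaselineStats",
    "IctalEvent",
    "BurdenSummary",
    "compute_rms",
    "estimate_baseline",
    "detect_ictal",
    "bin_events",
    "burden_summary",
]

compute_rms = ft.compute_rms  # shared definition; re-exported here


@dataclass
class BaselineStats:
    """Per-channel baseline RMS plus baseline biomarker means."""

    rms: np.ndarray  # per channel, uV
    window: tuple[float, float]  # (start, end) s
    channel_labels: list[str]
    feature_means: dict[str, float] = field(default_factory=dict)
    band_power: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rms = np.asarray(self.rms, dtype=float)
        if np.any(self.rms <= 0):
            raise ParameterError("baseline RMS must be positive on every channel")


@dataclass
class IctalEvent:
    """A detected (or ground-truth) seizure-like event."""

    channels: frozenset[str]
    onset: float  # s
    duration: float  # s
    peak_rms_ratio: float
    source: str = "detected"

    def __post_init__(self) -> None:
        self.channels = frozenset(self.channels)
        if self.duration <= 0:
            raise ParameterError("event duration must be positive")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class BurdenSummary:
    """Seizure-burden metrics over a recording span."""

    bin_width_h: float
    counts: np.ndarray  # events per bin
    auc: float  # events x hours (trapezoid over bin midpoints)
    mean_duration_s: float | None  # absent when no events
    onset_latency_h: float | None  # time of first event, absent when none


def estimate_baseline(
    recording: Recording,
    window: tuple[float, float],
    epoch_s: float = 4.0,
    min_window_s: float = 60.0,
    compute_features: bool = True,
) -> BaselineStats:
    """Baseline RMS and biomarker means over a designated quiet window.

    RMS, spectral entropy and band powers are averaged over non-overlapping
    `epoch_s` epochs; coherence and the Hurst exponent are computed once on
    the full window (the Hurst estimator needs more samples than a single
    epoch provides).
    """
    start_s, end_s = window
    fs = recording.sampling_rate
    if start_s < 0 or end_s * fs > recording.n_samples + 1e-9 or start_s >= end_s:
        raise ParameterError(f"baseline window {window} outside recording")
    if end_s - start_s < min_window_s:
        raise ParameterError(
            f"baseline window of {end_s - start_s:.1f} s is shorter than the "
            f"{min_window_s:.0f} s minimum")
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    data = recording.signal[:, i0:i1]
    n_ep = int((i1 - i0) // (epoch_s * fs))
    win = int(round(epoch_s * fs))
    epochs = [data[:, k * win:(k + 1) * win] for k in range(n_ep)]

    rms = np.array([
        np.mean([compute_rms(ep[ch]) for ep in epochs])
        for ch in range(recording.n_channels)
    ])
    stats = BaselineStats(rms=rms, window=window,
                          channel_labels=list(recording.channel_labels))
    if compute_features:
        ent, powers = [], []
        for ep in epochs:
            freqs, pxx = ft.psd(ep, fs)
            ent.append(ft.spectral_entropy(freqs, pxx))
            powers.append(ft.band_powers(freqs, pxx))
        stats.band_power = {
            name: float(np.mean([p[name] for p in powers]))
            for name in ft.DEFAULT_BANDS
        }
        stats.feature_means = {
            "spectral_entropy": float(np.mean(ent)),
            "mean_coherence": (ft.pairwise_mean_coherence(data, fs)
                               if recording.n_channels >= 2 else 1.0),
            "hurst": float(np.mean([ft.hurst(data[ch])
                                    for ch in range(recording.n_channels)])),
        }
    return stats


def _merge_flagged_windows(
    starts_s: np.ndarray, flags: np.ndarray, ratios: np.ndarray,
    window_s: float, merge_gap_s: float, min_duration_s: float,
) -> list[tuple[float, float, float]]:
    """Group flagged sliding windows into (onset, end, peak_ratio) intervals."""
    events = []
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return events
    run = [idx[0]]
    for i in idx[1:]:
        gap_s = starts_s[i] - (starts_s[run[-1]] + window_s)
        if gap_s <= merge_gap_s:
            run.append(i)
        else:
            events.append(run)
            run = [i]
    events.append(run)
    out = []
    for run in events:
        onset = float(starts_s[run[0]])
        end = float(starts_s[run[-1]] + window_s)
        if end - onset >= min_duration_s:
            out.append((onset, end, float(ratios[run].max())))
    return out


def _interval_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def detect_ictal(
    recording: Recording,
    baseline: BaselineStats,
    ratio: float = 3.0,
    min_duration_s: float = 2.0,
    merge_gap_s: float = 2.0,
    window_s: float = 2.0,
    hop_s: float = 1.0,
    simultaneity_iou: float = 0.5,
) -> list[IctalEvent]:
    """Detect ictal-like events: sliding-window RMS strictly above
    ``ratio`` x the per-channel baseline RMS.

    Per-channel detections whose intervals overlap with intersection-over-
    union >= ``simultaneity_iou`` are fused into one multi-channel event.
    """
    if ratio <= 0:
        raise ParameterError("detection ratio must be positive")
    fs = recording.sampling_rate
    win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    if win > recording.n_samples:
        return []
    starts = np.arange(0, recording.n_samples - win + 1, hop)
    starts_s = starts / fs

    per_channel: list[tuple[str, tuple[float, float], float]] = []
    for ch in range(recording.n_channels):
        x = recording.signal[ch]
        rms = np.array([compute_rms(x[s:s + win]) for s in starts])
        ratios = rms / baseline.rms[ch]
        flags = ratios > ratio  # strictly greater than the threshold
        for onset, end, peak in _merge_flagged_windows(
                starts_s, flags, ratios, window_s, merge_gap_s, min_duration_s):
            per_channel.append(
                (recording.channel_labels[ch], (onset, end), peak))

    # fuse simultaneous per-channel detections (IoU-based, transitive)
    per_channel.sort(key=lambda e: e[1][0])
    merged: list[dict] = []
    for label, interval, peak in per_channel:
        target = None
        for m in merged:
            if _interval_iou(m["interval"], interval) >= simultaneity_iou:
                target = m
                break
        if target is None:
            merged.append({"channels": {label}, "interval": list(interval),
                           "peak": peak})
        else:
            target["channels"].add(label)
            target["interval"][0] = min(target["interval"][0], interval[0])
            target["interval"][1] = max(target["interval"][1], interval[1])
            target["peak"] = max(target["peak"], peak)

    events = [
        IctalEvent(channels=frozenset(m["channels"]),
                   onset=m["interval"][0],
                   duration=m["interval"][1] - m["interval"][0],
                   peak_rms_ratio=m["peak"])
        for m in merged
    ]
    events.sort(key=lambda e: e.onset)
    return events


def bin_events(
    events: list[IctalEvent], total_span_h: float, bin_width_h: float = 4.0
) -> np.ndarray:
    """Count events per half-open [k*w, (k+1)*w) bin of onset time.

    An onset exactly on a bin edge belongs to the later bin.
    """
    if bin_width_h <= 0:
        raise ParameterError("bin width must be positive")
    n_bins = int(np.ceil(total_span_h / bin_width_h))
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        onset_h = ev.onset / 3600.0
        if not 0 <= onset_h < total_span_h:
            raise ParameterError(
                f"event onset {onset_h:.2f} h outside span {total_span_h} h")
        counts[int(onset_h // bin_width_h)] += 1
    return counts


def burden_summary(
    events: list[IctalEvent], total_span_h: float, bin_width_h: float = 4.0
) -> BurdenSummary:
    """Binned counts, trapezoidal AUC over bin midpoints, duration, latency."""
    if total_span_h <= 0:
        raise ParameterError("span must be positive")
    counts = bin_events(events, total_span_h, bin_width_h)
    midpoints = (np.arange(counts.size) + 0.5) * bin_width_h
    auc = float(np.trapezoid(counts, midpoints)) if counts.size > 1 else 0.0
    durations = [ev.duration for ev in events]
    return BurdenSummary(
        bin_width_h=bin_width_h,
        counts=counts,
        auc=auc,
        mean_duration_s=float(np.mean(durations)) if durations else None,
        onset_latency_h=(min(ev.onset for ev in events) / 3600.0
                         if events else None),
    )
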