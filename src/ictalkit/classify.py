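"""Focal vs generalized seizure classification.

Two complementary rules are applied to every detected event:

* a five-criterion majority vote on the biomarker vector - an event is
  called generalized when at least three generalized-favoring criteria are
  met: delta/fast-gamma ratio > 1.5, absence of the focal alpha/beta
  signature (alpha/beta <= 1.2), spectral entropy above the baseline mean,
  coherence above the baseline mean, and Hurst exponent below the baseline
  mean;
* a channel-extent rule for spike-wave events - focal when activity is
  confined to a single channel, generalized when detected simultaneously
  on two or more channels.

Both calls are always reported.  The headline label defaults to the
channel-extent call for spike-wave events and the feature call for ictal
events, selectable per call site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as ft
from .detection import BaselineStats, IctalEvent, detect_ictal
from .errors import ClassificationError, ParameterError
from .features import FeatureVector
from .io_preprocess import Recording

__all__ = [
    "VOTE_NAMES",
    "ClassifierThresholds",
    "SeizureLabel",
    "criterion_votes",
    "classify_event",
    "channel_extent",
    "classify_recording",
]

#: Ordered names of the five generalized-favoring criteria.
VOTE_NAMES = (
    "delta_fastgamma_high",   # delta/fast-gamma ratio > cut (low-freq dominance)
    "alpha_beta_not_focal",   # NOT (alpha/beta ratio > cut): focal signature absent
    "entropy_above_baseline",
    "coherence_above_baseline",
    "hurst_below_baseline",
)


@dataclass
class ClassifierThresholds:
    """Cut points and baseline references for the five-criterion vote."""

    entropy_reference: float
    coherence_reference: float
    hurst_reference: float
    delta_fastgamma_cut: float = 1.5
    alpha_beta_cut: float = 1.2
    min_generalized_votes: int = 3
    # when False, the alpha/beta criterion votes generalized when the focal
    # signature is PRESENT (the literal reading); default counts its negation
    count_focal_negation: bool = True

    def __post_init__(self) -> None:
        if self.delta_fastgamma_cut <= 0 or self.alpha_beta_cut <= 0:
            raise ParameterError("ratio cuts must be positive")
        if not 1 <= self.min_generalized_votes <= 5:
            raise ParameterError("min_generalized_votes must be in 1..5")

    @classmethod
    def from_baseline(cls, baseline: BaselineStats, **kwargs) -> "ClassifierThresholds":
        means = baseline.feature_means
        missing = {"spectral_entropy", "mean_coherence", "hurst"} - means.keys()
        if missing:
            raise ClassificationError(
                f"baseline feature means missing: {sorted(missing)}")
        return cls(
            entropy_reference=means["spectral_entropy"],
            coherence_reference=means["mean_coherence"],
            hurst_reference=means["hurst"],
            **kwargs,
        )


@dataclass
class SeizureLabel:
    """Criterion votes and the resulting focal/generalized calls."""

    votes: dict[str, bool]
    feature_call: str  # "focal" | "generalized"
    extent_call: str
    headline_policy: str = "extent"  # which call is the headline label

    def __post_init__(self) -> None:
        if set(self.votes) != set(VOTE_NAMES):
            raise ClassificationError("votes must cover exactly the 5 criteria")

    @property
    def vote_count(self) -> int:
        return sum(self.votes.values())

    @property
    def headline(self) -> str:
        return self.extent_call if self.headline_policy == "extent" \
            else self.feature_call


def criterion_votes(features: FeatureVector,
                    thresholds: ClassifierThresholds) -> dict[str, bool]:
    """Evaluate the five generalized-favoring criteria (strict inequalities).

    A tie with any reference counts against the generalized call - the less
    severe focal label wins ties.
    """
    needed = {
        "delta_fastgamma_ratio": features.delta_fastgamma_ratio,
        "alpha_beta_ratio": features.alpha_beta_ratio,
        "spectral_entropy": features.spectral_entropy,
        "mean_coherence": features.mean_coherence,
        "hurst": features.hurst,
    }
    for name, value in needed.items():
        if value is None or not math.isfinite(value):
            raise ClassificationError(f"feature {name!r} missing or non-finite")
    focal_signature = features.alpha_beta_ratio > thresholds.alpha_beta_cut
    return {
        "delta_fastgamma_high":
            features.delta_fastgamma_ratio > thresholds.delta_fastgamma_cut,
        "alpha_beta_not_focal":
            (not focal_signature) if thresholds.count_focal_negation
            else focal_signature,
        "entropy_above_baseline":
            features.spectral_entropy > thresholds.entropy_reference,
        "coherence_above_baseline":
            features.mean_coherence > thresholds.coherence_reference,
        "hurst_below_baseline":
            features.hurst < thresholds.hurst_reference,
    }


def classify_event(votes: dict[str, bool],
                   thresholds: ClassifierThresholds) -> str:
    """Majority vote: generalized iff >= `min_generalized_votes` criteria met."""
    if set(votes) != set(VOTE_NAMES):
        raise ClassificationError(
            f"expected exactly the 5 named votes, got {sorted(votes)}")
    n = sum(bool(v) for v in votes.values())
    return "generalized" if n >= thresholds.min_generalized_votes else "focal"


def channel_extent(event: IctalEvent) -> str:
    """Focal iff confined to one channel; generalized for multi-channel."""
    if len(event.channels) == 0:
        raise ClassificationError("event has an empty channel set")
    return "focal" if len(event.channels) == 1 else "generalized"


def _feature_window(event: IctalEvent, recording: Recording,
                    min_samples: int = 1024) -> tuple[int, int]:
    """Event sample bounds, symmetrically expanded to >= min_samples."""
    fs = recording.sampling_rate
    i0 = int(round(event.onset * fs))
    i1 = int(round(event.end * fs))
    short = min_samples - (i1 - i0)
    if short > 0:
        i0 = max(0, i0 - short // 2)
        i1 = min(recording.n_samples, i0 + min_samples)
        i0 = max(0, i1 - min_samples)
    return i0, i1


def classify_recording(
    recording: Recording,
    baseline: BaselineStats,
    thresholds: ClassifierThresholds | None = None,
    ratio: float = 3.0,
    headline_policy: str = "extent",
    **detect_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Detect, feature-extract and label every event of a recording.

    Returns a per-event table (onset, duration, channels, the five votes,
    vote count, feature and extent calls) and a summary dict with per-class
    event rates (events/hour) and mean durations.
    """
    if thresholds is None:
        thresholds = ClassifierThresholds.from_baseline(baseline)
    events = detect_ictal(recording, baseline, ratio=ratio, **detect_kwargs)
    label_order = {lab: i for i, lab in enumerate(recording.channel_labels)}
    rows = []
    for k, ev in enumerate(events):
        i0, i1 = _feature_window(ev, recording)
        window = recording.signal[:, i0:i1]
        ev_idx = sorted(label_order[c] for c in ev.channels)
        try:
            fv = ft.extract_features(window, recording.sampling_rate,
                                     event_channels=ev_idx,
                                     baseline_band_power=baseline.band_power
                                     or None)
            votes = criterion_votes(fv, thresholds)
        except Exception as exc:
            raise ClassificationError(f"event {k} at {ev.onset:.1f} s: {exc}"
                                      ) from exc
        label = SeizureLabel(
            votes=votes,
            feature_call=classify_event(votes, thresholds),
            extent_call=channel_extent(ev),
            headline_policy=headline_policy,
        )
        row = {
            "event_id": k,
            "onset_s": ev.onset,
            "duration_s": ev.duration,
            "channels": "|".join(sorted(ev.channels, key=label_order.get)),
            "peak_rms_ratio": ev.peak_rms_ratio,
            **{name: votes[name] for name in VOTE_NAMES},
            "vote_count": label.vote_count,
            "feature_call": label.feature_call,
            "extent_call": label.extent_call,
            "headline_call": label.headline,
        }
        rows.append(row)
    table = pd.DataFrame(rows, columns=[
        "event_id", "onset_s", "duration_s", "channels", "peak_rms_ratio",
        *VOTE_NAMES, "vote_count", "feature_call", "extent_call",
        "headline_call"])
    span_h = recording.duration / 3600.0
    summary: dict = {"n_events": len(events), "span_h": span_h}
    for call in ("focal", "generalized"):
        sub = table[table["headline_call"] == call] if len(table) else table
        summary[f"{call}_events_per_hour"] = (len(sub) / span_h
                                              if span_h > 0 else 0.0)
        summary[f"{call}_mean_duration_s"] = (
            float(sub["duration_s"].mean()) if len(sub) else None)
    return table, summary
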