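"""Behavioral sweeps and synthetic studies that exercise the whole pipeline.

These routines recover the pipeline's operating constants from behavior
(flag/no-flag boundaries, filter retention windows), measure estimator
accuracy on ground-truth processes, and score the end-to-end detection and
classification pipeline on seeded archetype recordings.  They are used by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import classify as clf
from . import detection as det
from . import features as ft
from . import structure_function as sf
from . import synthetic as syn
from .io_preprocess import Recording

__all__ = [
    "ratio_recording",
    "detection_flagged",
    "detection_boundary",
    "vote_boundary",
    "glast_retention_window",
    "gfap_min_retained",
    "parseval_error",
    "common_source_msc",
    "hurst_recovery",
    "run_archetype_study",
    "baseline_false_events",
    "constant_burden_auc",
    "cohort_recovery",
]

_FS = 250.0
_BASE_RMS = 20.0


def ratio_recording(r: float, fs: float = _FS) -> Recording:
    """A 10 Hz sine recording whose 70-90 s segment has RMS exactly
    ``r`` times the baseline RMS (20 uV).

    The sine has an integer number of cycles per analysis window, so every
    window RMS is exact and the detector's threshold behavior can be probed
    at machine precision.
    """
    t = np.arange(int(100 * fs)) / fs
    x = np.sqrt(2.0) * _BASE_RMS * np.sin(2 * np.pi * 10.0 * t)
    x[int(70 * fs): int(90 * fs)] *= r
    return Recording(signal=x[None, :], sampling_rate=fs,
                     channel_labels=["C3"])


def detection_flagged(r: float, ratio: float = 3.0) -> bool:
    """Does the detector flag an event on a recording at RMS ratio ``r``?"""
    rec = ratio_recording(r)
    base = det.estimate_baseline(rec, (0.0, 60.0), compute_features=False)
    return len(det.detect_ictal(rec, base, ratio=ratio)) > 0


def detection_boundary(lo: float = 2.0, hi: float = 4.0,
                       tol: float = 1e-6) -> float:
    """Bisection of the flag/no-flag boundary in units of baseline RMS."""
    if detection_flagged(lo) or not detection_flagged(hi):
        raise RuntimeError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if detection_flagged(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def _feature_vector(dfr: float = 1.0, abr: float = 1.0, entropy: float = 0.5,
                    coh: float = 0.1, hurst: float = 0.9) -> ft.FeatureVector:
    return ft.FeatureVector(
        band_power={k: 1.0 for k in ft.DEFAULT_BANDS},
        delta_fastgamma_ratio=dfr, alpha_beta_ratio=abr,
        spectral_entropy=entropy, rms=20.0, mean_coherence=coh, hurst=hurst)


def _reference_thresholds(**kwargs) -> clf.ClassifierThresholds:
    return clf.ClassifierThresholds(entropy_reference=0.8,
                                    coherence_reference=0.2,
                                    hurst_reference=0.8, **kwargs)


def vote_boundary(which: str = "delta_fastgamma", lo: float = 0.5,
                  hi: float = 3.0, tol: float = 1e-6) -> float:
    """Bisection of the feature-vote transition along one band ratio.

    The other features are fixed so that exactly two generalized votes
    (coherence and Hurst) are already cast; the swept ratio's vote decides
    the call, so the generalized/focal flip locates the criterion's cut
    point.  For the delta/fast-gamma ratio the generalized call occurs at
    HIGH values; for alpha/beta it occurs at LOW values (the vote is the
    negation of the focal signature).
    """
    th = _reference_thresholds()

    def generalized(v: float) -> bool:
        if which == "delta_fastgamma":
            fv = _feature_vector(dfr=v, abr=2.0, entropy=0.5, coh=0.5,
                                 hurst=0.5)
        elif which == "alpha_beta":
            fv = _feature_vector(dfr=1.0, abr=v, entropy=0.5, coh=0.5,
                                 hurst=0.5)
        else:
            raise ValueError(f"unknown sweep {which!r}")
        return clf.classify_event(clf.criterion_votes(fv, th), th) == "generalized"

    g_lo, g_hi = generalized(lo), generalized(hi)
    if g_lo == g_hi:
        raise RuntimeError(f"bracket [{lo}, {hi}] does not straddle the cut")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if generalized(mid) == g_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def glast_retention_window(step: float = 0.01) -> tuple[float, float]:
    """Smallest and largest graded particle area retained by the
    GLAST/synaptophysin filter."""
    areas = np.round(np.arange(step, 4.0 + step / 2, step), 10)
    table = pd.DataFrame({"area_um2": areas,
                          "circularity": np.full(areas.size, 0.8)})
    kept = sf.apply_filter(table, sf.GLAST_FILTER)["area_um2"]
    return float(kept.min()), float(kept.max())


def gfap_min_retained(step: float = 0.01) -> float:
    """Smallest graded particle area retained by the GFAP filter."""
    areas = np.round(np.arange(step, 10.0 + step / 2, step), 10)
    table = pd.DataFrame({"area_um2": areas,
                          "circularity": np.full(areas.size, 0.8)})
    kept = sf.apply_filter(table, sf.GFAP_FILTER)["area_um2"]
    return float(kept.min())


def parseval_error(seed: int = 0, duration_s: float = 60.0) -> float:
    """Relative error between the Welch PSD integral and the variance of
    unit-variance white noise."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(duration_s * _FS))
    freqs, pxx = ft.psd(x, _FS)
    total = float(np.trapezoid(pxx, freqs))
    return abs(total - x.var()) / x.var()


def common_source_msc(seed: int = 0, duration_s: float = 120.0) -> float:
    """Mean MSC of x = s + n1, y = s + n2 with equal source/noise variance.

    The closed form for this model is (SNR / (1 + SNR))**2 = 0.25.
    """
    rng = np.random.default_rng(seed)
    n = int(duration_s * _FS)
    s = rng.standard_normal(n)
    x = s + rng.standard_normal(n)
    y = s + rng.standard_normal(n)
    return ft.coherence(x, y, _FS)


def hurst_recovery(h: float, n: int = 8192, n_seeds: int = 20,
                   seed0: int = 0) -> float:
    """Mean R/S Hurst estimate over seeded exact-fGn realizations."""
    ests = [ft.hurst(syn.gen_fgn(h, n, seed0 + k)) for k in range(n_seeds)]
    return float(np.mean(ests))


def run_archetype_study(n_recordings: int = 50, seed: int = 0,
                        n_events: int = 4) -> dict:
    """Detection + classification scorecard over seeded archetype recordings.

    Detections are matched to ground-truth events by interval overlap.
    Sensitivity counts matched truth events; classification accuracy
    compares the headline (channel-extent) label with the injected kind,
    and generalized events are additionally scored on the feature vote.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_recordings)]
    n_truth = matched = correct = gen_total = gen_feature_ok = 0
    for rec_seed in seeds:
        spec = syn.archetype_spec(rec_seed, n_events=n_events)
        rec, truth = syn.assemble_recording(spec)
        base = det.estimate_baseline(rec, (0.0, 100.0))
        table, _ = clf.classify_recording(rec, base)
        for _, tr in truth.iterrows():
            n_truth += 1
            t0, t1 = tr.onset_s, tr.onset_s + tr.duration_s
            hits = table[(table.onset_s < t1)
                         & (table.onset_s + table.duration_s > t0)]
            if not len(hits):
                continue
            matched += 1
            hit = hits.iloc[0]
            if hit.extent_call == tr.kind:
                correct += 1
            if tr.kind == "generalized":
                gen_total += 1
                if hit.feature_call == "generalized":
                    gen_feature_ok += 1
    return {
        "n_recordings": n_recordings,
        "n_truth_events": n_truth,
        "sensitivity": matched / n_truth if n_truth else float("nan"),
        "classification_accuracy": correct / matched if matched else float("nan"),
        "generalized_feature_accuracy": (gen_feature_ok / gen_total
                                         if gen_total else float("nan")),
    }


def baseline_false_events(n_recordings: int = 50, seed: int = 0,
                          duration_s: float = 300.0) -> int:
    """Total events detected on pure-baseline recordings (expected: 0)."""
    ss = np.random.SeedSequence([seed, 0xBA5E])
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
             ss.spawn(n_recordings)]
    total = 0
    for rec_seed in seeds:
        rec = syn.gen_baseline(syn.SyntheticEEGSpec(duration=duration_s,
                                                    seed=rec_seed))
        base = det.estimate_baseline(rec, (0.0, 60.0), compute_features=False)
        total += len(det.detect_ictal(rec, base))
    return total


def constant_burden_auc(events_per_bin: int = 2, n_bins: int = 12,
                        bin_width_h: float = 4.0) -> float:
    """AUC of a constant count-per-bin schedule (oracle: count x span)."""
    events = []
    for b in range(n_bins):
        for k in range(events_per_bin):
            onset_h = b * bin_width_h + 0.5 + k * 0.25
            events.append(det.IctalEvent(channels={"C3"}, onset=onset_h * 3600,
                                         duration=10.0, peak_rms_ratio=5.0))
    summary = det.burden_summary(events, total_span_h=n_bins * bin_width_h,
                                 bin_width_h=bin_width_h)
    return summary.auc


def cohort_recovery(seed: int = 0, slope: float = 2.0, intercept: float = 1.0,
                    noise_sd: float = 0.0, n_animals: int = 6) -> sf.RegressionResult:
    """Fit a generated cohort and return the recovered regression."""
    cohort = syn.gen_cohort(syn.SyntheticCohortSpec(
        n_animals=n_animals, slope=slope, intercept=intercept,
        noise_sd=noise_sd, predictor_range=(0.0, 1.0), seed=seed))
    return sf.linfit(cohort["predictor"], cohort["response"])
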