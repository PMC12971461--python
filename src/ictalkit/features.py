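"""Per-epoch EEG biomarkers.

Six canonical frequency bands are analyzed: Delta (1-4 Hz), Theta (4-8),
Alpha (8-12), Beta (12-30), Slow Gamma (30-60) and Fast Gamma (70-120).
Note the deliberate 60-70 Hz gap between the gamma bands; band powers sum
to slightly less than the 1-120 Hz total because of it.

Biomarkers per epoch: Welch band powers and the two diagnostic band ratios
(delta/fast-gamma, alpha/beta), normalized Shannon spectral entropy, RMS
amplitude, broadband mean magnitude-squared coherence across channel pairs,
and the rescaled-range (R/S) Hurst exponent with the Anis-Lloyd-Peters
finite-sample correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.special import gammaln

from .errors import ClassificationError, ParameterError, UndefinedFeatureError
from .io_preprocess import Epoch

__all__ = [
    "DEFAULT_BANDS",
    "ANALYSIS_BAND",
    "FeatureVector",
    "psd",
    "band_power",
    "band_powers",
    "band_ratio",
    "spectral_entropy",
    "coherence",
    "pairwise_mean_coherence",
    "hurst",
    "normalized_psd",
    "compute_rms",
    "extract_features",
]

#: Ordered band scheme; edges in Hz.  The 60-70 Hz gap is intentional.
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "slow_gamma": (30.0, 60.0),
    "fast_gamma": (70.0, 120.0),
}

#: Broadband analysis range (Hz) used for entropy and coherence averaging.
ANALYSIS_BAND: tuple[float, float] = (1.0, 120.0)


@dataclass
class FeatureVector:
    """Quantitative biomarkers for one epoch or event window."""

    band_power: dict[str, float]
    delta_fastgamma_ratio: float
    alpha_beta_ratio: float
    spectral_entropy: float
    rms: float
    mean_coherence: float
    hurst: float
    normalized_band_power: dict[str, float] | None = field(default=None)

    def as_dict(self) -> dict[str, float]:
        d = {f"power_{k}": v for k, v in self.band_power.items()}
        d.update(
            delta_fastgamma_ratio=self.delta_fastgamma_ratio,
            alpha_beta_ratio=self.alpha_beta_ratio,
            spectral_entropy=self.spectral_entropy,
            rms=self.rms,
            mean_coherence=self.mean_coherence,
            hurst=self.hurst,
        )
        if self.normalized_band_power is not None:
            d.update({f"norm_power_{k}": v
                      for k, v in self.normalized_band_power.items()})
        return d


def _as_array(epoch, fs: float | None) -> tuple[np.ndarray, float]:
    if isinstance(epoch, Epoch):
        return np.atleast_2d(epoch.data), epoch.recording.sampling_rate
    if fs is None:
        raise ParameterError("sampling rate required for raw-array input")
    return np.atleast_2d(np.asarray(epoch, dtype=float)), float(fs)


def psd(epoch, fs: float | None = None, segment_s: float = 2.0):
    """One-sided Welch PSD (Hann window, 50% overlap, 2-s segments).

    For multichannel input the PSD is averaged across channels.  Satisfies
    Parseval up to the usual Welch tapering loss: the trapezoidal integral
    of the returned densities approximates the signal variance.
    """
    data, srate = _as_array(epoch, fs)
    n = data.shape[1]
    if n < 2 * srate:
        raise ParameterError(
            f"epoch of {n} samples is shorter than the 2 s PSD minimum")
    nperseg = min(int(round(segment_s * srate)), n)
    freqs, pxx = sps.welch(data, fs=srate, window="hann", nperseg=nperseg,
                           noverlap=nperseg // 2, detrend="constant", axis=-1)
    return freqs, pxx.mean(axis=0)


def band_power(freqs: np.ndarray, pxx: np.ndarray,
               band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [low, high)."""
    low, high = band
    if low < freqs[0] or high > freqs[-1] + 1e-9:
        raise ParameterError(f"band {band} outside PSD range "
                             f"[{freqs[0]}, {freqs[-1]}] Hz")
    mask = (freqs >= low) & (freqs < high)
    if mask.sum() < 2:
        raise ParameterError(f"band {band} spans fewer than 2 PSD bins")
    return float(np.trapezoid(pxx[mask], freqs[mask]))


def band_powers(freqs: np.ndarray, pxx: np.ndarray,
                bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
                ) -> dict[str, float]:
    return {name: band_power(freqs, pxx, edges) for name, edges in bands.items()}


def band_ratio(powers: dict[str, float], numerator: str, denominator: str) -> float:
    if powers[denominator] == 0:
        raise UndefinedFeatureError(
            f"band ratio {numerator}/{denominator} undefined: "
            f"zero {denominator} power")
    return powers[numerator] / powers[denominator]


def spectral_entropy(freqs: np.ndarray, pxx: np.ndarray,
                     frange: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Shannon entropy (base 2) of the PSD over `frange`, normalized to [0, 1].

    0 for power concentrated in a single bin, 1 for an exactly flat PSD.
    """
    mask = (freqs >= frange[0]) & (freqs <= frange[1])
    p = np.asarray(pxx, dtype=float)[mask]
    if p.size < 2:
        raise ParameterError("need at least 2 PSD bins for spectral entropy")
    if np.any(p < 0):
        raise ParameterError("PSD must be non-negative")
    total = p.sum()
    if total == 0:
        raise UndefinedFeatureError("spectral entropy undefined for all-zero PSD")
    p = p / total
    nz = p[p > 0]
    h = float(-(nz * np.log2(nz)).sum())
    return h / math.log2(p.size)


def _coh_nperseg(n: int, fs: float) -> int:
    # 2-s segments when the window allows >=8 of them, else shrink.
    return max(64, min(int(round(2 * fs)), n // 8))


def coherence(x, y, fs: float | None = None,
              frange: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Mean magnitude-squared coherence of two signals over `frange`."""
    xa, srate = _as_array(x, fs)
    ya, _ = _as_array(y, fs if fs is not None else srate)
    xa, ya = xa.ravel(), ya.ravel()
    if xa.shape != ya.shape:
        raise ParameterError("coherence requires equal-length epochs")
    nperseg = _coh_nperseg(xa.size, srate)
    freqs, cxy = sps.coherence(xa, ya, fs=srate, window="hann",
                               nperseg=nperseg, noverlap=nperseg // 2)
    mask = (freqs >= frange[0]) & (freqs <= frange[1])
    return float(np.clip(cxy[mask].mean(), 0.0, 1.0))


def pairwise_mean_coherence(data: np.ndarray, fs: float,
                            frange: tuple[float, float] = ANALYSIS_BAND) -> float:
    """Mean MSC over all unordered channel pairs of a channels x samples array."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch = data.shape[0]
    if n_ch < 2:
        raise ParameterError("pairwise coherence needs at least 2 channels")
    vals = [coherence(data[i], data[j], fs, frange)
            for i in range(n_ch) for j in range(i + 1, n_ch)]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Hurst exponent (rescaled range)
# ---------------------------------------------------------------------------

def _expected_rs(w: int) -> float:
    """Anis-Lloyd expected R/S of white noise with the Peters correction."""
    i = np.arange(1, w)
    s = float(np.sqrt((w - i) / i).sum())
    if w <= 340:
        pref = math.exp(gammaln((w - 1) / 2.0) - gammaln(w / 2.0)) / math.sqrt(math.pi)
    else:
        pref = 1.0 / math.sqrt(w * math.pi / 2.0)
    return (w - 0.5) / w * pref * s


def hurst(x, fs: float | None = None, min_block: int = 16) -> float:
    """Rescaled-range (R/S) Hurst exponent with finite-sample correction.

    Blocks of logarithmically spaced sizes between `min_block` and n/4 are
    analyzed; the estimate is 0.5 plus the log-log slope of the observed
    R/S over its white-noise expectation (Anis-Lloyd-Peters).  0.5 indicates
    memoryless noise, > 0.5 persistence, < 0.5 anti-persistence.
    """
    if isinstance(x, Epoch):
        x = x.data.ravel()
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if n < 1024:
        raise ParameterError(f"Hurst estimation needs >= 1024 samples, got {n}")
    if np.ptp(x) == 0:
        raise UndefinedFeatureError("Hurst exponent undefined for constant signal")
    sizes = np.unique(np.floor(np.logspace(
        math.log10(min_block), math.log10(n // 4), 12)).astype(int))
    log_w, log_ratio = [], []
    for w in sizes:
        k = n // w
        blocks = x[: k * w].reshape(k, w)
        centered = blocks - blocks.mean(axis=1, keepdims=True)
        cums = np.cumsum(centered, axis=1)
        r = cums.max(axis=1) - cums.min(axis=1)
        s = blocks.std(axis=1, ddof=1)
        ok = s > 0
        if not ok.any():
            continue
        rs = float((r[ok] / s[ok]).mean())
        log_w.append(math.log(w))
        log_ratio.append(math.log(rs) - math.log(_expected_rs(int(w))))
    if len(log_w) < 3:
        raise UndefinedFeatureError("too few usable block sizes for Hurst")
    slope = np.polyfit(log_w, log_ratio, 1)[0]
    return float(0.5 + slope)


# ---------------------------------------------------------------------------
# Aggregate extraction
# ---------------------------------------------------------------------------

def compute_rms(x) -> float:
    """Root-mean-square amplitude of an epoch or array, in uV."""
    if isinstance(x, Epoch):
        x = x.data
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ParameterError("RMS of an empty epoch is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def normalized_psd(epoch, baseline_band_power: dict[str, float],
                   fs: float | None = None,
                   bands: dict[str, tuple[float, float]] = DEFAULT_BANDS,
                   ) -> dict[str, float]:
    """Per-band power of an epoch divided by the baseline mean band power."""
    freqs, pxx = psd(epoch, fs)
    out = {}
    for name, edges in bands.items():
        ref = baseline_band_power.get(name)
        if ref is None or ref == 0:
            raise UndefinedFeatureError(
                f"baseline power for band {name!r} is zero or missing")
        out[name] = band_power(freqs, pxx, edges) / ref
    return out


def extract_features(window: np.ndarray, fs: float,
                     event_channels: list[int] | None = None,
                     baseline_band_power: dict[str, float] | None = None,
                     ) -> FeatureVector:
    """Compute the full biomarker vector for a multichannel window.

    Band powers, entropy, RMS and Hurst are computed on the event channels
    (all channels if unspecified); coherence is the mean MSC over *all*
    channel pairs of the window, since cross-channel synchrony is the
    quantity of interest even for single-channel events.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    ev = window if event_channels is None else window[event_channels]
    if ev.size == 0:
        raise ClassificationError("empty event channel selection")
    freqs, pxx = psd(ev, fs)
    powers = band_powers(freqs, pxx)
    fv = FeatureVector(
        band_power=powers,
        delta_fastgamma_ratio=band_ratio(powers, "delta", "fast_gamma"),
        alpha_beta_ratio=band_ratio(powers, "alpha", "beta"),
        spectral_entropy=spectral_entropy(freqs, pxx),
        rms=compute_rms(ev),
        mean_coherence=(pairwise_mean_coherence(window, fs)
                        if window.shape[0] >= 2 else 1.0),
        hurst=float(np.mean([hurst(ch) for ch in ev])),
    )
    if baseline_band_power is not None:
        fv.normalized_band_power = {
            name: powers[name] / baseline_band_power[name]
            for name in powers
        }
    return fv
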