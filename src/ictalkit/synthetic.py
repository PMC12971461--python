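"""Ground-truth-labeled synthetic data for the EEG and histology pipelines.

Three generators with fully known ground truth:

* 4-channel, 250 Hz EEG with 1/f baseline activity and scheduled ictal
  bursts - focal 3 Hz spike-wave trains confined to one channel, or
  generalized bursts driven by a common source mixed into every channel at
  a controlled coherence level and Hurst exponent;
* fluorescence-style puncta images with per-layer counts and analytically
  known particle areas and circularities;
* small per-animal cohort tables drawn from a known linear
  structure-function relationship.

Every generator is a pure function of its spec (seed included): the same
spec reproduces the same output bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .errors import ParameterError, PlacementError, ScheduleError, SpecError
from .features import DEFAULT_BANDS
from .io_preprocess import CANONICAL_MONTAGE, Recording

__all__ = [
    "SyntheticEEGSpec",
    "ScheduledEvent",
    "SyntheticImageSpec",
    "SyntheticCohortSpec",
    "gen_fgn",
    "gen_baseline",
    "assemble_recording",
    "archetype_spec",
    "gen_puncta_image",
    "gen_cohort",
]

_CHANNEL_ORDER = ["C3", "C4", "P3", "P4"]

#: Representative burst fundamental / band-noise edges per named band.
_BAND_FUNDAMENTAL = {
    "delta": 3.0, "theta": 6.0, "alpha": 10.0,
    "beta": 20.0, "slow_gamma": 40.0, "fast_gamma": 90.0,
}


@dataclass
class ScheduledEvent:
    """One ictal burst to inject into a synthetic recording."""

    kind: str  # "focal" | "generalized"
    onset: float  # s
    duration: float  # s
    target_channel: int | None = None  # focal only
    amplitude_ratio: float = 5.0  # total in-event RMS as multiple of baseline RMS
    dominant_band: str = "delta"
    coherence_level: float = 0.9  # generalized only; target mean MSC
    hurst_target: float = 0.3  # generalized source Hurst exponent

    def __post_init__(self) -> None:
        if self.kind not in ("focal", "generalized"):
            raise SpecError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0 or self.onset < 0:
            raise SpecError("event onset must be >= 0 and duration > 0")
        if self.amplitude_ratio <= 0:
            raise SpecError("amplitude_ratio must be positive")
        if self.kind == "focal" and self.target_channel is None:
            raise SpecError("focal events need a target_channel")
        if self.dominant_band not in DEFAULT_BANDS:
            raise SpecError(f"unknown band {self.dominant_band!r}")
        if not 0 <= self.coherence_level < 1:
            raise SpecError("coherence_level must be in [0, 1)")
        if not 0 < self.hurst_target < 1:
            raise SpecError("hurst_target must be in (0, 1)")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SyntheticEEGSpec:
    """Parameters of a synthetic multichannel EEG recording."""

    duration: float  # s
    seed: int
    n_channels: int = 4
    sampling_rate: float = 250.0
    baseline_amplitude: float = 20.0  # uV RMS
    spectral_slope: float = 1.0  # 1/f exponent of the baseline
    event_schedule: list[ScheduledEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise SpecError("duration must be positive")
        if self.sampling_rate <= 240.0:
            raise SpecError("sampling_rate must exceed twice the 120 Hz "
                            "analysis band edge")
        if self.baseline_amplitude <= 0:
            raise SpecError("baseline_amplitude must be positive")
        if not 1 <= self.n_channels <= len(_CHANNEL_ORDER):
            raise SpecError(f"n_channels must be 1..{len(_CHANNEL_ORDER)}")
        for ev in self.event_schedule:
            if ev.end > self.duration + 1e-9:
                raise ScheduleError(
                    f"event ending at {ev.end} s exceeds the {self.duration} s "
                    "recording")
            if ev.kind == "focal" and not 0 <= ev.target_channel < self.n_channels:
                raise ScheduleError(
                    f"target_channel {ev.target_channel} outside 0.."
                    f"{self.n_channels - 1}")
        self._check_overlap()

    def _check_overlap(self) -> None:
        per_channel: dict[int, list[tuple[float, float]]] = {}
        for ev in self.event_schedule:
            chans = ([ev.target_channel] if ev.kind == "focal"
                     else list(range(self.n_channels)))
            for ch in chans:
                for s, e in per_channel.get(ch, []):
                    if ev.onset < e and s < ev.end:
                        raise ScheduleError(
                            f"events overlap on channel {ch} "
                            f"({s}-{e} s vs {ev.onset}-{ev.end} s)")
                per_channel.setdefault(ch, []).append((ev.onset, ev.end))


# ---------------------------------------------------------------------------
# Fractional Gaussian noise (Davies-Harte circulant embedding)
# ---------------------------------------------------------------------------

def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fGn at integer lags."""
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k ** h2 + np.abs(k - 1) ** h2)


def gen_fgn(hurst: float, n: int, seed) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding.

    Returns a unit-variance stationary series whose autocovariance is the
    exact fGn covariance for the requested Hurst parameter.  `n` must be a
    power of two (embedding convenience).
    """
    if not 0 < hurst < 1:
        raise ParameterError(f"hurst must lie in (0, 1), got {hurst}")
    if n < 2 or (n & (n - 1)) != 0:
        raise ParameterError(f"n must be a power of two >= 2, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = 2 * n
    gamma = fgn_autocovariance(hurst, np.arange(n + 1))
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n circulant row
    lam = np.fft.fft(row).real
    lam[lam < 0] = 0.0  # numerically tiny negatives only; fGn embedding is PSD
    w = np.zeros(m, dtype=complex)
    g = rng.standard_normal(m)
    w[0] = math.sqrt(lam[0] / m) * g[0]
    w[n] = math.sqrt(lam[n] / m) * g[n]
    k = np.arange(1, n)
    amp = np.sqrt(lam[k] / (2 * m))
    w[k] = amp * (g[k] + 1j * g[n + k])
    w[m - k] = np.conj(w[k])
    x = np.fft.fft(w).real[:n]
    return x


# ---------------------------------------------------------------------------
# Baseline EEG
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, fs: float, slope: float,
                      rng: np.random.Generator,
                      highpass_hz: float = 0.5) -> np.ndarray:
    """Gaussian noise with power spectrum proportional to 1/f**slope, unit RMS.

    A gentle spectral high-pass below `highpass_hz` emulates the acquisition
    hardware's DC rejection and keeps the infrared divergence of 1/f noise
    from destabilizing window RMS estimates.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-slope / 2.0)
    shaping[nonzero] /= np.sqrt(1.0 + (highpass_hz / freqs[nonzero]) ** 4)
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x ** 2))


def gen_baseline(spec: SyntheticEEGSpec) -> Recording:
    """Event-free baseline recording: independent 1/f noise per channel."""
    if spec.event_schedule:
        raise SpecError("gen_baseline requires an empty event_schedule; "
                        "use assemble_recording for scheduled events")
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.sampling_rate))
    sig = np.vstack([
        spec.baseline_amplitude *
        _one_over_f_noise(n, spec.sampling_rate, spec.spectral_slope, rng)
        for _ in range(spec.n_channels)
    ])
    labels = _CHANNEL_ORDER[: spec.n_channels]
    return Recording(
        signal=sig,
        sampling_rate=spec.sampling_rate,
        channel_labels=labels,
        montage={lab: CANONICAL_MONTAGE[lab] for lab in labels},
        meta={"synthetic": True, "seed": spec.seed,
              "baseline_amplitude": spec.baseline_amplitude},
    )


# ---------------------------------------------------------------------------
# Ictal burst synthesis
# ---------------------------------------------------------------------------

def _amplitude_ramp(n: int, fs: float, ramp_s: float = 0.5) -> np.ndarray:
    """Cosine on/off ramp over the first and last `ramp_s` seconds."""
    env = np.ones(n)
    r = min(int(round(ramp_s * fs)), n // 2)
    if r > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = ramp
        env[-r:] = ramp[::-1]
    return env

def _spike_wave_train(n: int, fs: float, fundamental: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Rhythmic biphasic spike-wave train, unit RMS before enveloping.

    Each cycle is a sharp positive spike followed by a slower negative
    half-sine wave - the stereotyped spike-and-wave discharge morphology.
    """
    t = np.arange(n) / fs
    period = 1.0 / fundamental
    phase = np.mod(t, period) / period  # 0..1 within each cycle
    spike = np.exp(-0.5 * ((phase - 0.12) / 0.035) ** 2)
    wave_mask = (phase >= 0.30) & (phase <= 0.95)
    wave = np.where(wave_mask,
                    -0.55 * np.sin(np.pi * (phase - 0.30) / 0.65), 0.0)
    x = spike + wave
    # small cycle-to-cycle jitter so the train is not perfectly periodic
    x = x * (1.0 + 0.05 * rng.standard_normal(n))
    x = x - x.mean()
    return x / np.sqrt(np.mean(x ** 2))


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to the given band."""
    low, high = band
    sos = butter(4, [low, min(high, fs / 2 * 0.95)], btype="bandpass",
                 fs=fs, output="sos")
    pad = int(2 * fs)
    x = sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:-pad]
    return x / np.sqrt(np.mean(x ** 2))


def _fgn_segment(hurst: float, n: int, rng: np.random.Generator) -> np.ndarray:
    n2 = 1 << max(1, (n - 1).bit_length())
    return gen_fgn(hurst, n2, rng)[:n]


def assemble_recording(spec: SyntheticEEGSpec) -> tuple[Recording, pd.DataFrame]:
    """Baseline plus scheduled additive bursts, with a ground-truth table.

    Focal events add a spike-wave train to one channel; generalized events
    mix a common band-emphasized source of controlled Hurst exponent into
    every channel, with per-channel noise sized so the within-event mean
    magnitude-squared coherence approximates ``coherence_level`` via
    MSC = (SNR / (1 + SNR))**2.  The additive component is scaled so the
    total in-event RMS is ``amplitude_ratio`` times the baseline RMS.
    """
    base_spec = SyntheticEEGSpec(
        duration=spec.duration, seed=spec.seed, n_channels=spec.n_channels,
        sampling_rate=spec.sampling_rate,
        baseline_amplitude=spec.baseline_amplitude,
        spectral_slope=spec.spectral_slope,
    )
    rec = gen_baseline(base_spec)
    fs = spec.sampling_rate
    b_var = spec.baseline_amplitude ** 2
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xE7E7]))
    rows = []
    for idx, ev in enumerate(spec.event_schedule):
        i0 = int(round(ev.onset * fs))
        i1 = int(round(ev.end * fs))
        n_ev = i1 - i0
        env = _amplitude_ramp(n_ev, fs)
        # additive variance so total in-event RMS = amplitude_ratio * baseline RMS
        add_var = max(ev.amplitude_ratio ** 2 - 1.0, 1e-6) * b_var
        if ev.kind == "focal":
            fundamental = _BAND_FUNDAMENTAL[ev.dominant_band]
            burst = _spike_wave_train(n_ev, fs, fundamental, rng)
            rec.signal[ev.target_channel, i0:i1] += (
                math.sqrt(add_var) * burst * env)
            channels = [rec.channel_labels[ev.target_channel]]
        else:
            msc = ev.coherence_level
            snr = (math.sqrt(msc) / (1 - math.sqrt(msc))) if msc > 0 else 0.0
            band = DEFAULT_BANDS[ev.dominant_band]
            src = (0.8 * _band_noise(n_ev, fs, band, rng)
                   + 0.6 * _fgn_segment(ev.hurst_target, n_ev, rng))
            src /= np.sqrt(np.mean(src ** 2))
            # split additive variance between the common source and channel
            # noise so that source / (baseline + extra noise) variance = SNR
            if snr > 0 and add_var > snr * b_var:
                extra = (add_var - snr * b_var) / (1.0 + snr)
                s_var = add_var - extra
            else:  # cannot reach the target MSC at this amplitude
                extra = 0.0
                s_var = add_var
            for ch in range(spec.n_channels):
                noise = rng.standard_normal(n_ev)
                rec.signal[ch, i0:i1] += env * (
                    math.sqrt(s_var) * src
                    + math.sqrt(extra) * noise)
            channels = list(rec.channel_labels)
        rows.append({
            "event_id": idx,
            "kind": ev.kind,
            "onset_s": ev.onset,
            "duration_s": ev.duration,
            "channels": "|".join(channels),
            "amplitude_ratio": ev.amplitude_ratio,
            "dominant_band": ev.dominant_band,
            "coherence_level": ev.coherence_level if ev.kind == "generalized"
            else np.nan,
            "hurst_target": ev.hurst_target if ev.kind == "generalized"
            else np.nan,
        })
    truth = pd.DataFrame(
        rows, columns=["event_id", "kind", "onset_s", "duration_s", "channels",
                       "amplitude_ratio", "dominant_band", "coherence_level",
                       "hurst_target"])
    rec.meta["n_injected_events"] = len(rows)
    return rec, truth


def archetype_spec(
    seed: int,
    n_events: int = 4,
    baseline_s: float = 110.0,
    amplitude_ratio: float = 5.0,
    coherence_level: float = 0.9,
    hurst_target: float = 0.3,
) -> SyntheticEEGSpec:
    """A study-condition recording spec: quiet baseline then alternating
    focal / generalized archetype bursts with randomized durations and gaps.

    Focal bursts are 3 Hz spike-wave trains on one randomly chosen channel;
    generalized bursts are delta-dominant common-source events at the given
    coherence level and source Hurst exponent.  Durations are drawn from
    8-15 s (the few-second spike-wave range scaled up enough for stable
    per-event feature estimation) with 25-35 s inter-event gaps.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA5C]))
    sched = []
    t = baseline_s + 10.0
    for k in range(n_events):
        kind = "focal" if k % 2 == 0 else "generalized"
        dur = float(rng.uniform(8.0, 15.0))
        if kind == "focal":
            sched.append(ScheduledEvent(
                kind="focal", onset=t, duration=dur,
                target_channel=int(rng.integers(0, 4)),
                amplitude_ratio=amplitude_ratio))
        else:
            sched.append(ScheduledEvent(
                kind="generalized", onset=t, duration=dur,
                amplitude_ratio=amplitude_ratio,
                coherence_level=coherence_level, hurst_target=hurst_target))
        t += dur + float(rng.uniform(25.0, 35.0))
    return SyntheticEEGSpec(duration=t + 10.0, seed=seed,
                            event_schedule=sched)


# ---------------------------------------------------------------------------
# Puncta images
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImageSpec:
    """Parameters of a synthetic laminar puncta field.

    Depth (the laminar axis) runs along image rows; ``layer_bands`` maps
    layer labels to (top, bottom) depth intervals in micrometers.
    """

    field_size: tuple[float, float]  # (width, height) um
    pixel_size: float  # um / px
    layer_bands: dict[str, tuple[float, float]]
    puncta_per_layer: dict[str, int]
    seed: int
    area_distribution: tuple[float, float] = (0.5, 0.2)  # mean, sd um^2
    circularity_distribution: tuple[float, float] = (0.7, 1.0)  # min, max
    background_level: float = 0.1
    noise_sd: float = 0.02
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise SpecError("pixel_size must be positive")
        if any(v < 0 for v in self.puncta_per_layer.values()):
            raise SpecError("puncta counts must be non-negative")
        lo, hi = self.circularity_distribution
        if not 0 < lo <= hi <= 1:
            raise SpecError("circularity bounds must satisfy 0 < lo <= hi <= 1")
        for lab in self.puncta_per_layer:
            if lab not in self.layer_bands:
                raise SpecError(f"no depth band for layer {lab!r}")


def _ellipse_circularity(a: float, b: float) -> float:
    """4*pi*A / P**2 with Ramanujan's perimeter approximation."""
    p = math.pi * (3 * (a + b) - math.sqrt((3 * a + b) * (a + 3 * b)))
    return 4 * math.pi * (math.pi * a * b) / p ** 2


def _axes_for_circularity(area: float, circ: float) -> tuple[float, float]:
    """Semi-axes (a >= b) of an ellipse with given area and circularity."""
    r = math.sqrt(area / math.pi)
    if circ >= 1.0 - 1e-9:
        return r, r
    lo, hi = 1.0, 1.0
    while _ellipse_circularity(r * hi, r / hi) > circ:
        hi *= 1.5
        if hi > 100:
            raise SpecError(f"circularity {circ} unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _ellipse_circularity(r * mid, r / mid) > circ:
            lo = mid
        else:
            hi = mid
    s = 0.5 * (lo + hi)
    return r * s, r / s


def gen_puncta_image(spec: SyntheticImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping elliptical puncta with known ground truth.

    Returns a float image in [0, 1] and a table with one row per punctum:
    centroid (um), analytic area pi*a*b (um^2), rasterized pixel-count area
    (um^2), circularity and layer.  Raises :class:`PlacementError` if a
    punctum cannot be placed without overlap within the retry budget.
    """
    rng = np.random.default_rng(spec.seed)
    w_um, h_um = spec.field_size
    px = spec.pixel_size
    width, height = int(round(w_um / px)), int(round(h_um / px))
    img = np.clip(spec.background_level
                  + spec.noise_sd * rng.standard_normal((height, width)),
                  0.0, 1.0)
    occupied = np.zeros((height, width), dtype=bool)
    yy, xx = np.mgrid[0:height, 0:width]
    rows = []
    mean_a, sd_a = spec.area_distribution
    clo, chi = spec.circularity_distribution
    for layer, count in spec.puncta_per_layer.items():
        d0, d1 = spec.layer_bands[layer]
        for _ in range(count):
            placed = False
            for _attempt in range(spec.max_retries):
                area = -1.0
                while area <= 0.01:
                    area = mean_a + sd_a * rng.standard_normal()
                circ = rng.uniform(clo, chi)
                a_um, b_um = _axes_for_circularity(area, circ)
                theta = rng.uniform(0, math.pi)
                cx = rng.uniform(a_um, w_um - a_um)
                cy = rng.uniform(max(d0, a_um), min(d1, h_um - a_um))
                if cy - a_um < d0 - 1e-9 or cy + a_um > d1 + 1e-9:
                    continue
                cxp, cyp = cx / px, cy / px
                ct, st = math.cos(theta), math.sin(theta)
                u = (xx - cxp) * ct + (yy - cyp) * st
                v = -(xx - cxp) * st + (yy - cyp) * ct
                mask = (u / (a_um / px)) ** 2 + (v / (b_um / px)) ** 2 <= 1.0
                if not mask.any():
                    continue
                # require a 1-px clearance so segmentation separates puncta
                grow = ((np.abs(u) <= a_um / px + 1.5)
                        & (np.abs(v) <= b_um / px + 1.5))
                if (occupied & grow).any():
                    continue
                occupied |= mask
                img[mask] = np.clip(
                    0.9 + 0.03 * rng.standard_normal(int(mask.sum())), 0, 1)
                rows.append({
                    "layer": layer,
                    "cx_um": cx, "cy_um": cy,
                    "area_analytic_um2": math.pi * a_um * b_um,
                    "area_um2": float(mask.sum()) * px ** 2,
                    "circularity": circ,
                    "semi_major_um": a_um, "semi_minor_um": b_um,
                })
                placed = True
                break
            if not placed:
                raise PlacementError(
                    f"could not place punctum in layer {layer!r} after "
                    f"{spec.max_retries} retries")
    table = pd.DataFrame(rows, columns=[
        "layer", "cx_um", "cy_um", "area_analytic_um2", "area_um2",
        "circularity", "semi_major_um", "semi_minor_um"])
    return img, table


# ---------------------------------------------------------------------------
# Cohort tables
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """A linear structure-function relationship across animals."""

    n_animals: int
    slope: float
    intercept: float
    noise_sd: float
    predictor_range: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        if self.n_animals < 3:
            raise SpecError("need at least 3 animals for a regression")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be non-negative")
        if self.predictor_range[0] >= self.predictor_range[1]:
            raise SpecError("predictor_range must be increasing")


def gen_cohort(spec: SyntheticCohortSpec) -> pd.DataFrame:
    """Per-animal (predictor, response) table from the specified line."""
    rng = np.random.default_rng(spec.seed)
    x = np.linspace(*spec.predictor_range, spec.n_animals)
    y = spec.slope * x + spec.intercept + spec.noise_sd * rng.standard_normal(
        spec.n_animals)
    return pd.DataFrame({
        "animal": [f"A{i:03d}" for i in range(spec.n_animals)],
        "predictor": x,
        "response": y,
    })
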