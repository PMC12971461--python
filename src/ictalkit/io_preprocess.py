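"""EDF I/O, montage standardization, band-pass filtering and epoching.

The recordings this package targets are 4-channel epidural EEG sampled at
250 Hz from the left/right anterior/posterior somatosensory cortices,
mapped onto a custom montage named after the nearest standard human 10-20
positions (C3/C4 anterior, P3/P4 posterior).

Reading EDF goes through MNE.  Writing uses a minimal 16-bit EDF writer
implemented here, which the MNE reader round-trips in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import MontageError, ParameterError

__all__ = [
    "Recording",
    "Epoch",
    "CANONICAL_MONTAGE",
    "read_edf",
    "write_edf",
    "standardize_montage",
    "bandpass",
    "epochize",
]


@dataclass
class Recording:
    """A multichannel EEG recording in microvolts.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Sample values in uV.
    sampling_rate : float
        Sampling frequency in Hz.
    channel_labels : list of str
        One label per signal row.
    montage : dict
        Canonical label -> (x, y) position in arbitrary head coordinates.
    meta : dict
        Free-form acquisition metadata (subject id, treatment group, ...).
    """

    signal: np.ndarray
    sampling_rate: float
    channel_labels: list[str]
    montage: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ParameterError("signal must be a channels x samples matrix")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ParameterError("one label per channel is required")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate


@dataclass
class Epoch:
    """A half-open [start_sample, end_sample) slice of a recording."""

    recording: Recording
    start_sample: int
    end_sample: int
    channels: list[int] | None = None  # indices; None = all channels

    def __post_init__(self) -> None:
        if not (0 <= self.start_sample < self.end_sample <= self.recording.n_samples):
            raise ParameterError(
                f"epoch bounds [{self.start_sample}, {self.end_sample}) outside "
                f"recording of {self.recording.n_samples} samples"
            )

    @property
    def data(self) -> np.ndarray:
        sl = self.recording.signal[:, self.start_sample : self.end_sample]
        if self.channels is not None:
            sl = sl[self.channels]
        return sl

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


# Canonical 4-lead epidural montage over the somatosensory cortices, named by
# the nearest human 10-20 electrode.  Positions are schematic (x: left-,
# right+; y: posterior-, anterior+).
CANONICAL_MONTAGE: dict[str, tuple[float, float]] = {
    "C3": (-0.5, 0.5),   # left anterior somatosensory
    "C4": (0.5, 0.5),    # right anterior somatosensory
    "P3": (-0.5, -0.5),  # left posterior somatosensory
    "P4": (0.5, -0.5),   # right posterior somatosensory
}

_ALIASES: dict[str, str] = {}
for _canon, _variants in {
    "C3": ["c3", "l-ant-ssc", "left-anterior", "left_anterior", "la", "l-ant",
           "eeg la", "left anterior ssc"],
    "C4": ["c4", "r-ant-ssc", "right-anterior", "right_anterior", "ra", "r-ant",
           "eeg ra", "right anterior ssc"],
    "P3": ["p3", "l-post-ssc", "left-posterior", "left_posterior", "lp", "l-post",
           "eeg lp", "left posterior ssc"],
    "P4": ["p4", "r-post-ssc", "right-posterior", "right_posterior", "rp", "r-post",
           "eeg rp", "right posterior ssc"],
}.items():
    for _v in _variants:
        _ALIASES[_v] = _canon


def standardize_montage(
    labels: list[str],
) -> tuple[list[str], dict[str, tuple[float, float]], list[str]]:
    """Map raw channel labels onto the canonical 4-lead montage.

    Returns ``(canonical_labels, positions, unmapped)``.  Unknown labels are
    passed through unchanged, flagged in ``unmapped`` and reported with a
    warning rather than silently dropped.  Two raw labels resolving to the
    same canonical lead is an error.
    """
    canonical: list[str] = []
    positions: dict[str, tuple[float, float]] = {}
    unmapped: list[str] = []
    for lab in labels:
        key = lab.strip().lower()
        canon = _ALIASES.get(key)
        if canon is None:
            warnings.warn(f"channel label {lab!r} not in montage alias table; "
                          "passing through unmapped", stacklevel=2)
            unmapped.append(lab)
            canonical.append(lab)
            continue
        if canon in positions:
            raise MontageError(f"label {lab!r} duplicates canonical lead {canon}")
        canonical.append(canon)
        positions[canon] = CANONICAL_MONTAGE[canon]
    return canonical, positions, unmapped


# ---------------------------------------------------------------------------
# EDF I/O
# ---------------------------------------------------------------------------

def _fit_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _format_physical(v: float) -> str:
    """Render a physical min/max into <=8 ASCII chars, parseable by float()."""
    for fmt in ("%.6g", "%.5g", "%.4g", "%.3g"):
        s = fmt % v
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot format {v} in 8 chars")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF with physical unit uV.

    Uses 1-second data records when the sample count divides evenly by the
    sampling rate, otherwise a single data record spanning the whole signal.
    Quantization error is bounded by (physical range) / 2**16 per channel.
    """
    path = Path(path)
    sig = recording.signal
    n_ch, n_samp = sig.shape
    fs = recording.sampling_rate
    if float(fs).is_integer() and n_samp % int(fs) == 0:
        spr = int(fs)  # samples per record
        n_records = n_samp // spr
        record_dur = "1"
    else:
        spr = n_samp
        n_records = 1
        record_dur = _format_physical(n_samp / fs)

    phys_min, phys_max, scales = [], [], []
    for ch in range(n_ch):
        amp = float(np.max(np.abs(sig[ch]))) if n_samp else 0.0
        if amp == 0.0:
            amp = 1.0
        pmax_s = _format_physical(amp)
        pmin_s = _format_physical(-amp)
        pmax, pmin = float(pmax_s), float(pmin_s)
        if pmax < amp:  # formatting rounded down; bump so data fit the range
            pmax_s = _format_physical(amp * 1.001)
            pmin_s = _format_physical(-amp * 1.001)
            pmax, pmin = float(pmax_s), float(pmin_s)
        phys_min.append(pmin_s)
        phys_max.append(pmax_s)
        scales.append((pmin, pmax))

    header = b"".join([
        _fit_field("0", 8),
        _fit_field(recording.meta.get("subject_id", "X"), 80),
        _fit_field(recording.meta.get("recording_id", "ictalkit"), 80),
        _fit_field(recording.meta.get("start_date", "01.01.24"), 8),
        _fit_field(recording.meta.get("start_time", "00.00.00"), 8),
        _fit_field(256 * (1 + n_ch), 8),
        _fit_field("", 44),
        _fit_field(n_records, 8),
        _fit_field(record_dur, 8),
        _fit_field(n_ch, 4),
    ])
    labels = [lab[:16] for lab in recording.channel_labels]
    header += b"".join(_fit_field(lab, 16) for lab in labels)
    header += b"".join(_fit_field("", 80) for _ in range(n_ch))
    header += b"".join(_fit_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_fit_field(s, 8) for s in phys_min)
    header += b"".join(_fit_field(s, 8) for s in phys_max)
    header += b"".join(_fit_field(-32768, 8) for _ in range(n_ch))
    header += b"".join(_fit_field(32767, 8) for _ in range(n_ch))
    header += b"".join(_fit_field("", 80) for _ in range(n_ch))
    header += b"".join(_fit_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_fit_field("", 32) for _ in range(n_ch))

    digital = np.empty((n_ch, n_samp), dtype="<i2")
    for ch in range(n_ch):
        pmin, pmax = scales[ch]
        g = (pmax - pmin) / 65535.0
        digital[ch] = np.clip(np.rint((sig[ch] - pmin) / g) - 32768,
                              -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            block = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(block.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (signal in uV)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"EDF file not found: {path}")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt-file path
        raise IOError(f"could not read EDF file {path}: {exc}") from exc
    sfreqs = {raw.info["sfreq"]}
    if len(sfreqs) != 1:  # pragma: no cover - mne resamples mixed rates
        raise IOError(f"unsupported EDF with mixed sampling rates: {path}")
    data = raw.get_data(units="uV")
    labels, montage, _ = standardize_montage(list(raw.ch_names))
    return Recording(
        signal=np.asarray(data, dtype=float),
        sampling_rate=float(raw.info["sfreq"]),
        channel_labels=labels,
        montage=montage,
        meta={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# Filtering and epoching
# ---------------------------------------------------------------------------

def bandpass(recording: Recording, low: float = 1.0, high: float = 120.0) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass copy of a recording.

    The default 1-120 Hz passband matches the analysis band of every
    downstream biomarker.
    """
    nyq = recording.sampling_rate / 2.0
    if high >= nyq:
        raise ParameterError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
    if not 0 < low < high:
        raise ParameterError("need 0 < low < high")
    sos = butter(4, [low, high], btype="bandpass", fs=recording.sampling_rate,
                 output="sos")
    filtered = sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(
        signal=filtered,
        sampling_rate=recording.sampling_rate,
        channel_labels=list(recording.channel_labels),
        montage=dict(recording.montage),
        meta={**recording.meta, "bandpass_hz": (low, high)},
    )


def epochize(
    recording: Recording, window_s: float = 4.0, overlap_fraction: float = 0.5
) -> list[Epoch]:
    """Slice a recording into equally spaced half-open epochs.

    The trailing partial window is dropped.  A window longer than the
    recording yields an empty list with a warning.
    """
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must be in [0, 1)")
    win = int(round(window_s * recording.sampling_rate))
    if win < 2:
        raise ParameterError("window must span at least 2 samples")
    if win > recording.n_samples:
        warnings.warn("window longer than recording; no epochs produced",
                      stacklevel=2)
        return []
    hop = max(1, int(round(win * (1 - overlap_fraction))))
    starts = range(0, recording.n_samples - win + 1, hop)
    return [Epoch(recording, s, s + win) for s in starts]
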