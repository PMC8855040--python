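"""Deterministic signal conditioning.

Fixed arithmetic shared by every analysis stage: broadband 2-60 Hz
zero-phase bandpass filtering, trimming of filter transients, selection of
the 50 s complexity epoch, segmentation into ten 5 s connectivity epochs,
decomposition into the five canonical EEG bands, per-channel z-scoring, and
relative band power.

All durations assume the native 200 Hz sampling of the study design: a 60 s
recording is 12,000 samples, the complexity epoch is 10,000 samples, each
connectivity epoch is 1,000 samples.  Indexing is 0-based with half-open
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .io import Recording

#: Broadband analysis range (Hz).
BROADBAND = (2.0, 60.0)

#: Samples in one full epoch / the trimmed complexity epoch / one
#: connectivity epoch at 200 Hz.
EPOCH_SAMPLES = 12_000
COMPLEXITY_SAMPLES = 10_000
PLI_EPOCH_SAMPLES = 1_000
TRIM_SAMPLES = 1_000
N_PLI_EPOCHS = 10


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float


#: The five canonical EEG bands.
BANDS = (
    BandDefinition("delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 60.0),
)

BAND_BY_NAME = {b.name: b for b in BANDS}


@dataclass
class AnalysisEpoch:
    """A fixed-length analysis window cut from one subject's recording."""

    samples: np.ndarray  # channels x time
    sampling_rate: float
    origin: tuple[str, int] = ("", 0)  # (subject_id, start sample)
    purpose: str = "complexity"  # or "pli"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4) -> np.ndarray:
    nyquist = fs / 2.0
    if not 0.0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(f"high cut {high} Hz is not below the Nyquist {nyquist} Hz")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: Recording, low: float = BROADBAND[0], high: float = BROADBAND[1]) -> Recording:
    """Zero-phase 4th-order Butterworth bandpass, applied forward-backward.

    Zero-phase filtering preserves the relative Hilbert phases on which the
    phase-lag index depends; the signal length is unchanged.
    """
    sos = _bandpass_sos(low, high, recording.sampling_rate)
    return recording.copy_with(sps.sosfiltfilt(sos, recording.samples, axis=-1))


def trim_select(recording: Recording) -> AnalysisEpoch:
    """Cut the central 50 s complexity epoch from a (>=) 60 s recording.

    The first 60 s are taken as the analysis epoch, then the first and last
    5 s (1,000 samples each at 200 Hz) are dropped to discard the bandpass
    filter transient, leaving samples [1000, 11000).
    """
    if recording.n_samples < EPOCH_SAMPLES:
        raise ValueError(
            f"recording has {recording.n_samples} samples; "
            f"need at least {EPOCH_SAMPLES} (60 s at 200 Hz)"
        )
    window = recording.samples[:, :EPOCH_SAMPLES]
    trimmed = window[:, TRIM_SAMPLES : EPOCH_SAMPLES - TRIM_SAMPLES]
    return AnalysisEpoch(
        samples=trimmed,
        sampling_rate=recording.sampling_rate,
        origin=(recording.subject_id, TRIM_SAMPLES),
        purpose="complexity",
    )


def segment_for_pli(epoch: AnalysisEpoch) -> list[AnalysisEpoch]:
    """Split the 10,000-sample complexity epoch into ten 1,000-sample epochs."""
    if epoch.n_samples != COMPLEXITY_SAMPLES:
        raise ValueError(
            f"expected a {COMPLEXITY_SAMPLES}-sample complexity epoch, "
            f"got {epoch.n_samples} samples"
        )
    subject, start0 = epoch.origin
    out = []
    for k in range(N_PLI_EPOCHS):
        lo = k * PLI_EPOCH_SAMPLES
        out.append(
            AnalysisEpoch(
                samples=epoch.samples[:, lo : lo + PLI_EPOCH_SAMPLES],
                sampling_rate=epoch.sampling_rate,
                origin=(subject, start0 + lo),
                purpose="pli",
            )
        )
    return out


def band_decompose(
    epoch: AnalysisEpoch, bands: tuple[BandDefinition, ...] = BANDS
) -> dict[str, AnalysisEpoch]:
    """One zero-phase band-limited copy of the epoch per band, same length."""
    out = {}
    for band in bands:
        sos = _bandpass_sos(band.low, band.high, epoch.sampling_rate)
        out[band.name] = AnalysisEpoch(
            samples=sps.sosfiltfilt(sos, epoch.samples, axis=-1),
            sampling_rate=epoch.sampling_rate,
            origin=epoch.origin,
            purpose=epoch.purpose,
        )
    return out


def zscore(series: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, SD 1 along the last axis.

    A constant series raises rather than returning zeros, to surface
    degenerate configurations early.
    """
    series = np.asarray(series, dtype=float)
    sd = series.std(axis=-1, keepdims=True)
    scale = np.maximum(np.abs(series).max(axis=-1, keepdims=True), 1.0)
    if np.any(sd <= 1e-12 * scale):
        raise ValueError("cannot z-score a (numerically) constant series")
    return (series - series.mean(axis=-1, keepdims=True)) / sd


def relative_band_power(epoch: AnalysisEpoch, band: BandDefinition) -> np.ndarray:
    """Per-channel fraction of 2-60 Hz power falling inside ``band``.

    Power is estimated by Welch's method (2 s Hann windows, 50% overlap)
    and integrated with the trapezoid rule.
    """
    fs = epoch.sampling_rate
    if epoch.n_samples < 2 * fs:
        raise ValueError("epoch must be at least 2 s long for Welch estimation")
    nperseg = int(2 * fs)
    freqs, psd = sps.welch(epoch.samples, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)

    def _power(lo: float, hi: float) -> np.ndarray:
        mask = (freqs >= lo) & (freqs <= hi)
        return np.trapezoid(psd[:, mask], freqs[mask], axis=-1)

    total = _power(*BROADBAND)
    if np.any(total <= 0):
        raise ValueError("zero total power in the 2-60 Hz range")
    return _power(band.low, band.high) / total
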