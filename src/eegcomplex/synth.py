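"""Synthetic two-group EEG cohort generator.

Real resting-state EEG from the aging cohorts this pipeline targets is not
redistributable, so every downstream stage is exercised on synthetic signals
with *known* ground truth instead.  Each channel is built from four
ingredients whose parameters differ between a "younger" and an "older"
group:

* a multifractal random walk (MRW) backbone controlling self-similarity
  (Hurst exponent ``H`` -> first log-cumulant ``c1``) and intermittency
  (``lambda^2`` -> second log-cumulant ``c2 = -lambda^2``),
* additive fast Gaussian noise controlling fine-scale irregularity
  (-> small-scale sample entropy),
* narrow-band alpha oscillations, realised as band-filtered Gaussian noise
  so that both phase and amplitude drift randomly; selected channel pairs
  share an oscillation with a constant non-zero phase lag
  (-> phase-lag-index connectivity), and
* one zero-lag broadband source mixed into all channels, emulating volume
  conduction, which phase-lag-based connectivity must ignore.

Fractional Brownian motion is synthesised by exact circulant embedding
(Davies-Harte), so the covariance of the increments is exact and parameter
recovery tests are meaningful.  The MRW uses a Gaussian log-correlated
volatility cascade with integral scale equal to the series length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import signal as sps

from .io import CHANNELS_10_20, GROUP_OLDER, GROUP_YOUNGER, Recording

#: Passbands (Hz) of the oscillatory components, the interior of each
#: canonical band.  Oscillations are band-filtered Gaussian noise: their
#: instantaneous phase drifts randomly with decorrelation time ~1/bandwidth,
#: so independent channels share no systematic phase relation (a pure
#: fixed-frequency sinusoid per channel would instead lock spuriously with
#: any channel whose frequency happened to land nearby).
BAND_FREQ_RANGE_HZ = {
    "delta": (2.5, 3.5),
    "theta": (4.5, 7.5),
    "alpha": (8.5, 12.5),
    "beta": (14.0, 28.0),
    "gamma": (32.0, 55.0),
}

#: High-pass corner (Hz) of the fast-noise component.  Aging-related
#: irregularity in this model is fast (gamma-band-like) activity: confining
#: the noise above ~35 Hz makes it drive the small-scale sample entropy
#: without swamping the mid-frequency wavelet scales from which the
#: multifractal cumulants are estimated.
FAST_NOISE_HIGHPASS_HZ = 35.0


@dataclass
class SynthSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the two-group resting-state design this pipeline was
    built for: 32 younger and 18 older subjects, 16 channels of the 10-20
    montage at 200 Hz for 60 s.  The older group has a lower Hurst exponent,
    weaker intermittency, and stronger fast noise, reproducing the direction
    of the reported aging contrasts (lower c1, lower |c2|, higher fast-scale
    entropy) without targeting any particular magnitude.
    """

    n_young: int = 32
    n_old: int = 18
    n_channels: int = 16
    sampling_rate: float = 200.0
    duration: float = 60.0
    hurst_by_group: dict = field(
        default_factory=lambda: {GROUP_YOUNGER: 0.80, GROUP_OLDER: 0.70}
    )
    intermittency_by_group: dict = field(
        default_factory=lambda: {GROUP_YOUNGER: 0.08, GROUP_OLDER: 0.03}
    )
    fast_noise_gain_by_group: dict = field(
        default_factory=lambda: {GROUP_YOUNGER: 0.30, GROUP_OLDER: 0.45}
    )
    coupling_edges: list = field(
        default_factory=lambda: [("C3", "C4", "alpha", math.pi / 4, 0.8)]
    )
    common_source_gain: float = 0.2
    #: Amplitude of the per-channel background alpha oscillation relative to
    #: the unit-variance backbone; resting EEG is alpha dominant.
    alpha_amplitude: float = 0.6
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    def validate(self) -> None:
        if self.n_young < 2 or self.n_old < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_samples < 12_000:
            raise ValueError(
                "duration x sampling_rate must give at least 12,000 samples "
                "(one 60 s epoch at 200 Hz) so the trimming arithmetic applies"
            )
        for g, h in self.hurst_by_group.items():
            if not 0.0 < h < 1.0:
                raise ValueError(f"Hurst exponent for group {g!r} must be in (0, 1)")
        for g, lam2 in self.intermittency_by_group.items():
            if lam2 < 0:
                raise ValueError(f"intermittency for group {g!r} must be >= 0")
        for g, gain in self.fast_noise_gain_by_group.items():
            if gain < 0:
                raise ValueError(f"fast noise gain for group {g!r} must be >= 0")
        if not 0.0 <= self.common_source_gain <= 1.0:
            raise ValueError("common_source_gain must be in [0, 1]")
        for a, b, band, _lag, strength in self.coupling_edges:
            if band not in BAND_FREQ_RANGE_HZ:
                raise ValueError(f"unknown band {band!r} in coupling edge")
            if not 0.0 <= strength <= 1.0:
                raise ValueError("coupling strength must be in [0, 1]")
            if a == b:
                raise ValueError("coupling edge must join two distinct channels")


# ---------------------------------------------------------------------------
# Gaussian process synthesis (circulant embedding)
# ---------------------------------------------------------------------------


def _fgn_autocovariance(n: int, hurst: float) -> np.ndarray:
    k = np.arange(n + 1, dtype=float)
    two_h = 2.0 * hurst
    return 0.5 * (
        np.abs(k + 1) ** two_h - 2.0 * np.abs(k) ** two_h + np.abs(k - 1) ** two_h
    )


def _circulant_gaussian(acov: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``size`` stationary Gaussian series with autocovariance ``acov``.

    ``acov`` holds lags 0..n; returns an array of shape (size, n).  Uses the
    Davies-Harte embedding of the covariance into a circulant of length 2n,
    drawing two independent real series per complex FFT.  Slightly negative
    embedding eigenvalues (possible for the log-correlated volatility
    covariance) are clipped to zero.
    """
    n = len(acov) - 1
    row = np.concatenate([acov, acov[-2:0:-1]])  # length 2n
    lam = np.fft.fft(row).real
    neg = lam.min()
    if neg < -1e-6 * np.abs(lam).max():
        lam = np.clip(lam, 0.0, None)
    else:
        lam = np.maximum(lam, 0.0)
    m = len(row)
    n_complex = (size + 1) // 2
    z = rng.standard_normal((n_complex, m)) + 1j * rng.standard_normal((n_complex, m))
    spectrum = np.sqrt(lam / m) * z
    paths = np.fft.fft(spectrum, axis=1)
    out = np.empty((2 * n_complex, n))
    out[0::2] = paths.real[:, :n]
    out[1::2] = paths.imag[:, :n]
    return out[:size]


def _fgn_batch(n: int, hurst: float, rng: np.random.Generator, size: int) -> np.ndarray:
    """Exact fractional Gaussian noise, shape (size, n), unit increments."""
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must lie strictly inside (0, 1)")
    return _circulant_gaussian(_fgn_autocovariance(n, hurst), size, rng)


def _omega_batch(
    n: int, lam2: float, rng: np.random.Generator, size: int, integral_scale: int | None = None
) -> np.ndarray:
    """Log-volatility field of the MRW: Gaussian, cov lam2*ln(L/(|k|+1))_+."""
    L = n if integral_scale is None else integral_scale
    k = np.arange(n + 1, dtype=float)
    acov = lam2 * np.log(np.maximum(L / (k + 1.0), 1.0))
    omega = _circulant_gaussian(acov, size, rng)
    # Centre so that E[exp(2*omega)] = 1: shift by -Var(omega).
    return omega - lam2 * np.log(L)


def generate_fbm(n: int, hurst: float, seed: int | np.random.Generator) -> np.ndarray:
    """Fractional Brownian motion of length ``n`` by exact circulant embedding.

    Increments are stationary Gaussian with the exact fGn covariance;
    ``hurst`` = 0.5 gives ordinary Brownian motion.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    fgn = _fgn_batch(n, hurst, rng, size=1)[0]
    return np.cumsum(fgn)


def generate_mrw(
    n: int,
    hurst: float,
    intermittency: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Multifractal random walk with second log-cumulant ``-intermittency``.

    Increments are fGn(H) modulated by the exponential of an independent
    log-correlated Gaussian field with variance parameter
    ``intermittency`` (= lambda^2) and integral scale equal to ``n``.
    ``intermittency = 0`` reduces exactly to :func:`generate_fbm`.
    """
    if intermittency < 0:
        raise ValueError("intermittency (lambda^2) must be >= 0")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    return _mrw_batch(n, hurst, intermittency, rng, size=1)[0]


def _mrw_batch(
    n: int, hurst: float, intermittency: float, rng: np.random.Generator, size: int
) -> np.ndarray:
    fgn = _fgn_batch(n, hurst, rng, size)
    if intermittency == 0.0:
        return np.cumsum(fgn, axis=1)
    omega = _omega_batch(n, intermittency, rng, size)
    return np.cumsum(fgn * np.exp(omega), axis=1)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@lru_cache(maxsize=32)
def _band_sos(band: str, fs: float) -> np.ndarray:
    low, high = BAND_FREQ_RANGE_HZ[band]
    return sps.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")


@lru_cache(maxsize=8)
def _fast_noise_sos(fs: float) -> np.ndarray:
    return sps.butter(4, FAST_NOISE_HIGHPASS_HZ, btype="highpass", fs=fs, output="sos")


def _band_oscillation(
    n: int, band: str, fs: float, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Unit-SD narrow-band oscillation(s): Gaussian noise filtered to the band
    interior, so instantaneous phase and amplitude both drift randomly."""
    shape = (n,) if size is None else (size, n)
    x = sps.sosfiltfilt(_band_sos(band, fs), rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _phase_lagged(oscillation: np.ndarray, lag: float) -> np.ndarray:
    """Copy of a narrow-band oscillation with every phase retarded by ``lag``."""
    return np.real(sps.hilbert(oscillation) * np.exp(-1j * lag))


def _fast_noise(
    n_channels: int, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD Gaussian noise high-passed above FAST_NOISE_HIGHPASS_HZ."""
    noise = sps.sosfiltfilt(_fast_noise_sos(fs), rng.standard_normal((n_channels, n)), axis=-1)
    return noise / noise.std(axis=-1, keepdims=True)


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def generate_subject(
    spec: SynthSpec, group: str, subject_id: str, rng: np.random.Generator
) -> Recording:
    """One subject's channels x time signal under the cohort conditions."""
    n = spec.n_samples
    fs = spec.sampling_rate
    labels = CHANNELS_10_20[: spec.n_channels]
    label_index = {lab: i for i, lab in enumerate(labels)}

    backbone = _zscore_rows(
        _mrw_batch(
            n,
            spec.hurst_by_group[group],
            spec.intermittency_by_group[group],
            rng,
            size=spec.n_channels,
        )
    )
    noise = spec.fast_noise_gain_by_group[group] * _fast_noise(
        spec.n_channels, n, fs, rng
    )
    common = rng.standard_normal(n)

    g = spec.common_source_gain
    signals = (1.0 - g) * (backbone + noise) + g * common[None, :]

    # Background alpha oscillation, independent per channel; channels touched
    # by a coupling edge mix their private oscillation of that band linearly
    # with the shared, constant-lag oscillation of the edge (strength 1 means
    # full replacement by the shared component).
    coupled = {}
    for a, b, band, lag, strength in spec.coupling_edges:
        if a not in label_index or b not in label_index:
            raise ValueError(f"coupling edge references unknown channel ({a}, {b})")
        shared = _band_oscillation(n, band, fs, rng)
        coupled.setdefault((a, band), []).append((strength, shared))
        coupled.setdefault((b, band), []).append((strength, _phase_lagged(shared, lag)))

    privates = _band_oscillation(n, "alpha", fs, rng, size=spec.n_channels)
    for ch in labels:
        i = label_index[ch]
        mixes = coupled.get((ch, "alpha"), [])
        private = privates[i]
        if mixes:
            strength, shared = mixes[0]
            osc = (1.0 - strength) * private + strength * shared
        else:
            osc = private
        signals[i] += spec.alpha_amplitude * osc
        # Non-alpha coupled components are added on top (no background
        # oscillation exists in those bands to mix against).
        for band in BAND_FREQ_RANGE_HZ:
            if band == "alpha":
                continue
            for strength, shared in coupled.get((ch, band), []):
                signals[i] += spec.alpha_amplitude * strength * shared

    return Recording(
        samples=signals,
        sampling_rate=fs,
        channel_labels=labels,
        group=group,
        subject_id=subject_id,
    )


def generate_cohort(spec: SynthSpec) -> list[Recording]:
    """Deterministically generate the full two-group cohort.

    The same ``spec`` (including its seed) always yields a bitwise-identical
    cohort; each subject draws from an independent child of the cohort seed,
    so cohorts are stable under changes in group sizes elsewhere.
    """
    spec.validate()
    recordings: list[Recording] = []
    plan = [(GROUP_YOUNGER, i) for i in range(spec.n_young)] + [
        (GROUP_OLDER, i) for i in range(spec.n_old)
    ]
    for j, (group, i) in enumerate(plan):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, j]))
        subject_id = f"{'y' if group == GROUP_YOUNGER else 'o'}{i + 1:03d}"
        recordings.append(generate_subject(spec, group, subject_id, rng))
    return recordings
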