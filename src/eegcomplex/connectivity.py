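"""Phase-lag-index (PLI) functional connectivity.

The PLI between two channels is the absolute time-average of the sign of
their wrapped instantaneous phase difference,

    PLI_ab = | mean_t sign(sin(phi_a(t) - phi_b(t))) |,

with sign(0) = 0.  Because only the *asymmetry* of the phase-difference
distribution around zero counts, couplings at exactly zero (or pi) lag --
the signature of volume conduction from a common source -- contribute
nothing, while any consistent non-zero lag drives the PLI toward 1.

Phases come from the Hilbert analytic signal of band-limited epochs; the
first and last 5% of samples of each epoch are excluded from the average to
avoid the analytic-signal edge transient.  Per-epoch PLI values are
averaged over the ten 5 s epochs of one subject.  Node strength NS_a is the
mean PLI of channel a to the K-1 others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import BANDS, AnalysisEpoch, BandDefinition, band_decompose

#: Fraction of samples flagged as edge region at each end of an epoch.
EDGE_FRACTION = 0.05

#: |sin(delta phi)| below this is treated as an exact 0 or pi lag, whose
#: samples must contribute nothing (sign(0) = 0); covers the floating-point
#: representation of sin(pi).
_SIN_TOL = 1e-9


def _signed_lag(delta: np.ndarray) -> np.ndarray:
    s = np.sin(delta)
    return np.sign(np.where(np.abs(s) < _SIN_TOL, 0.0, s))


@dataclass
class PhaseSeries:
    """Instantaneous phase/amplitude of one band-limited channel."""

    phase: np.ndarray  # radians in (-pi, pi]
    amplitude: np.ndarray
    band: BandDefinition | None = None
    channel: str = ""
    edge_samples: int = 0

    @property
    def valid_slice(self) -> slice:
        return slice(self.edge_samples, len(self.phase) - self.edge_samples)


@dataclass
class PLIMatrix:
    """band x channel x channel symmetric PLI array, zero diagonal."""

    values: np.ndarray
    bands: tuple[str, ...]
    channel_labels: tuple[str, ...]
    n_epochs_averaged: int
    samples_per_epoch: int

    def band_matrix(self, band: str) -> np.ndarray:
        return self.values[self.bands.index(band)]


@dataclass
class NodeStrengthVector:
    values: np.ndarray  # band x channel
    bands: tuple[str, ...]
    channel_labels: tuple[str, ...]


def instantaneous_phase(
    band_epoch: np.ndarray,
    band: BandDefinition | None = None,
    channel: str = "",
) -> PhaseSeries:
    """Analytic-signal phase and amplitude of one band-limited series."""
    x = np.asarray(band_epoch, dtype=float)
    if x.ndim != 1:
        raise ValueError("instantaneous_phase expects a single channel")
    if np.allclose(x, 0.0):
        raise ValueError("all-zero input has no defined phase")
    analytic = sps.hilbert(x)
    return PhaseSeries(
        phase=np.angle(analytic),
        amplitude=np.abs(analytic),
        band=band,
        channel=channel,
        edge_samples=int(EDGE_FRACTION * len(x)),
    )


def pli_pair(pa: PhaseSeries, pb: PhaseSeries) -> float:
    """PLI of one channel pair: |mean sign(sin(delta phi))| over non-edge samples.

    sign(sin .) wraps the raw difference implicitly and sends both 0 and pi
    lags to zero contribution, so identical signals and perfectly
    anti-phase (dipole-opposite) signals both give PLI = 0 exactly.
    """
    if len(pa.phase) != len(pb.phase):
        raise ValueError("phase series have different lengths")
    edge = max(pa.edge_samples, pb.edge_samples)
    sl = slice(edge, len(pa.phase) - edge)
    delta = pa.phase[sl] - pb.phase[sl]
    return float(np.abs(np.mean(_signed_lag(delta))))


def _pli_matrix_one(phases: np.ndarray, edge: int) -> np.ndarray:
    """Pairwise PLI of a channels x time phase array for one epoch."""
    p = phases[:, edge : phases.shape[1] - edge]
    return np.abs(np.mean(_signed_lag(p[:, None, :] - p[None, :, :]), axis=-1))


def pli_matrix(
    pli_epochs: list[AnalysisEpoch],
    bands: tuple[BandDefinition, ...] = BANDS,
) -> PLIMatrix:
    """Band-wise pairwise PLI averaged over the (ten) 5 s epochs.

    Each epoch is band-decomposed, Hilbert-transformed per channel, and its
    pairwise PLI computed; the per-epoch matrices are then averaged (not
    pooled sample-wise), so every epoch contributes equally.
    """
    if not pli_epochs:
        raise ValueError("no epochs supplied")
    n_samples = pli_epochs[0].n_samples
    n_channels = pli_epochs[0].n_channels
    for i, ep in enumerate(pli_epochs):
        if ep.n_samples != n_samples or ep.n_channels != n_channels:
            raise ValueError(f"epoch {i} has inconsistent shape")
    edge = int(EDGE_FRACTION * n_samples)
    values = np.zeros((len(bands), n_channels, n_channels))
    for ep in pli_epochs:
        per_band = band_decompose(ep, bands)
        for bi, band in enumerate(bands):
            analytic = sps.hilbert(per_band[band.name].samples, axis=-1)
            values[bi] += _pli_matrix_one(np.angle(analytic), edge)
    values /= len(pli_epochs)
    np.fill_diagonal(values[0], 0.0)
    for bi in range(len(bands)):
        np.fill_diagonal(values[bi], 0.0)
    labels = tuple(f"ch{i}" for i in range(n_channels))
    return PLIMatrix(
        values=values,
        bands=tuple(b.name for b in bands),
        channel_labels=labels,
        n_epochs_averaged=len(pli_epochs),
        samples_per_epoch=n_samples,
    )


def node_strength(m: PLIMatrix) -> NodeStrengthVector:
    """NS_a = mean of row a of each band's PLI matrix, diagonal excluded."""
    n_channels = m.values.shape[-1]
    if n_channels < 2:
        raise ValueError("node strength needs at least 2 channels")
    sums = m.values.sum(axis=-1)  # diagonal is zero
    return NodeStrengthVector(
        values=sums / (n_channels - 1),
        bands=m.bands,
        channel_labels=m.channel_labels,
    )
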