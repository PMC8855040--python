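"""Multiscale sample entropy.

Sample entropy (SampEn) is the negative log of the conditional probability
that two length-m templates matching within tolerance r (Chebyshev
distance, self-matches excluded) still match when extended to length m+1.
Multiscale entropy evaluates SampEn on coarse-grained versions of the
signal: scale tau replaces the series by non-overlapping block means of
length tau, so at 200 Hz scale tau corresponds to a window of tau/200 s
(scale 30 = 0.15 s).

Conventions: m = 2, r = 0.2 in units of the SD of the z-scored scale-1
series, r held fixed across scales; pair counting uses unordered template
pairs i < j with the strict inequality d < r; an undefined entropy (zero
matches at either length) is a flagged NaN, never +/-inf.  Counting sorts
the templates by their first coordinate and scans the |delta| < r window,
which is exactly the naive all-pairs count but near-linear in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba
import numpy as np

from .preprocess import AnalysisEpoch, zscore


@dataclass
class MSEParams:
    m: int = 2
    r: float = 0.2
    max_scale: int = 30

    def validate(self) -> None:
        if self.m < 1:
            raise ValueError("embedding dimension m must be >= 1")
        if not self.r > 0:
            raise ValueError("tolerance r must be > 0")
        if self.max_scale < 1:
            raise ValueError("max_scale must be >= 1")


@dataclass
class MSEProfile:
    """Sample entropy per channel per scale; NaN marks undefined entries."""

    entropy: np.ndarray  # channels x scales
    scales_seconds: np.ndarray  # per-scale window length in seconds
    params: MSEParams = field(default_factory=MSEParams)

    @property
    def n_undefined(self) -> int:
        return int(np.sum(~np.isfinite(self.entropy)))


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping block means of length ``tau``; remainder dropped."""
    series = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = len(series)
    if tau > n:
        raise ValueError(f"tau={tau} exceeds series length {n}")
    if tau == 1:
        return series.copy()
    n_blocks = n // tau
    return series[: n_blocks * tau].reshape(n_blocks, tau).mean(axis=1)


def _embed(series: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(series, m)


@numba.njit
def _windowed_pair_counts(emb: np.ndarray, r: float) -> tuple[int, int]:
    """(B, A) over rows sorted by column 0; columns 0..m-1 give B, all give A."""
    n, mp1 = emb.shape
    b = 0
    a = 0
    for i in range(n):
        j = i + 1
        while j < n and emb[j, 0] - emb[i, 0] < r:
            match_m = True
            for d in range(1, mp1 - 1):
                if abs(emb[i, d] - emb[j, d]) >= r:
                    match_m = False
                    break
            if match_m:
                b += 1
                if abs(emb[i, mp1 - 1] - emb[j, mp1 - 1]) < r:
                    a += 1
            j += 1
    return b, a


def template_match_counts(series: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered pair counts (B, A) of m- and (m+1)-template Chebyshev matches.

    Both counts use the N - m templates that admit an (m+1)-extension, the
    standard convention that makes the ratio a conditional probability.
    Matching is strict (d < r).
    """
    series = np.ascontiguousarray(series, dtype=float)
    n = len(series)
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    emb = _embed(series, m + 1)  # n - m rows; first m columns are the m-template
    order = np.argsort(emb[:, 0], kind="stable")
    b, a = _windowed_pair_counts(np.ascontiguousarray(emb[order]), float(r))
    return b, a


def sample_entropy(series: np.ndarray, params: MSEParams | None = None) -> float:
    """SampEn = -ln(A / B); NaN if either match count is zero."""
    params = params or MSEParams()
    params.validate()
    series = np.asarray(series, dtype=float)
    b, a = template_match_counts(series, params.m, params.r)
    if a == 0 or b == 0:
        return float("nan")
    return float(-math.log(a / b))


def mse_curve(epoch: AnalysisEpoch, params: MSEParams | None = None) -> MSEProfile:
    """Sample entropy per channel at scales 1..max_scale.

    Each channel is z-scored once at scale 1; the tolerance r then stays
    fixed (0.2 x the scale-1 SD = 0.2) for every coarser scale, so changes
    across scales reflect structure, not renormalisation.
    """
    params = params or MSEParams()
    params.validate()
    z = zscore(epoch.samples)
    out = np.full((epoch.n_channels, params.max_scale), np.nan)
    for ch in range(epoch.n_channels):
        for tau in range(1, params.max_scale + 1):
            coarse = coarse_grain(z[ch], tau)
            if len(coarse) < params.m + 2:
                raise ValueError(
                    f"channel {ch}, scale {tau}: coarse series too short"
                )
            out[ch, tau - 1] = sample_entropy(coarse, params)
    scales_seconds = np.arange(1, params.max_scale + 1) / epoch.sampling_rate
    return MSEProfile(entropy=out, scales_seconds=scales_seconds, params=params)


def fast_scale_mean(
    profile: MSEProfile, scale_lo: int = 1, scale_hi: int = 5
) -> np.ndarray:
    """Per-channel mean entropy over scales ``scale_lo``..``scale_hi``.

    Undefined (NaN) entries propagate: a channel with any undefined scale in
    the range yields NaN, so silent averaging over missing values cannot
    occur.
    """
    if profile.entropy.shape[1] < scale_hi:
        raise ValueError(
            f"profile covers {profile.entropy.shape[1]} scales; "
            f"need at least {scale_hi}"
        )
    return profile.entropy[:, scale_lo - 1 : scale_hi].mean(axis=1)
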