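"""Wavelet-leader multifractal analysis.

The multifractal formalism summarises a signal by the fractal dimension
D(h) of the sets of time points sharing local (Hoelder) regularity h.  The
wavelet-leader route estimates it from discrete wavelet coefficients
d_X(j, k):

* the *leader* L_X(j, k) is the supremum of |d_X| over all dyadic
  intervals at scales finer than or equal to 2^j contained in the
  three-interval neighbourhood of position k at scale j;
* structure functions S_L(q, j) = (1/n_j) sum_k L_X(j, k)^q scale as
  2^{j zeta(q)}; the scaling exponents zeta(q) are slopes of
  log2 S_L(q, j) against j;
* D(h) = inf_{q != 0} (1 + q h - zeta(q)) (a Legendre transform);
* the log-cumulants c1 and c2 are the first two polynomial coefficients of
  zeta(q) = c1 q + c2 q^2 / 2 + ...; c1 locates the peak of D(h)
  (overall smoothness) and c2 < 0 measures its width (multifractality /
  intermittency).  They are estimated, lower-variance, from the scaling of
  the sample cumulants of ln L_X(j, .) across j.

Conventions: Daubechies-3 mother wavelet (>= 2 vanishing moments for
polynomial-trend immunity), L1 coefficient normalisation (so monofractal
fBm(H) gives zeta(q) = qH), strict 'valid' convolution so no coefficient
touches zero-padding, and leaders at positions lacking a complete
three-interval neighbourhood are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

DEFAULT_WAVELET = "db3"

#: Default moment grid: symmetric, step 0.25, q = 0 excluded (the Legendre
#: transform is an infimum over q != 0).
DEFAULT_Q_GRID = tuple(
    q / 4.0 for q in range(-20, 21) if q != 0
)

#: Default Hoelder grid for tabulating D(h).
DEFAULT_H_GRID = tuple(h / 100.0 for h in range(0, 151))

#: Minimum leaders per scale for that scale to enter the fits.
MIN_COEFFS_PER_SCALE = 8


@dataclass
class WaveletDecomposition:
    """Per-scale detail coefficients, L1-normalised, boundary-free."""

    coefficients: dict[int, np.ndarray]
    wavelet_name: str
    n_levels: int
    signal_length: int


@dataclass
class LeaderSet:
    """Wavelet leaders per scale (sup over the 3-neighbourhood tree)."""

    leaders: dict[int, np.ndarray]
    wavelet_name: str = DEFAULT_WAVELET
    signal_length: int = 0


@dataclass
class StructureScaling:
    q_grid: np.ndarray
    S: np.ndarray  # len(q_grid) x n_scales
    scales: np.ndarray  # the j values of the columns of S
    zeta: np.ndarray
    fit_scale_range: tuple[int, int]
    n_j: dict[int, int]


@dataclass
class SingularitySpectrum:
    h_grid: np.ndarray
    D: np.ndarray
    c1: float
    c2: float

    @property
    def c2_abs(self) -> float:
        return abs(self.c2)


def max_levels(n: int, wavelet_name: str = DEFAULT_WAVELET) -> int:
    """Deepest scale at which at least MIN_COEFFS_PER_SCALE valid leaders survive."""
    filt_len = len(pywt.Wavelet(wavelet_name).dec_lo)
    j, length = 0, n
    while True:
        length = (length - filt_len + 1) // 2
        if length < MIN_COEFFS_PER_SCALE + 2:
            return j
        j += 1


def dwt(
    series: np.ndarray, wavelet_name: str = DEFAULT_WAVELET, n_levels: int | None = None
) -> WaveletDecomposition:
    """Pyramid DWT with 'valid' convolution and L1 normalisation.

    Every retained coefficient is an exact inner product of true signal
    samples (no padding), so boundary effects are eliminated rather than
    mitigated; the per-scale coefficient counts shrink accordingly.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("dwt expects a 1-D series")
    wavelet = pywt.Wavelet(wavelet_name)
    if wavelet.vanishing_moments_psi < 2:
        raise ValueError("mother wavelet needs at least 2 vanishing moments")
    feasible = max_levels(len(series), wavelet_name)
    if n_levels is None:
        n_levels = feasible
    if n_levels < 1 or n_levels > feasible:
        raise ValueError(
            f"n_levels={n_levels} infeasible for length {len(series)} "
            f"(at most {feasible})"
        )
    lo = np.asarray(wavelet.dec_lo)
    hi = np.asarray(wavelet.dec_hi)
    coeffs: dict[int, np.ndarray] = {}
    approx = series
    for j in range(1, n_levels + 1):
        detail = sps.convolve(approx, hi, mode="valid")[::2]
        approx = sps.convolve(approx, lo, mode="valid")[::2]
        coeffs[j] = detail * 2.0 ** (-j / 2.0)  # L2 -> L1 normalisation
    return WaveletDecomposition(
        coefficients=coeffs,
        wavelet_name=wavelet_name,
        n_levels=n_levels,
        signal_length=len(series),
    )


def compute_leaders(decomp: WaveletDecomposition) -> LeaderSet:
    """Leaders: sup of |coefficients| over the 3-neighbourhood dyadic tree.

    Computed bottom-up: s(j, k) is the sup over interval (j, k) and all its
    descendants (children (j-1, 2k) and (j-1, 2k+1)); the leader at (j, k)
    is max(s(j, k-1), s(j, k), s(j, k+1)).  Positions whose neighbourhood or
    descendants fall outside the decomposed range are dropped.
    """
    n_levels = decomp.n_levels
    sup_tree: dict[int, np.ndarray] = {}
    for j in range(1, n_levels + 1):
        absd = np.abs(decomp.coefficients[j])
        if j == 1:
            sup_tree[j] = absd
            continue
        prev = sup_tree[j - 1]
        n_k = min(len(absd), len(prev) // 2)
        children = np.maximum(prev[0 : 2 * n_k : 2], prev[1 : 2 * n_k : 2])
        sup_tree[j] = np.maximum(absd[:n_k], children)
    leaders: dict[int, np.ndarray] = {}
    for j, s in sup_tree.items():
        if len(s) < 3:
            continue
        leaders[j] = np.maximum(np.maximum(s[:-2], s[1:-1]), s[2:])
    return LeaderSet(
        leaders=leaders,
        wavelet_name=decomp.wavelet_name,
        signal_length=decomp.signal_length,
    )


def default_fit_range(signal_length: int, leaders: LeaderSet) -> tuple[int, int]:
    """Scales j1=3 .. floor(log2 N) - 3, clipped to scales that actually have leaders."""
    usable = sorted(
        j for j, arr in leaders.leaders.items() if np.sum(arr > 0) >= MIN_COEFFS_PER_SCALE
    )
    if not usable:
        raise ValueError("no usable scales for fitting")
    j1 = max(3, usable[0])
    j2 = min(int(np.floor(np.log2(signal_length))) - 3, usable[-1])
    return j1, j2


def _fit_scales(
    leaders: LeaderSet, fit_scale_range: tuple[int, int] | None
) -> tuple[list[int], tuple[int, int]]:
    if fit_scale_range is None:
        fit_scale_range = default_fit_range(leaders.signal_length, leaders)
    j1, j2 = fit_scale_range
    scales = [
        j
        for j in sorted(leaders.leaders)
        if j1 <= j <= j2 and np.sum(leaders.leaders[j] > 0) >= MIN_COEFFS_PER_SCALE
    ]
    if len(scales) < 3:
        raise ValueError(
            f"need at least 3 usable scales in the fit range {fit_scale_range}, "
            f"got {len(scales)}"
        )
    return scales, (j1, j2)


def _wls_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted least-squares slope of y on x."""
    w = w / w.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    return float(np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2))


def structure_functions(
    leaders: LeaderSet,
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
    fit_scale_range: tuple[int, int] | None = None,
) -> StructureScaling:
    """S_L(q, j) and the scaling exponents zeta(q).

    zeta(q) is the linear slope of log2 S_L(q, j) against j over the fitted
    scale range, each scale weighted equally; with L1 normalisation,
    monofractal fBm(H) gives zeta(q) ~= qH.  Zero leaders are excluded
    from the averages.  Equal scale weights (rather than per-scale counts)
    keep the fine scales, where leader statistics are biased for rough
    signals, from dominating the fit.
    """
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(q_grid == 0):
        raise ValueError("q = 0 is excluded from the moment grid")
    scales, fit_range = _fit_scales(leaders, fit_scale_range)
    n_j = {}
    S = np.empty((len(q_grid), len(scales)))
    for col, j in enumerate(scales):
        lj = leaders.leaders[j]
        lj = lj[lj > 0]
        n_j[j] = len(lj)
        S[:, col] = np.mean(lj[None, :] ** q_grid[:, None], axis=1)
    jarr = np.array(scales, dtype=float)
    weights = np.ones(len(scales))
    zeta = np.array([_wls_slope(jarr, np.log2(S[i]), weights) for i in range(len(q_grid))])
    return StructureScaling(
        q_grid=q_grid, S=S, scales=np.array(scales), zeta=zeta,
        fit_scale_range=fit_range, n_j=n_j,
    )


def legendre_spectrum(
    scaling: StructureScaling, h_grid: tuple[float, ...] = DEFAULT_H_GRID
) -> SingularitySpectrum:
    """D(h) = inf over the q grid of (1 + q h - zeta(q)); c1, c2 attached.

    The infimum is taken exactly over the discrete q grid; non-finite zeta
    values are excluded.  D(h) <= 1 always (the q -> 0 limit).
    """
    h_grid = np.asarray(h_grid, dtype=float)
    finite = np.isfinite(scaling.zeta)
    q = scaling.q_grid[finite]
    zeta = scaling.zeta[finite]
    if len(q) == 0:
        raise ValueError("no finite scaling exponents")
    # D(h) for each h: min over q of 1 + q h - zeta(q)
    D = 1.0 + np.min(np.outer(h_grid, q) - zeta[None, :], axis=1)
    # Quadratic summary of zeta for (c1, c2) consistency with the spectrum.
    c1, c2 = _cumulants_from_zeta(q, zeta)
    return SingularitySpectrum(h_grid=h_grid, D=D, c1=c1, c2=c2)


def _cumulants_from_zeta(q: np.ndarray, zeta: np.ndarray) -> tuple[float, float]:
    # zeta(q) ~ c1 q + (c2/2) q^2 (least squares, no intercept).
    A = np.stack([q, q**2 / 2.0], axis=1)
    coef, *_ = np.linalg.lstsq(A, zeta, rcond=None)
    return float(coef[0]), float(coef[1])


def log_cumulants(
    leaders: LeaderSet, fit_scale_range: tuple[int, int] | None = None
) -> tuple[float, float]:
    """(c1, c2) from the scaling of the sample cumulants of ln L_X(j, .).

    c_p = log2(e) x slope of the p-th sample cumulant of ln L across j,
    each fitted scale weighted equally.  For fBm(H): c1 ~= H, c2 ~= 0; for
    an MRW with volatility parameter lambda^2: c2 ~= -lambda^2.
    """
    scales, _ = _fit_scales(leaders, fit_scale_range)
    means, variances, counts = [], [], []
    for j in scales:
        lj = leaders.leaders[j]
        lj = lj[lj > 0]
        logl = np.log(lj)
        v = np.var(logl, ddof=1)
        if not np.isfinite(v) or v == 0.0:
            raise ValueError(f"degenerate leader distribution at scale {j}")
        means.append(np.mean(logl))
        variances.append(v)
        counts.append(len(lj))
    jarr = np.array(scales, dtype=float)
    w = np.ones(len(scales))
    log2e = np.log2(np.e)
    c1 = log2e * _wls_slope(jarr, np.array(means), w)
    c2 = log2e * _wls_slope(jarr, np.array(variances), w)
    return float(c1), float(c2)


def analyze_series(
    series: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    q_grid: tuple[float, ...] = DEFAULT_Q_GRID,
    h_grid: tuple[float, ...] = DEFAULT_H_GRID,
    fit_scale_range: tuple[int, int] | None = None,
) -> SingularitySpectrum:
    """Full pipeline for one series: DWT -> leaders -> D(h) with (c1, c2).

    The attached c1/c2 come from the log-cumulant estimator (not from the
    quadratic fit of zeta), matching the values used in the feature tables.
    """
    leaders = compute_leaders(dwt(series, wavelet_name))
    scaling = structure_functions(leaders, q_grid, fit_scale_range)
    spectrum = legendre_spectrum(scaling, h_grid)
    c1, c2 = log_cumulants(leaders, fit_scale_range)
    spectrum.c1, spectrum.c2 = c1, c2
    return spectrum


def channel_cumulants(
    samples: np.ndarray,
    wavelet_name: str = DEFAULT_WAVELET,
    fit_scale_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """(c1, c2) per row of a channels x time matrix; shape (channels, 2)."""
    samples = np.atleast_2d(samples)
    out = np.empty((samples.shape[0], 2))
    for i, row in enumerate(samples):
        leaders = compute_leaders(dwt(row, wavelet_name))
        out[i] = log_cumulants(leaders, fit_scale_range)
    return out
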