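"""Wavelet-leader machinery against hand computations and brute-force oracles."""

import numpy as np
import pytest

from eegcomplex.multifractal import (
    DEFAULT_Q_GRID,
    LeaderSet,
    WaveletDecomposition,
    analyze_series,
    compute_leaders,
    dwt,
    legendre_spectrum,
    log_cumulants,
    structure_functions,
)
from eegcomplex.synth import _mrw_batch


def brute_force_leaders(coefficients: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
    """Exhaustive sup over all dyadic intervals contained in the 3-neighbourhood.

    Interval (j, k) covers positions [k 2^j, (k+1) 2^j); the leader at (j, k)
    is the sup of |d(j', k')| over every interval at scale j' <= j contained
    in [(k-1) 2^j, (k+2) 2^j).  Positions whose neighbourhood or whose finer
    descendants extend past the available coefficients are dropped, matching
    the package's boundary policy.
    """
    scales = sorted(coefficients)
    out = {}
    for j in scales:
        vals = []
        for k in range(1, len(coefficients[j]) - 1):
            lo, hi = (k - 1) * 2**j, (k + 2) * 2**j
            candidates = []
            complete = True
            for jp in scales:
                if jp > j:
                    continue
                for kp, d in enumerate(coefficients[jp]):
                    if kp * 2**jp >= lo and (kp + 1) * 2**jp <= hi:
                        candidates.append(abs(d))
                # descendants of the neighbourhood must all be available
                if (hi // 2**jp) > len(coefficients[jp]):
                    complete = False
            if complete:
                vals.append(max(candidates))
            else:
                vals.append(np.nan)
        out[j] = np.array(vals)
    return out


class TestDwt:
    def test_constant_series_has_vanishing_details(self):
        decomp = dwt(np.full(1024, 7.0))
        for coeffs in decomp.coefficients.values():
            np.testing.assert_allclose(coeffs, 0.0, atol=1e-10)

    def test_linear_ramp_annihilated_by_two_vanishing_moments(self):
        decomp = dwt(np.linspace(0.0, 5.0, 1024))
        for coeffs in decomp.coefficients.values():
            np.testing.assert_allclose(coeffs, 0.0, atol=1e-9)

    def test_impulse_energy_confined_to_cone_of_influence(self):
        x = np.zeros(1024)
        x[512] = 1.0
        decomp = dwt(x)
        filt_len = 6  # db3 support
        for j, coeffs in decomp.coefficients.items():
            nonzero = np.abs(coeffs) > 1e-12
            # at scale j the impulse can touch at most ~filt_len positions
            assert np.sum(nonzero) <= filt_len + 2

    def test_infeasible_depth_rejected(self):
        with pytest.raises(ValueError):
            dwt(np.random.default_rng(0).standard_normal(256), n_levels=12)


class TestLeaders:
    def test_single_scale_hand_example(self):
        """Coefficients [1, -3, 2]: only the middle position has a complete
        3-neighbourhood, and its leader is sup(|1|, |-3|, |2|) = 3."""
        decomp = WaveletDecomposition(
            coefficients={1: np.array([1.0, -3.0, 2.0])},
            wavelet_name="db3", n_levels=1, signal_length=8,
        )
        leaders = compute_leaders(decomp).leaders
        np.testing.assert_array_equal(leaders[1], [3.0])

    def test_equal_coefficients_give_equal_leaders(self):
        decomp = WaveletDecomposition(
            coefficients={1: np.full(16, -2.5), 2: np.full(8, -2.5)},
            wavelet_name="db3", n_levels=2, signal_length=32,
        )
        leaders = compute_leaders(decomp).leaders
        np.testing.assert_allclose(leaders[1], 2.5)
        np.testing.assert_allclose(leaders[2], 2.5)

    def test_two_scale_toy_matches_brute_force(self, rng):
        decomp = WaveletDecomposition(
            coefficients={1: rng.standard_normal(8), 2: rng.standard_normal(4)},
            wavelet_name="db3", n_levels=2, signal_length=16,
        )
        mine = compute_leaders(decomp).leaders
        brute = brute_force_leaders(decomp.coefficients)
        for j in mine:
            keep = ~np.isnan(brute[j][: len(mine[j])])
            np.testing.assert_allclose(mine[j][keep], brute[j][: len(mine[j])][keep])

    @pytest.mark.parametrize("seed", range(5))
    def test_short_signals_match_brute_force(self, seed):
        """On signals of length <= 64 the fast tree recursion equals the
        exhaustive sup over contained dyadic intervals."""
        x = np.random.default_rng(seed).standard_normal(64)
        decomp = dwt(x)
        mine = compute_leaders(decomp).leaders
        brute = brute_force_leaders(decomp.coefficients)
        for j in mine:
            keep = ~np.isnan(brute[j][: len(mine[j])])
            np.testing.assert_allclose(mine[j][keep], brute[j][: len(mine[j])][keep])

    def test_leader_dominates_own_coefficient(self, rng):
        decomp = dwt(rng.standard_normal(2048))
        leaders = compute_leaders(decomp)
        for j, lead in leaders.leaders.items():
            own = np.abs(decomp.coefficients[j][1 : 1 + len(lead)])
            assert np.all(lead >= own - 1e-12)


class TestStructureFunctions:
    @staticmethod
    def _constant_leader_set(value=2.0):
        return LeaderSet(
            leaders={j: np.full(2 ** (10 - j), value) for j in range(1, 8)},
            signal_length=2**10,
        )

    def test_constant_leaders_are_scale_free(self):
        scaling = structure_functions(self._constant_leader_set(), q_grid=(2.0,))
        np.testing.assert_allclose(scaling.S[0], 4.0)
        assert scaling.zeta[0] == pytest.approx(0.0, abs=1e-12)

    def test_q_zero_is_excluded(self):
        with pytest.raises(ValueError):
            structure_functions(self._constant_leader_set(), q_grid=(-1.0, 0.0, 1.0))

    def test_too_few_scales_is_a_fit_error(self):
        leaders = LeaderSet(leaders={3: np.full(64, 1.0)}, signal_length=2**10)
        with pytest.raises(ValueError):
            structure_functions(leaders)

    def test_fbm_scaling_exponents_are_linear_in_q(self):
        rng = np.random.default_rng(4)
        zetas = []
        for _ in range(8):
            x = _mrw_batch(2**14, 0.7, 0.0, rng, 1)[0]
            scaling = structure_functions(compute_leaders(dwt(x)), q_grid=(1.0, 2.0))
            zetas.append(scaling.zeta)
        mean = np.mean(zetas, axis=0)
        assert mean[0] == pytest.approx(0.7, abs=0.05)
        assert mean[1] == pytest.approx(1.4, abs=0.10)

    def test_zeta_is_concave_on_the_grid(self):
        x = _mrw_batch(2**14, 0.6, 0.04, np.random.default_rng(5), 1)[0]
        scaling = structure_functions(compute_leaders(dwt(x)))
        q, zeta = scaling.q_grid, scaling.zeta
        for side in (q < 0, q > 0):  # the grid has a gap at q = 0
            qs, zs = q[side], zeta[side]
            second_diff = np.diff(zs, 2) / np.diff(qs)[:-1] ** 2
            assert np.all(second_diff < 0.02)


class TestLegendreSpectrum:
    @staticmethod
    def _scaling_from(zeta_fn):
        q = np.asarray(DEFAULT_Q_GRID)
        return type(
            "S", (), {"q_grid": q, "zeta": zeta_fn(q)}
        )()

    def test_monofractal_spectrum_peaks_at_the_single_exponent(self):
        spectrum = legendre_spectrum(self._scaling_from(lambda q: 0.7 * q))
        peak = spectrum.h_grid[np.argmax(spectrum.D)]
        assert peak == pytest.approx(0.7, abs=0.011)
        assert spectrum.D.max() == pytest.approx(1.0, abs=1e-9)

    def test_quadratic_scaling_gives_the_analytic_parabola(self):
        c1, c2 = 0.7, -0.05
        spectrum = legendre_spectrum(
            self._scaling_from(lambda q: c1 * q + 0.5 * c2 * q**2)
        )
        # the discrete transform only represents slopes |q| <= 5, i.e.
        # |h - c1| <= 5 |c2|
        inside = np.abs(spectrum.h_grid - c1) < 0.24
        expected = 1.0 + (spectrum.h_grid[inside] - c1) ** 2 / (2.0 * c2)
        np.testing.assert_allclose(spectrum.D[inside], expected, atol=2e-3)

    def test_dimension_never_exceeds_one(self, rng):
        x = rng.standard_normal(4096)
        spectrum = analyze_series(np.cumsum(x))
        assert np.all(spectrum.D <= 1.0 + 1e-9)


class TestLogCumulants:
    def test_amplitude_invariance_is_exact(self, rng):
        x = np.cumsum(rng.standard_normal(8192))
        leaders_a = compute_leaders(dwt(x))
        leaders_b = compute_leaders(dwt(50.0 * x))
        np.testing.assert_allclose(
            log_cumulants(leaders_a), log_cumulants(leaders_b), atol=1e-9
        )

    def test_degenerate_leader_distribution_is_a_fit_error(self):
        leaders = LeaderSet(
            leaders={j: np.full(2 ** (10 - j), 1.0) for j in range(1, 8)},
            signal_length=2**10,
        )
        with pytest.raises(ValueError):
            log_cumulants(leaders)

    def test_c1_agrees_with_spectrum_peak(self):
        """The cumulant c1 and argmax_h D(h) locate the same exponent."""
        rng = np.random.default_rng(6)
        for _ in range(5):
            x = _mrw_batch(2**13, 0.65, 0.02, rng, 1)[0]
            spectrum = analyze_series(x)
            peak = spectrum.h_grid[np.argmax(spectrum.D)]
            assert peak == pytest.approx(spectrum.c1, abs=0.1)
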