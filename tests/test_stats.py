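"""Group statistics: BH step-up, mixed ANOVA (vs pingouin), ANCOVA, post-hocs."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from statsmodels.stats.multitest import multipletests

from eegcomplex.stats import (
    ancova_covariate,
    bh_mask,
    family_size,
    mixed_anova,
    n_electrode_pairs,
    posthoc_ttests,
    spearman_ns_complexity,
)


def brute_force_bh(p, q):
    """Literal step-up definition: reject H_(1..k) for the largest k with
    p_(k) <= k q / n."""
    p = np.asarray(p)
    n = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, n + 1):
        if p[order[k - 1]] <= k * q / n:
            k_star = k
    mask = np.zeros(n, dtype=bool)
    mask[order[:k_star]] = True
    return mask


class TestBenjaminiHochberg:
    def test_hand_example(self):
        mask = bh_mask(np.array([0.001, 0.01, 0.02, 0.9]), q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_no_rejections_when_all_p_are_one(self):
        assert not bh_mask(np.ones(10)).any()

    @settings(derandomize=True, max_examples=200)
    @given(
        hst.lists(hst.floats(0.0, 1.0), min_size=1, max_size=20),
        hst.floats(0.01, 0.2),
    )
    def test_matches_brute_force_step_up(self, p, q):
        np.testing.assert_array_equal(bh_mask(np.array(p), q), brute_force_bh(p, q))

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 30))
            ours = bh_mask(p, 0.05)
            theirs = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(ours, theirs)


class TestFamilySizes:
    def test_published_comparison_families(self):
        assert n_electrode_pairs(16) == 120
        assert family_size("channel") == 16
        assert family_size("channel_scale") == 480
        assert family_size("pair_band") == 600
        assert family_size("channel_band") == 80

    def test_unknown_scope_rejected(self):
        with pytest.raises(ValueError):
            family_size("voxel")


def _two_group_data(rng, n1=12, n2=8, k=6, shift=0.0, scale=None):
    data = rng.standard_normal((n1 + n2, k))
    if scale is not None:
        data = data @ np.diag(scale)
    data[n1:] += shift
    groups = np.array(["younger"] * n1 + ["older"] * n2)
    return data, groups


class TestMixedAnova:
    def test_group_and_interaction_match_pingouin(self, rng):
        data, groups = _two_group_data(rng, scale=[1, 2, 0.5, 1.5, 1, 0.8])
        data[groups == "older", 2] += 1.2
        ours = {r.effect: r for r in mixed_anova(data, groups, ("node",))}
        df = pd.DataFrame(
            {
                "score": data.ravel(),
                "subject": np.repeat(np.arange(len(groups)), data.shape[1]),
                "node": np.tile(np.arange(data.shape[1]), len(groups)),
                "group": np.repeat(groups, data.shape[1]),
            }
        )
        ref = pg.mixed_anova(
            df, dv="score", within="node", subject="subject", between="group"
        ).set_index("Source")
        assert ours["group"].F == pytest.approx(ref.loc["group", "F"], rel=1e-9)
        assert ours["group"].p == pytest.approx(ref.loc["group", "p_unc"], rel=1e-9)
        assert ours["group"].partial_eta2 == pytest.approx(
            ref.loc["group", "np2"], rel=1e-9
        )
        assert ours["group x node"].F == pytest.approx(
            ref.loc["Interaction", "F"], rel=1e-9
        )

    def test_compound_symmetry_gives_epsilon_near_one(self, rng):
        # exchangeable covariance: iid noise plus a subject random effect
        n, k = 60, 5
        data = rng.standard_normal((n, k)) + rng.standard_normal((n, 1))
        groups = np.array(["younger"] * 30 + ["older"] * 30)
        res = {r.effect: r for r in mixed_anova(data, groups)}
        assert res["group x node"].epsilon > 0.85

    def test_large_group_shift_is_detected_with_big_effect_size(self, rng):
        data, groups = _two_group_data(rng, n1=25, n2=25, k=16, shift=1.5)
        res = {r.effect: r for r in mixed_anova(data, groups)}
        assert res["group"].p < 0.001
        assert res["group"].partial_eta2 > 0.3

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(77)
        rejections = 0
        reps = 200
        for _ in range(reps):
            data, groups = _two_group_data(rng, n1=32, n2=18, k=16)
            res = {r.effect: r for r in mixed_anova(data, groups)}
            rejections += res["group"].p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_three_way_layout_reports_all_interactions(self, rng):
        data = rng.standard_normal((20, 4, 3))
        groups = np.array(["younger"] * 12 + ["older"] * 8)
        res = mixed_anova(data, groups, ("node", "scale"))
        effects = [r.effect for r in res]
        assert effects == [
            "group",
            "group x node",
            "group x scale",
            "group x node x scale",
        ]
        for r in res:
            assert 0.0 <= r.partial_eta2 <= 1.0 and 0.0 < r.epsilon <= 1.0

    def test_partial_eta_squared_matches_hand_computation(self):
        """Two groups x 3 within levels, computed with textbook sums of squares."""
        data = np.array(
            [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [5.0, 5.0, 6.0], [6.0, 7.0, 7.0]]
        )
        groups = np.array(["younger", "younger", "older", "older"])
        k = 3
        subj_means = data.mean(axis=1)
        grand = subj_means.mean()
        gm = [subj_means[:2].mean(), subj_means[2:].mean()]
        ss_group = k * (2 * (gm[0] - grand) ** 2 + 2 * (gm[1] - grand) ** 2)
        ss_err = k * (
            np.sum((subj_means[:2] - gm[0]) ** 2) + np.sum((subj_means[2:] - gm[1]) ** 2)
        )
        expected = ss_group / (ss_group + ss_err)
        res = {r.effect: r for r in mixed_anova(data, groups)}
        assert res["group"].partial_eta2 == pytest.approx(expected, rel=1e-12)

    def test_missing_cells_are_a_hard_error(self, rng):
        data, groups = _two_group_data(rng)
        data[3, 2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova(data, groups)


class TestAncova:
    def test_uncorrelated_covariate_barely_moves_the_group_f(self, rng):
        data, groups = _two_group_data(rng, n1=32, n2=18, k=16, shift=0.8)
        cov = rng.standard_normal(50)
        plain = {r.effect: r for r in mixed_anova(data, groups)}
        adj = {r.effect: r for r in ancova_covariate(data, groups, cov)}
        assert adj["group"].F == pytest.approx(plain["group"].F, rel=0.10)

    def test_fully_mediated_group_difference_vanishes(self, rng):
        n1, n2, k = 25, 25, 8
        cov = np.r_[rng.standard_normal(n1), 3.0 + rng.standard_normal(n2)]
        data = cov[:, None] + 0.3 * rng.standard_normal((n1 + n2, k))
        groups = np.array(["younger"] * n1 + ["older"] * n2)
        plain = {r.effect: r for r in mixed_anova(data, groups)}
        adj = {r.effect: r for r in ancova_covariate(data, groups, cov)}
        assert plain["group"].p < 0.001
        assert adj["group"].p > 0.05

    def test_constant_covariate_rejected(self, rng):
        data, groups = _two_group_data(rng)
        with pytest.raises(ValueError):
            ancova_covariate(data, groups, np.full(len(groups), 2.0))


class TestPosthoc:
    def test_welch_t_matches_scipy_per_column(self, rng):
        from scipy import stats as ss

        a, b = rng.standard_normal((10, 5)), rng.standard_normal((14, 5)) + 0.5
        res = posthoc_ttests(a, b)
        for col in range(5):
            t, p = ss.ttest_ind(a[:, col], b[:, col], equal_var=False)
            assert res.t_values[col] == pytest.approx(t)
            assert res.raw_p[col] == pytest.approx(p)

    def test_family_size_guard(self, rng):
        a, b = rng.standard_normal((5, 10)), rng.standard_normal((5, 10))
        with pytest.raises(ValueError, match="family"):
            posthoc_ttests(a, b, expected_family=16)

    def test_family_type_one_error_is_controlled(self):
        """On null cohorts the chance of any BH-significant channel stays low."""
        rng = np.random.default_rng(5)
        any_hit = 0
        reps = 200
        for _ in range(reps):
            a, b = rng.standard_normal((32, 16)), rng.standard_normal((18, 16))
            any_hit += posthoc_ttests(a, b).significant.any()
        assert any_hit / reps <= 0.10


class TestSpearman:
    def test_monotone_transform_gives_perfect_correlation(self, rng):
        ns = rng.uniform(0.1, 0.9, size=(20, 16))
        index = np.exp(3 * ns)  # strictly increasing transform
        r, corr = spearman_ns_complexity(ns, index)
        np.testing.assert_allclose(r, 1.0)
        assert corr.significant.all()

    def test_sign_flip_negates_r_exactly(self, rng):
        ns = rng.uniform(size=(15, 4))
        index = rng.uniform(size=(15, 4))
        r_pos, _ = spearman_ns_complexity(ns, index)
        r_neg, _ = spearman_ns_complexity(-ns, index)
        np.testing.assert_allclose(r_neg, -r_pos)

    def test_independent_features_show_no_systematic_correlation(self):
        rng = np.random.default_rng(8)
        clean = 0
        mean_abs_r = []
        reps = 50
        for _ in range(reps):
            ns = rng.standard_normal((32, 16))
            index = rng.standard_normal((32, 16))
            r, corr = spearman_ns_complexity(ns, index)
            mean_abs_r.append(np.mean(np.abs(r)))
            clean += not corr.significant.any()
        assert np.mean(mean_abs_r) < 0.2
        assert clean / reps >= 0.9

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            spearman_ns_complexity(rng.uniform(size=(3, 16)), rng.uniform(size=(3, 16)))
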