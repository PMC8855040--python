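"""Group statistics for the two-group (younger vs older) design.

* Mixed-design repeated-measures ANOVA: one between-subjects factor (age
  group) and one or two within-subjects factors (electrode, temporal
  scale), with Greenhouse-Geisser sphericity correction of the degrees of
  freedom and partial eta squared effect sizes.  The within-subject strata
  are analysed through orthonormal contrast scores, which makes the
  Greenhouse-Geisser epsilon the standard Box estimate
  (tr S)^2 / (q tr S^2) on the pooled contrast covariance and extends
  naturally to the three-way group x electrode x scale layout.
* ANCOVA variant: a subject-level covariate (e.g. gamma-band relative
  power) is partialled out of every stratum by regression before the group
  terms are assessed.
* Post-hoc Welch two-sample t-tests with Benjamini-Hochberg FDR control
  over the full comparison family (per-channel, per-channel-x-scale,
  per-pair-x-band, or per-channel-x-band).
* Spearman rank correlations between node strength and the complexity
  indices, BH-corrected over the 16 electrodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as ss


@dataclass
class AnovaResult:
    effect: str
    F: float
    p: float
    partial_eta2: float
    df: tuple[float, float]  # after Greenhouse-Geisser correction
    epsilon: float


@dataclass
class CorrectedComparisons:
    t_values: np.ndarray
    raw_p: np.ndarray
    significant: np.ndarray
    q_threshold: float = 0.05


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------


def bh_mask(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``.

    Rejects the hypotheses with the k smallest p-values, where k is the
    largest rank with p_(k) <= k q / n.
    """
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, n + 1) * q / n)
    mask = np.zeros(n, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        mask[order[: k + 1]] = True
    return mask


def n_electrode_pairs(n_channels: int) -> int:
    """Number of unordered electrode pairs (the pairwise-PLI family size)."""
    return n_channels * (n_channels - 1) // 2


def family_size(scope: str, n_channels: int = 16, n_scales: int = 30, n_bands: int = 5) -> int:
    """Comparison-family sizes for the four post-hoc scopes."""
    if scope == "channel":
        return n_channels
    if scope == "channel_scale":
        return n_channels * n_scales
    if scope == "pair_band":
        return n_electrode_pairs(n_channels) * n_bands
    if scope == "channel_band":
        return n_channels * n_bands
    raise ValueError(f"unknown scope {scope!r}")


# ---------------------------------------------------------------------------
# Mixed-design repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal basis of the space orthogonal to the constant."""
    basis = np.linalg.svd(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    return basis


def _gg_epsilon(pooled_cov: np.ndarray) -> float:
    q = pooled_cov.shape[0]
    if q == 1:
        return 1.0
    tr = np.trace(pooled_cov)
    eps = tr**2 / (q * np.sum(pooled_cov**2))
    return float(np.clip(eps, 1.0 / q, 1.0))


def _group_indices(groups: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(groups == g) for g in np.unique(groups)]


def mixed_anova(
    data: np.ndarray,
    groups: np.ndarray,
    within_names: tuple[str, ...] = ("node",),
) -> list[AnovaResult]:
    """Group effect and group x within interactions of a split-plot design.

    ``data`` is subjects x levels (one within factor) or subjects x
    levels1 x levels2 (two within factors, e.g. electrode x scale);
    ``groups`` labels each subject's row.  All subjects must have every
    within cell (NaNs are a hard error naming the offending cells).

    Returns the between-group main effect plus one interaction per within
    effect (including the two-factor interaction for the three-way layout),
    each with Greenhouse-Geisser-corrected degrees of freedom, p-value and
    partial eta squared.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise ValueError("data must be subjects x levels (x levels2)")
    if not np.all(np.isfinite(data)):
        bad = np.argwhere(~np.isfinite(data))
        raise ValueError(f"missing/non-finite cells at (subject, level, ...): {bad[:5]}")
    n_subjects, k1, k2 = data.shape
    if len(groups) != n_subjects:
        raise ValueError("groups length does not match data")
    idx = _group_indices(groups)
    n_groups = len(idx)
    if n_groups < 2:
        raise ValueError("need at least two groups")
    flat = data.reshape(n_subjects, k1 * k2)
    k = k1 * k2

    results: list[AnovaResult] = []

    # Between-subjects stratum: subject means, weighted by cell count.
    subj_means = flat.mean(axis=1)
    grand = subj_means.mean()
    group_means = np.array([subj_means[i].mean() for i in idx])
    ss_group = k * sum(len(i) * (gm - grand) ** 2 for i, gm in zip(idx, group_means))
    ss_subj = k * sum(
        np.sum((subj_means[i] - gm) ** 2) for i, gm in zip(idx, group_means)
    )
    df_group, df_subj = n_groups - 1, n_subjects - n_groups
    f_group = (ss_group / df_group) / (ss_subj / df_subj)
    results.append(
        AnovaResult(
            effect="group",
            F=float(f_group),
            p=float(ss.f.sf(f_group, df_group, df_subj)),
            partial_eta2=float(ss_group / (ss_group + ss_subj)),
            df=(float(df_group), float(df_subj)),
            epsilon=1.0,
        )
    )

    # Within-subject strata via orthonormal contrasts.
    c1 = _orthonormal_contrasts(k1)
    ones1 = np.full((k1, 1), 1.0 / np.sqrt(k1))
    effects: list[tuple[str, np.ndarray]] = []
    if k2 == 1:
        effects.append((f"group x {within_names[0]}", c1))
    else:
        c2 = _orthonormal_contrasts(k2)
        ones2 = np.full((k2, 1), 1.0 / np.sqrt(k2))
        effects.append((f"group x {within_names[0]}", np.kron(c1, ones2)))
        effects.append((f"group x {within_names[1]}", np.kron(ones1, c2)))
        effects.append(
            (f"group x {within_names[0]} x {within_names[1]}", np.kron(c1, c2))
        )

    for name, contrast in effects:
        scores = flat @ contrast  # subjects x q
        q = scores.shape[1]
        t_group_means = np.stack([scores[i].mean(axis=0) for i in idx])
        t_grand = scores.mean(axis=0)
        ss_inter = sum(
            len(i) * np.sum((tm - t_grand) ** 2)
            for i, tm in zip(idx, t_group_means)
        )
        resid = np.concatenate(
            [scores[i] - tm[None, :] for i, tm in zip(idx, t_group_means)]
        )
        ss_err = np.sum(resid**2)
        pooled_cov = resid.T @ resid / df_subj
        eps = _gg_epsilon(pooled_cov)
        df1, df2 = df_group * q, df_subj * q
        f_val = (ss_inter / df1) / (ss_err / df2)
        results.append(
            AnovaResult(
                effect=name,
                F=float(f_val),
                p=float(ss.f.sf(f_val, eps * df1, eps * df2)),
                partial_eta2=float(ss_inter / (ss_inter + ss_err)),
                df=(eps * df1, eps * df2),
                epsilon=eps,
            )
        )
    return results


def ancova_covariate(
    data: np.ndarray,
    groups: np.ndarray,
    covariate: np.ndarray,
    within_names: tuple[str, ...] = ("node",),
) -> list[AnovaResult]:
    """Mixed ANOVA with a subject-level covariate partialled from every stratum.

    The covariate (one value per subject) is entered as a regressor in the
    between-subjects stratum (classic split-plot ANCOVA on subject means)
    and removed from each within-stratum contrast score before the group
    terms are assessed; each adjustment spends one error degree of freedom.
    """
    data = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    cov = np.asarray(covariate, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    n_subjects, k1, k2 = data.shape
    if cov.shape != (n_subjects,):
        raise ValueError("covariate must hold one value per subject")
    if np.std(cov) == 0:
        raise ValueError("covariate has zero variance")
    flat = data.reshape(n_subjects, k1 * k2)
    k = k1 * k2
    idx = _group_indices(groups)
    n_groups = len(idx)
    cov_c = cov - cov.mean()

    def _rss(y: np.ndarray, X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    dummies = np.zeros((n_subjects, n_groups - 1))
    for gi, i in enumerate(idx[1:]):
        dummies[i, gi] = 1.0

    results: list[AnovaResult] = []
    ones = np.ones((n_subjects, 1))
    subj_means = flat.mean(axis=1)
    X_red = np.column_stack([ones, cov_c])
    X_full = np.column_stack([ones, cov_c, dummies])
    rss_red = _rss(subj_means, X_red)
    rss_full = _rss(subj_means, X_full)
    ss_group = k * (rss_red - rss_full)
    ss_err = k * rss_full
    df_group = n_groups - 1
    df_err = n_subjects - n_groups - 1
    f_group = (ss_group / df_group) / (ss_err / df_err)
    results.append(
        AnovaResult(
            effect="group",
            F=float(f_group),
            p=float(ss.f.sf(f_group, df_group, df_err)),
            partial_eta2=float(ss_group / (ss_group + ss_err)),
            df=(float(df_group), float(df_err)),
            epsilon=1.0,
        )
    )

    c1 = _orthonormal_contrasts(k1)
    ones1 = np.full((k1, 1), 1.0 / np.sqrt(k1))
    effects: list[tuple[str, np.ndarray]] = []
    if k2 == 1:
        effects.append((f"group x {within_names[0]}", c1))
    else:
        c2 = _orthonormal_contrasts(k2)
        ones2 = np.full((k2, 1), 1.0 / np.sqrt(k2))
        effects.append((f"group x {within_names[0]}", np.kron(c1, ones2)))
        effects.append((f"group x {within_names[1]}", np.kron(ones1, c2)))
        effects.append(
            (f"group x {within_names[0]} x {within_names[1]}", np.kron(c1, c2))
        )

    for name, contrast in effects:
        scores = flat @ contrast
        q = scores.shape[1]
        ss_inter = 0.0
        ss_err_w = 0.0
        resid_cols = []
        for col in range(q):
            y = scores[:, col]
            rss_red = _rss(y, X_red)
            rss_full = _rss(y, X_full)
            ss_inter += rss_red - rss_full
            ss_err_w += rss_full
            beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
            resid_cols.append(y - X_full @ beta)
        resid = np.stack(resid_cols, axis=1)
        pooled_cov = resid.T @ resid / df_err
        eps = _gg_epsilon(pooled_cov)
        df1, df2 = df_group * q, df_err * q
        f_val = (ss_inter / df1) / (ss_err_w / df2)
        results.append(
            AnovaResult(
                effect=name,
                F=float(f_val),
                p=float(ss.f.sf(f_val, eps * df1, eps * df2)),
                partial_eta2=float(ss_inter / (ss_inter + ss_err_w)),
                df=(eps * df1, eps * df2),
                epsilon=eps,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Post-hoc comparisons and correlations
# ---------------------------------------------------------------------------


def posthoc_ttests(
    group_a: np.ndarray,
    group_b: np.ndarray,
    q_threshold: float = 0.05,
    expected_family: int | None = None,
) -> CorrectedComparisons:
    """Welch two-sample t per comparison column, BH-corrected over the family.

    ``group_a``/``group_b`` are subjects x comparisons; the family is the
    full set of columns (flattened if multi-dimensional), matching the
    published family sizes (16, 480, 600, or 80).  ``expected_family``
    guards against scope mistakes.
    """
    a = np.asarray(group_a, dtype=float).reshape(len(group_a), -1)
    b = np.asarray(group_b, dtype=float).reshape(len(group_b), -1)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups have different comparison families")
    if expected_family is not None and a.shape[1] != expected_family:
        raise ValueError(
            f"family has {a.shape[1]} comparisons, expected {expected_family}"
        )
    t, p = ss.ttest_ind(a, b, axis=0, equal_var=False)
    return CorrectedComparisons(
        t_values=np.asarray(t),
        raw_p=np.asarray(p),
        significant=bh_mask(np.asarray(p), q_threshold),
        q_threshold=q_threshold,
    )


def spearman_ns_complexity(
    node_strength: np.ndarray,
    complexity_index: np.ndarray,
    q_threshold: float = 0.05,
) -> tuple[np.ndarray, CorrectedComparisons]:
    """Per-channel Spearman R between NS and a complexity index in one group.

    ``node_strength`` and ``complexity_index`` are subjects x channels for
    the same subjects; ties are handled by average ranks.  Returns the R
    values and the BH-corrected comparison family over channels.
    """
    ns = np.asarray(node_strength, dtype=float)
    ci = np.asarray(complexity_index, dtype=float)
    if ns.shape != ci.shape:
        raise ValueError("arrays must align subject x channel")
    if ns.shape[0] < 4:
        raise ValueError("need at least 4 subjects per group")
    r = np.empty(ns.shape[1])
    p = np.empty(ns.shape[1])
    for ch in range(ns.shape[1]):
        r[ch], p[ch] = ss.spearmanr(ns[:, ch], ci[:, ch])
    comparisons = CorrectedComparisons(
        t_values=r,  # R-scores play the role of the test statistic here
        raw_p=p,
        significant=bh_mask(p, q_threshold),
        q_threshold=q_threshold,
    )
    return r, comparisons


def electrode_pair_labels(channel_labels: tuple[str, ...]) -> list[tuple[str, str]]:
    return list(combinations(channel_labels, 2))
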