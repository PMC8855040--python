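"""Aging classification: PCA-inside-CV logistic regression and ROC/AUC.

Feature blocks (per-channel c1, |c2|, fast-scale sample entropy, and
band-wise PLI node strength) are concatenated into a standardized subject x
feature matrix.  Classification accuracy is the AUC of a logistic
regression on the first principal components, with the PCA fitted on the
training folds only (fitting it on all subjects before splitting leaks the
test fold's covariance and inflates the estimate).  Each of 20 repeats of
stratified 5-fold cross-validation pools its held-out probabilities into
one ROC; the mean and SD over the 20 repeat-AUCs are reported, and feature
sets are compared by a paired t-test across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

#: Canonical feature-block names and their column prefixes in a feature table.
BLOCK_PREFIXES = {
    "c1": "c1_",
    "c2_abs": "c2abs_",
    "fast_entropy": "entropy_",
    "ns_delta": "ns_delta_",
    "ns_theta": "ns_theta_",
    "ns_alpha": "ns_alpha_",
    "ns_beta": "ns_beta_",
    "ns_gamma": "ns_gamma_",
}

LABEL_OLDER = 1
LABEL_YOUNGER = 0


@dataclass
class FeatureSetSpec:
    name: str
    blocks: tuple[str, ...]
    n_components: int = 3

    def validate(self) -> None:
        if not self.blocks:
            raise ValueError("feature set must name at least one block")
        unknown = set(self.blocks) - set(BLOCK_PREFIXES)
        if unknown:
            raise ValueError(f"unknown feature blocks: {sorted(unknown)}")


@dataclass
class RocResult:
    name: str
    auc_mean: float
    auc_sd: float
    per_repeat_auc: np.ndarray
    folds: int
    seed: int
    #: Held-out probabilities pooled across the folds of the last repeat
    #: (kept for the Mann-Whitney internal cross-check of the ROC area).
    pooled_probabilities: np.ndarray | None = None


@dataclass
class DecisionRegion:
    axis_x: int
    axis_y: int
    x_grid: np.ndarray
    y_grid: np.ndarray
    grid: np.ndarray  # boolean mask, probability of "older" > threshold
    threshold: float = 0.9
    fixed_values: np.ndarray = field(default_factory=lambda: np.array([]))


def assemble_features(
    table: pd.DataFrame, spec: FeatureSetSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardized feature matrix and 0/1 labels (older = 1).

    ``table`` is one row per subject with a ``group`` column and the block
    columns named ``<prefix><channel>``.  Constant columns are an error
    (they carry no information and break standardization); missing values
    are reported with their subject ids.
    """
    spec.validate()
    cols: list[str] = []
    for block in spec.blocks:
        prefix = BLOCK_PREFIXES[block]
        block_cols = [c for c in table.columns if c.startswith(prefix)]
        if not block_cols:
            raise ValueError(f"feature table has no columns for block {block!r}")
        cols.extend(block_cols)
    X = table[cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        bad_rows = table.index[np.isnan(X).any(axis=1)]
        ids = table.loc[bad_rows, "subject_id"].tolist() if "subject_id" in table else list(bad_rows)
        raise ValueError(f"missing feature values for subjects: {ids}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        flat = [cols[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant feature columns: {flat}")
    X = (X - X.mean(axis=0)) / sd
    if spec.n_components > X.shape[1]:
        raise ValueError("n_components exceeds the feature count")
    y = (table["group"].to_numpy() == "older").astype(int)
    return X, y


def _fold_model(n_components: int, n_train: int) -> tuple[PCA, LogisticRegression]:
    # Small ridge penalty lambda ~ 1/n for numerical stability at n ~ 50.
    return PCA(n_components=n_components), LogisticRegression(C=float(n_train))


def cv_auc(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    repeats: int = 20,
    folds: int = 5,
    seed: int = 0,
    name: str = "",
    fit_log: list | None = None,
) -> RocResult:
    """Mean and SD of the AUC over repeated stratified k-fold CV.

    Within each fold the PCA and the logistic regression are fitted on the
    training subjects only; held-out predicted probabilities are pooled
    across the k folds of a repeat into a single ROC, giving one AUC per
    repeat.  Fold shuffling is seeded from (seed, repeat), so two feature
    sets evaluated with the same seed share their fold assignments and
    their per-repeat AUCs are pairable.

    ``fit_log``, if given, receives (repeat, fold, train_idx, test_idx)
    tuples — used to verify that no test row ever enters a fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < folds:
        raise ValueError("each class needs at least one subject per fold")
    per_repeat = np.empty(repeats)
    for rep in range(repeats):
        fold_seed = (seed * 100_003 + rep) % (2**31)
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=fold_seed)
        prob = np.empty(len(y))
        for fold_i, (train, test) in enumerate(splitter.split(X, y)):
            if fit_log is not None:
                fit_log.append((rep, fold_i, train.copy(), test.copy()))
            pca, clf = _fold_model(n_components, len(train))
            scores_train = pca.fit_transform(X[train])
            clf.fit(scores_train, y[train])
            prob[test] = clf.predict_proba(pca.transform(X[test]))[:, 1]
        per_repeat[rep] = roc_auc_score(y, prob)
    return RocResult(
        name=name,
        auc_mean=float(per_repeat.mean()),
        auc_sd=float(per_repeat.std(ddof=1) if repeats > 1 else 0.0),
        per_repeat_auc=per_repeat,
        folds=folds,
        seed=seed,
        pooled_probabilities=prob,
    )


def compare_auc(a: RocResult, b: RocResult) -> tuple[float, float]:
    """Paired t-test of the per-repeat AUCs of two feature sets.

    Pairing is by repeat index (identical fold assignments when the two
    results share a seed).  Identical results give (0, 1) by convention.
    """
    if len(a.per_repeat_auc) != len(b.per_repeat_auc):
        raise ValueError("results have different repeat counts")
    diff = a.per_repeat_auc - b.per_repeat_auc
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    t, p = ss.ttest_rel(a.per_repeat_auc, b.per_repeat_auc)
    return float(t), float(p)


def decision_region(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 3,
    axis_x: int = 0,
    axis_y: int = 1,
    grid_resolution: int = 100,
    threshold: float = 0.9,
    margin: float = 1.0,
) -> DecisionRegion:
    """High-confidence region for "older" over a principal-component plane.

    PCA and the logistic model are fitted on the full standardized feature
    matrix; the plane spanned by components ``axis_x`` and ``axis_y`` is
    scanned on a regular grid with every other component held at its grand
    mean, and cells with predicted P(older) > ``threshold`` are marked.
    """
    if axis_x >= n_components or axis_y >= n_components:
        raise ValueError("plane axes must be among the retained components")
    y = np.asarray(y, dtype=int)
    pca, clf = _fold_model(n_components, len(y))
    scores = pca.fit_transform(np.asarray(X, dtype=float))
    if len(np.unique(y)) < 2:
        # Degenerate training set: the model can never announce the absent
        # class, so the region is empty (all younger) or everything (all older).
        g = int(grid_resolution)
        full = bool(y[0] == LABEL_OLDER)
        return DecisionRegion(
            axis_x=axis_x, axis_y=axis_y,
            x_grid=np.linspace(-1, 1, g), y_grid=np.linspace(-1, 1, g),
            grid=np.full((g, g), full), threshold=threshold,
            fixed_values=scores.mean(axis=0),
        )
    clf.fit(scores, y)
    fixed = scores.mean(axis=0)
    x_grid = np.linspace(scores[:, axis_x].min() - margin, scores[:, axis_x].max() + margin, grid_resolution)
    y_grid = np.linspace(scores[:, axis_y].min() - margin, scores[:, axis_y].max() + margin, grid_resolution)
    pts = np.tile(fixed, (grid_resolution * grid_resolution, 1))
    xx, yy = np.meshgrid(x_grid, y_grid)
    pts[:, axis_x] = xx.ravel()
    pts[:, axis_y] = yy.ravel()
    prob = clf.predict_proba(pts)[:, 1].reshape(grid_resolution, grid_resolution)
    return DecisionRegion(
        axis_x=axis_x,
        axis_y=axis_y,
        x_grid=x_grid,
        y_grid=y_grid,
        grid=prob > threshold,
        threshold=threshold,
        fixed_values=fixed,
    )
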