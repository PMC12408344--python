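"""Linking fermentation features to chocolate sensory attributes.

The abiotic (temperature/pH kinetics) and biotic (taxon growth) features
are first min-max rescaled, then de-duplicated: pairwise Pearson
correlations between features are clustered hierarchically (Ward
linkage, Euclidean distances between feature-wise correlation vectors)
and each cluster is represented by its most variable member (highest
coefficient of variation on the raw values).  For every sensory
attribute (panel scores on a 0-10 scale) a regression random forest is
then fitted on the representatives, and each feature's importance is
measured as %IncMSE: the percentage increase in out-of-bag mean squared
error when that feature is permuted within each tree's out-of-bag
samples, averaged over trees and normalized by the baseline OOB MSE.

The forest is built from scikit-learn decision trees with explicit
bootstrap/out-of-bag bookkeeping so that every permutation used in the
importance computation is recorded and replayable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "FeatureClusters",
    "ImportanceMap",
    "RFConfig",
    "PermutationForest",
    "rescale01",
    "pearson_pvalue_matrix",
    "corr_cluster",
    "select_representatives",
    "rf_importance",
    "importance_map",
]


def rescale01(matrix: pd.DataFrame) -> pd.DataFrame:
    """Min-max rescale each column to [0, 1]; constant columns map to 0.

    Idempotent: applying it to an already-rescaled matrix is the
    identity.
    """
    out = {}
    for col in matrix.columns:
        x = matrix[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"column {col!r} has non-finite values")
        lo, hi = x.min(), x.max()
        out[col] = np.zeros_like(x) if hi == lo else (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=matrix.index)


def pearson_pvalue_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Pearson r and two-sided p-values between feature columns.

    p-values come from t = r sqrt((n-2)/(1-r^2)) against Student's t
    with n-2 degrees of freedom; |r| = 1 gives p = 0 in the limit.
    """
    X = matrix.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 instances for correlation p-values")
    r = np.corrcoef(X, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    np.fill_diagonal(p, 0.0)
    cols = matrix.columns
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass(frozen=True)
class FeatureClusters:
    correlation: pd.DataFrame
    pvalues: pd.DataFrame
    linkage_tree: np.ndarray
    assignment: dict           # feature -> cluster id (1-based)
    cv: dict                   # feature -> coefficient of variation (raw scale)
    representatives: tuple     # one feature per cluster, sorted by cluster id
    n_clusters: int
    dropped: tuple = ()        # zero-variance features excluded before clustering


def _silhouette_k(coords: np.ndarray, features) -> int:
    """Default cut: the k in [2, n-1] maximizing mean silhouette."""
    n = coords.shape[0]
    Z = linkage(coords, method="ward")
    best_k, best_s = 2, -np.inf
    for k in range(2, n):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(set(labels)) < 2:
            continue
        s = silhouette_score(coords, labels)
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    return best_k


def corr_cluster(
    matrix: pd.DataFrame,
    k: int | None = None,
    height: float | None = None,
    raw_matrix: pd.DataFrame | None = None,
) -> FeatureClusters:
    """Cluster features by the similarity of their correlation profiles.

    Ward linkage on Euclidean distances between rows of the Pearson
    correlation matrix (each feature's vector of correlations with all
    features).  The tree is cut at ``k`` clusters, at ``height``, or, if
    neither is given, at the silhouette-maximizing cluster count.
    Zero-variance features are excluded with a warning.  ``raw_matrix``
    (pre-rescaling values) is used for the coefficient of variation;
    defaults to ``matrix`` itself.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 features to cluster")
    X = matrix.to_numpy(dtype=float)
    variances = X.var(axis=0)
    dropped = tuple(matrix.columns[variances == 0])
    if dropped:
        warnings.warn(f"excluding zero-variance feature(s): {list(dropped)}")
        matrix = matrix.drop(columns=list(dropped))
        if matrix.shape[1] < 2:
            raise ValueError("fewer than 2 features left after dropping constants")

    r, p = pearson_pvalue_matrix(matrix)
    coords = r.to_numpy()
    Z = linkage(coords, method="ward")

    features = list(matrix.columns)
    if k is not None:
        labels = fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = fcluster(Z, t=height, criterion="distance")
    else:
        labels = fcluster(Z, t=_silhouette_k(coords, features), criterion="maxclust")
    assignment = dict(zip(features, (int(l) for l in labels)))

    raw = matrix if raw_matrix is None else raw_matrix[features]
    cv = {}
    for f in features:
        x = raw[f].to_numpy(dtype=float)
        mean = x.mean()
        cv[f] = float(x.std(ddof=1) / mean) if mean != 0 else np.nan

    reps = _pick_representatives(assignment, cv)
    return FeatureClusters(
        correlation=r, pvalues=p, linkage_tree=Z, assignment=assignment,
        cv=cv, representatives=reps, n_clusters=len(set(assignment.values())),
        dropped=dropped,
    )


def _pick_representatives(assignment: dict, cv: dict) -> tuple:
    """Max-CV member per cluster; NaN CV deprioritized; ties break to the
    lexicographically first feature name."""
    reps = []
    for cid in sorted(set(assignment.values())):
        members = sorted(f for f, c in assignment.items() if c == cid)
        scored = [(not np.isnan(cv[f]), -np.inf if np.isnan(cv[f]) else cv[f], f) for f in members]
        # valid CV first, then largest CV, then earliest name
        scored.sort(key=lambda s: (-s[0], -s[1], s[2]))
        reps.append(scored[0][2])
    return tuple(reps)


def select_representatives(
    clusters: FeatureClusters, raw_matrix: pd.DataFrame | None = None
) -> tuple:
    """One representative per cluster: the member with the highest
    coefficient of variation (computed on pre-normalization values).

    Zero-mean features have undefined CV and are deprioritized.
    """
    if raw_matrix is None:
        return clusters.representatives
    cv = {}
    for f in clusters.assignment:
        x = raw_matrix[f].to_numpy(dtype=float)
        mean = x.mean()
        cv[f] = float(x.std(ddof=1) / mean) if mean != 0 else np.nan
    return _pick_representatives(clusters.assignment, cv)


# ---------------------------------------------------------------------------
# random forest permutation importance (%IncMSE)

@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 500
    mtry: int | None = None     # default: max(n_features // 3, 1)
    min_samples_leaf: int = 5
    seed: int = 0


@dataclass
class PermutationForest:
    """Bootstrap forest with recorded OOB permutations.

    ``records`` holds, per tree, the bootstrap and OOB indices, the
    baseline OOB error, and the exact permutation applied to each
    feature, so reported importances can be reproduced from the frozen
    forest without re-running the estimator.
    """

    config: RFConfig
    trees: list = field(default_factory=list)
    records: list = field(default_factory=list)
    baseline_oob_mse: float = np.nan
    oob_r2: float = np.nan
    importances: np.ndarray | None = None
    feature_names: tuple = ()

    def fit_importance(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 5:
            raise ValueError("need at least 5 instances")
        if np.ptp(y) == 0:
            warnings.warn("constant response: all importances defined as 0")
            self.importances = np.zeros(p)
            self.baseline_oob_mse = 0.0
            self.oob_r2 = np.nan
            return self.importances

        mtry = cfg.mtry or max(p // 3, 1)
        rng = np.random.default_rng(cfg.seed)
        deltas = np.zeros((cfg.n_trees, p))
        base_errs = []
        oob_pred_sum = np.zeros(n)
        oob_pred_cnt = np.zeros(n)

        for b in range(cfg.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                min_samples_leaf=cfg.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            rec = {"boot": boot, "oob": oob, "perms": {}, "oob_mse": np.nan}
            if oob.size == 0:
                self.records.append(rec)
                continue
            Xo = X[oob]
            pred = tree.predict(Xo)
            err = float(np.mean((pred - y[oob]) ** 2))
            rec["oob_mse"] = err
            base_errs.append(err)
            oob_pred_sum[oob] += pred
            oob_pred_cnt[oob] += 1
            for j in range(p):
                perm = rng.permutation(oob.size)
                rec["perms"][j] = perm
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                err_j = float(np.mean((tree.predict(Xp) - y[oob]) ** 2))
                deltas[b, j] = err_j - err
            self.records.append(rec)

        self.baseline_oob_mse = float(np.mean(base_errs))
        seen = oob_pred_cnt > 0
        if seen.sum() >= 2:
            oob_pred = oob_pred_sum[seen] / oob_pred_cnt[seen]
            ss_res = float(np.sum((y[seen] - oob_pred) ** 2))
            ss_tot = float(np.sum((y[seen] - y[seen].mean()) ** 2))
            self.oob_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        if self.baseline_oob_mse == 0:
            self.importances = np.zeros(p)
        else:
            self.importances = 100.0 * deltas.mean(axis=0) / self.baseline_oob_mse
        return self.importances


def rf_importance(
    X: pd.DataFrame, y: pd.Series | np.ndarray, config: RFConfig | None = None
) -> tuple[pd.Series, PermutationForest]:
    """%IncMSE of each feature for one sensory attribute.

    Fits a bootstrap regression forest and reports, per feature,
    100 * mean over trees of (OOB MSE after permuting the feature within
    the tree's OOB set - OOB MSE before) / baseline OOB MSE.
    """
    cfg = config or RFConfig()
    forest = PermutationForest(config=cfg)
    forest.feature_names = tuple(X.columns)
    imp = forest.fit_importance(X.to_numpy(dtype=float), np.asarray(y, dtype=float))
    return pd.Series(imp, index=X.columns, name=getattr(y, "name", None)), forest


@dataclass(frozen=True)
class ImportanceMap:
    """%IncMSE for every (sensory attribute, feature) pair."""

    table: pd.DataFrame        # attributes x features
    oob_r2: pd.Series          # per attribute
    seed: int

    def clustered_order(self) -> tuple[list, list]:
        """Row/column order from Ward clustering of the importance matrix."""
        from scipy.cluster.hierarchy import leaves_list

        M = self.table.to_numpy(dtype=float)
        rows = list(self.table.index)
        cols = list(self.table.columns)
        if len(rows) > 2:
            rows = [rows[i] for i in leaves_list(linkage(M, method="ward"))]
        if len(cols) > 2:
            cols = [cols[i] for i in leaves_list(linkage(M.T, method="ward"))]
        return rows, cols


def importance_map(
    X: pd.DataFrame, sensory: pd.DataFrame, config: RFConfig | None = None
) -> ImportanceMap:
    """One forest per sensory attribute over the representative features.

    Each attribute's forest is seeded deterministically from the base
    seed so the full map is reproducible.
    """
    cfg = config or RFConfig()
    rows, r2 = {}, {}
    for i, attr in enumerate(sensory.columns):
        attr_cfg = RFConfig(
            n_trees=cfg.n_trees, mtry=cfg.mtry,
            min_samples_leaf=cfg.min_samples_leaf,
            seed=cfg.seed + 1009 * i,
        )
        imp, forest = rf_importance(X, sensory[attr], attr_cfg)
        rows[attr] = imp
        r2[attr] = forest.oob_r2
    table = pd.DataFrame(rows).T
    table.index.name = "attribute"
    return ImportanceMap(table=table, oob_r2=pd.Series(r2), seed=cfg.seed)
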