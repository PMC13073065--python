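"""Hierarchical clustering of interaction profiles with a BIC-optimal cut.

Gene profiles are the adjusted z-score vectors (adjK2, adjK3, adjL2,
adjL3); the unperturbed z-scores (z_K1, z_L1) may be carried along for
display but never enter the distance computation. Features are used
unscaled -- they are already z-standardized upstream, so distances keep the
screen's effect-size semantics.

The tree is cut at every candidate k and scored with the BIC of a
hard-assignment Gaussian model: per-cluster mean vectors, a single pooled
spherical variance, and (by default) multinomial mixing proportions. The
proportion (entropy) term is what lets the criterion resist the spurious
variance reduction any balanced split of a single Gaussian produces;
without it a hard cut always looks better than k = 1. The means-only
variant is available via ``mixing_term=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = ["adjK2", "adjK3", "adjL2", "adjL3"]
DISPLAY_COLUMNS = ["z_K1", "z_L1"]

DEFAULT_K_MAX = 60


@dataclass
class ProfileMatrix:
    """Feature matrix for clustering plus display-only context columns."""

    features: pd.DataFrame          # rows: gene entries; cols: FEATURE_COLUMNS
    display: pd.DataFrame | None    # aligned unperturbed z-scores, display only
    dropped: list[str] = field(default_factory=list)
    imputed: list[str] = field(default_factory=list)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)


@dataclass
class ClusterAssignment:
    labels: pd.Series               # entry -> cluster label in 1..k
    k: int
    tree: np.ndarray                # scipy linkage matrix
    bic_curve: pd.DataFrame         # columns k, bic


def build_profile_matrix(
    interaction_table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    max_missing_fraction: float = 0.5,
) -> ProfileMatrix:
    """Assemble the clustering matrix from a scored screen.

    Rows with more than ``max_missing_fraction`` missing features are
    dropped (and logged); remaining gaps are imputed with the feature's
    median across retained rows.
    """
    cols = feature_columns or [c for c in FEATURE_COLUMNS if c in interaction_table.columns]
    if interaction_table.empty or not cols:
        raise ValueError("empty screen: no interaction profiles to cluster")
    df = interaction_table.copy()
    if "entry" not in df.columns:
        if {"array", "row", "col"} <= set(df.columns):
            df["entry"] = [
                f"{s}@{a}:{r}.{c}"
                for s, a, r, c in zip(df["strain"], df["array"], df["row"], df["col"])
            ]
        else:
            df["entry"] = df["strain"]
    df = df.set_index("entry")
    feats = df[cols].astype(float)
    miss_frac = feats.isna().mean(axis=1)
    dropped = list(feats.index[miss_frac > max_missing_fraction])
    if dropped:
        logger.info("dropping %d profiles with >%.0f%% missing features: %s",
                    len(dropped), 100 * max_missing_fraction, dropped[:10])
    feats = feats.loc[miss_frac <= max_missing_fraction]
    imputed = list(feats.index[feats.isna().any(axis=1)])
    if imputed:
        logger.info("median-imputing %d profiles with missing features", len(imputed))
        feats = feats.fillna(feats.median())
    display_cols = [c for c in DISPLAY_COLUMNS if c in df.columns]
    display = df.loc[feats.index, display_cols] if display_cols else None
    return ProfileMatrix(features=feats, display=display, dropped=dropped, imputed=imputed)


def hierarchical_cluster(
    matrix: ProfileMatrix, method: str = "ward", metric: str = "euclidean"
) -> np.ndarray:
    """Deterministic agglomerative tree (scipy linkage matrix)."""
    X = matrix.X
    if X.shape[0] < 2:
        raise ValueError("need at least two profiles to cluster")
    if not np.all(np.isfinite(X)):
        bad = matrix.features.index[~np.isfinite(X).all(axis=1)][0]
        raise ValueError(f"non-finite feature after imputation for entry {bad!r}")
    if metric == "correlation":
        return linkage(pdist(X, metric="correlation"), method=method)
    return linkage(X, method=method, metric=metric)


def _bic_for_labels(
    X: np.ndarray,
    labels: np.ndarray,
    mixing_term: bool,
    pooled_variance: bool,
    sigma2_floor: float = 0.0,
) -> float:
    n, d = X.shape
    uniq = np.unique(labels)
    k = uniq.size
    rss = 0.0
    entropy = 0.0
    per_cluster_var_terms = 0.0
    for u in uniq:
        grp = X[labels == u]
        nj = grp.shape[0]
        mu = grp.mean(axis=0)
        rj = float(((grp - mu) ** 2).sum())
        rss += rj
        if mixing_term:
            entropy += nj * np.log(nj / n)
        if not pooled_variance:
            var_j = max(rj / (nj * d), 1e-12)
            per_cluster_var_terms += nj * d * np.log(var_j)
    if pooled_variance:
        if k >= n:
            return np.inf
        # df-corrected pooled variance: the k*d fitted means consume k
        # degrees of freedom per coordinate, which is what cuts that only
        # isolate duplicate/near-duplicate rows exploit
        sigma2 = rss / ((n - k) * d)
        if k > 1 and sigma2 <= sigma2_floor:
            return np.inf  # degenerate cut (duplicate rows): likelihood unbounded
        sigma2 = max(sigma2, 1e-300)
        ll = entropy - 0.5 * n * d * (np.log(2 * np.pi * sigma2) + 1.0)
        n_var = 1
    else:
        ll = entropy - 0.5 * (per_cluster_var_terms + n * d * (np.log(2 * np.pi) + 1.0))
        n_var = k
    p = k * d + n_var + (k - 1 if mixing_term else 0)
    return float(-2.0 * ll + p * np.log(n * d))


def _resolution_floor(X: np.ndarray) -> float:
    """Pooled-variance floor at the data's nearest-distinct-neighbor scale.

    A tree cut whose pooled within-cluster variance falls below the typical
    spacing between *distinct* profiles is no longer resolving biological
    structure -- it is isolating duplicated or near-duplicated rows, where
    the hard-assignment Gaussian likelihood is unbounded. Such cuts are
    scored as invalid (+inf BIC).
    """
    from scipy.spatial import cKDTree

    n, d = X.shape
    k_query = min(n, 8)
    dist, _ = cKDTree(X).query(X, k=k_query)
    nn = []
    for row in dist:
        pos = row[row > 0]
        if pos.size:
            nn.append(pos[0])
    if not nn:
        return 0.0
    return float(np.median(np.square(nn))) / (2.0 * d)


def bic_cut(
    tree: np.ndarray,
    matrix: ProfileMatrix,
    k_max: int = DEFAULT_K_MAX,
    mixing_term: bool = True,
    pooled_variance: bool = True,
) -> ClusterAssignment:
    """Cut the tree at the BIC-optimal number of clusters.

    For each k in 1..k_max the tree is cut into k groups and scored with
    BIC = -2 lnL + p ln(n d); ties select the smallest k. ``lnL`` is the
    hard-assignment Gaussian likelihood described in the module docstring.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = matrix.X
    n = X.shape[0]
    k_max = min(k_max, n)
    sigma2_floor = _resolution_floor(X)
    ks, bics, label_sets = [], [], {}
    for k in range(1, k_max + 1):
        labels = (
            np.ones(n, dtype=int) if k == 1 else fcluster(tree, t=k, criterion="maxclust")
        )
        bic = _bic_for_labels(X, labels, mixing_term, pooled_variance, sigma2_floor)
        ks.append(k)
        bics.append(bic)
        label_sets[k] = labels
    curve = pd.DataFrame({"k": ks, "bic": bics})
    best_k = int(curve.loc[curve["bic"].idxmin(), "k"])  # idxmin: first minimum -> smallest k
    labels = label_sets[best_k]
    # relabel 1..k in order of first appearance for stable output
    remap = {old: new for new, old in enumerate(pd.unique(labels), start=1)}
    labels = np.array([remap[v] for v in labels])
    return ClusterAssignment(
        labels=pd.Series(labels, index=matrix.features.index, name="cluster"),
        k=int(np.unique(labels).size),
        tree=tree,
        bic_curve=curve,
    )


def cluster_report(
    assignment: ClusterAssignment, matrix: ProfileMatrix
) -> pd.DataFrame:
    """Per-cluster summary: size, feature means, enhancer/suppressor tendency.

    Tendency follows the sign of the mean adjusted L at the highest
    concentration (positive -> enhancer, negative -> suppressor), the
    drug-inhibition sign convention of the interaction model.
    """
    feats = matrix.features
    out = []
    tendency_col = feats.columns[-1] if "adjL" not in "".join(feats.columns) else (
        sorted([c for c in feats.columns if c.startswith("adjL")])[-1]
    )
    for label, idx in assignment.labels.groupby(assignment.labels).groups.items():
        sub = feats.loc[idx]
        mean_l = float(sub[tendency_col].mean())
        rec = {
            "cluster": int(label),
            "size": len(sub),
            "tendency": "enhancer" if mean_l > 0 else ("suppressor" if mean_l < 0 else "neutral"),
            "members": ";".join(map(str, idx)),
        }
        for c in feats.columns:
            rec[f"mean_{c}"] = float(sub[c].mean())
        out.append(rec)
    return pd.DataFrame(out).sort_values("cluster").reset_index(drop=True)
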