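"""Behavioral profiles and PC1-loading-weighted hierarchical clustering.

A behavioral profile is the named 125-parameter vector per mouse or per
group: 15 tracking-derived + 52 pose-derived parameters, plus 29
syllable usage frequencies and 29 syllable mean durations.  Because
several parameters are near-redundant (e.g. speed and burst share
variance), parameters are weighted by their loading on the first
principal component before clustering: profiles are z-scored, each
parameter is multiplied by |PC1 loading| / max |PC1 loading|, and the
weighted vectors are clustered with Ward's method on Euclidean
distances (Ward.D2 convention: squared-increment criterion).

The estimator :class:`PC1WeightedWard` packages the whole procedure in
scikit-learn form; the module-level functions are thin wrappers over
it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA as _SKPCA

from .behavior import POSE_PARAM_IDS, POSE_PREFIX, TRACK_PARAM_IDS, TRACK_PREFIX
from .syllables import SYLLABLE_IDS

#: canonical profile key order: tracking block, pose block, syllable
#: frequencies, syllable durations (125 keys)
PROFILE_KEYS: tuple[str, ...] = (
    tuple(f"{TRACK_PREFIX}:{k}" for k in TRACK_PARAM_IDS)
    + tuple(f"{POSE_PREFIX}:{k}" for k in POSE_PARAM_IDS)
    + tuple(f"f{s}" for s in SYLLABLE_IDS)
    + tuple(f"d{s}" for s in SYLLABLE_IDS)
)

N_PROFILE_PARAMS = len(PROFILE_KEYS)  # 15 + 52 + 29 + 29 = 125


def assemble_profiles(
    track_table: pd.DataFrame,
    pose_table: pd.DataFrame,
    syllable_table: pd.DataFrame,
    groups: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Concatenate the three parameter blocks into per-mouse profiles.

    Parameters
    ----------
    track_table, pose_table, syllable_table : DataFrame
        One row per mouse; columns are the 15 tracking ids, the 52 pose
        ids, and the 58 f*/d* syllable entries respectively (prefixed
        tracking/pose ids are also accepted).
    groups : Series
        Mouse id -> group label.

    Returns
    -------
    profiles : DataFrame, (n_mice, 125)
    group_profiles : DataFrame, (n_groups, 125)
        Per-parameter means over the mice of each group.
    imputed : DataFrame of bool
        True where an undefined entry was imputed by its group mean.
    """
    for name, tab in (
        ("tracking", track_table),
        ("pose", pose_table),
        ("syllable", syllable_table),
    ):
        if tab is None or len(tab) == 0:
            raise ValueError(f"missing {name} parameter block")
    trk = track_table.rename(
        columns=lambda c: c if c.startswith(TRACK_PREFIX) else f"{TRACK_PREFIX}:{c}"
    )
    pos = pose_table.rename(
        columns=lambda c: c if c.startswith(POSE_PREFIX) else f"{POSE_PREFIX}:{c}"
    )
    prof = pd.concat([trk, pos, syllable_table], axis=1)
    missing = [k for k in PROFILE_KEYS if k not in prof.columns]
    if missing:
        raise ValueError(f"profile is missing parameters: {missing[:5]}...")
    prof = prof[list(PROFILE_KEYS)]
    groups = groups.reindex(prof.index)
    if groups.isna().any():
        raise ValueError("every mouse needs a group label")

    imputed = prof.isna()
    if imputed.any().any():
        group_means = prof.groupby(groups).transform("mean")
        prof = prof.where(~imputed, group_means)
        still = prof.isna()
        if still.any().any():  # whole group undefined: fall back to grand mean
            prof = prof.where(~still, prof.mean())
    group_profiles = prof.groupby(groups).mean()
    return prof, group_profiles, imputed


# ---------------------------------------------------------------------------
# PCA and weights
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    loadings: pd.DataFrame                 # (n_components, n_params)
    explained_variance_ratio: np.ndarray
    scores: pd.DataFrame                   # (n_profiles, n_components)
    dropped: list[str]                     # zero-variance parameters


def standardize(profiles: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise z-scores (sample sd); zero-variance columns untouched."""
    sd = profiles.std(ddof=ddof)
    sd = sd.replace(0.0, np.nan)
    return (profiles - profiles.mean()) / sd


def pca(profiles: pd.DataFrame, standardize_input: bool = True) -> PCAResult:
    """Principal axes of the (standardized) profile matrix.

    Zero-variance parameters are dropped with a warning.  Loadings are
    sign-fixed so each component's largest-magnitude loading is
    positive.  Requires at least 3 profiles.
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 profiles")
    var = profiles.var(ddof=1)
    dropped = list(profiles.columns[(var == 0) | var.isna()])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance parameter(s)")
    data = profiles.drop(columns=dropped)
    x = standardize(data).to_numpy() if standardize_input else data.to_numpy(float)
    n_comp = min(x.shape[0] - 1, x.shape[1])
    model = _SKPCA(n_components=n_comp)
    scores = model.fit_transform(x)
    loadings = model.components_
    for i in range(n_comp):  # sign convention
        j = np.argmax(np.abs(loadings[i]))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    comp_index = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=comp_index, columns=data.columns),
        explained_variance_ratio=model.explained_variance_ratio_,
        scores=pd.DataFrame(scores, index=profiles.index, columns=comp_index),
        dropped=dropped,
    )


def pc1_weights(result: PCAResult | pd.DataFrame, mode: str = "abs") -> pd.Series:
    """Per-parameter weights from the PC1 loadings.

    ``abs`` (default): |loading| / max |loading|; ``squared``:
    loading^2 / max loading^2; ``raw``: loading / max |loading|
    (signed).  Dropped parameters get weight 0.
    """
    loadings = result.loadings if isinstance(result, PCAResult) else result
    pc1 = loadings.loc["PC1"]
    scale = pc1.abs().max()
    if not np.isfinite(scale) or scale == 0:
        raise ValueError("PC1 loadings are all zero")
    if mode == "abs":
        w = pc1.abs() / scale
    elif mode == "squared":
        w = pc1**2 / scale**2
    elif mode == "raw":
        w = pc1 / scale
    else:
        raise ValueError("mode must be 'abs', 'squared' or 'raw'")
    if isinstance(result, PCAResult) and result.dropped:
        w = pd.concat([w, pd.Series(0.0, index=result.dropped)])
    return w


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------


class PC1WeightedWard(BaseEstimator, ClusterMixin):
    """Ward clustering of z-scored profiles weighted by PC1 loadings.

    Parameters
    ----------
    n_clusters : int, default 3
        Number of flat clusters cut from the dendrogram.
    weight_mode : {"abs", "squared", "raw", "none"}, default "abs"
        How PC1 loadings become weights; "none" skips weighting
        entirely (plain Ward on z-scores).
    standardize : bool, default True
        Z-score parameters before weighting.
    weights : array-like or None
        Precomputed per-parameter weights; overrides ``weight_mode``.

    Attributes
    ----------
    labels_ : flat cluster labels (0-based) of the fitted profiles
    weights_ : per-parameter weights actually used
    linkage_ : scipy linkage matrix (Ward)
    leaf_order_ : dendrogram leaf order (indices into the input rows)
    explained_variance_ratio_ : PCA explained-variance ratios
    loadings_ : PCA loadings (components x parameters)
    """

    def __init__(
        self,
        n_clusters: int = 3,
        weight_mode: str = "abs",
        standardize: bool = True,
        weights=None,
    ):
        self.n_clusters = n_clusters
        self.weight_mode = weight_mode
        self.standardize = standardize
        self.weights = weights

    def fit(self, X, y=None):
        X = pd.DataFrame(X).astype(float)
        if self.n_clusters > len(X):
            raise ValueError("n_clusters cannot exceed the number of profiles")
        z = standardize(X) if self.standardize else X
        z = z.fillna(0.0)  # zero-variance parameters carry no signal

        if self.weights is not None:
            w = pd.Series(np.asarray(self.weights, float), index=X.columns)
            self.loadings_ = None
            self.explained_variance_ratio_ = None
        elif self.weight_mode == "none":
            w = pd.Series(1.0, index=X.columns)
            self.loadings_ = None
            self.explained_variance_ratio_ = None
        else:
            res = pca(X, standardize_input=self.standardize)
            self.loadings_ = res.loadings
            self.explained_variance_ratio_ = res.explained_variance_ratio
            w = pc1_weights(res, mode=self.weight_mode).reindex(X.columns).fillna(0.0)
        if (np.asarray(w) < 0).any():
            raise ValueError("weights must be non-negative")
        self.weights_ = w

        weighted = z * w
        self.weighted_matrix_ = weighted
        self.linkage_ = hierarchy.ward(weighted.to_numpy())
        self.leaf_order_ = hierarchy.leaves_list(self.linkage_)
        self.labels_ = (
            hierarchy.fcluster(self.linkage_, t=self.n_clusters, criterion="maxclust")
            - 1
        )
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.index_ = X.index
        return self


# ---------------------------------------------------------------------------
# functional wrappers and reporting
# ---------------------------------------------------------------------------


def weighted_cluster(
    profiles: pd.DataFrame,
    weights: pd.Series | None = None,
    k: int = 3,
    standardize_input: bool = True,
) -> PC1WeightedWard:
    """Weighted Ward clustering; computes PC1 weights when none given."""
    est = PC1WeightedWard(
        n_clusters=k,
        standardize=standardize_input,
        weights=None if weights is None else weights.reindex(profiles.columns).to_numpy(),
    )
    return est.fit(profiles)


def cluster_report(est: PC1WeightedWard, labels=None) -> dict:
    """Leaf ordering, per-cluster membership, and the weighted matrix."""
    names = list(labels) if labels is not None else list(est.index_)
    leaf_names = [names[i] for i in est.leaf_order_]
    members: dict[int, list] = {}
    for name, lab in zip(names, est.labels_):
        members.setdefault(int(lab), []).append(name)
    matrix = est.weighted_matrix_.iloc[est.leaf_order_]
    return {"leaf_order": leaf_names, "clusters": members, "matrix": matrix}


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(linkage)

    def recurse(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"
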