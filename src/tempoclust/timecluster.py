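"""Temporal-profile clustering of differentially expressed genes.

The central computation of the package. Genes called differentially
expressed at any age are pooled into a union set; each gene's log2
fold-change profile across the ordered ages is standardized by its maximum
absolute fold-change (constraining values to [-1, 1] so that *shape*, not
magnitude, drives similarity); profiles are clustered hierarchically under
1 - Pearson correlation distance; the tree is cut at a fixed height; and two
filters produce the final clusters: genes correlating poorly with their
cluster centroid are removed, then clusters left with too few genes are
dropped entirely.

Defaults follow the analysis being modeled: adjusted p < 0.1 for the union,
cut height 1.6, centroid correlation >= 0.5, minimum 30 genes per cluster.
The linkage method is a parameter (default ``complete``, the default of the
classic ``hclust`` routine).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ValidationError

__all__ = [
    "ClusterParams",
    "Dendrogram",
    "ClusterAssignment",
    "union_profiles",
    "standardize",
    "correlation_distance",
    "hcluster",
    "cut",
    "filter_by_centroid",
    "filter_by_size",
    "cluster_profiles",
    "recurrent_gene_report",
]

LINKAGES = ("complete", "average", "single", "ward")

STATUS_RETAINED = "retained"
STATUS_FILTERED_CORR = "filtered_corr"
STATUS_FILTERED_SIZE = "filtered_size"


@dataclass
class ClusterParams:
    """Thresholds of the clustering stage (defaults mirror the modeled analysis)."""

    adjp_threshold: float = 0.1
    cut_height: float = 1.6
    min_centroid_corr: float = 0.5
    min_cluster_size: int = 30
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if self.cut_height < 0:
            raise ValueError("cut_height must be >= 0")
        if not (-1.0 <= self.min_centroid_corr <= 1.0):
            raise ValueError("min_centroid_corr must lie in [-1, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.linkage not in LINKAGES:
            raise ValueError(f"linkage must be one of {LINKAGES}")


def union_profiles(
    de: pd.DataFrame,
    params: ClusterParams | None = None,
    timepoints: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Log2 fold-change profiles of the union of per-age DE genes.

    Rows are exactly the genes with adjusted p below the threshold at one or
    more timepoints; columns hold the fold-changes at *all* timepoints,
    including non-significant ones — the temporal shape needs every age.
    """
    params = params or ClusterParams()
    if timepoints is None:
        timepoints = tuple(dict.fromkeys(de["timepoint"]))
    wide_fc = de.pivot(index="gene_id", columns="timepoint", values="log2fc")[list(timepoints)]
    wide_adjp = de.pivot(index="gene_id", columns="timepoint", values="adjp")[list(timepoints)]
    if wide_fc.isna().any().any():
        raise ValidationError("DE table is incomplete: missing gene x timepoint entries")
    sig_any = (wide_adjp < params.adjp_threshold).any(axis=1)
    if not sig_any.any():
        raise ValidationError(
            f"no gene reaches adjp < {params.adjp_threshold} at any timepoint; union is empty"
        )
    return wide_fc.loc[sig_any]


def standardize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's profile by its maximum absolute fold-change.

    Every retained row attains +/-1 at some timepoint. All-zero rows (possible
    only with degenerate DE input) carry no shape and are dropped with a
    warning.
    """
    vals = np.ascontiguousarray(profiles.to_numpy(dtype=float))
    maxabs = np.max(np.abs(vals), axis=1)
    zero = maxabs == 0.0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero fold-change profile(s) before standardization"
        )
        profiles = profiles.loc[~zero]
        vals = vals[~zero]
        maxabs = maxabs[~zero]
    return pd.DataFrame(vals / maxabs[:, None], index=profiles.index, columns=profiles.columns)


def _pairwise_correlation(vals: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix with a fixed zero-variance convention.

    A constant profile has no defined correlation; it is set to 0 against
    every non-constant profile, and between two constant profiles to 1 when
    their constant values share a sign (identical shape) and 0 otherwise.
    This keeps identical flat profiles together without producing NaNs.
    """
    centered = vals - vals.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    const = norms == 0.0
    safe = np.where(const, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    if const.any():
        corr[const, :] = 0.0
        corr[:, const] = 0.0
        ci = np.where(const)[0]
        sign = np.sign(vals[ci].mean(axis=1))
        same = sign[:, None] == sign[None, :]
        corr[np.ix_(ci, ci)] = np.where(same, 1.0, 0.0)
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def correlation_distance(profiles: pd.DataFrame) -> pd.DataFrame:
    """1 - Pearson correlation distance matrix, range [0, 2], zero diagonal."""
    if profiles.shape[0] < 2:
        raise ValidationError("need at least 2 profiles")
    if profiles.shape[1] < 2:
        raise ValidationError("need at least 2 timepoints")
    d = 1.0 - _pairwise_correlation(np.ascontiguousarray(profiles.to_numpy(dtype=float)))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float round-off
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


@dataclass
class Dendrogram:
    """Agglomeration result: scipy-format merge matrix plus leaf labels.

    ``merges`` row i joins clusters ``left`` and ``right`` (ids < n are
    leaves, id n+i is the cluster created by row i) at ``height`` into a
    cluster of ``size`` leaves.
    """

    merges: np.ndarray  # (n-1, 4): left, right, height, size
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def max_height(self) -> float:
        return float(self.merges[:, 2].max()) if len(self.merges) else 0.0

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]


def hcluster(distances: pd.DataFrame, linkage: str = "complete") -> Dendrogram:
    """Agglomerative clustering of a precomputed distance matrix."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if (d < -1e-10).any():
        raise ValidationError("distances must be nonnegative")
    condensed = squareform(np.clip(d, 0.0, None), checks=False)
    Z = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(merges=Z, labels=list(distances.index))


def cut(dendrogram: Dendrogram, height: float) -> pd.Series:
    """Flat clusters from all merges strictly below the cut height.

    A merge at exactly the cut height is *not* applied (implementations
    differ here; the strict rule is fixed for reproducibility). Cluster ids
    are assigned 1..k by decreasing size, ties broken by the smallest member
    index. ``height`` 0 therefore yields one singleton per leaf.
    """
    if height < 0:
        raise ValueError("cut height must be >= 0")
    n = dendrogram.n_leaves
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, (left, right, h, _size) in enumerate(dendrogram.merges):
        if h < height:
            new_id = n + i
            parent[find(int(left))] = new_id
            parent[find(int(right))] = new_id
    roots = [find(i) for i in range(n)]
    members: dict[int, list[int]] = {}
    for leaf, root in enumerate(roots):
        members.setdefault(root, []).append(leaf)
    ordered = sorted(members.values(), key=lambda m: (-len(m), m[0]))
    labels = np.empty(n, dtype=int)
    for cid, mem in enumerate(ordered, start=1):
        labels[mem] = cid
    return pd.Series(labels, index=dendrogram.labels, name="preliminary_cluster")


def _corr_to_centroid(profile: np.ndarray, centroid: np.ndarray) -> float:
    """Pearson correlation with the module's zero-variance convention."""
    pc = profile - profile.mean()
    cc = centroid - centroid.mean()
    np_, nc = np.linalg.norm(pc), np.linalg.norm(cc)
    if np_ == 0.0 and nc == 0.0:
        return 1.0 if np.sign(profile.mean()) == np.sign(centroid.mean()) else 0.0
    if np_ == 0.0 or nc == 0.0:
        return 0.0
    return float(np.clip(pc @ cc / (np_ * nc), -1.0, 1.0))


@dataclass
class ClusterAssignment:
    """Per-gene cluster membership through the filtering stages.

    ``table`` columns: preliminary_cluster, final_cluster (<NA> when
    filtered), corr_to_centroid, status in {retained, filtered_corr,
    filtered_size}. ``centroids`` holds, per cluster label, the per-timepoint
    mean of the members' standardized profiles computed from the *unfiltered*
    preliminary membership (single-pass filtering).
    """

    table: pd.DataFrame
    centroids: pd.DataFrame = field(default_factory=pd.DataFrame)

    def final_members(self) -> dict[int, list[str]]:
        t = self.table[self.table["status"] == STATUS_RETAINED]
        return {
            int(c): list(t.index[t["final_cluster"] == c])
            for c in sorted(t["final_cluster"].dropna().unique())
        }

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    def centroids_to_tsv(self, path: str | Path) -> None:
        long = self.centroids.stack().rename("value").reset_index()
        long.columns = ["cluster", "timepoint", "value"]
        long.to_csv(path, sep="\t", index=False)


def filter_by_centroid(
    prelim: pd.Series,
    profiles: pd.DataFrame,
    params: ClusterParams | None = None,
) -> ClusterAssignment:
    """Single-pass centroid-correlation filter.

    Each preliminary cluster's centroid is the per-timepoint mean of its
    members' standardized profiles, computed once from the unfiltered
    membership; centroids are not recomputed after removal. A gene in a
    singleton cluster equals its centroid and has correlation 1 by
    convention. Genes with correlation below the threshold are marked
    ``filtered_corr``.
    """
    params = params or ClusterParams()
    profiles = profiles.loc[prelim.index]
    vals = np.ascontiguousarray(profiles.to_numpy(dtype=float))
    corr = np.empty(len(prelim))
    centroid_rows = {}
    for cid in np.sort(prelim.unique()):
        mask = (prelim == cid).to_numpy()
        centroid = vals[mask].mean(axis=0)
        centroid_rows[int(cid)] = centroid
        if mask.sum() == 1:
            corr[mask] = 1.0
        else:
            corr[mask] = [_corr_to_centroid(v, centroid) for v in vals[mask]]
    status = np.where(corr < params.min_centroid_corr, STATUS_FILTERED_CORR, STATUS_RETAINED)
    table = pd.DataFrame(
        {
            "preliminary_cluster": prelim.to_numpy(),
            "final_cluster": pd.array([pd.NA] * len(prelim), dtype="Int64"),
            "corr_to_centroid": corr,
            "status": status,
        },
        index=prelim.index,
    )
    centroids = pd.DataFrame.from_dict(centroid_rows, orient="index", columns=profiles.columns)
    centroids.index.name = "cluster"
    return ClusterAssignment(table=table, centroids=centroids)


def filter_by_size(
    assignment: ClusterAssignment,
    params: ClusterParams | None = None,
) -> ClusterAssignment:
    """Drop clusters left below the minimum size after centroid filtering.

    Surviving clusters are renumbered 1..K by decreasing post-filter size
    (ties by smallest member position). A cluster with exactly
    ``min_cluster_size`` genes is retained; one gene fewer and it is dropped.
    """
    params = params or ClusterParams()
    table = assignment.table.copy()
    surviving = table[table["status"] == STATUS_RETAINED]
    sizes = surviving.groupby("preliminary_cluster").size()
    keep = sizes[sizes >= params.min_cluster_size]
    if keep.empty:
        raise ValidationError(
            "all clusters fall below min_cluster_size after centroid filtering; "
            f"post-filter sizes were {sizes.to_dict()}"
        )
    pos = {g: i for i, g in enumerate(table.index)}
    first_member = {
        int(c): min(pos[g] for g in surviving.index[surviving["preliminary_cluster"] == c])
        for c in keep.index
    }
    order = sorted(keep.index, key=lambda c: (-int(keep[c]), first_member[int(c)]))
    relabel = {int(c): i for i, c in enumerate(order, start=1)}

    dropped = surviving["preliminary_cluster"].map(lambda c: int(c) not in relabel)
    table.loc[surviving.index[dropped], "status"] = STATUS_FILTERED_SIZE
    kept_idx = surviving.index[~dropped]
    table.loc[kept_idx, "final_cluster"] = (
        table.loc[kept_idx, "preliminary_cluster"].map(lambda c: relabel[int(c)]).astype("Int64")
    )
    centroids = assignment.centroids.loc[[int(c) for c in order]].copy()
    centroids.index = pd.Index([relabel[int(c)] for c in order], name="cluster")
    return ClusterAssignment(table=table, centroids=centroids)


def cluster_profiles(
    de: pd.DataFrame,
    params: ClusterParams | None = None,
    timepoints: tuple[str, ...] | None = None,
) -> tuple[ClusterAssignment, pd.DataFrame, Dendrogram]:
    """Full clustering stage: union -> standardize -> tree -> cut -> filters.

    Returns the final assignment, the standardized profiles it was computed
    on, and the dendrogram.
    """
    params = params or ClusterParams()
    profiles = union_profiles(de, params, timepoints)
    std = standardize(profiles)
    dist = correlation_distance(std)
    dendro = hcluster(dist, linkage=params.linkage)
    prelim = cut(dendro, params.cut_height)
    assignment = filter_by_centroid(prelim, std, params)
    assignment = filter_by_size(assignment, params)
    return assignment, std, dendro


def recurrent_gene_report(
    de: pd.DataFrame,
    params: ClusterParams | None = None,
) -> dict[int, list[str]]:
    """Genes significant in exactly k of the timepoints, for every k.

    Partitions all genes by the number of ages at which they pass the
    adjusted-p threshold; the sizes over k = 0..T sum to the gene total.
    """
    params = params or ClusterParams()
    wide = de.pivot(index="gene_id", columns="timepoint", values="adjp")
    n_tp = wide.shape[1]
    k_of = (wide < params.adjp_threshold).sum(axis=1)
    return {k: sorted(wide.index[k_of == k]) for k in range(n_tp + 1)}
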