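"""Cluster-based sexual-dichromatism detection.

Within each body region, the pooled pairwise JND matrix (chromatic dS or
achromatic dL) is clustered by UPGMA (average linkage). The resulting
tree is cut at 2..6 clusters; leaves that form singleton clusters at any
cut are treated as outliers, dropped, and the tree rebuilt once. A region
is called sexually dichromatic if some cut yields a cluster that is

  (1) >= 90 % one sex ("pct_within"),
  (2) >= 10 % of the region's samples ("pct_tot"), and
  (3) >= 2 JND on average from all other clusters ("jnd_to_rest"),

i.e. a perceptually distinct, numerically relevant, sex-specific color
patch. The smallest qualifying number of clusters is reported; regions
with no qualifying cluster at any cut are classified 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import (
    DegenerateInputError,
    DegenerateRegionError,
    ParameterError,
)
from .visual_model import DistanceMatrix

#: Default qualification thresholds: (pct_within, pct_tot, jnd).
DEFAULT_THRESHOLDS = (90.0, 10.0, 2.0)
DEFAULT_K_RANGE = (2, 6)


def upgma(d: np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a dissimilarity matrix.

    Returns a linkage matrix (n-1 rows: merged pair, merge height,
    cluster size); heights are checked to be non-decreasing.
    """
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("dissimilarity matrix must be square")
    if d.shape[0] < 2:
        raise ParameterError("need at least 2 leaves")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ParameterError("dissimilarity matrix must be symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-12):
        raise ParameterError("dissimilarity matrix must have a zero diagonal")
    condensed = d[np.triu_indices(d.shape[0], k=1)]
    Z = hierarchy.linkage(condensed, method="average")
    heights = Z[:, 2]
    if np.any(np.diff(heights) < -1e-9):
        raise ParameterError("non-monotone merge heights: malformed input")
    return Z


def cut_tree_k(Z: np.ndarray, k: int) -> np.ndarray:
    """Membership labels from cutting the tree into k clusters.

    Labels are contiguous integers starting at 0, numbered by first
    appearance in leaf order.
    """
    n = Z.shape[0] + 1
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(Z, n_clusters=k).ravel()
    _, contiguous = np.unique(labels, return_inverse=True)
    order = {}
    out = np.empty_like(contiguous)
    for i, lab in enumerate(contiguous):
        out[i] = order.setdefault(lab, len(order))
    return out


def singleton_leaves(Z: np.ndarray, k_range=DEFAULT_K_RANGE) -> set[int]:
    """Leaves forming a singleton cluster at any examined cut."""
    n = Z.shape[0] + 1
    out: set[int] = set()
    for k in range(k_range[0], min(k_range[1], n) + 1):
        labels = cut_tree_k(Z, k)
        counts = np.bincount(labels)
        for leaf in np.flatnonzero(counts[labels] == 1):
            out.add(int(leaf))
    return out


def remove_singletons(d: np.ndarray, k_max: int = 6,
                      iterate: bool = False):
    """Drop outlier leaves (singleton clusters at any cut k=2..k_max).

    Returns ``(kept_indices, excluded_indices)``. The tree is rebuilt
    once on the remainder (set ``iterate=True`` to repeat until no
    singleton remains). Raises if fewer than 4 leaves would remain.
    """
    d = np.asarray(d, float)
    kept = np.arange(d.shape[0])
    excluded: list[int] = []
    while True:
        Z = upgma(d[np.ix_(kept, kept)])
        sing = singleton_leaves(Z, (2, k_max))
        if not sing:
            break
        excluded.extend(int(kept[i]) for i in sorted(sing))
        keep_mask = np.ones(kept.size, bool)
        keep_mask[sorted(sing)] = False
        kept = kept[keep_mask]
        if kept.size < 4:
            raise DegenerateRegionError(
                f"singleton removal leaves {kept.size} samples (< 4)"
            )
        if not iterate:
            break
    return kept, excluded


@dataclass(frozen=True)
class ClusterStats:
    """Qualification statistics of one cluster at one cut."""

    k: int
    label: int
    size: int
    jnd_to_rest: float  # mean JND member vs non-member, over all pairs
    pct_tot: float  # cluster size / region total * 100
    pct_within: float  # share of the majority sex in the cluster * 100
    majority_sex: str
    pct_males: float  # % of the region's male individuals with >= 1 spectrum here
    qualifies: bool


@dataclass(frozen=True)
class RegionDichromatism:
    """Detector outcome for one region and one channel (dS or dL)."""

    region: str
    channel: str
    tree_clust: int  # smallest qualifying k; 0 = no dichromatism
    best: ClusterStats | None
    cluster_sex: str | None
    excluded_ids: list = field(default_factory=list)
    all_qualifying: list = field(default_factory=list)

    @property
    def dichromatic(self) -> bool:
        return self.tree_clust > 0


def evaluate_cluster_criteria(
    labels: np.ndarray,
    sexes: np.ndarray,
    individuals: np.ndarray,
    d: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
    k: int | None = None,
) -> list[ClusterStats]:
    """Score every cluster of one cut against the three criteria.

    ``jnd_to_rest`` is the mean JND over all member/non-member pairs;
    thresholds are inclusive (>=). ``pct_males`` is the percentage of
    male individuals in the region contributing at least one spectrum to
    the cluster.
    """
    labels = np.asarray(labels)
    sexes = np.asarray(sexes)
    individuals = np.asarray(individuals)
    d = np.asarray(d, float)
    n = labels.size
    if not (sexes.size == n == d.shape[0]):
        raise ParameterError("labels, sexes and matrix must align")
    thr_within, thr_tot, thr_jnd = thresholds
    male_inds = set(individuals[sexes == "M"])
    k = int(labels.max()) + 1 if k is None else k
    out = []
    for lab in range(int(labels.max()) + 1):
        members = labels == lab
        size = int(members.sum())
        rest = ~members
        jnd = float(d[np.ix_(members, rest)].mean()) if rest.any() else 0.0
        pct_tot = 100.0 * size / n
        m_share = 100.0 * np.mean(sexes[members] == "M")
        if m_share >= 50.0:
            majority, pct_within = "M", m_share
        else:
            majority, pct_within = "F", 100.0 - m_share
        cluster_males = set(individuals[members & (sexes == "M")])
        pct_males = (100.0 * len(cluster_males) / len(male_inds)
                     if male_inds else 0.0)
        qualifies = (pct_within >= thr_within and pct_tot >= thr_tot
                     and jnd >= thr_jnd)
        out.append(ClusterStats(k=k, label=lab, size=size, jnd_to_rest=jnd,
                                pct_tot=pct_tot, pct_within=pct_within,
                                majority_sex=majority, pct_males=pct_males,
                                qualifies=qualifies))
    return out


def _candidate_score(c: ClusterStats, thresholds) -> tuple:
    thr_within, thr_tot, thr_jnd = thresholds
    met = (int(c.pct_within >= thr_within) + int(c.pct_tot >= thr_tot)
           + int(c.jnd_to_rest >= thr_jnd))
    return (met, c.jnd_to_rest)


def detect_dichromatism(
    dm: DistanceMatrix,
    channel: str,
    thresholds=DEFAULT_THRESHOLDS,
    k_range=DEFAULT_K_RANGE,
    remove_outliers: bool = True,
) -> RegionDichromatism:
    """Full per-region detector on one channel of a DistanceMatrix.

    Requires both sexes in the region. After optional singleton removal
    the tree is cut at each k in ``k_range``; the smallest k with a
    qualifying cluster is reported (0 if none, together with the
    best-scoring non-qualifying candidate).
    """
    if dm.meta is None:
        raise ParameterError("DistanceMatrix lacks sample metadata")
    sexes = dm.meta["sex"].to_numpy()
    if len(set(sexes)) < 2:
        raise DegenerateInputError(
            f"region {dm.region!r} has a single sex; dichromatism undefined"
        )
    d = dm.channel(channel)
    individuals = dm.meta["individual_id"].to_numpy()
    ids = np.asarray(dm.ids)

    if remove_outliers:
        kept, excl = remove_singletons(d, k_max=k_range[1])
    else:
        kept, excl = np.arange(d.shape[0]), []
    d_k = d[np.ix_(kept, kept)]
    sexes_k, inds_k = sexes[kept], individuals[kept]

    Z = upgma(d_k)
    n = d_k.shape[0]
    qualifying: list[ClusterStats] = []
    best_candidate: ClusterStats | None = None
    tree_clust = 0
    for k in range(k_range[0], min(k_range[1], n) + 1):
        labels = cut_tree_k(Z, k)
        stats = evaluate_cluster_criteria(labels, sexes_k, inds_k, d_k,
                                          thresholds, k=k)
        quals = [c for c in stats if c.qualifies]
        qualifying.extend(quals)
        if quals and tree_clust == 0:
            tree_clust = k
        for c in stats:
            if best_candidate is None or (
                _candidate_score(c, thresholds)
                > _candidate_score(best_candidate, thresholds)
            ):
                best_candidate = c
    if tree_clust:
        at_k = [c for c in qualifying if c.k == tree_clust]
        best = max(at_k, key=lambda c: c.jnd_to_rest)
    else:
        best = best_candidate
    return RegionDichromatism(
        region=dm.region,
        channel=channel,
        tree_clust=tree_clust,
        best=best,
        cluster_sex=best.majority_sex if (tree_clust and best) else None,
        excluded_ids=[str(i) for i in ids[excl]] if len(excl) else [],
        all_qualifying=qualifying,
    )


def dichromatism_table(results: list[RegionDichromatism]) -> pd.DataFrame:
    """Report table: region, channel, tree_clust, JND, pct_tot,
    pct_within, pct_males."""
    rows = []
    for r in results:
        b = r.best
        rows.append({
            "region": r.region,
            "channel": r.channel,
            "tree_clust": r.tree_clust,
            "JND": b.jnd_to_rest if b else np.nan,
            "pct_tot": b.pct_tot if b else np.nan,
            "pct_within": b.pct_within if b else np.nan,
            "pct_males": b.pct_males if b else np.nan,
        })
    return pd.DataFrame(
        rows, columns=["region", "channel", "tree_clust", "JND",
                       "pct_tot", "pct_within", "pct_males"]
    )
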