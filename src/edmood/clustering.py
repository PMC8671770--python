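"""Two-stage cluster analysis of anxiety/depression scores.

Stage one is Ward's minimum-variance hierarchical agglomeration on the
(GAD-7 total, PHQ-2 total) plane.  The agglomeration schedule records, for
each merge, the cumulative within-cluster sum of squares after the merge
(the convention classic statistical packages print); the sequence is
non-decreasing and its final value equals the total sum of squares about the
grand mean.  The number of clusters k is chosen from the schedule by an
elbow rule on the coefficient differences (see :func:`detect_elbow`).

Stage two partitions the sample with seeded K-means at that k, and the
clusters are named against the standard diagnostic cutoffs (GAD-7 >= 10,
PHQ-2 >= 3): not depressed/anxious, mixed (subclinical) depression-anxiety,
moderate, and high.

The two scale totals are clustered raw, without standardization; the GAD-7's
larger range therefore dominates the distance, which matches the near-total
anxiety separation such cohorts show.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

CANONICAL_LABELS = [
    "not_depressed_or_anxious",
    "mixed_depression_anxiety",
    "moderate_depression_anxiety",
    "high_depression_anxiety",
]

GAD_CUTOFF = 10.0
PHQ_CUTOFF = 3.0

#: candidate k window for the elbow search (k in 2..DEFAULT_MAX_K)
DEFAULT_MAX_K = 15


@dataclass
class AgglomerationSchedule:
    """Stage-by-stage record of a Ward agglomeration.

    ``coefficients[s-1]`` is the cumulative within-cluster sum of squares
    after stage ``s`` (stages are 1-based, n-1 of them for n points);
    ``merged_pairs`` follows the scipy linkage convention (original points
    are 0..n-1, the cluster formed at stage s gets id n-1+s).
    """

    coefficients: np.ndarray
    merged_pairs: np.ndarray  # (n-1, 2) int
    n_points: int

    @property
    def n_stages(self) -> int:
        return len(self.coefficients)

    def first_differences(self) -> np.ndarray:
        """d[s] = coeff(s+1) - coeff(s) for stages s = 1..n-2 (1-based)."""
        return np.diff(self.coefficients)

    def to_frame(self) -> pd.DataFrame:
        d = self.first_differences()
        return pd.DataFrame(
            {
                "stage": np.arange(1, self.n_stages + 1),
                "coefficient": self.coefficients,
                "first_difference": np.concatenate([d, [np.nan]]),
            }
        )


@dataclass
class ClusterSolution:
    """A K-means partition with optional diagnostic labels.

    ``assignments`` are 1-based cluster indices; after
    :func:`label_clusters` the indices are ordered by ascending mean GAD-7
    and ``labels[i]`` names cluster ``i+1``.
    """

    k: int
    assignments: np.ndarray
    centroids: np.ndarray  # (k, 2): mean GAD-7, mean PHQ-2 per cluster
    inertia: float
    seed: int
    labels: Optional[list[str]] = None
    cutoff_flags: Optional[list[dict]] = None
    consistent: Optional[bool] = None
    warnings: list[str] = field(default_factory=list)


def _as_points(points) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (GAD-7, PHQ-2) totals")
    if np.isnan(x).any():
        raise ValueError("points contain missing values")
    return x


def ward_schedule(points) -> AgglomerationSchedule:
    """Ward's agglomeration schedule for n >= 3 points.

    scipy's Ward linkage height h at a merge satisfies h^2 = 2 * (increase in
    within-cluster SS), so the cumulative-within-SS coefficient at stage s is
    the running sum of h^2 / 2.  The final coefficient equals the total sum
    of squares about the grand mean (conservation).
    """
    x = _as_points(points)
    n = len(x)
    if n < 3:
        raise ValueError("ward_schedule requires at least 3 points")
    z = linkage(x, method="ward")
    coeff = np.cumsum(z[:, 2] ** 2 / 2.0)
    return AgglomerationSchedule(
        coefficients=coeff, merged_pairs=z[:, :2].astype(int), n_points=n
    )


#: a merge consuming more than this share of the total SS is "drastic"
DEFAULT_SHARE = 0.05


def detect_elbow(
    schedule: AgglomerationSchedule,
    n: Optional[int] = None,
    criterion: str = "share",
    max_k: int = DEFAULT_MAX_K,
    share: float = DEFAULT_SHARE,
) -> int:
    """Choose k from the agglomeration schedule's elbow.

    The elbow is the stage s* after which the coefficient difference
    d(s) = coeff(s+1) - coeff(s) "takes off"; the returned k is n - s*, the
    number of clusters in hand before the drastic merge (for the canonical
    n = 1792 schedule with its first drastic jump after stage 1788 this is
    1792 - 1788 = 4).

    ``criterion="share"`` (default)
        First-exceedance rule on explained variance: scanning the stages in
        order, s* is the first stage whose following merge consumes more
        than ``share`` (default 5%) of the total sum of squares — the
        largest k at which merging starts collapsing real structure.  The
        rule is scale-free, and deliberately not the globally largest jump:
        for nested group structures the final (2 -> 1) merge always has the
        largest absolute jump, which would return k = 2 regardless of the
        actual number of groups.
    ``criterion="absolute"``
        s* maximizes d(s) over the candidate window k in 2..``max_k``,
        earliest stage on ties.

    The share criterion falls back to the windowed argmax when no merge
    reaches the share (e.g. linear coefficient growth; the constant-
    difference tie then resolves to the earliest window stage, i.e. the
    largest candidate k).
    """
    m = schedule.n_stages
    if n is None:
        n = schedule.n_points
    if m != n - 1:
        raise ValueError(f"schedule has {m} stages; expected n-1 = {n - 1}")
    if m < 3:
        raise ValueError("cannot detect an elbow with fewer than 3 stages")
    d = schedule.first_differences()  # d[i-1] = d(s=i) = coeff(i+1) - coeff(i)
    lo_s = max(1, n - max_k)  # earliest candidate stage (k = n - lo_s <= max_k)
    hi_s = n - 2  # latest candidate stage (k = 2)
    if lo_s > hi_s:
        raise ValueError("no candidate stages in the elbow window")
    if criterion == "share":
        total_ss = schedule.coefficients[-1]
        if total_ss > 0:
            exceed = np.flatnonzero(d > share * total_ss)  # 0-based: s = i + 1
            if exceed.size:
                s_star = int(exceed[0]) + 1
                return max(2, min(n - s_star, max_k))
        criterion = "absolute"  # fall through
    if criterion == "absolute":
        idx = np.arange(lo_s - 1, hi_s)  # 0-based positions in d
        s_star = int(idx[np.argmax(d[idx])]) + 1
        return n - s_star
    raise ValueError(f"unknown elbow criterion {criterion!r}")


def ward_cut_means(points, k: int) -> np.ndarray:
    """Cluster means of the Ward tree cut at k clusters (K-means seeding aid)."""
    x = _as_points(points)
    labels = fcluster(linkage(x, method="ward"), t=k, criterion="maxclust")
    return np.vstack([x[labels == c].mean(axis=0) for c in range(1, k + 1)])


def kmeans_partition(
    points,
    k: int,
    seed: int = 0,
    restarts: int = 10,
    init: str = "plusplus",
) -> ClusterSolution:
    """Seeded K-means (Lloyd's algorithm) at a fixed k.

    ``init="plusplus"`` runs ``restarts`` k-means++ starts and keeps the
    lowest-inertia solution; ``init="ward_means"`` starts from the Ward
    k-cluster means (the classic two-stage convention), one run.  Centroids
    are recomputed as exact means of the assigned points.
    """
    x = _as_points(points)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = len(np.unique(x, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    if init == "plusplus":
        km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                    random_state=seed, tol=1e-6)
    elif init == "ward_means":
        km = KMeans(n_clusters=k, init=ward_cut_means(x, k), n_init=1, tol=1e-6)
    else:
        raise ValueError(f"unknown init {init!r}")
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # sklearn chatter on duplicate-heavy data
        km.fit(x)
    assignments = km.labels_ + 1
    centroids = np.vstack([x[assignments == c].mean(axis=0) for c in range(1, k + 1)])
    return ClusterSolution(
        k=k,
        assignments=assignments,
        centroids=centroids,
        inertia=float(km.inertia_),
        seed=seed,
    )


def label_clusters(
    solution: ClusterSolution,
    gad_cutoff: float = GAD_CUTOFF,
    phq_cutoff: float = PHQ_CUTOFF,
) -> ClusterSolution:
    """Order clusters by ascending mean GAD-7 and attach diagnostic labels.

    With k = 4 and a cutoff pattern matching the four-tier narrative (two
    clusters with both means below the GAD-7/PHQ-2 cutoffs, two at/above),
    the canonical labels are used; otherwise clusters get rank labels
    (``cluster_1`` .. ``cluster_k``) and an inconsistency warning.  Each
    cluster's position relative to both cutoffs is recorded either way.
    """
    order = np.argsort(solution.centroids[:, 0], kind="stable")
    rank_of = np.empty(solution.k, dtype=int)
    rank_of[order] = np.arange(1, solution.k + 1)
    assignments = rank_of[solution.assignments - 1]
    centroids = solution.centroids[order]
    flags = [
        {
            "mean_gad7": float(g),
            "mean_phq2": float(p),
            "gad_below_cutoff": bool(g < gad_cutoff),
            "phq_below_cutoff": bool(p < phq_cutoff),
        }
        for g, p in centroids
    ]
    warnings: list[str] = []
    if solution.k == 4:
        # four-tier narrative: two subclinical clusters below both cutoffs,
        # then moderate (anxiety at/above its cutoff; depression may sit just
        # under) and high (both at/above)
        consistent = (
            flags[0]["gad_below_cutoff"] and flags[0]["phq_below_cutoff"]
            and flags[1]["gad_below_cutoff"] and flags[1]["phq_below_cutoff"]
            and not flags[2]["gad_below_cutoff"]
            and not flags[3]["gad_below_cutoff"] and not flags[3]["phq_below_cutoff"]
        )
        if consistent:
            labels = list(CANONICAL_LABELS)
        else:
            labels = [f"cluster_{i}" for i in range(1, 5)]
            warnings.append(
                "cluster means inconsistent with the four-tier diagnostic-cutoff "
                "narrative; rank labels assigned"
            )
    else:
        consistent = False
        labels = [f"cluster_{i}" for i in range(1, solution.k + 1)]
        warnings.append(f"k={solution.k} != 4; ordinal labels assigned")
    return ClusterSolution(
        k=solution.k,
        assignments=assignments,
        centroids=centroids,
        inertia=solution.inertia,
        seed=solution.seed,
        labels=labels,
        cutoff_flags=flags,
        consistent=consistent,
        warnings=solution.warnings + warnings,
    )


def cluster_frame(ids: Sequence[str], solution: ClusterSolution) -> pd.DataFrame:
    """Per-respondent cluster output: id, cluster_index, cluster_label."""
    labels = solution.labels or [f"cluster_{i}" for i in range(1, solution.k + 1)]
    return pd.DataFrame(
        {
            "id": list(ids),
            "cluster_index": solution.assignments,
            "cluster_label": [labels[a - 1] for a in solution.assignments],
        }
    )
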