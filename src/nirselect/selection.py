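"""Calibration-subset selection in the standardized PC score space.

Two families of representative-sample selection are provided:

* **NH grouping** — a greedy reconstruction of the SELECT-style procedure:
  repeatedly seed a group at the unassigned sample with the most unassigned
  neighbours within the NH threshold, assign seed plus neighbours, and pick
  either the most central member of each group or round(sqrt(m)) spread-out
  members per group.

* **Hierarchical clustering** — agglomerative Ward linkage on squared
  Euclidean distances over the standardized scores; the dendrogram is cut at
  a percentage of its maximum merge height (D_link/D_max) and one random
  sample, or one per sqrt(m)-subcluster, is drawn from each group.

Both families also run in count-targeted mode, searching the threshold (NH)
or the cut (HC) that yields a requested number of groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage

from .spectral_space import ScoreMatrix
from .synthetic import round_half_up


@dataclass
class NHGroup:
    seed_index: int          # greedy formation seed; members are within threshold of it
    center_index: int        # member minimizing the sum of NH to the others
    member_indices: list


@dataclass
class NHGrouping:
    threshold: float
    groups: list  # of NHGroup
    sample_ids: list

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class Dendrogram:
    """Ward merge table on the squared-Euclidean (ESS) height scale.

    ``merges`` has n-1 rows (child_a, child_b, height, size) in scipy linkage
    convention: children below n are leaves, row i forms cluster n + i.
    """

    merges: np.ndarray
    n_leaves: int
    sample_ids: list

    @property
    def d_max(self) -> float:
        return float(self.merges[-1, 2]) if len(self.merges) else 0.0


@dataclass
class SelectionResult:
    method: str  # "NH" or "HC"
    params: dict
    selected_ids: list
    group_labels: np.ndarray  # group index per sample, aligned with sample_ids
    sample_ids: list

    @property
    def n_selected(self) -> int:
        return len(self.selected_ids)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected_ids)
        return pd.DataFrame(
            {
                "id": self.sample_ids,
                "group": self.group_labels,
                "selected": [s in sel for s in self.sample_ids],
            }
        )


# ---------------------------------------------------------------------------
# NH grouping

def _check_nh(nh: np.ndarray) -> np.ndarray:
    nh = np.asarray(nh, dtype=float)
    if nh.ndim != 2 or nh.shape[0] != nh.shape[1]:
        raise ValueError("NH matrix must be square")
    if not np.allclose(nh, nh.T, atol=1e-10):
        raise ValueError("NH matrix must be symmetric")
    return nh


def group_by_nh(nh: np.ndarray, threshold: float, sample_ids=None) -> NHGrouping:
    """Greedy neighbourhood grouping at the given NH threshold.

    Ties on the neighbour count break toward the smallest sample index, so
    the grouping is deterministic.
    """
    nh = _check_nh(nh)
    n = nh.shape[0]
    if sample_ids is None:
        sample_ids = list(range(n))
    neighbours = nh <= threshold
    unassigned = np.ones(n, dtype=bool)
    groups: list[NHGroup] = []
    while unassigned.any():
        counts = (neighbours & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        seed = int(np.argmax(counts))  # argmax takes the smallest index on ties
        members = np.flatnonzero(neighbours[seed] & unassigned)
        unassigned[members] = False
        sub = nh[np.ix_(members, members)]
        center = int(members[np.argmin(sub.sum(axis=1))])
        groups.append(NHGroup(seed_index=seed, center_index=center,
                              member_indices=members.tolist()))
    return NHGrouping(threshold=threshold, groups=groups, sample_ids=list(sample_ids))


def _labels_from_groups(n: int, groups) -> np.ndarray:
    labels = np.empty(n, dtype=int)
    for gi, members in enumerate(groups):
        labels[np.asarray(members, dtype=int)] = gi
    return labels


def pick_center(grouping: NHGrouping) -> SelectionResult:
    """One sample per group: the member minimizing its summed NH to the rest."""
    if not grouping.groups:
        raise ValueError("empty grouping")
    selected = [grouping.sample_ids[g.center_index] for g in grouping.groups]
    labels = _labels_from_groups(
        len(grouping.sample_ids), [g.member_indices for g in grouping.groups]
    )
    return SelectionResult(
        method="NH",
        params={"threshold": grouping.threshold, "pick": "center"},
        selected_ids=selected,
        group_labels=labels,
        sample_ids=list(grouping.sample_ids),
    )


def _maximin_picks(candidates: list, first: int, dist: np.ndarray, count: int) -> list:
    """Greedy maximin spread: start at ``first``, then repeatedly add the
    candidate farthest (by its minimum distance) from the picks so far."""
    picks = [first]
    rest = [c for c in candidates if c != first]
    while len(picks) < count and rest:
        dmin = [min(dist[c, p] for p in picks) for c in rest]
        best = int(np.argmax(dmin))  # ties -> smallest index (list order)
        picks.append(rest.pop(best))
    return picks


def pick_sqrt_n(grouping: NHGrouping, nh: np.ndarray, seed: int | None = None) -> SelectionResult:
    """round(sqrt(m)) samples per group of size m: the center first, then
    maximin additions so picks are as spread out in the group as possible."""
    nh = _check_nh(nh)
    selected = []
    for g in grouping.groups:
        m = len(g.member_indices)
        count = max(1, round_half_up(math.sqrt(m)))
        picks = _maximin_picks(sorted(g.member_indices), g.center_index, nh, count)
        selected.extend(grouping.sample_ids[i] for i in picks)
    labels = _labels_from_groups(
        len(grouping.sample_ids), [g.member_indices for g in grouping.groups]
    )
    return SelectionResult(
        method="NH",
        params={"threshold": grouping.threshold, "pick": "sqrt_n", "seed": seed},
        selected_ids=selected,
        group_labels=labels,
        sample_ids=list(grouping.sample_ids),
    )


# ---------------------------------------------------------------------------
# Ward hierarchical clustering

def ward_dendrogram(scores: ScoreMatrix) -> Dendrogram:
    """Agglomerative Ward linkage over the standardized scores.

    Merge heights are on the squared-Euclidean scale (twice the increase in
    within-cluster error sum of squares), the scale on which D_link/D_max
    percentages are read; they are non-decreasing down the table.
    """
    X = scores.scores
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    Z = linkage(X, method="ward")
    merges = Z.copy()
    merges[:, 2] = Z[:, 2] ** 2
    return Dendrogram(merges=merges, n_leaves=X.shape[0], sample_ids=list(scores.sample_ids))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _cluster_members(dend: Dendrogram) -> list:
    """Leaf sets of every internal node, indexed scipy-style (node n + i)."""
    n = dend.n_leaves
    members = [[i] for i in range(n)]
    for a, b, _, _ in dend.merges:
        members.append(members[int(a)] + members[int(b)])
    return members


def _labels_after_merges(dend: Dendrogram, n_merges: int) -> np.ndarray:
    """Group labels after applying the first ``n_merges`` merges (ascending
    height order, as in the merge table), relabelled by first occurrence."""
    uf = _UnionFind(dend.n_leaves)
    members = _cluster_members(dend)
    for i in range(n_merges):
        a, b = int(dend.merges[i, 0]), int(dend.merges[i, 1])
        uf.union(members[a][0], members[b][0])
    roots = {}
    labels = np.empty(dend.n_leaves, dtype=int)
    for i in range(dend.n_leaves):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots)
        labels[i] = roots[r]
    return labels


def cut_dendrogram(dend: Dendrogram, dlink_over_dmax_percent: float) -> np.ndarray:
    """Cut at height (percent/100) * D_max; groups are the connected
    components below the cut.  Returns a group label per sample."""
    if not (0 < dlink_over_dmax_percent <= 100):
        raise ValueError("cut percent must be in (0, 100]")
    height = dlink_over_dmax_percent / 100.0 * dend.d_max
    n_merges = int(np.sum(dend.merges[:, 2] <= height))
    return _labels_after_merges(dend, n_merges)


def _subtree_sqrt_subclusters(dend: Dendrogram, members: list) -> list:
    """Split one dendrogram group into round(sqrt(m)) subclusters by undoing
    its largest internal merges.  Returns a list of member-index lists."""
    m = len(members)
    r = max(1, min(m, round_half_up(math.sqrt(m))))
    member_set = set(members)
    node_members = _cluster_members(dend)
    internal = [
        i
        for i in range(len(dend.merges))
        if set(node_members[dend.n_leaves + i]) <= member_set
    ]
    # merges are height-ascending; keep the m - r smallest internal merges
    uf = _UnionFind(dend.n_leaves)
    for i in internal[: m - r]:
        a, b = int(dend.merges[i, 0]), int(dend.merges[i, 1])
        uf.union(node_members[a][0], node_members[b][0])
    comps: dict[int, list] = {}
    for i in members:
        comps.setdefault(uf.find(i), []).append(i)
    return list(comps.values())


def hc_pick(
    dend: Dendrogram, group_labels: np.ndarray, mode: str, seed: int | None = 0
) -> SelectionResult:
    """Pick samples from dendrogram groups.

    mode ``"one"`` — one uniformly random sample per group; mode ``"sqrt_n"``
    — cut each group's subtree into round(sqrt(m)) subclusters at its largest
    internal merge heights and take one random sample per subcluster.
    """
    if mode not in ("one", "sqrt_n"):
        raise ValueError("mode must be 'one' or 'sqrt_n'")
    rng = np.random.default_rng(seed)
    groups = [np.flatnonzero(group_labels == g).tolist() for g in np.unique(group_labels)]
    selected = []
    for members in groups:
        if mode == "one":
            pools = [members]
        else:
            pools = _subtree_sqrt_subclusters(dend, members)
        for pool in pools:
            selected.append(dend.sample_ids[int(rng.choice(pool))])
    return SelectionResult(
        method="HC",
        params={"pick": mode, "seed": seed},
        selected_ids=selected,
        group_labels=np.asarray(group_labels),
        sample_ids=list(dend.sample_ids),
    )


# ---------------------------------------------------------------------------
# count-targeted selection

def _hc_central_member(members: list, sq_dist: np.ndarray) -> int:
    sub = sq_dist[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.sum(axis=1)))])


def select_by_count(
    method: str,
    target: int,
    nh: np.ndarray | None = None,
    scores: ScoreMatrix | None = None,
    dend: Dendrogram | None = None,
    sample_ids=None,
) -> SelectionResult:
    """Select exactly ``target`` samples by tuning the grouping threshold.

    NH: smallest threshold whose greedy grouping yields ``target`` groups
    (binary search over the observed NH values; raises with the nearest
    achievable counts if ties make the target unattainable).  HC: the cut
    producing exactly ``target`` clusters.  One central pick per group.
    """
    if method == "NH":
        if nh is None:
            raise ValueError("NH mode needs the NH matrix")
        nh = _check_nh(nh)
        n = nh.shape[0]
        if not (1 <= target <= n):
            raise ValueError("target out of range")
        if sample_ids is None:
            sample_ids = list(range(n))
        values = np.unique(nh)
        counts_cache: dict[int, int] = {}

        def count_at(vi: int) -> int:
            if vi not in counts_cache:
                counts_cache[vi] = group_by_nh(nh, values[vi]).n_groups
            return counts_cache[vi]

        lo, hi = 0, len(values) - 1  # count_at(hi) == 1, count_at(0) == n or fewer
        # find smallest threshold index with count <= target (count is
        # non-increasing in the threshold)
        while lo < hi:
            mid = (lo + hi) // 2
            if count_at(mid) <= target:
                hi = mid
            else:
                lo = mid + 1
        if count_at(lo) != target:
            below = count_at(lo)
            above = count_at(lo - 1) if lo > 0 else below
            raise ValueError(
                f"NH target {target} unattainable; nearest achievable group "
                f"counts are {below} and {above}"
            )
        grouping = group_by_nh(nh, values[lo], sample_ids)
        result = pick_center(grouping)
        result.params = {"target": target, "threshold": float(values[lo]), "pick": "center"}
        return result

    if method == "HC":
        if dend is None:
            if scores is None:
                raise ValueError("HC mode needs a dendrogram or scores")
            dend = ward_dendrogram(scores)
        n = dend.n_leaves
        if not (1 <= target <= n):
            raise ValueError("target out of range")
        labels = _labels_after_merges(dend, n - target)
        if scores is not None:
            from scipy.spatial.distance import pdist, squareform

            sq = squareform(pdist(scores.scores, metric="sqeuclidean"))
        else:
            sq = _cophenetic_like(dend)
        groups = [np.flatnonzero(labels == g).tolist() for g in np.unique(labels)]
        selected = [dend.sample_ids[_hc_central_member(g, sq)] for g in groups]
        return SelectionResult(
            method="HC",
            params={"target": target, "pick": "center"},
            selected_ids=selected,
            group_labels=labels,
            sample_ids=list(dend.sample_ids),
        )

    raise ValueError("method must be 'NH' or 'HC'")


def _cophenetic_like(dend: Dendrogram) -> np.ndarray:
    """Merge-height distance between leaves, used for central picks when the
    original scores are unavailable."""
    n = dend.n_leaves
    members = _cluster_members(dend)
    d = np.zeros((n, n))
    for i, (a, b, h, _) in enumerate(dend.merges):
        for x in members[int(a)]:
            for y in members[int(b)]:
                d[x, y] = d[y, x] = h
    return d


__all__ = [
    "NHGroup",
    "NHGrouping",
    "Dendrogram",
    "SelectionResult",
    "group_by_nh",
    "pick_center",
    "pick_sqrt_n",
    "ward_dendrogram",
    "cut_dendrogram",
    "hc_pick",
    "select_by_count",
]
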