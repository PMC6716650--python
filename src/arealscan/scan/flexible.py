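"""Flexible scan: irregular connected windows scored with a restricted LLR.

Candidate windows are connected subsets of at most K regions drawn from each
region's K-1 nearest neighbours, so clusters need not be circular.  The
restricted log-likelihood ratio multiplies the Poisson LLR by indicators
that every member region is individually elevated (region-wise one-tailed
mid-p below a threshold alpha1), which stops low-risk regions from riding
inside an irregular cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..regions import StudyArea, k_nearest
from .common import (
    Cluster,
    ScanConfig,
    ScoredZone,
    ZoneFamily,
    monte_carlo_test,
    null_expected,
    poisson_llr,
    risk_ratios,
    select_clusters,
)

__all__ = [
    "Adjacency",
    "knn_graph",
    "polygon_adjacency",
    "enumerate_flexible",
    "region_mid_p",
    "RestrictionState",
    "restricted_llr",
    "flexible_scan",
]

#: adjacency: region index -> set of adjacent region indices
Adjacency = dict[int, set[int]]


def knn_graph(area: StudyArea, k: int) -> Adjacency:
    """Symmetric k-nearest-neighbour graph on centroids (i ~ j if either is
    among the other's k nearest)."""
    nbrs = k_nearest(area, min(k + 1, area.n_regions))
    adj: Adjacency = {i: set() for i in range(area.n_regions)}
    for i in range(area.n_regions):
        for j in nbrs.order[i]:
            adj[i].add(int(j))
            adj[int(j)].add(i)
    return adj


def polygon_adjacency(area: StudyArea) -> Adjacency:
    """Rook-style adjacency from polygon geometry: regions are neighbours
    when their boundaries share a segment of positive length."""
    if area.geometry is None:
        raise ValueError("study area carries no polygon geometry")
    from shapely.geometry import shape

    polys = [shape(g) for g in area.geometry]
    adj: Adjacency = {i: set() for i in range(area.n_regions)}
    for i in range(area.n_regions):
        for j in range(i + 1, area.n_regions):
            inter = polys[i].boundary.intersection(polys[j].boundary)
            if inter.length > 0:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _connected_subsets(
    anchor: int, allowed: frozenset[int], adj: Adjacency, max_size: int
):
    """Yield every connected subset of ``allowed`` that contains ``anchor``
    (size <= max_size) exactly once, by ordered extension with exclusion."""

    def rec(sub: set[int], ext: list[int], forbidden: set[int]):
        yield tuple(sorted(sub))
        if len(sub) == max_size:
            return
        ext = list(ext)
        forbidden = set(forbidden)
        while ext:
            v = ext.pop(0)
            grown = sub | {v}
            frontier = [
                u
                for u in sorted(adj[v] & allowed)
                if u not in grown and u not in forbidden and u not in ext
            ]
            yield from rec(grown, ext + frontier, forbidden)
            forbidden.add(v)

    start_ext = sorted(u for u in adj[anchor] & allowed if u != anchor)
    yield from rec({anchor}, start_ext, set())


def enumerate_flexible(
    area: StudyArea,
    k: int,
    adjacency: Adjacency | None = None,
    zone_budget: int = 5_000_000,
) -> ZoneFamily:
    """Enumerate all connected windows of at most ``k`` regions.

    For each centre region the window must lie within the centre plus its
    k-1 nearest neighbours and be connected on ``adjacency`` (default: the
    k-nearest-neighbour graph).  Duplicate member sets from different
    centres are emitted once.  Enumeration aborts with an error if the
    family would exceed ``zone_budget`` zones, since exhaustive flexible
    scanning is only practical for small-to-moderate window sizes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = adjacency if adjacency is not None else knn_graph(area, k)
    nbrs = k_nearest(area, min(k, area.n_regions))
    centre_order = sorted(range(area.n_regions), key=lambda i: area.ids[i])
    seen: set[frozenset[int]] = set()
    members: list[tuple[int, ...]] = []
    for i in centre_order:
        allowed = frozenset({i, *(int(j) for j in nbrs.order[i])})
        for sub in _connected_subsets(i, allowed, adj, k):
            key = frozenset(sub)
            if key not in seen:
                seen.add(key)
                members.append(sub)
                if len(members) > zone_budget:
                    raise ValueError(
                        f"flexible zone family exceeds budget ({zone_budget}); "
                        "reduce k or supply sparser adjacency"
                    )
    return ZoneFamily.from_members(area.ids, members)


def region_mid_p(c, e, mid: bool = True):
    """One-tailed region-wise p-value under X ~ Poisson(e).

    mid-p (default): P(X > c) + 0.5 * P(X = c); plain tail: P(X >= c).
    Vectorised over arrays of counts and expecteds.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("expected counts must be positive")
    if mid:
        p = stats.poisson.sf(c, e) + 0.5 * stats.poisson.pmf(c, e)
    else:
        p = stats.poisson.sf(c - 1.0, e)
    return p if p.ndim else float(p)


@dataclass(frozen=True)
class RestrictionState:
    """Region-wise restriction: p-values and the threshold alpha1.

    Regions with p >= alpha1 cannot contribute to a restricted high
    cluster; any zone containing one scores 0.
    """

    p_values: np.ndarray
    alpha1: float

    @property
    def hot(self) -> np.ndarray:
        return self.p_values < self.alpha1


def restricted_llr(llr, members_hot):
    """Restricted LLR: the zone's LLR if every member is individually hot,
    else 0.  ``members_hot`` is the all-members-hot indicator (bool)."""
    llr = np.asarray(llr, dtype=float)
    out = np.where(np.asarray(members_hot, dtype=bool), llr, 0.0)
    return out if out.ndim else float(out)


def flexible_scan(
    area: StudyArea,
    config: ScanConfig | None = None,
    adjacency: Adjacency | None = None,
    baseline: np.ndarray | None = None,
) -> list[Cluster]:
    """Run the full flexible scan and return ranked, filtered clusters.

    Pipeline: enumerate connected windows within each region's nearest
    neighbours, score each with the restricted Poisson LLR (restriction
    recomputed on every Monte Carlo replicate), rank against the replicate
    distribution of the family maximum, and keep non-overlapping
    significant clusters whose prevalence ratio clears the threshold.
    """
    config = config or ScanConfig(scan="flexible")
    if config.scan != "flexible":
        raise ValueError("config.scan must be 'flexible'")
    if area.total_cases == 0:
        return []
    family = enumerate_flexible(
        area, config.max_regions, adjacency=adjacency, zone_budget=config.zone_budget
    )
    e_region = null_expected(area, baseline=baseline)
    e_zone = family.aggregate(e_region)
    C = area.total_cases
    mid = config.restriction == "midp"

    def max_restricted_stats(cases: np.ndarray) -> np.ndarray:
        c_zone = family.aggregate(cases)
        llr = poisson_llr(c_zone, e_zone[:, None], C)
        cold = (region_mid_p(cases, e_region[:, None], mid=mid) >= config.alpha1)
        any_cold = family.aggregate(cold.astype(float)) > 0
        return restricted_llr(llr, ~any_cold)

    p, _ = monte_carlo_test(
        area, family, max_restricted_stats, config.n_sim, config.seed,
        baseline=baseline,
    )
    stats_obs = max_restricted_stats(area.cases[:, None])[:, 0]
    c_obs = family.aggregate(area.cases)
    pop_obs = family.aggregate(area.populations)
    rr_io, oe = risk_ratios(c_obs, e_zone, C)
    scored = [
        ScoredZone(
            members=family.members[z],
            cases=float(c_obs[z]),
            population=float(pop_obs[z]),
            expected=float(e_zone[z]),
            llr=float(stats_obs[z]),
            rr_io=float(rr_io[z]),
            oe=float(oe[z]),
            p_value=float(p[z]),
        )
        for z in range(family.n_zones)
    ]
    return select_clusters(
        scored, area.ids, config.alpha, config.pr_min, config.resolved_pr_definition()
    )
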