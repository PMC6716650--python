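"""Circular scan: nested distance-ordered windows around each centroid.

The circular window of variable radius is realised discretely: for each
region taken as a centre, zones are the nested sets {centre + j nearest
regions by centroid distance}, truncated once cumulative population exceeds
a fraction of the study total.  A region is wholly in or out of a window.
"""

from __future__ import annotations

import numpy as np

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

__all__ = ["enumerate_circular", "circular_scan"]


def enumerate_circular(
    area: StudyArea,
    max_pop_fraction: float,
    baseline: np.ndarray | None = None,
) -> ZoneFamily:
    """Enumerate every distinct circular zone within the population cap.

    For each centre region, neighbours are added in ascending centroid
    distance (ties broken by region id) while the cumulative population
    stays within ``max_pop_fraction`` of the study total; duplicate member
    sets arising from different centres are emitted once.  ``baseline``
    substitutes adjusted expected counts for raw population in the cap.
    """
    if not 0 < max_pop_fraction < 1:
        raise ValueError("max_pop_fraction must be in (0, 1)")
    w = area.populations if baseline is None else np.asarray(baseline, dtype=float)
    cap = max_pop_fraction * w.sum()
    nbrs = k_nearest(area, area.n_regions)

    # iterate centres in id order so the family ignores input row order
    centre_order = sorted(range(area.n_regions), key=lambda i: area.ids[i])
    seen: set[frozenset[int]] = set()
    members: list[tuple[int, ...]] = []
    for i in centre_order:
        if w[i] > cap:
            continue
        seq = [i, *nbrs.order[i]]
        cum = np.cumsum(w[seq])
        n_ok = int(np.searchsorted(cum, cap, side="right"))
        for j in range(1, n_ok + 1):
            key = frozenset(seq[:j])
            if key not in seen:
                seen.add(key)
                members.append(tuple(sorted(seq[:j])))
    if not members:
        oversized = [area.ids[i] for i in range(area.n_regions) if w[i] > cap]
        raise ValueError(
            "population cap admits no zone; regions exceeding the cap: "
            + ", ".join(oversized)
        )
    return ZoneFamily.from_members(area.ids, members)


def circular_scan(
    area: StudyArea,
    config: ScanConfig | None = None,
    baseline: np.ndarray | None = None,
) -> list[Cluster]:
    """Run the full circular scan and return ranked, filtered clusters.

    Pipeline: enumerate nested circular zones, score each with the Poisson
    LLR against proportional expecteds, obtain Monte Carlo p-values from
    the replicate distribution of the family maximum, then keep
    non-overlapping significant clusters whose prevalence ratio clears the
    reporting threshold.  ``baseline`` switches the scan to
    covariate-adjusted expecteds.
    """
    config = config or ScanConfig(scan="circular")
    if config.scan != "circular":
        raise ValueError("config.scan must be 'circular'")
    if area.total_cases == 0:
        return []
    family = enumerate_circular(area, config.max_pop_fraction, baseline=baseline)
    e_region = null_expected(area, baseline=baseline)
    e_zone = family.aggregate(e_region)
    C = area.total_cases

    def max_llr_stats(cases: np.ndarray) -> np.ndarray:
        c_zone = family.aggregate(cases)
        return poisson_llr(c_zone, e_zone[:, None], C)

    p, _ = monte_carlo_test(
        area, family, max_llr_stats, config.n_sim, config.seed, baseline=baseline
    )
    c_obs = family.aggregate(area.cases)
    pop_obs = family.aggregate(area.populations)
    llr_obs = poisson_llr(c_obs, e_zone, C)
    rr_io, oe = risk_ratios(c_obs, e_zone, C)
    scored = [
        ScoredZone(
            members=family.members[z],
            cases=float(c_obs[z]),
            population=float(pop_obs[z]),
            expected=float(e_zone[z]),
            llr=float(llr_obs[z]),
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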