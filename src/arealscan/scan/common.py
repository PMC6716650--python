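"""Poisson-model machinery shared by the circular and flexible scans.

Both scans search a family of candidate *zones* (subsets of regions) for the
zone maximising a Poisson log-likelihood ratio comparing the case rate inside
the zone with the rate outside.  Inference conditions on the observed total
case count C: replicate datasets redistribute C cases over regions by a
multinomial with probabilities proportional to population (or to
covariate-adjusted expected counts), and each zone's p-value is the rank of
its observed statistic within the replicate distribution of the family
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import xlogy

from ..regions import StudyArea

__all__ = [
    "Zone",
    "ZoneFamily",
    "Cluster",
    "ScanConfig",
    "null_expected",
    "poisson_llr",
    "risk_ratios",
    "monte_carlo_test",
    "select_clusters",
    "clusters_to_frame",
]


@dataclass(frozen=True)
class Zone:
    """A candidate window: a set of regions with aggregated counts."""

    members: frozenset[str]
    cases: float  # c_z
    population: float  # n_z
    expected: float  # e_z under the null

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("zone must be non-empty")


@dataclass(frozen=True)
class Cluster:
    """A reported cluster: a zone with its statistics and rank."""

    zone: Zone
    llr: float
    rr_io: float  # inside/outside relative risk
    oe: float  # observed / expected
    p_value: float
    rank: int

    @property
    def members(self) -> frozenset[str]:
        return self.zone.members


@dataclass(frozen=True)
class ScanConfig:
    """Configuration for a scan run.

    Parameters
    ----------
    scan : {"circular", "flexible"}
    max_pop_fraction : float
        Circular scan: cap on zone population as a fraction of the study
        total (default 0.13 so the largest Florida county can be a zone).
    max_regions : int
        Flexible scan: cap K on the number of regions per window (default 10).
    n_sim : int
        Monte Carlo replications (default 999, so the minimum attainable
        p-value is 0.001).
    seed : int
    alpha : float
        Significance level on the Monte Carlo p-value (default 0.05).
    pr_min : float
        Reporting threshold: clusters with prevalence ratio <= pr_min are
        dropped (default 1.2).
    pr_definition : {"rr_io", "oe"} or None
        Which risk-ratio variant feeds the pr_min filter and the reported
        PR.  Default None resolves to "rr_io" for the circular scan and
        "oe" for the flexible scan, matching the conventions of the
        standard implementations of each.
    alpha1 : float
        Restriction threshold for the restricted LLR (flexible scan only).
    restriction : {"midp", "tail"}
        Region-wise p-value used by the restriction.
    zone_budget : int
        Refuse flexible enumerations that would exceed this many zones.
    """

    model: Literal["poisson"] = "poisson"
    scan: Literal["circular", "flexible"] = "circular"
    max_pop_fraction: float = 0.13
    max_regions: int = 10
    n_sim: int = 999
    seed: int = 0
    alpha: float = 0.05
    pr_min: float = 1.2
    pr_definition: Literal["rr_io", "oe"] | None = None
    alpha1: float = 0.2
    restriction: Literal["midp", "tail"] = "midp"
    zone_budget: int = 5_000_000

    def __post_init__(self) -> None:
        if self.model != "poisson":
            raise ValueError("only the Poisson model is supported")
        if not 0 < self.max_pop_fraction < 1:
            raise ValueError("max_pop_fraction must be in (0, 1)")
        if self.max_regions < 1:
            raise ValueError("max_regions must be >= 1")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def resolved_pr_definition(self) -> str:
        if self.pr_definition is not None:
            return self.pr_definition
        return "rr_io" if self.scan == "circular" else "oe"

    def with_(self, **kw) -> "ScanConfig":
        return replace(self, **kw)


@dataclass
class ZoneFamily:
    """A family of candidate zones over a fixed region ordering.

    ``members`` lists each zone's region indices; ``indicator`` is the
    (n_zones x n_regions) sparse 0/1 membership matrix used to aggregate
    counts for observed and replicate data in one sparse product.
    """

    ids: list[str]
    members: list[tuple[int, ...]]
    indicator: sparse.csr_matrix = field(repr=False)

    @classmethod
    def from_members(cls, ids: Sequence[str], members: list[tuple[int, ...]]) -> "ZoneFamily":
        n_zones, n_regions = len(members), len(ids)
        indptr = np.zeros(n_zones + 1, dtype=np.int64)
        for z, m in enumerate(members):
            indptr[z + 1] = indptr[z] + len(m)
        indices = np.concatenate([np.asarray(m, dtype=np.int32) for m in members]) if members else np.array([], dtype=np.int32)
        data = np.ones(len(indices), dtype=np.float64)
        ind = sparse.csr_matrix((data, indices, indptr), shape=(n_zones, n_regions))
        return cls(ids=list(ids), members=members, indicator=ind)

    @property
    def n_zones(self) -> int:
        return len(self.members)

    def aggregate(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` over each zone.  ``values`` may be (n_regions,)
        or (n_regions, n_replicates)."""
        return self.indicator @ values

    def member_ids(self, z: int) -> frozenset[str]:
        return frozenset(self.ids[i] for i in self.members[z])


def null_expected(area: StudyArea, baseline: np.ndarray | None = None) -> np.ndarray:
    """Expected counts e_i = C * w_i / sum(w) under spatial randomness.

    ``baseline`` defaults to the raw populations; a covariate-adjusted scan
    passes model-fitted expected counts instead, which then play the role of
    population throughout.
    """
    w = area.populations if baseline is None else np.asarray(baseline, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total population (baseline weight) must be positive")
    if np.any(w < 0):
        raise ValueError("baseline weights must be non-negative")
    return area.total_cases * w / total


def poisson_llr(c, e, total_cases: float, high_only: bool = True):
    """Poisson scan log-likelihood ratio for a zone.

    LLR = c*ln(c/e) + (C-c)*ln((C-c)/(C-e)) when the zone is anomalous,
    else 0.  With ``high_only`` (the default, matching a high-prevalence
    scan) zones with c <= e score 0.  0*ln(0) is taken as 0, so c = 0 and
    c = C are both finite.  Accepts scalars or arrays.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    C = float(total_cases)
    if np.any((e <= 0) | (e >= C)):
        raise ValueError("expected counts must lie strictly in (0, C)")
    if np.any((c < 0) | (c > C)):
        raise ValueError("zone cases must lie in [0, C]")
    with np.errstate(divide="ignore", invalid="ignore"):
        llr = xlogy(c, c / e) + xlogy(C - c, (C - c) / (C - e))
    if high_only:
        llr = np.where(c > e, llr, 0.0)
    llr = np.maximum(llr, 0.0)  # guard tiny negative rounding at c ~= e
    return llr if llr.ndim else float(llr)


def risk_ratios(c, e, total_cases: float):
    """Both risk-ratio variants for a zone: (rr_io, oe).

    rr_io = (c/e) / ((C-c)/(C-e)) is the relative risk inside versus
    outside the zone; oe = c/e is the observed/expected ratio.  The two
    coincide at 1 when c = e and diverge as the zone grows.
    """
    c = np.asarray(c, dtype=float)
    e = np.asarray(e, dtype=float)
    C = float(total_cases)
    if np.any(e <= 0):
        raise ValueError("expected count must be positive")
    oe = c / e
    outside = np.where(c < C, (C - c) / (C - e), np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr_io = np.where(outside > 0, oe / outside, np.inf)
    if rr_io.ndim == 0:
        return float(rr_io), float(oe)
    return rr_io, oe


def monte_carlo_test(
    area: StudyArea,
    family: ZoneFamily,
    statistic_fn: Callable[[np.ndarray], np.ndarray],
    n_sim: int,
    seed: int,
    baseline: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional Monte Carlo test of the family maximum statistic.

    Replicate datasets redistribute the C observed cases across regions by
    a multinomial with probabilities w_i / sum(w) (w = population or
    adjusted expecteds), so every replicate conserves C.  ``statistic_fn``
    maps an (n_regions, n_replicates) case matrix to (n_zones,
    n_replicates) statistics — the same function scores the observed data.

    Returns ``(p_values, replicate_maxima)`` where ``p_values[z] =
    (1 + #{replicate max >= observed stat of z}) / (n_sim + 1)``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    w = area.populations if baseline is None else np.asarray(baseline, dtype=float)
    probs = w / w.sum()
    rng = np.random.default_rng(seed)
    C = area.total_cases

    obs_stats = statistic_fn(area.cases[:, None])[:, 0]

    rep_max = np.empty(n_sim)
    # moderate batches bound the n_regions x batch memory footprint
    batch = max(1, min(n_sim, int(4e6 // max(1, area.n_regions))))
    done = 0
    while done < n_sim:
        b = min(batch, n_sim - done)
        cases = rng.multinomial(C, probs, size=b).T.astype(float)
        stats = statistic_fn(cases)
        rep_max[done : done + b] = stats.max(axis=0) if stats.size else 0.0
        done += b
    exceed = (rep_max[None, :] >= obs_stats[:, None]).sum(axis=1)
    p = (1.0 + exceed) / (n_sim + 1.0)
    return p, rep_max


@dataclass(frozen=True)
class ScoredZone:
    """Internal: a zone with its statistics prior to selection."""

    members: tuple[int, ...]
    cases: float
    population: float
    expected: float
    llr: float
    rr_io: float
    oe: float
    p_value: float


def select_clusters(
    scored: Sequence[ScoredZone],
    ids: Sequence[str],
    alpha: float,
    pr_min: float,
    pr_definition: str,
) -> list[Cluster]:
    """Greedy non-overlapping cluster selection and reporting filter.

    Zones are taken in descending statistic order; a zone sharing any
    region with an already-kept zone is discarded.  Kept zones are then
    filtered to Monte Carlo p <= alpha and prevalence ratio > pr_min
    (using the configured PR definition), and ranks are reassigned 1..n
    with rank 1 the primary (largest-statistic) cluster.
    """
    order = sorted(
        range(len(scored)),
        key=lambda z: (-scored[z].llr, scored[z].members),
    )
    taken: set[int] = set()
    kept: list[ScoredZone] = []
    for z in order:
        sz = scored[z]
        if sz.llr <= 0:
            break
        if any(i in taken for i in sz.members):
            continue
        taken.update(sz.members)
        kept.append(sz)
    out: list[Cluster] = []
    for sz in kept:
        pr = sz.rr_io if pr_definition == "rr_io" else sz.oe
        if sz.p_value > alpha or not pr > pr_min:
            continue
        zone = Zone(
            members=frozenset(ids[i] for i in sz.members),
            cases=sz.cases,
            population=sz.population,
            expected=sz.expected,
        )
        out.append(
            Cluster(
                zone=zone,
                llr=sz.llr,
                rr_io=sz.rr_io,
                oe=sz.oe,
                p_value=sz.p_value,
                rank=len(out) + 1,
            )
        )
    return out


def clusters_to_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster report with the columns of the standard printed tables."""
    rows = []
    for cl in clusters:
        rows.append(
            {
                "cluster": cl.rank,
                "population": cl.zone.population,
                "observed": cl.zone.cases,
                "expected": cl.zone.expected,
                "llr": cl.llr,
                "rr_io": cl.rr_io,
                "oe": cl.oe,
                "n_regions": len(cl.members),
                "p_value": cl.p_value,
                "members": ";".join(sorted(cl.members)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster", "population", "observed", "expected", "llr",
            "rr_io", "oe", "n_regions", "p_value", "members",
        ],
    )
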