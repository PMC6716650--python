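"""Formal comparison of two cluster solutions over the same regions.

Given the binary cluster-membership classification each method induces on
the regions, this module computes the 2x2 membership contingency, an exact
McNemar test on the discordant counts, Cohen's kappa with its large-sample
confidence interval, the prevalence-and-bias-adjusted kappa (PABAK, the S
coefficient) with an exact-binomial-derived interval, the Landis-Koch
agreement label, Yates-corrected two-sample proportion tests, and the
Cluster Information Criterion (CLIC) goodness-of-fit score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "MembershipContingency",
    "AgreementStats",
    "contingency",
    "exact_mcnemar",
    "kappa_stats",
    "landis_koch_label",
    "proportion_test",
    "clic",
    "compare_solutions",
    "ComparisonResult",
]


@dataclass(frozen=True)
class MembershipContingency:
    """2x2 cross-classification of regions by two methods.

    a = positive under both, b = method-2 only, c = method-1 only,
    d = negative under both.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def contingency(
    membership_1: Sequence[bool], membership_2: Sequence[bool]
) -> MembershipContingency:
    """Cross-classify regions by two binary membership vectors
    (same region order in both)."""
    m1 = np.asarray(membership_1, dtype=bool)
    m2 = np.asarray(membership_2, dtype=bool)
    if m1.shape != m2.shape or m1.ndim != 1:
        raise ValueError("membership vectors must be 1-d and equal length")
    return MembershipContingency(
        a=int(np.sum(m1 & m2)),
        b=int(np.sum(~m1 & m2)),
        c=int(np.sum(m1 & ~m2)),
        d=int(np.sum(~m1 & ~m2)),
    )


def exact_mcnemar(t: MembershipContingency) -> float:
    """Two-sided exact McNemar p-value on the discordant cells.

    p = min(1, 2 * P(X <= min(b, c))) with X ~ Binomial(b + c, 1/2);
    defined as 1 when there are no discordant pairs.
    """
    n_disc = t.b + t.c
    if n_disc == 0:
        return 1.0
    k = min(t.b, t.c)
    return float(min(1.0, 2.0 * stats.binom.cdf(k, n_disc, 0.5)))


def landis_koch_label(kappa: float) -> str:
    """Landis-Koch interpretation bands for a kappa-type statistic."""
    if kappa < 0:
        return "No agreement"
    bands = [
        (0.2, "Slight agreement"),
        (0.4, "Fair agreement"),
        (0.6, "Moderate agreement"),
        (0.8, "Substantial agreement"),
        (1.0 + 1e-12, "Almost perfect agreement"),
    ]
    for upper, label in bands:
        if kappa <= upper:
            return label
    return "Almost perfect agreement"


@dataclass(frozen=True)
class AgreementStats:
    """Observed/chance agreement, kappa and PABAK with 95% intervals."""

    po: float
    pe: float
    kappa: float
    kappa_ci: tuple[float, float]
    pabak: float
    pabak_ci: tuple[float, float]
    label: str


def kappa_stats(t: MembershipContingency, conf_level: float = 0.95) -> AgreementStats:
    """Agreement statistics for a 2x2 membership contingency.

    Po = (a+d)/n; Pe = ((a+b)(a+c) + (c+d)(b+d))/n^2; kappa = (Po-Pe)/(1-Pe)
    with the Fleiss large-sample SE sqrt(Po(1-Po)/(n(1-Pe)^2)); PABAK =
    2*Po - 1 with its interval obtained by transforming the Clopper-Pearson
    exact binomial interval of Po.  The label applies Landis-Koch bands to
    kappa.
    """
    n = t.n
    if n == 0:
        raise ValueError("empty contingency")
    a, b, c, d = t.a, t.b, t.c, t.d
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1, kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    kappa_ci = (kappa - z * se, kappa + z * se)
    x = a + d
    lo = stats.beta.ppf((1 - conf_level) / 2, x, n - x + 1) if x > 0 else 0.0
    hi = stats.beta.ppf(1 - (1 - conf_level) / 2, x + 1, n - x) if x < n else 1.0
    pabak = 2.0 * po - 1.0
    return AgreementStats(
        po=po,
        pe=pe,
        kappa=kappa,
        kappa_ci=kappa_ci,
        pabak=pabak,
        pabak_ci=(2.0 * lo - 1.0, 2.0 * hi - 1.0),
        label=landis_koch_label(kappa),
    )


def proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample equality-of-proportions test with continuity correction.

    Pooled-variance chi-square with the Yates correction on the underlying
    2x2 table (the convention of R's prop.test); returns (statistic,
    two-sided p).  The statistic floors at 0 when the correction exceeds
    the observed difference.
    """
    if min(n1, n2) <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if np.any(expected == 0):
        raise ValueError("degenerate margins")
    yates = min(0.5, abs(table[0, 0] - expected[0, 0]))
    chi2 = float((((np.abs(table - expected) - yates) ** 2) / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def clic(
    llrs: Sequence[float], cluster_population: float, n_clusters: int | None = None
) -> tuple[float, float]:
    """Cluster Information Criterion for one cluster solution.

    CLIC = -2 * sum(LLR) + ln(p) * n, where p is the total population in
    the cluster regions and n the number of significant clusters.  Returns
    (signed value, magnitude); solutions are conventionally ranked
    lower-is-better on the magnitude.
    """
    llrs = list(llrs)
    if not llrs:
        raise ValueError("need at least one cluster LLR")
    if cluster_population <= 0:
        raise ValueError("cluster population must be positive")
    n = n_clusters if n_clusters is not None else len(llrs)
    if n < 1:
        raise ValueError("n_clusters must be >= 1")
    value = -2.0 * float(np.sum(llrs)) + math.log(cluster_population) * n
    return value, abs(value)


@dataclass(frozen=True)
class ComparisonResult:
    """Full comparison of two cluster solutions."""

    table: MembershipContingency
    agreement: AgreementStats
    mcnemar_p: float
    case_proportion_test: tuple[float, float]
    population_proportion_test: tuple[float, float]
    clic_1: tuple[float, float] | None
    clic_2: tuple[float, float] | None


def compare_solutions(area, clusters_1, clusters_2) -> ComparisonResult:
    """Compare two cluster solutions detected on the same study area.

    A region is cluster-positive under a method if it belongs to any of
    the method's reported clusters.  Proportion tests compare the share of
    cases and of population living in cluster regions between methods;
    CLIC is computed from each solution's LLRs and cluster population
    (None for an empty solution).
    """
    ids = area.ids
    pos1 = set().union(*[c.members for c in clusters_1]) if clusters_1 else set()
    pos2 = set().union(*[c.members for c in clusters_2]) if clusters_2 else set()
    m1 = [rid in pos1 for rid in ids]
    m2 = [rid in pos2 for rid in ids]
    t = contingency(m1, m2)

    C = area.total_cases
    N = area.total_population
    cases1 = int(sum(r.cases for r in area.regions if r.id in pos1))
    cases2 = int(sum(r.cases for r in area.regions if r.id in pos2))
    pop1 = int(sum(r.population for r in area.regions if r.id in pos1))
    pop2 = int(sum(r.population for r in area.regions if r.id in pos2))

    def _clic(clusters, pop):
        if not clusters:
            return None
        return clic([c.llr for c in clusters], pop, len(clusters))

    return ComparisonResult(
        table=t,
        agreement=kappa_stats(t),
        mcnemar_p=exact_mcnemar(t),
        case_proportion_test=proportion_test(cases1, C, cases2, C),
        population_proportion_test=proportion_test(pop1, N, pop2, N),
        clic_1=_clic(clusters_1, pop1),
        clic_2=_clic(clusters_2, pop2),
    )
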