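"""Published benchmark tables for the Florida 2013 stroke-prevalence setting.

These read-only fixtures transcribe the county-level cluster summaries of a
2013 Florida BRFSS stroke-prevalence analysis: the circular-scan and
flexible-scan cluster tables, the covariate-adjusted circular-scan clusters,
the 2x2 county-membership contingency between the two methods, and the
study-area totals.  Expected counts are stored exactly as printed (two
decimals), so tests built on them tolerate the rounding this induces.
"""

from __future__ import annotations

import pandas as pd

from .compare import MembershipContingency

__all__ = [
    "TOTAL_CASES",
    "TOTAL_POPULATION",
    "N_COUNTIES",
    "circular_cluster_table",
    "flexible_cluster_table",
    "adjusted_cluster_table",
    "membership_contingency",
    "shared_cluster_counties",
    "circular_only_counties",
    "flexible_only_counties",
]

#: Study-area totals: C adult stroke cases over N adult population.
TOTAL_CASES = 705_718
TOTAL_POPULATION = 19_314_396
N_COUNTIES = 67


def circular_cluster_table() -> pd.DataFrame:
    """Circular-scan clusters (population cap 13%, 999 replications, PR > 1.2).

    Columns: cluster rank, population, observed and expected cases (expected
    as printed, 2 dp), prevalence ratio as printed, number of counties,
    Monte Carlo p-value (minimum attainable 0.001 with 999 replications).
    """
    return pd.DataFrame(
        {
            "cluster": [1, 2, 3, 4, 5],
            "population": [1_314_154, 549_144, 2_210_618, 39_770, 148_189],
            "observed": [74_397, 32_949, 97_622, 2_784, 6_669],
            "expected": [48_017.14, 20_064.86, 80_772.54, 1_453.12, 5_414.59],
            "prevalence_ratio": [1.61, 1.67, 1.24, 1.91, 1.23],
            "n_counties": [14, 1, 2, 1, 1],
            "p_value": [0.001] * 5,
        }
    )


def flexible_cluster_table() -> pd.DataFrame:
    """Flexible-scan clusters (window cap 10 counties, restricted LLR)."""
    return pd.DataFrame(
        {
            "cluster": [1, 2, 3, 4, 5, 6],
            "population": [2_009_003, 1_074_486, 139_787, 56_629, 148_189, 11_613],
            "observed": [112_106, 50_139, 7_129, 3_212, 6_669, 592],
            "expected": [73_405.80, 39_260.00, 5_107.60, 2_069.14, 5_414.60, 424.32],
            "prevalence_ratio": [1.53, 1.28, 1.40, 1.55, 1.23, 1.40],
            "n_counties": [7, 7, 1, 2, 1, 1],
            "p_value": [0.001] * 6,
        }
    )


def adjusted_cluster_table() -> pd.DataFrame:
    """Circular-scan clusters after covariate adjustment of expected counts."""
    return pd.DataFrame(
        {
            "cluster": [1, 2],
            "observed": [8_052, 32_949],
            "expected": [3_207.44, 26_527.38],
            "prevalence_ratio": [2.53, 1.25],
            "n_counties": [1, 1],
            "p_value": [0.001] * 2,
        }
    )


def membership_contingency() -> MembershipContingency:
    """County cluster-membership contingency between the two methods.

    a = counties flagged by both, b = flexible-only, c = circular-only,
    d = flagged by neither; 67 counties in total.
    """
    return MembershipContingency(a=12, b=7, c=7, d=41)


def shared_cluster_counties() -> list[str]:
    """The 12 counties flagged as cluster members by both methods."""
    return [
        "Bradford", "Brevard", "Citrus", "Columbia", "Dixie", "Levy",
        "Marion", "Martin", "Putnam", "Sumter", "Suwannee", "Union",
    ]


def circular_only_counties() -> list[str]:
    """Counties flagged only by the circular scan."""
    return [
        "Alachua", "Gilchrist", "Hernando", "Lafayette",
        "Hillsborough", "Pinellas", "Okeechobee",
    ]


def flexible_only_counties() -> list[str]:
    """Counties flagged only by the flexible scan."""
    return [
        "Baker", "Duval", "Franklin", "Hamilton",
        "Indian River", "Lake", "Volusia",
    ]
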