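import numpy as np
import pytest
from scipy import stats

from arealscan import (
    ScanConfig,
    monte_carlo_test,
    null_expected,
    poisson_llr,
    risk_ratios,
    select_clusters,
)
from arealscan.scan.common import ScoredZone, ZoneFamily
from conftest import make_area

C_FLORIDA = 705_718


class TestNullExpected:
    def test_proportional_to_population(self):
        area = make_area([0, 1], [0, 0], [100, 300], [10, 30])
        assert null_expected(area) == pytest.approx([10.0, 30.0])

    def test_equal_populations_give_equal_expecteds(self):
        area = make_area(range(5), [0] * 5, [200] * 5, [3, 1, 4, 1, 5])
        e = null_expected(area)
        assert np.allclose(e, e[0])

    def test_sums_to_total_cases(self, florida_like):
        e = null_expected(florida_like)
        C = florida_like.total_cases
        assert abs(e.sum() - C) <= 1e-9 * C


class TestPoissonLLR:
    def test_zero_at_null(self):
        assert poisson_llr(50.0, 50.0, 1000.0) == 0.0

    def test_printed_primary_cluster_value(self):
        # frozen from high-precision evaluation of the closed form
        assert poisson_llr(74_397, 48_017.14, C_FLORIDA) == pytest.approx(
            6731.687053, rel=1e-9
        )

    def test_deficit_zone_scores_zero_when_high_only(self):
        assert poisson_llr(0.0, 10.0, 100.0, high_only=True) == 0.0
        assert poisson_llr(0.0, 10.0, 100.0, high_only=False) > 0.0

    def test_finite_when_zone_holds_all_cases(self):
        assert np.isfinite(poisson_llr(100.0, 20.0, 100.0))

    def test_invalid_expected_raises(self):
        with pytest.raises(ValueError):
            poisson_llr(5.0, 0.0, 100.0)
        with pytest.raises(ValueError):
            poisson_llr(5.0, 100.0, 100.0)

    def test_agrees_with_poisson_loglikelihood_difference(self):
        """LLR equals the alternative-minus-null Poisson log-likelihood of
        the (inside, outside) counts at their respective MLE means."""
        rng = np.random.default_rng(0)
        tiny = 1e-300  # Poisson mean 0 handled as a limit: logpmf(0, 0) -> 0
        for _ in range(1000):
            C = int(rng.integers(10, 1_000_000))
            c = int(rng.integers(0, C + 1))
            e = float(rng.uniform(1e-3, C - 1e-3))
            direct = (
                stats.poisson.logpmf(c, max(c, tiny))
                + stats.poisson.logpmf(C - c, max(C - c, tiny))
                - stats.poisson.logpmf(c, e)
                - stats.poisson.logpmf(C - c, C - e)
            )
            got = poisson_llr(c, e, C, high_only=False)
            assert got == pytest.approx(direct, rel=1e-9, abs=1e-9)


class TestRiskRatios:
    @pytest.mark.parametrize(
        "c,e,which,printed",
        [
            (74_397, 48_017.14, "rr_io", 1.61),
            (112_106, 73_405.80, "oe", 1.53),
            (8_052, 3_207.44, "rr_io", 2.53),
        ],
    )
    def test_reproduces_printed_prevalence_ratios(self, c, e, which, printed):
        rr_io, oe = risk_ratios(c, e, C_FLORIDA)
        assert round(rr_io if which == "rr_io" else oe, 2) == printed

    def test_identity_at_null(self):
        rr_io, oe = risk_ratios(40.0, 40.0, 400.0)
        assert rr_io == pytest.approx(1.0)
        assert oe == pytest.approx(1.0)


def _one_zone_family(ids, members):
    return ZoneFamily.from_members(ids, members)


class TestMonteCarlo:
    def _area(self):
        rng = np.random.default_rng(21)
        pops = rng.integers(100, 1000, size=8)
        cases = rng.binomial(pops, 0.05)
        return make_area(range(8), [0] * 8, pops, cases,
                         ids=[f"r{i}" for i in range(8)])

    def test_p_matches_direct_rank_arithmetic(self):
        """p = (1 + #{replicate max >= observed}) / (n_sim + 1), checked by
        replaying the identical seeded multinomial stream by hand."""
        area = self._area()
        fam = _one_zone_family(area.ids, [(0, 1), (3,), (5, 6, 7)])
        e = null_expected(area)
        e_z = fam.aggregate(e)
        C = area.total_cases

        def stat(cases):
            return poisson_llr(fam.aggregate(cases), e_z[:, None], C)

        n_sim, seed = 49, 123
        p, rep_max = monte_carlo_test(area, fam, stat, n_sim, seed)
        rng = np.random.default_rng(seed)
        probs = area.populations / area.total_population
        draws = rng.multinomial(C, probs, size=n_sim).T.astype(float)
        expect_max = stat(draws).max(axis=0)
        assert np.allclose(rep_max, expect_max)
        obs = stat(area.cases[:, None])[:, 0]
        for z in range(3):
            manual = (1 + np.sum(expect_max >= obs[z])) / (n_sim + 1)
            assert p[z] == pytest.approx(manual)
        assert np.all(p >= 1 / (n_sim + 1)) and np.all(p <= 1.0)

    def test_zero_statistic_has_p_one(self):
        area = self._area()
        fam = _one_zone_family(area.ids, [(0,)])

        def stat(cases):
            return np.zeros((1, cases.shape[1]))

        p, _ = monte_carlo_test(area, fam, stat, 19, 5)
        assert p[0] == 1.0

    def test_replicates_condition_on_total_cases(self):
        area = self._area()
        fam = _one_zone_family(area.ids, [(0,)])
        totals = []

        def stat(cases):
            totals.append(cases.sum(axis=0))
            return np.zeros((1, cases.shape[1]))

        monte_carlo_test(area, fam, stat, 25, 9)
        rep_totals = np.concatenate([t for t in totals[1:]])
        assert np.all(rep_totals == area.total_cases)

    def test_reproducible_given_seed(self):
        area = self._area()
        fam = _one_zone_family(area.ids, [(0, 1, 2)])
        e_z = fam.aggregate(null_expected(area))
        C = area.total_cases

        def stat(cases):
            return poisson_llr(fam.aggregate(cases), e_z[:, None], C)

        p1, m1 = monte_carlo_test(area, fam, stat, 99, 7)
        p2, m2 = monte_carlo_test(area, fam, stat, 99, 7)
        assert np.array_equal(p1, p2) and np.array_equal(m1, m2)


def _sz(members, llr, p=0.001, rr=1.5, c=100.0, e=50.0):
    return ScoredZone(members=members, cases=c, population=1000.0, expected=e,
                      llr=llr, rr_io=rr, oe=rr, p_value=p)


class TestSelectClusters:
    IDS = list("ABCDEFGH")

    def test_overlapping_zone_discarded(self):
        scored = [_sz((0, 1), 10.0), _sz((1, 2), 8.0)]
        kept = select_clusters(scored, self.IDS, 0.05, 1.2, "rr_io")
        assert len(kept) == 1
        assert kept[0].members == frozenset({"A", "B"})

    def test_low_pr_excluded_even_if_significant(self):
        scored = [_sz((0,), 12.0, p=0.001, rr=1.15)]
        assert select_clusters(scored, self.IDS, 0.05, 1.2, "rr_io") == []

    def test_insignificant_excluded(self):
        scored = [_sz((0,), 12.0, p=0.2)]
        assert select_clusters(scored, self.IDS, 0.05, 1.2, "rr_io") == []

    def test_five_disjoint_significant_zones_all_kept(self):
        # mimics the printed circular-scan table: five disjoint clusters,
        # all p < 0.001, prevalence ratios all above the 1.2 threshold
        prs = [1.61, 1.67, 1.24, 1.91, 1.23]
        llrs = [6731.7, 3580.1, 1875.8, 480.5, 136.4]
        scored = [
            _sz((i,), llrs[i], rr=prs[i]) for i in range(5)
        ]
        kept = select_clusters(scored, self.IDS, 0.05, 1.2, "rr_io")
        assert len(kept) == 5
        assert kept[0].llr == max(llrs)  # primary = largest statistic
        assert [c.rank for c in kept] == [1, 2, 3, 4, 5]

    def test_output_zones_pairwise_disjoint(self):
        rng = np.random.default_rng(3)
        scored = []
        for _ in range(30):
            m = tuple(sorted(rng.choice(8, size=rng.integers(1, 4), replace=False)))
            scored.append(_sz(m, float(rng.uniform(0, 20))))
        kept = select_clusters(scored, self.IDS, 0.05, 1.0, "rr_io")
        seen = set()
        for cl in kept:
            assert not (cl.members & seen)
            seen |= cl.members
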