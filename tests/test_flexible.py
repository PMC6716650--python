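import itertools
import math

import numpy as np
import pytest

from arealscan import (
    ScanConfig,
    enumerate_flexible,
    flexible_scan,
    k_nearest,
    region_mid_p,
    restricted_llr,
)
from arealscan.scan.common import null_expected, poisson_llr
from arealscan.scan.flexible import RestrictionState, knn_graph
from arealscan.simulate import EmbeddedZone, SimulationScenario, generate, grid_adjacency
from arealscan.scan.circular import enumerate_circular
from conftest import make_area


def member_sets(family):
    return {frozenset(m) for m in family.members}


def brute_force_family(area, k, adj):
    """Exhaustive oracle: all connected subsets of size <= k lying within
    some centre's (k-1)-nearest-neighbour ball and containing that centre."""
    n = area.n_regions
    nbrs = k_nearest(area, min(k, n))
    balls = {i: {i, *(int(j) for j in nbrs.order[i])} for i in range(n)}

    def connected(sub):
        sub = set(sub)
        seen = {next(iter(sub))}
        stack = list(seen)
        while stack:
            v = stack.pop()
            for u in adj[v] & sub:
                if u not in seen:
                    seen.add(u)
                    stack.append(u)
        return seen == sub

    out = set()
    for size in range(1, k + 1):
        for sub in itertools.combinations(range(n), size):
            if not connected(sub):
                continue
            if any(set(sub) <= balls[i] for i in sub):
                out.add(frozenset(sub))
    return out


class TestEnumerateFlexible:
    def test_path_graph_hand_enumeration(self, collinear_area):
        adj = {0: {1}, 1: {0, 2}, 2: {1}}
        fam = enumerate_flexible(collinear_area, 3, adjacency=adj)
        # {A,C} is rejected as disconnected; the other 6 subsets survive
        assert member_sets(fam) == {
            frozenset(s) for s in [{0}, {1}, {2}, {0, 1}, {1, 2}, {0, 1, 2}]
        }

    def test_k_one_gives_singletons(self, collinear_area):
        fam = enumerate_flexible(collinear_area, 1)
        assert member_sets(fam) == {frozenset({i}) for i in range(3)}

    @pytest.mark.parametrize("n,k,seed", [(12, 4, 1), (14, 5, 2), (10, 10, 3)])
    def test_matches_exhaustive_oracle_on_random_graphs(self, n, k, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(0, 10, size=(n, 2))
        area = make_area(xy[:, 0], xy[:, 1], [100] * n, [3] * n,
                         ids=[f"r{i:02d}" for i in range(n)])
        adj = knn_graph(area, 3)
        fam = enumerate_flexible(area, k, adjacency=adj)
        assert member_sets(fam) == brute_force_family(area, k, adj)

    def test_matches_oracle_on_grid(self):
        scen = SimulationScenario(rows=3, cols=4, uniform_population=100.0)
        area, _ = generate(scen, seed=0)
        adj = grid_adjacency(3, 4)
        fam = enumerate_flexible(area, 4, adjacency=adj)
        assert member_sets(fam) == brute_force_family(area, 4, adj)

    def test_zone_budget_enforced(self, florida_like):
        with pytest.raises(ValueError, match="budget"):
            enumerate_flexible(florida_like, 10, zone_budget=50)

    def test_every_zone_connected_on_adjacency(self):
        scen = SimulationScenario(rows=4, cols=4, uniform_population=100.0)
        area, _ = generate(scen, seed=1)
        adj = grid_adjacency(4, 4)
        fam = enumerate_flexible(area, 5, adjacency=adj)
        oracle = brute_force_family(area, 5, adj)
        assert member_sets(fam) <= oracle  # connectivity + ball containment

    def test_contains_circular_zones_within_neighbour_balls(self):
        """Family nesting: every circular zone of <= K members whose set lies
        in its centre's K-1 nearest neighbours is also a flexible zone when
        adjacency admits it (here: complete adjacency)."""
        rng = np.random.default_rng(9)
        xy = rng.uniform(0, 10, size=(10, 2))
        area = make_area(xy[:, 0], xy[:, 1], [100] * 10, [3] * 10,
                         ids=[f"r{i}" for i in range(10)])
        complete = {i: set(range(10)) - {i} for i in range(10)}
        k = 5
        flex = member_sets(enumerate_flexible(area, k, adjacency=complete))
        nbrs = k_nearest(area, k)
        balls = {i: {i, *(int(j) for j in nbrs.order[i])} for i in range(10)}
        for idx in member_sets(enumerate_circular(area, 0.45)):
            if len(idx) <= k and any(idx <= balls[i] for i in idx):
                assert idx in flex


def poisson_tail_oracle(c, e):
    """Independent mid-p oracle: direct term-by-term Poisson tail sum."""
    pmf = lambda k: math.exp(-e) * e**k / math.factorial(k)
    upper = int(max(20, e + 20 * math.sqrt(e) + c))
    tail = math.fsum(pmf(k) for k in range(c + 1, upper))
    return tail + 0.5 * pmf(c)


class TestRegionMidP:
    def test_limit_small_expected(self):
        p = region_mid_p(0, 1e-12)
        assert p == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("c,e", [(10, 5.0), (5, 10.0), (0, 2.0), (30, 18.5)])
    def test_matches_direct_tail_sum(self, c, e):
        assert region_mid_p(c, e) == pytest.approx(poisson_tail_oracle(c, e), rel=1e-10)

    def test_elevated_count_has_small_p_deficit_large_p(self):
        assert region_mid_p(10, 5.0) < 0.05
        assert region_mid_p(5, 10.0) > 0.9

    def test_plain_tail_variant(self):
        # P(X >= c) for Poisson(e)
        from scipy import stats
        assert region_mid_p(4, 2.0, mid=False) == pytest.approx(
            stats.poisson.sf(3, 2.0)
        )
        assert region_mid_p(4, 2.0, mid=False) > region_mid_p(4, 2.0, mid=True)


class TestRestrictedLLR:
    def test_inactive_restriction_equals_unrestricted(self):
        assert restricted_llr(7.5, True) == 7.5

    def test_cold_member_zeroes_statistic(self):
        state = RestrictionState(p_values=np.array([0.01, 0.5]), alpha1=0.2)
        assert not state.hot[1]
        assert restricted_llr(7.5, bool(state.hot.all())) == 0.0

    def test_restricted_never_exceeds_unrestricted(self):
        rng = np.random.default_rng(4)
        llr = rng.uniform(0, 10, size=50)
        ok = rng.random(50) < 0.5
        assert np.all(restricted_llr(llr, ok) <= llr)


class TestFlexibleScan:
    def test_l_hotspot_recovered_exactly_where_circle_overshoots(self):
        """Constructed L-shaped hotspot: the flexible family's best
        restricted zone is exactly the truth, while the best circular zone
        must include at least one non-hotspot region."""
        scen = SimulationScenario(
            rows=8, cols=8, uniform_population=20_000.0,
            zones=(EmbeddedZone(shape="L", rr=2.0, anchor=(1, 1), size=3),),
        )
        area, truth = generate(scen, seed=12)
        true_idx = frozenset(np.flatnonzero(truth).tolist())
        C = area.total_cases
        e = null_expected(area)

        # K = 13 so the corner cell's neighbour ball covers both arm tips
        adj = grid_adjacency(8, 8)
        fam = enumerate_flexible(area, 13, adjacency=adj)
        llr = poisson_llr(fam.aggregate(area.cases), fam.aggregate(e), C)
        cold = region_mid_p(area.cases, e) >= 0.2
        ok = fam.aggregate(cold.astype(float)) == 0
        rstat = np.where(ok, llr, 0.0)
        best_flex = frozenset(fam.members[int(np.argmax(rstat))])
        assert best_flex == true_idx

        cfam = enumerate_circular(area, 0.2)
        cllr = poisson_llr(cfam.aggregate(area.cases), cfam.aggregate(e), C)
        best_circ = set(cfam.members[int(np.argmax(cllr))])
        assert best_circ - true_idx, "circular window should overshoot the L"

    def test_scan_detects_l_hotspot(self):
        from arealscan.simulate import scenario_suite
        area, truth = generate(scenario_suite()["l-hotspot"], seed=3)
        cfg = ScanConfig(scan="flexible", max_regions=7, n_sim=199, seed=3)
        clusters = flexible_scan(area, cfg, adjacency=grid_adjacency(10, 10))
        assert clusters and clusters[0].p_value <= 0.05
        true_ids = {area.ids[i] for i in np.flatnonzero(truth)}
        found = set().union(*[c.members for c in clusters])
        jacc = len(found & true_ids) / len(found | true_ids)
        assert jacc >= 0.5
        assert not found - true_ids  # restriction keeps cold regions out

    def test_all_zero_cases_yields_no_clusters(self):
        area = make_area(range(4), [0] * 4, [100] * 4, [0] * 4)
        cfg = ScanConfig(scan="flexible", max_regions=2, n_sim=19)
        assert flexible_scan(area, cfg) == []

    def test_reproducible_given_seed(self):
        from arealscan.simulate import scenario_suite
        from arealscan import clusters_to_frame
        area, _ = generate(scenario_suite()["l-hotspot"], seed=6)
        cfg = ScanConfig(scan="flexible", max_regions=5, n_sim=99, seed=11)
        adj = grid_adjacency(10, 10)
        f1 = clusters_to_frame(flexible_scan(area, cfg, adjacency=adj))
        f2 = clusters_to_frame(flexible_scan(area, cfg, adjacency=adj))
        assert f1.to_csv() == f2.to_csv()
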