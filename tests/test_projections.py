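import itertools

import numpy as np
import pytest

from quartpac.mutations import MappedMutations
from quartpac.projections import (
    mds_embed,
    run_graphpac,
    run_ipac,
    stress,
    tsp_order,
)
from quartpac.structures import distance_matrix
from quartpac.fixtures import ChainSpec, FixtureSpec, make_structure


def dm_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    diff = pts[:, None, :] - pts[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


LINE = dm_from_points([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
TRIANGLE = dm_from_points([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
SQUARE = dm_from_points([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])


class TestStress:
    def test_perfect_collinear_embedding(self):
        assert stress(np.array([0.0, 1.0, 2.0]), LINE) == pytest.approx(0.0,
                                                                        abs=1e-12)

    def test_two_points_always_embed(self):
        dm = dm_from_points([[0, 0, 0], [0, 0, 7.5]])
        assert stress(np.array([0.0, 7.5]), dm) == pytest.approx(0.0)

    def test_triangle_matches_direct_sum_oracle(self):
        coords = np.array([-0.5, 0.0, 0.5])
        num = den = 0.0
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                d1 = abs(coords[i] - coords[j])
                num += (TRIANGLE[i, j] - d1) ** 2
                den += d1 ** 2
        assert stress(coords, TRIANGLE) == pytest.approx(np.sqrt(num / den),
                                                         abs=1e-12)

    def test_degenerate_coords_raise(self):
        with pytest.raises(ValueError):
            stress(np.zeros(3), TRIANGLE)


def triangle_grid_oracle(step=0.01):
    """Grid search over centered 1D configs (x1 <= x2 <= x3, sum 0)."""
    best = np.inf
    # the family [-a, b, a] (recentred) spans all shapes of a centered
    # 1D triple up to reflection
    for a in np.arange(step, 1.5, step):
        for b in np.arange(-a, a + step, step):
            coords = np.array([-a, b, a])
            try:
                best = min(best, stress(coords - coords.mean(), TRIANGLE))
            except ValueError:
                pass
    return best


class TestMdsEmbed:
    def test_collinear_points_recovered(self):
        emb = mds_embed(LINE, seed=0)
        assert emb.stress < 1e-6
        order = emb.rank_order.tolist()
        assert order in ([0, 1, 2], [2, 1, 0])

    def test_triangle_not_worse_than_grid_oracle(self):
        emb = mds_embed(TRIANGLE, seed=0)
        assert emb.stress <= triangle_grid_oracle(0.01) + 1e-3

    def test_mirror_invariance(self):
        emb = mds_embed(TRIANGLE, seed=0)
        assert stress(-emb.coords, TRIANGLE) == pytest.approx(
            stress(emb.coords, TRIANGLE), abs=1e-12)

    def test_not_worse_than_sklearn_smacof(self):
        """Independent optimizer cross-check on a nontrivial cloud."""
        from sklearn.manifold import smacof

        rng = np.random.default_rng(5)
        dm = dm_from_points(rng.normal(size=(12, 3)))
        emb = mds_embed(dm, seed=0)
        pos, _ = smacof(dm, metric=True, n_components=1, n_init=4,
                        random_state=0, normalized_stress=False)
        assert emb.stress <= stress(pos.ravel(), dm) + 1e-6

    def test_rank_order_is_permutation(self):
        rng = np.random.default_rng(1)
        dm = dm_from_points(rng.normal(size=(15, 3)))
        emb = mds_embed(dm, seed=0)
        assert sorted(emb.rank_order.tolist()) == list(range(15))


def brute_force_path(dm):
    n = dm.shape[0]
    best_len, best = np.inf, None
    for perm in itertools.permutations(range(n)):
        if perm[0] > perm[-1]:
            continue  # reversal symmetric
        length = sum(dm[perm[t], perm[t + 1]] for t in range(n - 1))
        if length < best_len:
            best_len, best = length, perm
    return best_len, best


class TestTspOrder:
    @pytest.mark.parametrize("heuristic", ["nearest_neighbor",
                                           "cheapest_insertion",
                                           "two_opt_refined"])
    def test_collinear_points_in_order(self, heuristic):
        pts = [[3.8 * i, 0, 0] for i in range(6)]
        dm = dm_from_points(pts)
        tour = tsp_order(dm, heuristic=heuristic)
        assert tour.path.tolist() in ([0, 1, 2, 3, 4, 5], [5, 4, 3, 2, 1, 0])
        assert tour.path_length == pytest.approx(3.8 * 5)

    def test_unit_square_optimal_path(self):
        tour = tsp_order(SQUARE, heuristic="two_opt_refined")
        assert tour.path_length == pytest.approx(3.0)
        oracle_len, _ = brute_force_path(SQUARE)
        assert oracle_len == pytest.approx(3.0)

    @pytest.mark.parametrize("heuristic", ["nearest_neighbor",
                                           "cheapest_insertion",
                                           "two_opt_refined"])
    def test_small_random_within_factor_of_optimum(self, heuristic):
        rng = np.random.default_rng(3)
        for trial in range(5):
            dm = dm_from_points(rng.normal(scale=5, size=(7, 3)))
            tour = tsp_order(dm, heuristic=heuristic)
            oracle_len, _ = brute_force_path(dm)
            assert tour.path_length <= 1.25 * oracle_len + 1e-9

    def test_two_opt_never_longer_than_start(self):
        rng = np.random.default_rng(4)
        dm = dm_from_points(rng.normal(scale=5, size=(20, 3)))
        nn = tsp_order(dm, heuristic="nearest_neighbor")
        refined = tsp_order(dm, heuristic="two_opt_refined")
        assert refined.path_length <= nn.path_length + 1e-9

    def test_path_visits_every_residue_once(self):
        rng = np.random.default_rng(6)
        dm = dm_from_points(rng.normal(scale=5, size=(25, 3)))
        tour = tsp_order(dm)
        assert sorted(tour.path.tolist()) == list(range(25))
        # recomputed length matches stored value
        assert tour.path_length == pytest.approx(
            sum(dm[tour.path[t], tour.path[t + 1]] for t in range(24)))


class TestDomainLocality:
    def test_tsp_order_unaffected_by_distant_domain_translation(self):
        """Moving a far-away rigid domain must not reorder the local
        domain's residues on the path (the locality the TSP route buys)."""
        rng = np.random.default_rng(9)
        dom_a = rng.normal(scale=4, size=(12, 3))
        dom_b = rng.normal(scale=4, size=(12, 3)) + np.array([80.0, 0, 0])
        near = np.vstack([dom_a, dom_b])
        far = np.vstack([dom_a, dom_b + np.array([100.0, 0, 0])])
        path1 = tsp_order(dm_from_points(near)).path
        path2 = tsp_order(dm_from_points(far)).path
        a1 = [v for v in path1 if v < 12]
        a2 = [v for v in path2 if v < 12]
        assert a1 == a2 or a1 == a2[::-1]


def _linear_structure(n=100):
    spec = FixtureSpec(chains=[ChainSpec(length=n, accession="P1",
                                         chain_id="A")], seed=0)
    return make_structure(spec)[0]


class TestMethodRunners:
    def test_linear_structure_matches_raw_index_scan(self):
        """On an already-linear chain both projections are the identity (up
        to reversal), so the top cluster equals the raw-index scan."""
        from quartpac.nmc import find_linear_clusters, order_statistics

        st = _linear_structure(100)
        dm = distance_matrix(st)
        mapped = MappedMutations(positions=[5, 6, 6, 7, 50, 80],
                                 n_total_input=6, N=100)
        raw_om = order_statistics(mapped.positions, N_eff=100)
        raw, raw_min = find_linear_clusters(raw_om, serial_of=lambda s: s,
                                            alpha=0.05)
        for runner in (run_ipac, run_graphpac):
            res = runner(st, mapped, alpha=0.05, dm=dm)
            assert res.outcome == "clustering"
            assert res.min_p == pytest.approx(raw_min, rel=1e-9)
            top = res.clusters[0]
            assert {top.start_serial, top.end_serial} == \
                {raw[0].start_serial, raw[0].end_serial}

    def test_blank_short_circuits(self):
        st = _linear_structure(50)
        mapped = MappedMutations(positions=[10], n_total_input=1, N=50)
        for runner in (run_ipac, run_graphpac):
            assert runner(st, mapped).outcome == "blank"

    def test_arrangement_is_mutation_blind(self):
        st = _linear_structure(60)
        dm = distance_matrix(st)
        m1 = MappedMutations(positions=[1, 2, 3], n_total_input=3, N=60)
        m2 = MappedMutations(positions=[10, 40, 55], n_total_input=3, N=60)
        a1 = run_ipac(st, m1, dm=dm).arrangement
        a2 = run_ipac(st, m2, dm=dm).arrangement
        np.testing.assert_array_equal(a1, a2)

    def test_heuristic_choice_rarely_flips_the_call(self):
        """Planted hotspots: the significant/not call agrees across TSP
        heuristics in >= 90% of fixtures."""
        rng = np.random.default_rng(11)
        st = _linear_structure(120)
        dm = distance_matrix(st)
        agree = total = 0
        for trial in range(30):
            center = int(rng.integers(10, 110))
            pos = list(np.clip(rng.normal(center, 1.5, size=8).astype(int),
                               1, 120)) + \
                list(rng.integers(1, 121, size=4))
            mapped = MappedMutations(positions=pos, n_total_input=len(pos),
                                     N=120)
            calls = set()
            for h in ("nearest_neighbor", "cheapest_insertion",
                      "two_opt_refined"):
                res = run_graphpac(st, mapped, dm=dm, heuristic=h)
                calls.add(res.outcome)
            total += 1
            agree += len(calls) == 1
        assert agree / total >= 0.9
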