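"""Thresholding and directed graph measures against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from dirconn.connectivity import clip_connections
from dirconn.containers import ConnectivityMatrix
from dirconn.graphs import (
    auc_over_densities,
    default_density_grid,
    degrees,
    directed_clustering,
    directed_distances,
    global_efficiency,
    local_efficiency,
    measures_over_densities,
    modularity_louvain,
    threshold_by_density,
    transitivity,
)
from dirconn.synthetic import random_digraph

from _oracles import (
    bfs_distances,
    clustering_oracle,
    diameter_oracle,
    efficiency_oracle,
    local_efficiency_oracle,
    max_modularity_bruteforce,
    transitivity_oracle,
)


class TestThresholding:
    def test_keeps_k_largest(self, rng):
        w = clip_connections(rng.random((5, 5)))
        net = threshold_by_density(w, 0.20)
        assert net.n_edges == 4
        off = ~np.eye(5, dtype=bool)
        kept = w[net.adjacency > 0]
        dropped = w[(net.adjacency == 0) & off]
        assert kept.min() >= dropped.max()

    def test_tie_break_is_deterministic(self):
        w = np.full((5, 5), 0.3)
        np.fill_diagonal(w, 0)
        nets = [threshold_by_density(w, 0.20).adjacency for _ in range(3)]
        np.testing.assert_array_equal(nets[0], nets[1])
        np.testing.assert_array_equal(nets[0], nets[2])
        # ties resolve by (row, col): the first four off-diagonal slots
        expected = np.zeros((5, 5))
        expected[0, 1:5] = 1
        np.testing.assert_array_equal(nets[0], expected)

    def test_antisymmetric_at_half_density_keeps_all_positives(self, rng):
        raw = rng.standard_normal((8, 8))
        a = clip_connections(raw - raw.T)  # exactly one positive per pair
        n_pos = int((a > 0).sum())
        net = threshold_by_density(a, 0.5)
        assert net.n_edges == n_pos == 8 * 7 // 2
        np.testing.assert_array_equal(net.adjacency > 0, a > 0)

    def test_unattainable_density_names_maximum(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 2] = 1.0  # only 2 positive entries, max density 0.1
        with pytest.raises(ValueError, match="attainable maximum 0.1"):
            threshold_by_density(w, 0.3)

    def test_weighted_mode_retains_source_weights(self, rng):
        w = clip_connections(rng.random((6, 6)))
        net = threshold_by_density(w, 0.3, mode="weighted")
        nz = net.adjacency > 0
        np.testing.assert_array_equal(net.adjacency[nz], w[nz])

    def test_rejects_negative_matrix_and_bad_density(self, rng):
        with pytest.raises(ValueError, match="clipped"):
            threshold_by_density(rng.standard_normal((4, 4)), 0.2)
        with pytest.raises(ValueError, match="density"):
            threshold_by_density(clip_connections(rng.random((4, 4))), 0.7)

    def test_connectivity_matrix_provenance_propagates(self, rng):
        mat = ConnectivityMatrix(
            clip_connections(rng.random((4, 4))), "antisymmetric", 2, True
        )
        net = threshold_by_density(mat, 0.25)
        assert net.source_method == "antisymmetric" and net.lag == 2


class TestDegrees:
    def test_dag_triangle(self, fixtures):
        d_in, d_out, d_tot = degrees(fixtures["dag_triangle"])
        np.testing.assert_array_equal(d_out, [2, 1, 0])
        np.testing.assert_array_equal(d_in, [0, 1, 2])
        np.testing.assert_array_equal(d_tot, [2, 2, 2])

    def test_cycle(self, fixtures):
        d_in, d_out, _ = degrees(fixtures["cycle3"])
        np.testing.assert_array_equal(d_in, [1, 1, 1])
        np.testing.assert_array_equal(d_out, [1, 1, 1])

    def test_handshake_identity(self, random_digraphs_10):
        for a in random_digraphs_10[:50]:
            d_in, d_out, _ = degrees(a)
            assert d_in.sum() == d_out.sum() == a.sum()

    def test_weighted_strengths(self, rng):
        w = clip_connections(rng.random((5, 5)))
        d_in, d_out, _ = degrees(w)
        np.testing.assert_allclose(d_in, w.sum(axis=0))
        np.testing.assert_allclose(d_out, w.sum(axis=1))


class TestDistancesAndEfficiency:
    def test_cycle_distances_and_diameter(self, fixtures):
        D, diam, disc = directed_distances(fixtures["cycle3"])
        off = D[~np.eye(3, dtype=bool)]
        assert set(off) == {1.0, 2.0} and diam == 2 and not disc

    def test_complete_digraph(self, fixtures):
        D, diam, disc = directed_distances(fixtures["complete4"])
        assert diam == 1 and not disc
        ge = global_efficiency(fixtures["complete4"])
        assert ge["E_in"] == ge["E_out"] == ge["E"] == 1.0

    def test_disconnected_dyads(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1.0
        D, diam, disc = directed_distances(a)
        assert disc and diam == 1
        assert np.isinf(D[0, 2])

    def test_cycle_efficiency_hand_value(self, fixtures):
        ge = global_efficiency(fixtures["cycle3"])
        np.testing.assert_allclose(ge["e_out"], 0.75)
        assert ge["E"] == pytest.approx(0.75)

    def test_empty_network_zero_efficiency(self):
        ge = global_efficiency(np.zeros((5, 5)))
        assert ge["E"] == 0.0
        _, diam, _ = directed_distances(np.zeros((5, 5)))
        assert np.isnan(diam)

    def test_matches_bfs_oracle_on_random_graphs(self, random_digraphs_10):
        for a in random_digraphs_10[:40]:
            D, diam, _ = directed_distances(a)
            np.testing.assert_array_equal(D, bfs_distances(a))
            e_in, e_out, E_in, E_out, E = efficiency_oracle(a)
            ge = global_efficiency(a)
            np.testing.assert_allclose(ge["e_in"], e_in)
            np.testing.assert_allclose(ge["e_out"], e_out)
            assert ge["E"] == pytest.approx(E)
            if np.isfinite(diameter_oracle(a)):
                assert diam == diameter_oracle(a)

    def test_in_out_coincide_on_symmetric_adjacency(self, rng):
        a = random_digraph(8, 0.4, seed=3)
        a = ((a + a.T) > 0).astype(float)
        ge = global_efficiency(a)
        np.testing.assert_allclose(ge["e_in"], ge["e_out"])
        d_in, d_out, _ = degrees(a)
        np.testing.assert_array_equal(d_in, d_out)

    def test_average_identity_E(self, random_digraphs_10):
        for a in random_digraphs_10[:20]:
            ge = global_efficiency(a)
            assert ge["E"] == pytest.approx(0.5 * (ge["E_in"] + ge["E_out"]), abs=1e-15)


class TestLocalEfficiency:
    def test_complete_digraph_is_one(self, fixtures):
        le = local_efficiency(fixtures["complete4"])
        assert le["LE"] == pytest.approx(1.0)

    def test_star_center_zero(self, fixtures):
        le = local_efficiency(fixtures["star"])
        assert le["le_in"][0] == le["le_out"][0] == 0.0

    def test_fewer_than_two_neighbors_contribute_zero(self):
        a = np.zeros((3, 3))
        a[0, 1] = 1.0
        le = local_efficiency(a)
        assert le["LE"] == 0.0

    def test_matches_subgraph_oracle(self, random_digraphs_10):
        for a in random_digraphs_10[:30]:
            le = local_efficiency(a)
            o_in, o_out = local_efficiency_oracle(a)
            np.testing.assert_allclose(le["le_in"], o_in)
            np.testing.assert_allclose(le["le_out"], o_out)
            assert le["LE"] == pytest.approx(0.5 * (le["LE_in"] + le["LE_out"]))


class TestClusteringTransitivity:
    def test_cycle_clustering_one(self, fixtures):
        np.testing.assert_allclose(directed_clustering(fixtures["cycle3"]), 1.0)

    def test_bidirectional_triangle(self, fixtures):
        # (A^3)_ii = 2, d_in = d_out = 2, reciprocal = 2 -> 2/(4-2) = 1
        np.testing.assert_allclose(
            directed_clustering(fixtures["bidirectional_triangle"]), 1.0
        )

    def test_dag_triangle_no_cycles(self, fixtures):
        np.testing.assert_allclose(directed_clustering(fixtures["dag_triangle"]), 0.0)
        assert transitivity(fixtures["dag_triangle"]) == 0.0

    def test_cycle_transitivity_half(self, fixtures):
        assert transitivity(fixtures["cycle3"]) == pytest.approx(0.5)

    def test_edgeless_zero(self):
        assert transitivity(np.zeros((4, 4))) == 0.0
        np.testing.assert_array_equal(directed_clustering(np.zeros((4, 4))), 0.0)

    def test_matches_enumeration_oracle(self):
        for s in range(30):
            a = random_digraph(8, 0.15 + 0.7 * (s % 5) / 4, seed=400 + s)
            np.testing.assert_allclose(directed_clustering(a), clustering_oracle(a))
            assert transitivity(a) == pytest.approx(transitivity_oracle(a))

    def test_transitivity_bounded_on_random_graphs(self, random_digraphs_10):
        for a in random_digraphs_10[:50]:
            assert 0.0 <= transitivity(a) <= 1.0


class TestModularity:
    def test_two_cliques_exact(self, fixtures):
        q, part = modularity_louvain(fixtures["two_cliques"], n_restarts=20, seed=0)
        q_star, _ = max_modularity_bruteforce(fixtures["two_cliques"])
        assert q == pytest.approx(0.5) == pytest.approx(q_star)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_digraph_no_structure(self, fixtures):
        q, _ = modularity_louvain(fixtures["complete4"], n_restarts=10, seed=0)
        assert abs(q) < 1e-12

    def test_never_exceeds_bruteforce_maximum(self):
        for s in range(6):
            a = random_digraph(6, 0.35, seed=70 + s)
            if not a.any():
                continue
            q, _ = modularity_louvain(a, n_restarts=20, seed=s)
            q_star, _ = max_modularity_bruteforce(a)
            assert q <= q_star + 1e-12

    def test_relabeling_invariance(self, fixtures):
        a = fixtures["two_cliques"]
        perm = np.array([3, 0, 4, 1, 5, 2])
        b = a[np.ix_(perm, perm)]
        qa, _ = modularity_louvain(a, n_restarts=20, seed=0)
        qb, _ = modularity_louvain(b, n_restarts=20, seed=0)
        assert qa == pytest.approx(qb, abs=1e-9)

    def test_empty_network_raises(self):
        with pytest.raises(ValueError, match="edgeless"):
            modularity_louvain(np.zeros((4, 4)))


class TestDensitySweepAndAUC:
    def test_single_density_reduces_to_direct_calls(self, rng):
        w = clip_connections(rng.random((8, 8)))
        df = measures_over_densities(w, densities=[0.2], measures=["E", "transitivity"], seed=0)
        net = threshold_by_density(w, 0.2)
        assert df.loc[df.measure == "E", "value"].item() == pytest.approx(
            global_efficiency(net)["E"]
        )
        assert df.loc[df.measure == "transitivity", "value"].item() == pytest.approx(
            transitivity(net)
        )

    def test_row_count(self, rng):
        w = clip_connections(rng.random((6, 6)))
        grid = [0.1, 0.2, 0.3]
        df = measures_over_densities(w, densities=grid, measures=["in_degree", "E"], seed=0)
        assert len(df) == len(grid) * (6 + 1)  # nodal rows + one GLOBAL row

    def test_global_efficiency_nondecreasing_in_density(self, rng):
        w = clip_connections(rng.random((15, 15)))
        df = measures_over_densities(
            w, densities=default_density_grid(0.05, 0.5, 0.05), measures=["E"], seed=0
        )
        vals = df.sort_values("density")["value"].to_numpy()
        assert np.all(np.diff(vals) >= -1e-12)

    def test_unattainable_densities_skipped_with_warning(self, caplog):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 2] = w[2, 3] = 1.0  # max density 0.1
        with caplog.at_level("WARNING"):
            df = measures_over_densities(w, densities=[0.1, 0.4], measures=["E"], seed=0)
        assert set(df["density"]) == {0.1}
        assert "skipping density" in caplog.text

    @staticmethod
    def _curve(densities, values):
        return pd.DataFrame(
            {"density": densities, "measure": "m", "region": "R0", "value": values}
        )

    def test_constant_curve_rectangle(self):
        d = default_density_grid()
        auc = auc_over_densities(self._curve(d, np.ones(len(d))))
        assert auc["auc"].item() == pytest.approx(0.49)

    def test_linear_curve_closed_form(self):
        d = default_density_grid()
        auc = auc_over_densities(self._curve(d, d))
        assert auc["auc"].item() == pytest.approx((0.5**2 - 0.01**2) / 2)

    def test_refinement_quarters_quadratic_error(self):
        exact = (0.5**3 - 0.01**3) / 3
        errs = []
        for step in (0.07, 0.035):
            d = np.arange(0.01, 0.50 + 1e-9, step)
            errs.append(abs(auc_over_densities(self._curve(d, d**2))["auc"].item() - exact))
        assert errs[1] == pytest.approx(errs[0] / 4, rel=0.05)

    def test_non_monotone_grid_raises(self):
        with pytest.raises(ValueError, match="increasing"):
            auc_over_densities(self._curve([0.1, 0.3, 0.2], [1, 1, 1]))

    def test_too_few_densities_raise(self):
        with pytest.raises(ValueError, match="2 densities"):
            auc_over_densities(self._curve([0.1], [1.0]))
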