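"""Lattice geometry, ID conventions and the synaptic graph."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cholnet.topology import (LatticeGeometry, SynapseParams, cell_id,
                              build_default_topology, periodic_distance,
                              periodic_offset, read_edgelist, rewire_EE,
                              sparsify_inhibition, write_edgelist, _positions)

GEOM = LatticeGeometry()


class TestIdsAndDistance:
    @pytest.mark.parametrize("x,y,kind,expected", [
        (0, 0, "E", 1),
        (3, 5, "E", 66),
        (19, 19, "E", 400),
        (0, 0, "I", 401),
        (9, 9, "I", 500),
    ])
    def test_cell_id_examples(self, x, y, kind, expected):
        assert cell_id(x, y, kind) == expected

    def test_cell_id_bijective(self):
        e_ids = {cell_id(x, y, "E") for x in range(20) for y in range(20)}
        i_ids = {cell_id(x, y, "I") for x in range(10) for y in range(10)}
        assert e_ids == set(range(1, 401))
        assert i_ids == set(range(401, 501))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cell_id(20, 0, "E")
        with pytest.raises(ValueError):
            cell_id(0, 10, "I")

    def test_periodic_distance_examples(self):
        assert periodic_distance((0, 0), (19, 0), 20) == pytest.approx(1.0)
        assert periodic_distance((0, 0), (10, 10), 20) == pytest.approx(
            np.sqrt(200))
        assert periodic_distance((3, 7), (3, 7), 20) == 0.0

    @settings(max_examples=100, deadline=None)
    @given(st.tuples(*[st.floats(0, 20, exclude_max=True)] * 6))
    def test_triangle_inequality(self, coords):
        p, q, r = coords[:2], coords[2:4], coords[4:]
        d = periodic_distance
        assert d(p, r, 20) <= d(p, q, 20) + d(q, r, 20) + 1e-9

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 20, exclude_max=True), st.floats(0, 20, exclude_max=True),
           st.floats(0, 20, exclude_max=True), st.floats(0, 20, exclude_max=True))
    def test_symmetry_and_wrap_bound(self, px, py, qx, qy):
        d = periodic_distance((px, py), (qx, qy), 20)
        assert d == pytest.approx(periodic_distance((qx, qy), (px, py), 20))
        assert d <= np.sqrt(2) * 10 + 1e-9


class TestDefaultTopology:
    def test_out_degrees_exact(self, topology):
        w = topology.w
        for j in range(400):  # E sources: 40 E targets + 10 I targets
            assert np.count_nonzero(w[:400, j]) == 40
            assert np.count_nonzero(w[400:, j]) == 10
        for j in range(400, 500):  # I sources: all 400 E + 99 other I
            assert np.count_nonzero(w[:400, j]) == 400
            assert np.count_nonzero(w[400:, j]) == 99
            assert w[j, j] == 0.0

    def test_total_edge_count(self, topology):
        assert np.count_nonzero(topology.w) == 400 * (40 + 10) + 100 * (400 + 99)

    def test_class_weights(self, topology):
        w = topology.w
        assert set(np.unique(w[:400, :400])) == {0.0, 0.01}   # E->E
        assert set(np.unique(w[400:, :400])) == {0.0, 0.05}   # E->I
        assert set(np.unique(w[:400, 400:])) == {0.04}        # I->E full
        vals = set(np.unique(w[400:, 400:]))
        assert vals == {0.0, 0.04}                            # I->I minus autapse

    def test_nearest_neighbor_oracle(self, topology):
        """Brute-force pairwise-distance enumeration reproduces every E cell's
        E and I target sets exactly (same distance/angle/index tie rule)."""
        pos = _positions(GEOM)
        for j in range(0, 400, 7):  # every 7th source: 58 cells, full check
            for (block, k) in ((slice(0, 400), 40), (slice(400, 500), 10)):
                cand = [i for i in range(*block.indices(500)) if i != j]
                keys = []
                for i in cand:
                    dx = (pos[i, 0] - pos[j, 0] + 10) % 20 - 10
                    dy = (pos[i, 1] - pos[j, 1] + 10) % 20 - 10
                    dist = round(float(np.hypot(dx, dy)), 9)
                    ang = float(np.mod(np.arctan2(dy, dx), 2 * np.pi))
                    keys.append((dist, ang, i))
                expected = {i for _, _, i in sorted(keys)[:k]}
                actual = set(np.nonzero(topology.w[block, j])[0]
                             + block.indices(500)[0])
                assert actual == expected, f"source {j}, block {block}"


class TestRewiring:
    def test_p_zero_is_identity(self, topology):
        out = rewire_EE(topology, 0.0, seed=1)
        assert np.array_equal(out.w, topology.w)

    def test_degrees_and_other_edges_preserved(self, topology):
        out = rewire_EE(topology, 0.5, seed=3)
        for j in range(400):
            assert np.count_nonzero(out.w[:400, j]) == 40
            assert out.w[j, j] == 0.0
        assert np.array_equal(out.w[:, 400:], topology.w[:, 400:])
        assert np.array_equal(out.w[400:, :400], topology.w[400:, :400])

    def test_full_rewiring_matches_independent_process_oracle(self, topology):
        """At p=1 the fraction of original local targets surviving in the new
        set matches an independent re-simulation of the sequential
        remove-and-redraw process (each edge redrawn uniformly avoiding self
        and duplicates, processed in target order)."""
        n_seeds = 20
        orig = [set(np.nonzero(topology.w[:400, j])[0]) for j in range(400)]
        measured = []
        for seed in range(n_seeds):
            out = rewire_EE(topology, 1.0, seed=seed)
            ov = np.mean([len(orig[j] & set(np.nonzero(out.w[:400, j])[0]))
                          for j in range(400)])
            measured.append(ov / 40.0)
        # oracle: simulate the same marginal process with an unrelated RNG
        rng = np.random.default_rng(987654)
        oracle = []
        for _ in range(n_seeds):
            vals = []
            for j in range(0, 400, 4):
                targets = sorted(orig[j])
                current = set(targets)
                for t in targets:
                    current.discard(t)
                    while True:
                        new = int(rng.integers(400))
                        if new != j and new not in current:
                            break
                    current.add(new)
                vals.append(len(current & orig[j]) / 40.0)
            oracle.append(np.mean(vals))
        se = np.sqrt(np.var(measured, ddof=1) / n_seeds
                     + np.var(oracle, ddof=1) / n_seeds)
        assert abs(np.mean(measured) - np.mean(oracle)) < 3 * max(se, 1e-4)


class TestSparseInhibition:
    def test_full_density_default_weight_is_noop(self, topology):
        out = sparsify_inhibition(topology, 1.0, 0.04, seed=1)
        assert np.array_equal(out.w, topology.w)

    def test_kept_fraction_within_binomial_error(self, topology):
        density = 0.4
        out = sparsify_inhibition(topology, density, 0.075, seed=5)
        n_orig = np.count_nonzero(topology.w[:, 400:])
        n_kept = np.count_nonzero(out.w[:, 400:])
        se = np.sqrt(density * (1 - density) * n_orig)
        assert abs(n_kept - density * n_orig) < 3 * se
        kept = out.w[:, 400:][out.w[:, 400:] != 0]
        assert np.all(kept == 0.075)
        assert np.array_equal(out.w[:, :400], topology.w[:, :400])

    def test_invalid_density_rejected(self, topology):
        with pytest.raises(ValueError):
            sparsify_inhibition(topology, 0.0, 0.04, seed=1)


def test_edgelist_round_trip(topology, tmp_path):
    path = tmp_path / "topo.tsv"
    write_edgelist(topology, path, header={"note": "test"})
    back = read_edgelist(path)
    assert np.allclose(back.w, topology.w)
    assert back.geometry == topology.geometry
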