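"""RDFs, hydrogen bonds, clusters and their brute-force oracles."""

import numpy as np
import pytest

from membrane_probe import analysis, species as sp
from membrane_probe.analysis import HBondCriteria
from membrane_probe.core import Trajectory

from conftest import (
    brute_clusters,
    brute_hbonds,
    brute_pair_distance_counts,
    make_frame,
    make_hb_pair,
)


def _point_molecules(points):
    return [([sp.FLAV], [p]) for p in points]


class TestComRDF:
    def test_two_molecules_fixed_separation(self):
        frame = make_frame(_point_molecules([(1.0, 1.0, 1.0), (2.0, 1.0, 1.0)]), box=(6, 6, 6))
        rdf = analysis.com_rdf(Trajectory(frames=[frame]), "flav", r_max=2.0, bin_width=0.1)
        nz = np.nonzero(rdf.g)[0]
        assert len(nz) == 1
        assert rdf.r_centers[nz[0]] == pytest.approx(1.05, abs=0.051)

    @pytest.mark.parametrize("mode", ["3d", "lateral"])
    def test_poisson_gas_gives_unit_g(self, mode):
        rng = np.random.default_rng(3)
        box = (8.0, 8.0, 8.0)
        frames = [make_frame(_point_molecules(rng.uniform((0, 0, 0), box, (400, 3))), box)
                  for _ in range(6)]
        rdf = analysis.com_rdf(Trajectory(frames=frames), "flav", mode=mode,
                               r_max=3.5, bin_width=0.25)
        # skip the smallest shells where counting noise dominates
        assert np.all(np.abs(rdf.g[2:] - 1.0) < 0.25)
        assert abs(np.mean(rdf.g[2:]) - 1.0) < 0.03

    @pytest.mark.parametrize("mode", ["3d", "lateral"])
    def test_pair_counts_match_brute_force(self, mode):
        rng = np.random.default_rng(5)
        box = np.array([5.0, 5.0, 5.0])
        pts = rng.uniform(0, 5, (20, 3))
        frame = make_frame(_point_molecules(pts), box)
        bw, rmax = 0.25, 2.4
        rdf = analysis.com_rdf(Trajectory(frames=[frame]), "flav", mode=mode,
                               r_max=rmax, bin_width=bw)
        edges = np.arange(0, len(rdf.g) + 1) * bw
        brute = brute_pair_distance_counts(pts, box, edges, lateral=(mode == "lateral"))
        n_pairs = 20 * 19 / 2
        if mode == "3d":
            norm = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3) / np.prod(box)
        else:
            norm = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2) / (box[0] * box[1])
        np.testing.assert_allclose(rdf.g, brute / (n_pairs * norm), rtol=1e-12)

    def test_r_max_beyond_half_box_rejected(self):
        frame = make_frame(_point_molecules([(0, 0, 0), (1, 1, 1)]), box=(4, 4, 4))
        with pytest.raises(ValueError, match="half"):
            analysis.com_rdf(Trajectory(frames=[frame]), "flav", r_max=3.0)

    def test_aggregated_dda_has_large_g_at_small_r(self, aggregate_bilayer):
        rdf = analysis.com_rdf(aggregate_bilayer, "dda", mode="lateral",
                               r_max=4.0, bin_width=0.25)
        assert rdf.g[:4].max() > 5.0  # strong short-range excess for an aggregate


class TestHBondDetection:
    def test_planted_dimer_found_exactly(self):
        mol_a, mol_b = make_hb_pair(2.0, 2.0, 2.0)
        frame = make_frame([mol_a, mol_b], box=(6, 6, 6))
        graph = analysis.detect_hbonds(frame)
        inter = graph.intermolecular()
        assert len(inter) == 1
        bond = inter[0]
        assert (bond.donor_molecule, bond.acceptor_molecule) == (0, 1)
        assert bond.distance == pytest.approx(0.28, abs=1e-9)
        assert bond.angle == pytest.approx(180.0, abs=1e-6)

    def test_beyond_cutoff_no_bonds(self):
        mol_a, mol_b = make_hb_pair(2.0, 2.0, 2.0, oo=0.45)
        frame = make_frame([mol_a, mol_b], box=(6, 6, 6))
        assert analysis.detect_hbonds(frame).intermolecular() == []

    def test_angle_criterion_enforced(self):
        # bent geometry: acceptor placed perpendicular to the O-H bond
        d_o = np.array([2.0, 2.0, 2.0])
        h = d_o + (0.096, 0.0, 0.0)
        a_o = d_o + (0.0, 0.28, 0.0)  # D...A = 0.28 but angle ~ 70 deg
        frame = make_frame([
            ([sp.DDA_O, sp.DDA_H], [d_o, h]),
            ([sp.DDA_O], [a_o]),
        ], box=(6, 6, 6))
        assert analysis.detect_hbonds(frame).intermolecular() == []

    def test_minimum_image_bond_across_boundary(self):
        # donor near the box face bonds to an acceptor wrapped on the other side
        mol_a, mol_b = make_hb_pair(5.9, 2.0, 2.0)  # acceptor lands at x=6.18 -> wraps
        frame = make_frame([mol_a, mol_b], box=(6, 6, 6))
        inter = analysis.detect_hbonds(frame).intermolecular()
        assert len(inter) == 1
        assert inter[0].distance == pytest.approx(0.28, abs=1e-9)

    def test_agrees_with_brute_force_on_aggregate(self, aggregate_bilayer):
        for frame in aggregate_bilayer:
            got = {(b.donor_index, b.acceptor_index)
                   for b in analysis.detect_hbonds(frame).bonds}
            assert got == brute_hbonds(frame)


class TestMoleculeClusters:
    def _chain_frame(self, n):
        mols = []
        for i in range(n):
            a, b = make_hb_pair(1.0 + 0.5 * i, 2.0, 2.0)
            mols.append(a if i == 0 else a)
        # build an explicit chain: molecule i's donor bonds molecule i+1's acceptor
        mols = []
        for i in range(n):
            x = 1.0 + 0.4 * i
            d_o = np.array([x, 2.0, 2.0])
            h = d_o + (0.096, 0.0, 0.0)
            # acceptor O of this molecule sits where the previous donor points
            acc = d_o - (0.12, 0.0, 0.0)
            mols.append(([sp.DDA_O, sp.DDA_H, sp.DDA_O], [d_o, h, acc]))
        return make_frame(mols, box=(max(8.0, n), 4.0, 4.0))

    def test_pairwise_chained_molecules_form_one_cluster(self):
        frame = self._chain_frame(10)
        cs = analysis.molecule_clusters(frame, "dda", "hbond")
        assert cs.sizes[0] == 10 and len(cs.clusters) == 1

    def test_no_edges_gives_singletons(self):
        mols = [([sp.DDA_C, sp.DDA_C], [(i * 2.0, 1.0, 1.0), (i * 2.0, 1.0, 2.0)])
                for i in range(5)]
        frame = make_frame(mols, box=(10, 4, 4))
        cs = analysis.molecule_clusters(frame, "dda", "com_distance", cutoff=0.5)
        assert np.all(cs.sizes == 1) and len(cs.clusters) == 5
        assert cs.largest_z_span == pytest.approx(1.0, abs=1e-12)

    def test_unknown_edge_rule_rejected(self, aggregate_bilayer):
        with pytest.raises(ValueError, match="edge rule"):
            analysis.molecule_clusters(aggregate_bilayer[0], "dda", "voronoi")

    def test_com_distance_clusters_match_union_find_oracle(self):
        rng = np.random.default_rng(9)
        box = np.array([6.0, 6.0, 6.0])
        pts = rng.uniform(0, 6, (30, 3))
        frame = make_frame([([sp.DDA_C], [p]) for p in pts], box)
        cutoff = 1.2
        cs = analysis.molecule_clusters(frame, "dda", "com_distance", cutoff=cutoff)
        edges = []
        for i in range(30):
            for j in range(i + 1, 30):
                d = pts[i] - pts[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) <= cutoff:
                    edges.append((i, j))
        assert set(cs.clusters) == brute_clusters(range(30), edges)

    def test_planted_aggregate_spans_membrane_core(self, aggregate_bilayer):
        cs = analysis.molecule_clusters(aggregate_bilayer[0], "dda", "com_distance", cutoff=2.5)
        assert cs.largest_z_span > 2.0  # z_span 2.4 plus carboxyl protrusions


class TestHBondStatistics:
    def _frame_with_bonds(self, k, total=24):
        # constant particle count: ``total`` carboxyl pairs, of which the
        # first k sit in bonding geometry and the rest are too far apart
        mols = []
        for i in range(total):
            oo = 0.28 if i < k else 0.45
            a, b = make_hb_pair(0.7 + 1.9 * (i % 6), 0.7 + 1.9 * (i // 6), 2.0, oo=oo)
            mols.extend([a, b])
        return make_frame(mols, box=(12, 12, 4))

    def test_planted_counts_reproduce_mean_and_population_sd(self):
        counts = [18, 22, 20, 24, 19]
        traj = Trajectory(frames=[self._frame_with_bonds(k) for k in counts])
        stats = analysis.hbond_statistics(traj, window=None)
        assert stats.mean == pytest.approx(np.mean(counts))
        assert stats.sd == pytest.approx(np.std(counts, ddof=0))
        np.testing.assert_array_equal(stats.counts, counts)

    def test_constant_counts_give_zero_sd(self):
        traj = Trajectory(frames=[self._frame_with_bonds(5)] * 4)
        stats = analysis.hbond_statistics(traj, window=None)
        assert stats.mean == 5.0 and stats.sd == 0.0

    def test_window_selects_last_frames_exactly(self):
        counts = [1, 2, 3, 4]
        traj = Trajectory(frames=[self._frame_with_bonds(k) for k in counts])
        stats = analysis.hbond_statistics(traj, window=(0.5, 1.0))
        np.testing.assert_array_equal(stats.counts, [3, 4])

    def test_single_frame_sd_undefined(self):
        traj = Trajectory(frames=[self._frame_with_bonds(3)])
        stats = analysis.hbond_statistics(traj, window=None)
        assert stats.mean == 3.0 and stats.sd is None
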