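"""Generator contracts: planted geometry, determinism, validation."""

import numpy as np
import pytest

from membrane_probe import afm, saxs, species as sp
from membrane_probe.epr import read_epr_table
from membrane_probe.synthetic import (
    AggregateSpec,
    BilayerSpec,
    Flat,
    GaussianRoughness,
    SAXSGenSpec,
    Sinusoid,
    SpecValidationError,
    ThinPatchSpec,
    WaterSpec,
    WireSpec,
    build_trajectory,
    generate_epr_table,
    generate_force_curve,
    generate_height_map,
    generate_saxs_curve,
)


class TestBilayerGenerator:
    def test_plain_bilayer_construction(self, plain_bilayer):
        frame = plain_bilayer[0]
        heads = frame.select(sp.LIPID_HEAD)
        assert heads.sum() == 128
        assert len(np.unique(frame.molecule_id)) == 128
        z = frame.positions[heads, 2]
        # head beads at +-1.85 nm, jitter sigma 0.05 nm
        assert np.all(np.abs(np.abs(z) - 1.85) < 0.3)
        assert (z > 0).sum() == 64 and (z < 0).sum() == 64

    def test_lipid_com_sits_below_head_bead(self, plain_bilayer):
        # 11 equal-mass beads spaced 0.12 nm: COM is 0.6 nm below the head
        frame = plain_bilayer[0]
        mol0 = frame.positions[frame.molecule_id == 0]
        head_z = mol0[0, 2]
        assert abs((head_z - mol0[:, 2].mean()) - 0.6) < 0.1

    def test_planted_wire_geometry(self):
        spec = BilayerSpec(
            lipids_per_leaflet=4, lateral_box=(4.0, 4.0), positional_jitter_sigma=0.0,
            water=WaterSpec(count=0, slab_bounds=(2.2, 2.6),
                            wire=WireSpec(n_waters=8, spacing=0.28, endpoints_z=(-1.0, 1.0))),
            seed=3,
        )
        traj = build_trajectory(spec, 1)
        frame = traj[0]
        o = frame.positions[frame.select(sp.WATER_O)]
        assert len(o) == 8
        # collinear: identical x, y
        assert np.ptp(o[:, 0]) < 1e-12 and np.ptp(o[:, 1]) < 1e-12
        d = np.diff(np.sort(o[:, 2]))
        assert np.allclose(d, 0.28, atol=1e-12)
        assert traj.metadata["wire"]["molecule_ids"] == sorted(
            np.unique(frame.molecule_id[frame.select(sp.WATER_O)]).tolist())

    def test_determinism_bitwise(self):
        spec = BilayerSpec(lipids_per_leaflet=16, lateral_box=(5, 5),
                           aggregate=AggregateSpec(n_dda=4, center_xy=(2.5, 2.5)),
                           water=WaterSpec(count=30), flavonoid_count=5, seed=99)
        t1 = build_trajectory(spec, 3)
        t2 = build_trajectory(spec, 3)
        for f1, f2 in zip(t1, t2):
            assert np.array_equal(f1.positions, f2.positions)
            assert np.array_equal(f1.species, f2.species)

    def test_planted_patch_audit(self, patch_bilayer):
        frame = patch_bilayer[0]
        manifest = patch_bilayer.metadata
        inside = manifest["patch"]["lipid_ids_inside"]
        assert len(inside) == 8  # 4 lipids per leaflet fall inside radius 1.5
        for mol in inside:
            head_z = frame.positions[(frame.molecule_id == mol)
                                     & (frame.species == sp.LIPID_HEAD), 2][0]
            assert abs(abs(head_z) - 1.35) < 0.3

    def test_planted_aggregate_audit(self, aggregate_bilayer):
        frame = aggregate_bilayer[0]
        manifest = aggregate_bilayer.metadata["aggregate"]
        assert len(manifest["molecule_ids"]) == 8
        # brute-force coordinate inspection: every planted pair has one
        # donor O within 0.28 nm of an acceptor O of the partner molecule
        for mol_a, mol_b in manifest["planted_hbonds"]:
            oa = frame.positions[(frame.molecule_id == mol_a) & (frame.species == sp.DDA_O)]
            ob = frame.positions[(frame.molecule_id == mol_b) & (frame.species == sp.DDA_O)]
            dmin = min(np.linalg.norm(a - b) for a in oa for b in ob)
            assert abs(dmin - 0.28) < 1e-9

    @pytest.mark.parametrize("bad_spec, field", [
        (dict(patch=ThinPatchSpec(head_plane_offset_inside=2.5)), "head_plane_offset_inside"),
        (dict(water=WaterSpec(wire=WireSpec(endpoints_z=(0.5, 1.0)))), "endpoints_z"),
        (dict(aggregate=AggregateSpec(carboxyl_pairing=1.5)), "carboxyl_pairing"),
        (dict(head_plane_offset=0.3), "head_plane_offset"),
    ])
    def test_validation_names_offending_field(self, bad_spec, field):
        with pytest.raises(SpecValidationError, match=field):
            build_trajectory(BilayerSpec(**bad_spec), 1)


class TestSAXSGenerator:
    def test_zero_noise_equals_forward_model(self):
        spec = SAXSGenSpec(noise_fraction=0.0)
        curve = generate_saxs_curve(spec)
        ideal = saxs.model_intensity(spec.edp, spec.mct, spec.q_grid, spec.scale)
        assert np.max(np.abs(curve.I - ideal) / ideal) <= 1e-12

    def test_noise_statistics_and_reproducibility(self):
        spec = SAXSGenSpec(noise_fraction=0.01, seed=5)
        c1 = generate_saxs_curve(spec)
        c2 = generate_saxs_curve(spec)
        assert np.array_equal(c1.I, c2.I)
        ideal = saxs.model_intensity(spec.edp, spec.mct, spec.q_grid, spec.scale)
        mean_rel = np.mean(np.abs(c1.I - ideal) / ideal)
        # E|eps| = sigma * sqrt(2/pi) ~ 0.0080 for sigma = 0.01
        assert 0.006 < mean_rel < 0.010

    def test_unilamellar_limit_no_bragg_peaks(self):
        spec = SAXSGenSpec(noise_fraction=0.0, mct=saxs.MCTParams(n_layers=1))
        curve = generate_saxs_curve(spec)
        q = spec.q_grid
        expected = saxs.form_factor(spec.edp, q) ** 2 / q**2
        ratio = curve.I / expected
        assert np.allclose(ratio, ratio[0], rtol=1e-9)


class TestEPRTableGenerator:
    def test_round_trip_through_reader(self, tmp_path):
        path = tmp_path / "epr.csv"
        generate_epr_table([("control", 50.116, 18.576)], path=path)
        df = read_epr_table(path)
        assert df.loc[0, "two_A_par_G"] == 50.116
        assert df.loc[0, "two_A_perp_G"] == 18.576

    def test_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        generate_epr_table([], path=path)
        assert len(read_epr_table(path)) == 0

    def test_invalid_splittings_rejected(self):
        with pytest.raises(SpecValidationError):
            generate_epr_table([("bad", 18.0, 50.0)])
        with pytest.raises(SpecValidationError):
            generate_epr_table([("bad", float("nan"), 1.0)])


class TestForceCurveGenerator:
    def test_pure_hertz_inverse_consistency(self):
        curve = generate_force_curve(modulus=2.0e7, breakthrough=None, noise=0.0)
        fit = afm.fit_modulus(curve)
        assert abs(fit.modulus - 2.0e7) / 2.0e7 < 1e-12

    def test_planted_breakthrough_recovered_exactly(self):
        curve = generate_force_curve(modulus=2.0e7, breakthrough=(200.0, 4.0), noise=0.0)
        bt = afm.detect_breakthrough(curve)
        assert bt.yield_force == pytest.approx(200.0, abs=1e-9)
        assert bt.thickness == pytest.approx(4.0, abs=1e-9)

    def test_noise_reproducible(self):
        c1 = generate_force_curve(2.0e7, noise=5.0, seed=8)
        c2 = generate_force_curve(2.0e7, noise=5.0, seed=8)
        assert np.array_equal(c1.force, c2.force)

    def test_invalid_breakthrough_rejected(self):
        with pytest.raises(SpecValidationError):
            generate_force_curve(2.0e7, breakthrough=(-5.0, 4.0))


class TestHeightMapGenerator:
    def test_flat_surface_has_zero_roughness(self):
        hm = generate_height_map((16, 16), Flat())
        ra, rms = afm.surface_roughness(hm.heights)
        assert ra == 0.0 and rms == 0.0

    def test_sinusoid_closed_forms(self):
        # one whole period sampled at 2048 pixel centres: R_a -> 2A/pi
        # (second-order in the pixel size), RMS = A/sqrt(2) exactly
        amp, n = 1.2, 2048
        hm = generate_height_map((4, n), Sinusoid(amplitude=amp, period=n * 25.4), pixel_size=25.4)
        ra, rms = afm.surface_roughness(hm.heights)
        assert abs(ra - 2 * amp / np.pi) <= 1e-6
        assert abs(rms - amp / np.sqrt(2)) <= 1e-6

    def test_gaussian_rms_converges_to_sigma(self):
        hm = generate_height_map((512, 512), GaussianRoughness(sigma=0.5), seed=4)
        _, rms = afm.surface_roughness(hm.heights, flatten=False)
        assert abs(rms - 0.5) / 0.5 < 0.01
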