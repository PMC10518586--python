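"""Electron-density profile, form factor, Caillé structure factor, fitting."""

import numpy as np
import pytest
from scipy.integrate import quad

from membrane_probe import saxs
from membrane_probe.saxs import EDPParams, MCTParams
from membrane_probe.synthetic import SAXSGenSpec, generate_saxs_curve


def random_edp(rng):
    R = np.sort(rng.uniform(0.3, 3.0, 3))
    while np.min(np.diff(R)) < 0.2:
        R = np.sort(rng.uniform(0.3, 3.0, 3))
    return EDPParams(
        rho=(334.0, *rng.uniform(150.0, 500.0, 3)),
        R=tuple(R),
        sigma=tuple(rng.uniform(0.05, 0.5, 3)),
    )


def quadrature_form_factor(params, q):
    upper = params.R[2] + 12 * max(params.sigma)
    val, _ = quad(lambda r: (saxs.edp_evaluate(params, r) - params.rho[0]) * np.cos(q * r),
                  0.0, upper, limit=400)
    return 2.0 * val


class TestEDP:
    def test_tends_to_solvent_baseline_far_away(self):
        p = EDPParams(rho=(334, 300, 200, 260), R=(0.5, 1.3, 2.2), sigma=(0.2, 0.3, 0.3))
        assert saxs.edp_evaluate(p, 50.0) == pytest.approx(334.0, abs=1e-12)
        assert saxs.edp_evaluate(p, -50.0) == pytest.approx(334.0, abs=1e-12)

    def test_even_in_r(self):
        rng = np.random.default_rng(0)
        p = random_edp(rng)
        r = rng.uniform(-4, 4, 50)
        np.testing.assert_allclose(saxs.edp_evaluate(p, r), saxs.edp_evaluate(p, -r), rtol=1e-14)

    def test_sharp_step_limit_matches_piecewise_oracle(self):
        p = EDPParams(rho=(334, 300, 200, 260), R=(0.5, 1.3, 2.2), sigma=(1e-7, 1e-7, 1e-7))
        r = np.array([0.0, 0.3, 0.49, 0.51, 1.0, 1.6, 2.1, 2.3, 3.0])

        def oracle(ri):
            # each smoothed box becomes an indicator of |r| < R_i
            rho = p.rho[0]
            for i in range(3):
                if abs(ri) < p.R[i]:
                    rho += p.rho[i + 1] - p.rho[i]
            return rho

        np.testing.assert_allclose(saxs.edp_evaluate(p, r), [oracle(x) for x in r], rtol=1e-12)
        assert saxs.edp_evaluate(p, 0.0) == pytest.approx(p.rho[3], rel=1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            EDPParams(rho=(334, 300, 200, 260), R=(1.3, 0.5, 2.2), sigma=(0.2, 0.3, 0.3))
        with pytest.raises(ValueError, match="sigma"):
            EDPParams(rho=(334, 300, 200, 260), R=(0.5, 1.3, 2.2), sigma=(0.2, -0.3, 0.3))


class TestFormFactor:
    def test_zero_q_gives_total_excess_electrons_per_area(self):
        rng = np.random.default_rng(1)
        p = random_edp(rng)
        expected, _ = quad(lambda r: saxs.edp_evaluate(p, r) - p.rho[0], -60, 60, limit=400)
        assert saxs.form_factor(p, 0.0) == pytest.approx(expected, rel=1e-7)

    def test_closed_form_matches_quadrature(self):
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = random_edp(rng)
            for q in (0.05, 0.7, 2.1, 4.4, 6.0):
                F = float(saxs.form_factor(p, q))
                Fq = quadrature_form_factor(p, q)
                assert abs(F - Fq) <= 1e-6 * max(abs(Fq), 1.0)

    def test_zero_contrast_gives_zero(self):
        p = EDPParams(rho=(334, 334, 334, 334), R=(0.5, 1.3, 2.2), sigma=(0.2, 0.3, 0.3))
        q = np.linspace(0.0, 6.0, 100)
        assert np.all(saxs.form_factor(p, q) == 0.0)


class TestStructureFactor:
    def test_single_layer_is_unity(self):
        q = np.linspace(0.1, 6.0, 200)
        np.testing.assert_array_equal(saxs.mct_structure_factor(MCTParams(n_layers=1), q),
                                      np.ones_like(q))

    def test_zero_eta_reduces_to_ideal_lattice(self):
        m = MCTParams(n_layers=7, d_spacing=6.3, eta=0.0)
        q = np.linspace(0.2, 4.0, 1000)
        S = saxs.mct_structure_factor(m, q)
        ideal = np.sin(7 * q * 6.3 / 2) ** 2 / np.sin(q * 6.3 / 2) ** 2
        np.testing.assert_allclose(S, ideal, atol=1e-8)
        q1 = 2 * np.pi / 6.3
        assert saxs.mct_structure_factor(m, np.array([q1]))[0] == pytest.approx(49.0, rel=1e-10)

    def test_eta_monotonically_damps_the_bragg_peak(self):
        q1 = 2 * np.pi / 6.3
        peaks = [saxs.mct_structure_factor(MCTParams(n_layers=10, d_spacing=6.3, eta=e),
                                           np.array([q1]))[0]
                 for e in (0.0, 0.05, 0.1, 0.2, 0.4)]
        assert np.all(np.diff(peaks) < 0)

    def test_structure_factor_is_nonnegative(self):
        q = np.linspace(0.05, 6.0, 500)
        for eta in (0.0, 0.1, 0.3):
            assert np.all(saxs.mct_structure_factor(
                MCTParams(n_layers=12, d_spacing=6.3, eta=eta), q) >= 0.0)


class TestModelIntensity:
    def test_diffuse_only_is_lorentz_weighted_form_factor(self):
        p = random_edp(np.random.default_rng(3))
        m = MCTParams(n_layers=10, d_spacing=6.3, eta=0.1, diffuse_fraction=1.0)
        q = np.linspace(0.1, 6.0, 300)
        np.testing.assert_allclose(saxs.model_intensity(p, m, q),
                                   saxs.form_factor(p, q) ** 2 / q**2, rtol=1e-12)

    def test_single_layer_equals_diffuse_case(self):
        p = random_edp(np.random.default_rng(4))
        q = np.linspace(0.1, 6.0, 300)
        a = saxs.model_intensity(p, MCTParams(n_layers=1, diffuse_fraction=0.2), q)
        b = saxs.model_intensity(p, MCTParams(n_layers=10, diffuse_fraction=1.0), q)
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_q_zero_rejected(self):
        p = random_edp(np.random.default_rng(5))
        with pytest.raises(ValueError, match="q"):
            saxs.model_intensity(p, MCTParams(), np.array([0.0, 0.1]))


class TestFit:
    def test_noiseless_recovery_from_perturbed_init(self):
        spec = SAXSGenSpec(noise_fraction=0.0, mct=MCTParams(n_layers=1))
        curve = generate_saxs_curve(spec)
        truth = np.array([*spec.edp.rho[1:], *spec.edp.R, *spec.edp.sigma])
        rng = np.random.default_rng(8)
        f = 1 + rng.uniform(-0.1, 0.1, 9)
        edp0 = EDPParams(rho=(spec.edp.rho[0], *(truth[:3] * f[:3])),
                         R=tuple(truth[3:6] * f[3:6]), sigma=tuple(truth[6:9] * f[6:9]))
        fit = saxs.fit_saxs(curve, edp0, MCTParams(n_layers=1), scale0=1.0,
                            q_window=(0.05, 6.0), vary_scale=False)
        got = np.array([*fit.edp.rho[1:], *fit.edp.R, *fit.edp.sigma])
        assert np.max(np.abs(got - truth) / truth) <= 1e-3
        assert fit.success

    def test_intensity_scale_invariance(self):
        spec = SAXSGenSpec(noise_fraction=0.01, seed=3, mct=MCTParams(n_layers=1))
        curve = generate_saxs_curve(spec)
        c = 37.5
        scaled = saxs.SAXSCurve(q=curve.q, I=c * curve.I, sigma_I=c * curve.sigma_I)
        f1 = saxs.fit_saxs(curve, spec.edp, MCTParams(n_layers=1), q_window=(0.05, 6.0))
        f2 = saxs.fit_saxs(scaled, spec.edp, MCTParams(n_layers=1), q_window=(0.05, 6.0))
        assert f2.scale / f1.scale == pytest.approx(c, rel=1e-4)
        np.testing.assert_allclose(f2.edp.R, f1.edp.R, rtol=1e-5)
        np.testing.assert_allclose(f2.edp.sigma, f1.edp.sigma, rtol=1e-5)

    def test_empty_window_is_an_error(self):
        spec = SAXSGenSpec(noise_fraction=0.0)
        curve = generate_saxs_curve(spec)
        with pytest.raises(ValueError, match="q_window"):
            saxs.fit_saxs(curve, spec.edp, q_window=(10.0, 12.0))

    def test_curve_file_round_trip(self, tmp_path):
        spec = SAXSGenSpec(noise_fraction=0.01, seed=2)
        curve = generate_saxs_curve(spec)
        path = tmp_path / "curve.dat"
        saxs.write_saxs_curve(curve, path)
        back = saxs.read_saxs_curve(path)
        np.testing.assert_allclose(back.q, curve.q, rtol=1e-7)
        np.testing.assert_allclose(back.I, curve.I, rtol=1e-7)
        np.testing.assert_allclose(back.sigma_I, curve.sigma_I, rtol=1e-7)


class TestEDPReport:
    def test_center_density_contrast_flagged(self):
        # sharp steps so the centre-level change cannot leak into the
        # head-peak region through the smoothing tails
        base = EDPParams(rho=(334, 300, 200, 260), R=(0.5, 1.3, 2.2), sigma=(0.1, 0.1, 0.1))
        raised = EDPParams(rho=(334, 300, 200, 290), R=(0.5, 1.3, 2.2), sigma=(0.1, 0.1, 0.1))
        mct = MCTParams(n_layers=1)
        fits = [saxs.FitResult(edp=p, mct=mct, scale=1.0, redchi=0.0, stderr={},
                               q_window=(0.5, 2.5), success=True, message="")
                for p in (base, raised)]
        profiles, desc = saxs.edp_report(fits, ["control", "with_dda"])
        assert desc.loc["with_dda", "center_density_change_vs_first"] == 1
        assert desc.loc["with_dda", "head_position_change_vs_first"] == 0
        assert set(profiles.columns) == {"r_nm", "control", "with_dda"}

    def test_descriptors_match_dense_grid_oracle(self):
        p = EDPParams(rho=(334, 300, 185, 260), R=(0.55, 1.35, 2.35), sigma=(0.22, 0.4, 0.45))
        d = saxs.edp_descriptors(p)
        r = np.linspace(0, 4, 200001)
        rho = saxs.edp_evaluate(p, r)
        assert d["head_peak_position"] == pytest.approx(r[np.argmax(rho)], abs=1e-3)
        assert d["center_density"] == pytest.approx(saxs.edp_evaluate(p, 0.0), rel=1e-12)

    def test_single_fit_table(self):
        p = EDPParams(rho=(334, 300, 200, 260), R=(0.5, 1.3, 2.2), sigma=(0.2, 0.3, 0.3))
        fit = saxs.FitResult(edp=p, mct=MCTParams(n_layers=1), scale=1.0, redchi=0.0,
                             stderr={}, q_window=(0.5, 2.5), success=True, message="")
        profiles, desc = saxs.edp_report([fit])
        assert len(desc) == 1 and profiles.shape[1] == 2

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            saxs.edp_report([])
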