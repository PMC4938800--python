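import numpy as np
import pytest

from rotormech import fixtures, mechanics
from rotormech._geometry import rotation_about_axis
from rotormech.mechanics import (AnglePair, AngleSeries, VectorDefinition,
                                 amplification, angle_series, angle_sigma,
                                 coupling_relation, double_gaussian,
                                 fit_angle_models, resolve_vectors,
                                 single_gaussian, torsional_stiffness)
from rotormech.structure import ConformerEnsemble


def line_def(name, a, b):
    return VectorDefinition(name, "line", "A", (a, b))


class TestResolveVectors:
    def test_line_and_plane(self):
        s = fixtures.build_reference_trace((6,))
        s.coord[:] = 0.0
        s.coord[1] = [0, 0, 2]
        s.coord[2] = [1, 0, 0]
        s.coord[3] = [0, 1, 0]
        defs = {
            "l": line_def("l", 1, 2),
            "p": VectorDefinition("p", "plane_normal", "A", (1, 3, 4)),
            "p_rev": VectorDefinition("p_rev", "plane_normal", "A", (1, 4, 3)),
        }
        v = resolve_vectors(s.coord, s, defs)
        np.testing.assert_allclose(v["l"], [0, 0, 1])
        np.testing.assert_allclose(v["p"], [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(v["p_rev"], [0, 0, -1], atol=1e-12)

    def test_collinear_plane_anchors_error(self):
        s = fixtures.build_reference_trace((6,))
        s.coord[:] = 0.0
        s.coord[1] = [1, 0, 0]
        s.coord[2] = [2, 0, 0]
        defs = {"p": VectorDefinition("p", "plane_normal", "A", (1, 2, 3))}
        with pytest.raises(ValueError, match="collinear"):
            resolve_vectors(s.coord, s, defs)

    def test_bad_definitions_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            VectorDefinition("x", "screw", "A", (1, 2))
        with pytest.raises(ValueError, match="distinct"):
            VectorDefinition("x", "line", "A", (1, 1))


class TestAngleSeries:
    def test_rigid_ensemble_all_zero(self):
        gt = fixtures.HingeGroundTruth(segment_lengths=(20, 20),
                                       hinges=(fixtures.HingeSpec(),), seed=0)
        ens, _ = fixtures.make_hinge_ensemble(gt, n=16, seed=0)
        defs = fixtures.hinge_vector_definitions(gt)
        pair = fixtures.hinge_angle_pairs(gt)["hinge0_bend"]
        s = angle_series(ens, pair, defs)
        np.testing.assert_allclose(s.angles_deg, 0.0, atol=1e-9)

    def test_within_segment_pair_near_zero(self, gaussian_hinge_ensemble):
        ens, gt = gaussian_hinge_ensemble
        defs = {
            "h1": line_def("h1", 5, 14),
            "h2": line_def("h2", 15, 23),
        }
        sigma = angle_sigma(angle_series(ens, AnglePair("h1", "h2"), defs))
        assert sigma < 0.2  # the segment is rigid by construction

    def test_hinge_pair_recovers_generator_sigma(self,
                                                 gaussian_hinge_ensemble):
        ens, gt = gaussian_hinge_ensemble
        defs = fixtures.hinge_vector_definitions(gt)
        pairs = fixtures.hinge_angle_pairs(gt)
        bend = angle_sigma(angle_series(ens, pairs["hinge0_bend"], defs))
        twist = angle_sigma(angle_series(ens, pairs["hinge0_twist"], defs))
        assert bend == pytest.approx(10.0, rel=0.05)
        assert twist == pytest.approx(6.0, rel=0.05)

    def test_invariant_to_rigid_motion_per_conformer(
            self, gaussian_hinge_ensemble, rng):
        import dataclasses

        ens, gt = gaussian_hinge_ensemble
        sub = dataclasses.replace(ens, coords=ens.coords[:64].copy(),
                                  fit_rmsd=None)
        moved = sub.coords.copy()
        for m in range(64):
            R = rotation_about_axis(rng.normal(size=3), rng.uniform(0, 3))
            moved[m] = moved[m] @ R.T + rng.normal(size=3) * 8
        # vectors co-rotate: per-conformer angles are unchanged
        defs = fixtures.hinge_vector_definitions(gt)
        pair = fixtures.hinge_angle_pairs(gt)["hinge0_bend"]
        a = angle_series(sub, pair, defs).angles_deg

        def raw_angles(e):
            out = []
            ca = e.reference.ca_index()
            for m in range(e.n_conformers):
                v = resolve_vectors(e.coords[m], e.reference,
                                    {k: defs[k] for k in
                                     (pair.name_a, pair.name_b, pair.sign)},
                                    ca)
                out.append(mechanics._signed_angle(
                    v[pair.name_a], v[pair.name_b], v[pair.sign]))
            return np.degrees(out)

        np.testing.assert_allclose(
            raw_angles(sub),
            raw_angles(dataclasses.replace(sub, coords=moved)), atol=1e-8)

    def test_undefined_vector_errors(self, gaussian_hinge_ensemble):
        ens, gt = gaussian_hinge_ensemble
        with pytest.raises(ValueError, match="undefined"):
            angle_series(ens, AnglePair("nope", "seg0_axis"), {})


class TestSigmaAndAmplification:
    def test_sigma_trivials_and_formula(self, rng):
        pair = AnglePair("a", "b")
        assert angle_sigma(AngleSeries(pair, np.zeros(10))) == 0.0
        assert angle_sigma(AngleSeries(pair, np.array([-1.0, 1.0]))) == 1.0
        x = rng.normal(3, 2.5, 500)
        got = angle_sigma(AngleSeries(pair, x))
        assert got == pytest.approx(float(np.sqrt(np.mean((x - x.mean()) ** 2))),
                                    abs=1e-12)

    def test_amplification_trivials(self):
        pair = AnglePair("a", "b")
        s1 = AngleSeries(pair, np.array([-5.0, 5.0]))
        s2 = AngleSeries(pair, np.array([-10.0, 10.0]))
        assert amplification(s1, s1) == 1.0
        assert amplification(s2, s1) == 2.0
        with pytest.raises(ValueError, match="zero sigma"):
            amplification(s1, AngleSeries(pair, np.zeros(2)))

    def test_serial_hinge_amplification_matches_expectation(self):
        gt = fixtures.HingeGroundTruth(
            segment_lengths=(36, 36, 36),
            hinges=(fixtures.HingeSpec(bend_sigma=8.0),
                    fixtures.HingeSpec(bend_sigma=8.0)), seed=21)
        ens, _ = fixtures.make_hinge_ensemble(gt, n=2048, seed=21)
        defs = fixtures.hinge_vector_definitions(gt)
        pairs = fixtures.hinge_angle_pairs(gt)
        ratio = amplification(angle_series(ens, pairs["distal_bend"], defs),
                              angle_series(ens, pairs["hinge0_bend"], defs))
        expected = fixtures.expected_distal_bend_sigma(gt, n_mc=100_000) / 8.0
        assert ratio > 1.0
        assert ratio == pytest.approx(expected, rel=0.10)


class TestGaussianFits:
    def test_single_gaussian_peak_value(self):
        # fitted-form check with published-style parameters
        assert single_gaussian(0.2, 2904.0, 5.48, 0.2) == pytest.approx(2904.0)
        assert double_gaussian(0.0, 2701.0, 2.72, 3.55) == pytest.approx(
            2 * 2701.0 * np.exp(-0.5 * (3.55 / 2.72) ** 2))

    def test_two_state_samples_recover_x0(self, rng):
        centers = rng.choice([-3.55, 3.55], size=20000)
        x = rng.normal(centers, 2.72)
        fit = fit_angle_models(AngleSeries(AnglePair("a", "b"), x))
        assert fit.double["x0"] == pytest.approx(3.55, abs=0.3)
        assert fit.double["r2"] > fit.single["r2"]

    def test_unimodal_parsimony(self, rng):
        x = rng.normal(0, 5.0, 20000)
        fit = fit_angle_models(AngleSeries(AnglePair("a", "b"), x))
        assert fit.single["r2"] >= fit.double["r2"] - 0.02
        assert fit.single["b"] == pytest.approx(5.0, rel=0.05)


class TestStiffness:
    def test_unit_width(self):
        est = torsional_stiffness(np.degrees(1.0), temperature_k=300.0)
        assert est.kappa_pn_nm == pytest.approx(1.380649e-2 * 300.0, rel=1e-9)

    def test_tenth_radian(self):
        est = torsional_stiffness(np.degrees(0.1), temperature_k=300.0)
        assert est.kappa_pn_nm == pytest.approx(1.380649e-2 * 300.0 / 0.01,
                                                rel=1e-9)

    def test_halving_width_quadruples_stiffness(self):
        k1 = torsional_stiffness(10.0).kappa_pn_nm
        k2 = torsional_stiffness(5.0).kappa_pn_nm
        assert k2 == pytest.approx(4 * k1, rel=1e-9)

    def test_nonpositive_width_errors(self):
        with pytest.raises(ValueError):
            torsional_stiffness(0.0)


class TestCouplingRelation:
    def test_linear_with_noise(self, rng):
        x = rng.normal(0, 3, 3000)
        y = 8.0 * x + rng.normal(0, 2.0, 3000)
        fit = coupling_relation(x, y)
        assert fit.kind == "linear"
        s = fit.params["linear"]
        assert abs(s["slope"] - 8.0) < 3 * s["slope_se"] + 0.1

    def test_pure_parabola(self):
        x = np.linspace(-3, 3, 200)
        fit = coupling_relation(x, x ** 2)
        assert fit.kind == "parabolic"
        assert fit.params["parabolic"]["c"] == pytest.approx(1.0, abs=1e-9)
        assert fit.r2["parabolic"] == pytest.approx(1.0, abs=1e-12)

    def test_clamped_end_state(self, rng):
        x = rng.normal(0, 3, 4000)
        y = np.clip(8.0 * x, -10.0, 10.0) + rng.normal(0, 0.3, 4000)
        fit = coupling_relation(x, y)
        assert fit.kind == "end_state"
        assert fit.params["end_state"]["slope"] == pytest.approx(8.0, rel=0.1)
        assert fit.params["end_state"]["plateau"] == pytest.approx(10.0,
                                                                   rel=0.1)


def test_shipped_vector_config_parses():
    from importlib import resources

    from rotormech.mechanics import load_vector_config

    text = resources.files("rotormech.data").joinpath(
        "vector_config_flim_flig.json").read_text()
    defs, pairs = load_vector_config(text)
    assert {"ML0", "MGG", "GP2", "GL2", "MP1"} <= set(defs)
    assert pairs["rot_ML0_GL0"].sign == "MP1"
    assert all(p.name_a in defs and p.name_b in defs for p in pairs.values())
    with pytest.raises(ValueError, match="undefined vector"):
        load_vector_config('{"vectors": [], "pairs": [{"a": "X", "b": "Y"}]}')


def test_per_pc_variance_additivity(gaussian_hinge_ensemble):
    from rotormech import dynamics

    ens, gt = gaussian_hinge_ensemble
    pca = dynamics.fit_pca(ens)
    defs = fixtures.hinge_vector_definitions(gt)
    pair = fixtures.hinge_angle_pairs(gt)["hinge0_bend"]
    full_var = angle_sigma(angle_series(ens, pair, defs)) ** 2
    a, w = dynamics.gaussian_amplitude_grid()
    total = 0.0
    for k in range(1, pca.n_modes + 1):
        if pca.eigvals[k - 1] < 1e-8:
            break
        ang = angle_series(dynamics.pc_trajectory(pca, k, a), pair,
                           defs).angles_deg
        mu = np.sum(w * ang)
        total += float(np.sum(w * (ang - mu) ** 2))
    assert total == pytest.approx(full_var, rel=0.10)


@pytest.mark.parametrize("bend,twist", [(6.0, 0.0), (10.0, 5.0), (15.0, 10.0)])
@pytest.mark.parametrize("delta", [0.0, 4.0, 8.0])
def test_parameter_recovery_grid(bend, twist, delta):
    """Generator parameters recovered across a 3x3 grid of settings."""
    model = "two_state" if delta > 0 else "gaussian"
    gt = fixtures.HingeGroundTruth(
        segment_lengths=(36, 36),
        hinges=(fixtures.HingeSpec(bend_sigma=bend, twist_sigma=twist,
                                   model=model, bend_delta=delta),),
        seed=int(bend * 10 + delta))
    ens, _ = fixtures.make_hinge_ensemble(gt, n=1024, seed=gt.seed)
    defs = fixtures.hinge_vector_definitions(gt)
    pairs = fixtures.hinge_angle_pairs(gt)
    got = angle_sigma(angle_series(ens, pairs["hinge0_bend"], defs))
    expected = np.sqrt(bend ** 2 + delta ** 2)  # SD of the two-state mixture
    assert got == pytest.approx(expected, rel=0.07)
    if twist > 0:
        # twist_delta stays 0, so the twist well is Gaussian in all settings
        got_t = angle_sigma(angle_series(ens, pairs["hinge0_twist"], defs))
        assert got_t == pytest.approx(twist, rel=0.07)
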