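import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemrrm import rdc
from tandemrrm.containers import RdcSet, Structure
from tandemrrm.exceptions import GeometryError, ValidationError
from tandemrrm.synth import NoiseSpec, gen_rdc_set, gen_structure


def make_rdcset(vectors, tensor, noise=0.0, seed=0):
    d = rdc.back_calc_rdc(tensor, vectors)
    if noise:
        d = d + np.random.default_rng(seed).normal(0, noise, len(d))
    return RdcSet(pd.DataFrame({"residue_number": vectors.index, "D_obs_Hz": d}))


class TestNhVectors:
    def test_unit_norm(self, coil_structure):
        with pytest.warns(UserWarning):
            vec = rdc.nh_unit_vectors(coil_structure)
        np.testing.assert_allclose(np.linalg.norm(vec.to_numpy(), axis=1), 1.0, atol=1e-12)

    def test_build_h_matches_generated_h(self, coil_structure):
        noH = Structure(atoms=coil_structure.atoms[coil_structure.atoms["atom_name"] != "H"])
        with pytest.warns(UserWarning):
            rebuilt = rdc.nh_unit_vectors(noH, build_h=True)
            exact = rdc.nh_unit_vectors(coil_structure)
        common = rebuilt.index.intersection(exact.index)
        dots = np.sum(rebuilt.loc[common].to_numpy() * exact.loc[common].to_numpy(), axis=1)
        assert np.arccos(np.clip(dots, -1, 1)).max() < 1e-6

    def test_proline_skipped_with_notice(self, coil_structure):
        atoms = coil_structure.atoms.copy()
        atoms.loc[atoms["residue_number"] == 10, "residue_name"] = "PRO"
        s = Structure(atoms=atoms)
        with pytest.warns(UserWarning, match="10"):
            vec = rdc.nh_unit_vectors(s)
        assert 10 not in vec.index

    def test_missing_h_error_names_residues(self, coil_structure):
        atoms = coil_structure.atoms
        noH = Structure(atoms=atoms[~((atoms["atom_name"] == "H") & (atoms["residue_number"] == 7))])
        with pytest.raises(GeometryError, match="7"):
            with pytest.warns(UserWarning):
                rdc.nh_unit_vectors(noH)


class TestSvdFit:
    def test_noise_free_recovery_machine_precision(self, spread_vectors):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23, (30.0, 60.0, 40.0))
        fit = rdc.svd_fit_tensor(make_rdcset(spread_vectors, tensor), spread_vectors)
        np.testing.assert_allclose(fit.tensor.saupe, tensor.saupe, atol=1e-10)
        assert fit.r_factor_percent < 1e-8

    def test_four_rdcs_precondition(self, spread_vectors):
        tensor = rdc.AlignmentTensor.from_parameters(10.0, 0.2)
        rs = make_rdcset(spread_vectors.iloc[:4], tensor)
        with pytest.raises(ValidationError):
            rdc.svd_fit_tensor(rs, spread_vectors.iloc[:4])

    def test_collinear_vectors_conditioning_error(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        vec = pd.DataFrame(v, columns=["x", "y", "z"], index=np.arange(2, 12))
        tensor = rdc.AlignmentTensor.from_parameters(10.0, 0.2)
        rs = make_rdcset(vec, tensor)
        with pytest.raises(GeometryError):
            rdc.svd_fit_tensor(rs, vec)

    def test_noise_gives_positive_r_factor(self, spread_vectors):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23)
        fit = rdc.svd_fit_tensor(make_rdcset(spread_vectors, tensor, noise=1.0), spread_vectors)
        assert fit.r_factor_percent > 0

    def test_weighted_fit_runs(self, spread_vectors):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23)
        rs = make_rdcset(spread_vectors, tensor, noise=0.5)
        rs.data["D_err_Hz"] = 0.5
        fit = rdc.svd_fit_tensor(rs, spread_vectors, weighted=True)
        assert fit.n_rdcs == 40

    @settings(deadline=None, max_examples=25)
    @given(
        da=st.floats(2.0, 25.0), rh=st.floats(0.0, 0.66),
        phi=st.floats(0.0, 359.0), theta=st.floats(1.0, 89.0), psi=st.floats(0.0, 359.0),
        seed=st.integers(0, 1000),
    )
    def test_property_recovery_random_tensors_and_geometries(self, da, rh, phi, theta, psi, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=(25, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        vec = pd.DataFrame(v, columns=["x", "y", "z"], index=np.arange(2, 27))
        tensor = rdc.AlignmentTensor.from_parameters(da, rh, (phi, theta, psi))
        fit = rdc.svd_fit_tensor(make_rdcset(vec, tensor), vec)
        np.testing.assert_allclose(fit.tensor.saupe, tensor.saupe, atol=1e-9)

    def test_local_optimality_on_grid(self, spread_vectors):
        # SVD solution beats every tensor on a small 5-D grid around it
        tensor = rdc.AlignmentTensor.from_parameters(8.0, 0.4, (20.0, 50.0, 10.0))
        rs = make_rdcset(spread_vectors, tensor, noise=1.5, seed=3)
        fit = rdc.svd_fit_tensor(rs, spread_vectors)
        base = fit.tensor.saupe
        d_obs = rs.data["D_obs_Hz"].to_numpy()
        for i in range(5):
            for eps in (-0.05, 0.05):
                trial = base.copy()
                trial[i] += eps
                trial_r = rdc.r_factor(
                    d_obs, rdc.back_calc_rdc(rdc.AlignmentTensor(trial), spread_vectors))
                assert fit.r_factor_percent <= trial_r + 1e-12


class TestTensorParams:
    def test_axially_symmetric_r_zero(self):
        t = rdc.AlignmentTensor.from_matrix(np.diag([-5.0, -5.0, 10.0]))
        da, rh, _ = rdc.tensor_params(t.saupe)
        assert da == pytest.approx(5.0)
        assert rh == 0.0

    def test_maximally_rhombic(self):
        # Axx = 0, Ayy = -Azz: R = 2/3
        t = rdc.AlignmentTensor.from_matrix(np.diag([0.0, -10.0, 10.0]))
        _, rh, _ = rdc.tensor_params(t.saupe)
        assert rh == pytest.approx(2.0 / 3.0)

    def test_construct_decompose_exact(self):
        t = rdc.AlignmentTensor.from_parameters(9.2, 0.55, (189.0, 68.0, 94.0))
        da, rh, euler = rdc.tensor_params(t.saupe)
        assert da == pytest.approx(9.2, abs=1e-10)
        assert rh == pytest.approx(0.55, abs=1e-10)
        rebuilt = rdc.AlignmentTensor.from_parameters(da, rh, euler)
        np.testing.assert_allclose(rebuilt.matrix, t.matrix, atol=1e-9)

    def test_trace_always_zero(self):
        t = rdc.AlignmentTensor.from_parameters(12.0, 0.3, (10.0, 70.0, 200.0))
        assert abs(np.trace(t.matrix)) < 1e-10


class TestBackCalc:
    def test_vector_along_z_gives_2da(self):
        t = rdc.AlignmentTensor.from_matrix(np.diag([-5.0, -5.0, 10.0]))
        vec = pd.DataFrame([[0.0, 0.0, 1.0]], columns=["x", "y", "z"], index=[2])
        assert rdc.back_calc_rdc(t, vec)[0] == pytest.approx(10.0)

    def test_magic_angle_zero(self):
        t = rdc.AlignmentTensor.from_matrix(np.diag([-5.0, -5.0, 10.0]))
        theta = np.radians(54.7356103172)
        vec = pd.DataFrame([[np.sin(theta), 0.0, np.cos(theta)]],
                           columns=["x", "y", "z"], index=[2])
        assert rdc.back_calc_rdc(t, vec)[0] == pytest.approx(0.0, abs=1e-8)

    def test_matrix_and_polar_forms_agree(self):
        da, rh = 9.2, 0.55
        t = rdc.AlignmentTensor.from_parameters(da, rh, (0.0, 0.0, 0.0))
        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        vec = pd.DataFrame(v, columns=["x", "y", "z"], index=np.arange(2, 102))
        matrix_form = rdc.back_calc_rdc(t, vec)
        theta = np.arccos(np.clip(v[:, 2], -1, 1))
        phi = np.arctan2(v[:, 1], v[:, 0])
        polar = da * ((3 * np.cos(theta) ** 2 - 1)
                      + 1.5 * rh * np.sin(theta) ** 2 * np.cos(2 * phi))
        np.testing.assert_allclose(matrix_form, polar, atol=1e-10)


class TestRFactor:
    @pytest.mark.parametrize(
        "obs,calc,expected",
        [
            ([2.0, -2.0], [2.0, -2.0], 0.0),
            ([2.0, -2.0], [1.0, -1.0], 35.36),
            ([2.0, -2.0], [0.0, 0.0], 70.71),
        ],
    )
    def test_worked_examples(self, obs, calc, expected):
        assert rdc.r_factor(obs, calc) == pytest.approx(expected, abs=0.005)

    def test_all_zero_observed_errors(self):
        with pytest.raises(ValidationError):
            rdc.r_factor([0.0, 0.0], [1.0, 1.0])

    def test_invariant_under_corotation(self, spread_vectors):
        # rotating the structure and co-rotating the tensor leaves the fit
        # quality unchanged
        from tandemrrm.synth import _rotation_matrix

        tensor = rdc.AlignmentTensor.from_parameters(10.0, 0.3, (15.0, 40.0, 70.0))
        rs = make_rdcset(spread_vectors, tensor, noise=1.0, seed=2)
        fit1 = rdc.svd_fit_tensor(rs, spread_vectors)
        R = _rotation_matrix([1.0, 2.0, 0.5], 63.0)
        rot_vec = pd.DataFrame(spread_vectors.to_numpy() @ R.T,
                               columns=["x", "y", "z"], index=spread_vectors.index)
        fit2 = rdc.svd_fit_tensor(rs, rot_vec)
        assert fit1.r_factor_percent == pytest.approx(fit2.r_factor_percent, abs=1e-8)


class TestTensorDifference:
    def test_identical(self):
        t = rdc.AlignmentTensor.from_parameters(10.0, 0.3, (15.0, 40.0, 70.0))
        d = rdc.tensor_difference(t, t)
        assert d["normalized_scalar_product"] == pytest.approx(1.0)
        assert d["interframe_rotation_deg"] == pytest.approx(0.0, abs=1e-4)

    def test_axial_rotated_90_negative_scalar_product(self):
        a = rdc.AlignmentTensor.from_matrix(np.diag([-5.0, -5.0, 10.0]))
        b = rdc.AlignmentTensor.from_matrix(np.diag([-5.0, 10.0, -5.0]))  # 90 deg about x
        d = rdc.tensor_difference(a, b)
        assert d["normalized_scalar_product"] < 0

    def test_scale_invariance(self):
        a = rdc.AlignmentTensor.from_parameters(10.0, 0.3, (15.0, 40.0, 70.0))
        b = rdc.AlignmentTensor(a.saupe * 2.0)
        d = rdc.tensor_difference(a, b)
        assert d["normalized_scalar_product"] == pytest.approx(1.0)

    def test_zero_tensor_errors(self):
        a = rdc.AlignmentTensor.from_parameters(10.0, 0.3)
        with pytest.raises(ValidationError):
            rdc.tensor_difference(a, rdc.AlignmentTensor(np.zeros(5)))


class TestFitDomains:
    @pytest.fixture
    def two_domain(self):
        return gen_structure(25, "two_domain", seed=11)

    def test_identical_tensors_no_degradation(self, two_domain):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23, (30.0, 60.0, 40.0))
        with pytest.warns(UserWarning):
            rs = gen_rdc_set(two_domain, tensor)
            comp = rdc.fit_domains(rs, two_domain, mode="both")
        assert comp["joint_r_factor"] < 1e-8
        for res in comp["separate"].values():
            assert res.r_factor_percent < 1e-8

    def test_rotated_tensors_degrade_joint_fit(self, two_domain):
        tA = rdc.AlignmentTensor.from_parameters(10.6, 0.23, (30.0, 60.0, 40.0))
        tB = rdc.AlignmentTensor.from_parameters(10.6, 0.23, (30.0, 150.0, 40.0))
        with pytest.warns(UserWarning):
            rs = gen_rdc_set(two_domain, {"D1": tA, "D2": tB}, noise=NoiseSpec(1.0, 5))
            comp = rdc.fit_domains(rs, two_domain, mode="both")
        assert comp["joint"].r_factor_percent > max(
            r.r_factor_percent for r in comp["separate"].values())
        assert comp["percent_increase"] > 50.0

    def test_joint_r_factor_bounded_below_by_separate(self, two_domain):
        # with differing per-domain tensors, the joint single-tensor fit can
        # never beat the best per-domain fit at low noise
        tA = rdc.AlignmentTensor.from_parameters(10.0, 0.2, (0.0, 30.0, 0.0))
        tB = rdc.AlignmentTensor.from_parameters(8.0, 0.5, (60.0, 80.0, 120.0))
        with pytest.warns(UserWarning):
            rs = gen_rdc_set(two_domain, {"D1": tA, "D2": tB}, noise=NoiseSpec(0.2, 9))
            comp = rdc.fit_domains(rs, two_domain, mode="both")
        assert comp["joint"].r_factor_percent >= max(
            r.r_factor_percent for r in comp["separate"].values()) - 1e-6

    def test_separate_mode_omits_joint(self, two_domain):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23)
        with pytest.warns(UserWarning):
            rs = gen_rdc_set(two_domain, tensor)
            comp = rdc.fit_domains(rs, two_domain, mode="separate")
        assert "joint" not in comp and "percent_increase" not in comp

    def test_small_domain_errors_with_name(self, two_domain):
        tensor = rdc.AlignmentTensor.from_parameters(10.6, 0.23)
        with pytest.warns(UserWarning):
            rs = gen_rdc_set(two_domain, tensor)
        few = rs.data[(rs.data["residue_number"] > 25) | (rs.data["residue_number"] < 5)]
        with pytest.raises(ValidationError, match="D1"):
            with pytest.warns(UserWarning):
                rdc.fit_domains(RdcSet(few), two_domain, mode="both")
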