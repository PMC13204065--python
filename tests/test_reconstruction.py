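import numpy as np
import pytest

from savehsi.calibration import PolyExpansionSpec, apply_correction, fit_correction
from savehsi.colorimetry import N_WAVELENGTHS, WAVELENGTHS, linear_rgb_to_xyz, rmse, spectrum_to_xyz, srgb_decode, srgb_encode, xyz_to_linear_rgb
from savehsi.reconstruction import (
    ConversionModel,
    fit_basis,
    fit_conversion,
    project_scores,
    reconstruct_cube,
    reconstruct_spectrum,
)
from savehsi.synthetic import CameraModel, make_macbeth_spectra, simulate_camera


def _smooth_rank3_spectra(n=24, seed=0):
    """Spectra that are exact affine combinations of three smooth modes."""
    rng = np.random.default_rng(seed)
    modes = np.stack(
        [
            np.exp(-0.5 * ((WAVELENGTHS - c) / w) ** 2)
            for c, w in [(450, 60), (550, 70), (650, 60)]
        ]
    )
    coefs = rng.uniform(0.05, 0.3, size=(n, 3))
    return 0.1 + coefs @ modes  # all within [0, 1]


class TestFitBasis:
    def test_rank3_data_needs_three_components(self):
        spectra = _smooth_rank3_spectra()
        basis = fit_basis(spectra, variance_target=0.999999)
        assert basis.n_components == 3
        assert basis.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-10)

    def test_flat_grays_are_rank_one(self):
        levels = np.linspace(0.05, 0.95, 24)
        spectra = np.outer(levels, np.ones(N_WAVELENGTHS))
        basis = fit_basis(spectra)
        assert basis.n_components == 1
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_svd_oracle_up_to_sign(self, checker):
        spectra, _ = checker
        basis = fit_basis(spectra, n_components=5)
        centered = spectra - spectra.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        for j in range(5):
            dot = abs(float(basis.EV[:, j] @ vt[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)
        evr_oracle = s**2 / np.sum(s**2)
        assert np.allclose(basis.explained_variance_ratio, evr_oracle[:5], atol=1e-10)

    def test_orthonormal_columns_and_variance_ordering(self, calibrated):
        basis = calibrated["basis"]
        gram = basis.EV.T @ basis.EV
        assert np.allclose(gram, np.eye(basis.n_components), atol=1e-8)
        evr = basis.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12

    def test_zero_variance_degenerates_to_one_component(self):
        spectra = np.tile(np.full(N_WAVELENGTHS, 0.4), (5, 1))
        with pytest.warns(UserWarning, match="zero-variance"):
            basis = fit_basis(spectra)
        assert basis.n_components == 1

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError):
            fit_basis(np.ones((1, N_WAVELENGTHS)))


class TestScores:
    def test_mean_projects_to_zero(self, calibrated):
        basis = calibrated["basis"]
        scores = project_scores(basis, np.tile(basis.mean, (3, 1)))
        assert np.allclose(scores, 0.0, atol=1e-12)

    def test_round_trip_for_rank_p_data(self):
        spectra = _smooth_rank3_spectra()
        basis = fit_basis(spectra, n_components=3)
        scores = project_scores(basis, spectra)
        rebuilt = basis.mean + scores @ basis.EV.T
        assert np.allclose(rebuilt, spectra, atol=1e-10)


class TestFitConversion:
    def test_exact_linear_relation_has_zero_residual(self, rng):
        xyz = rng.uniform(0, 100, size=(24, 3))
        spec = PolyExpansionSpec(order=1)
        from savehsi.calibration import expand_variables

        V = expand_variables(xyz, spec)
        M_true = rng.normal(size=(4, spec.n_terms))
        scores = V @ M_true.T
        model = fit_conversion(scores, xyz, spec)
        assert np.allclose(V @ model.M.T, scores, atol=1e-8)

    def test_single_component_matches_regression_oracle(self, rng):
        xyz = rng.uniform(0, 100, size=(24, 3))
        scores = rng.normal(size=(24, 1))
        spec = PolyExpansionSpec(order=2)
        from savehsi.calibration import expand_variables

        model = fit_conversion(scores, xyz, spec)
        V = expand_variables(xyz, spec)
        beta, *_ = np.linalg.lstsq(V, scores, rcond=None)
        assert np.allclose(model.M, beta.T, atol=1e-8)

    def test_zero_scores_give_zero_matrix(self, rng):
        xyz = rng.uniform(0, 100, size=(24, 3))
        model = fit_conversion(np.zeros((24, 2)), xyz)
        assert np.allclose(model.M, 0.0)


class TestReconstruct:
    def test_zero_conversion_returns_clipped_mean(self, calibrated):
        basis = calibrated["basis"]
        model = ConversionModel(
            M=np.zeros((basis.n_components, PolyExpansionSpec().n_terms)),
            color_spec=PolyExpansionSpec(),
        )
        out = reconstruct_spectrum(basis, model, [50.0, 50.0, 50.0])
        assert np.allclose(out, np.clip(basis.mean, 0, 1))

    def test_in_span_noise_free_system_recovers_truth(self):
        # rank-3 spectra + affine camera distortion: everything is inside
        # the model class, so training patches reconstruct exactly
        spectra = _smooth_rank3_spectra()
        cam = CameraModel(
            crosstalk=((0.9, 0.07, 0.03), (0.05, 0.9, 0.05), (0.04, 0.06, 0.9)),
            response_exponent=1.0,
            dark_offset=0.02,
            noise_sigma=0.0,
        )
        rgb = simulate_camera(spectra, cam=cam)
        xyz_cam = 100 * linear_rgb_to_xyz(srgb_decode(rgb))
        xyz_true = spectrum_to_xyz(spectra)
        spec = PolyExpansionSpec(order=2)
        correction = fit_correction(xyz_cam, xyz_true, spec)
        xyz_corr = apply_correction(correction, xyz_cam)
        basis = fit_basis(spectra, n_components=3)
        conv = fit_conversion(project_scores(basis, spectra), xyz_corr, spec)
        recon = reconstruct_spectrum(basis, conv, xyz_corr)
        err = np.mean([rmse(a, b) for a, b in zip(recon, spectra)])
        assert err < 1e-6

    def test_noise_degrades_monotonically(self, checker):
        spectra, _ = checker
        errs = []
        for sigma in (0.0, 0.005, 0.02):
            cam = CameraModel(
                crosstalk=((0.92, 0.05, 0.03), (0.03, 0.92, 0.05), (0.05, 0.03, 0.92)),
                response_exponent=1.05,
                dark_offset=0.01,
                noise_sigma=sigma,
                seed=42,
            )
            rgb = simulate_camera(spectra, cam=cam)
            xyz_cam = 100 * linear_rgb_to_xyz(srgb_decode(rgb))
            xyz_true = spectrum_to_xyz(spectra)
            spec = PolyExpansionSpec(order=2)
            correction = fit_correction(xyz_cam, xyz_true, spec)
            xyz_corr = apply_correction(correction, xyz_cam)
            basis = fit_basis(spectra)
            conv = fit_conversion(project_scores(basis, spectra), xyz_corr, spec)
            recon = reconstruct_spectrum(basis, conv, xyz_corr)
            errs.append(np.mean([rmse(a, b) for a, b in zip(recon, spectra)]))
        assert errs[0] <= errs[1] <= errs[2]

    def test_reconstruction_is_clipped_to_physical_range(self, calibrated):
        out = reconstruct_spectrum(
            calibrated["basis"], calibrated["conversion"], [[500.0, 500.0, 500.0], [0.0, 0.0, 0.0]]
        )
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestCube:
    def test_uniform_image_gives_uniform_cube(self, calibrated):
        img = np.full((4, 5, 3), 128, dtype=np.uint8)
        cube = reconstruct_cube(calibrated["basis"], calibrated["conversion"], calibrated["correction"], img)
        assert cube.shape == (4, 5, 401)
        assert np.allclose(cube, cube[0, 0])

    def test_fast_path_matches_per_pixel_loop(self, calibrated, rng):
        img = (rng.uniform(0, 1, size=(8, 8, 3)) * 255).astype(np.uint8)
        fast = reconstruct_cube(calibrated["basis"], calibrated["conversion"], calibrated["correction"], img, fast=True)
        slow = reconstruct_cube(calibrated["basis"], calibrated["conversion"], calibrated["correction"], img, fast=False)
        assert np.allclose(fast, slow, atol=1e-6)

    def test_non_image_input_rejected(self, calibrated):
        with pytest.raises(ValueError):
            reconstruct_cube(calibrated["basis"], calibrated["conversion"], calibrated["correction"], np.ones((4, 4)))
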