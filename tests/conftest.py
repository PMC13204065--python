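import numpy as np
import pytest

from savehsi.calibration import PolyExpansionSpec, apply_correction, fit_correction
from savehsi.colorimetry import linear_rgb_to_xyz, spectrum_to_xyz, srgb_decode
from savehsi.reconstruction import fit_basis, fit_conversion, project_scores
from savehsi.synthetic import DEFAULT_CAMERA, make_macbeth_spectra, simulate_camera


@pytest.fixture(scope="session")
def checker():
    """24 synthetic checker spectra with their patch names (seed 42)."""
    spectra, names = make_macbeth_spectra(seed=42)
    return spectra, names


@pytest.fixture(scope="session")
def calibrated(checker):
    """Full seeded calibration: distorted camera, correction, basis, conversion."""
    spectra, _ = checker
    rgb = simulate_camera(spectra, cam=DEFAULT_CAMERA)
    xyz_cam = 100.0 * linear_rgb_to_xyz(srgb_decode(rgb))
    xyz_true = spectrum_to_xyz(spectra)
    spec = PolyExpansionSpec(order=2)
    correction = fit_correction(xyz_cam, xyz_true, spec)
    xyz_corr = apply_correction(correction, xyz_cam)
    basis = fit_basis(spectra)
    conversion = fit_conversion(project_scores(basis, spectra), xyz_corr, spec)
    return {
        "spectra": spectra,
        "camera_rgb": rgb,
        "xyz_camera": xyz_cam,
        "xyz_true": xyz_true,
        "xyz_corrected": xyz_corr,
        "correction": correction,
        "basis": basis,
        "conversion": conversion,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
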