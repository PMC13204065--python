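"""PCA spectral basis and colour-to-spectrum regression.

The measured checker reflectances are summarised by a mean-centred PCA
basis (mean spectrum mu and orthonormal eigenvector matrix EV).  Each
spectrum's PCA scores are regressed onto a polynomial expansion V_color of
the corrected camera colour,

    M = Score . pinv(V_color),

and a pixel's full 380-780 nm reflectance is then reconstructed as

    S = mu + EV . (M . V_color),

clipped to the physical range [0, 1].  Centering is on by default; the
uncentred variant (scores taken about zero) is available via
``center=False`` for the literal score-times-basis product, which cannot
reproduce the mean spectrum and exists for comparison only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .calibration import CorrectionModel, PolyExpansionSpec, apply_correction, expand_variables
from .colorimetry import N_WAVELENGTHS, linear_rgb_to_xyz, srgb_decode

__all__ = [
    "SpectralBasis",
    "ConversionModel",
    "fit_basis",
    "project_scores",
    "fit_conversion",
    "reconstruct_spectrum",
    "reconstruct_cube",
]


@dataclass
class SpectralBasis:
    """Mean spectrum plus orthonormal principal directions of reflectance."""

    mean: np.ndarray  # (401,)
    EV: np.ndarray  # (401, p)
    explained_variance_ratio: np.ndarray  # (p,)
    centered: bool = True

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.EV = np.asarray(self.EV, dtype=float)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, dtype=float)
        if self.mean.shape != (N_WAVELENGTHS,) or self.EV.shape[0] != N_WAVELENGTHS:
            raise ValueError("basis must live on the 401-point spectral grid")
        if self.EV.shape[1] != self.explained_variance_ratio.size:
            raise ValueError("component count mismatch")

    @property
    def n_components(self) -> int:
        return self.EV.shape[1]

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "EV": self.EV.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centered": self.centered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralBasis":
        return cls(
            mean=np.asarray(d["mean"], dtype=float),
            EV=np.asarray(d["EV"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
            centered=bool(d.get("centered", True)),
        )


@dataclass
class ConversionModel:
    """Regression from expanded corrected colours to PCA scores."""

    M: np.ndarray  # (p, n_colorterms)
    color_spec: PolyExpansionSpec

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[1] != self.color_spec.n_terms:
            raise ValueError("M columns must match the colour expansion term count")
        if not np.all(np.isfinite(self.M)):
            raise ValueError("M contains non-finite values")

    def to_dict(self) -> dict:
        return {"M": self.M.tolist(), "color_spec": self.color_spec.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ConversionModel":
        return cls(
            M=np.asarray(d["M"], dtype=float),
            color_spec=PolyExpansionSpec.from_dict(d["color_spec"]),
        )


# Cap on automatically selected components: with 24 checker patches more
# than ~12 directions mostly fit measurement noise.
_MAX_AUTO_COMPONENTS = 12


def fit_basis(
    spectra,
    variance_target: float = 0.999,
    n_components: int | None = None,
    center: bool = True,
) -> SpectralBasis:
    """Fit a mean-centred PCA basis to (n, 401) reflectance spectra.

    When ``n_components`` is not given, the smallest count whose cumulative
    explained variance reaches ``variance_target`` is used, capped at
    min(n - 1, 12).
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[1] != N_WAVELENGTHS:
        raise ValueError("spectra must be an (n, 401) array on the standard grid")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two spectra to fit a basis")

    max_rank = min(n - 1, N_WAVELENGTHS)
    if np.allclose(X, X[0]):
        warnings.warn("zero-variance spectra: basis reduced to one component", stacklevel=2)
        EV = np.zeros((N_WAVELENGTHS, 1))
        EV[0, 0] = 1.0
        return SpectralBasis(mean=X.mean(axis=0), EV=EV, explained_variance_ratio=np.array([1.0]), centered=center)

    pca = PCA(n_components=max_rank, svd_solver="full")
    pca.fit(X)
    evr = pca.explained_variance_ratio_
    if n_components is None:
        cum = np.cumsum(evr)
        p = int(np.searchsorted(cum, variance_target) + 1)
        p = min(p, min(n - 1, _MAX_AUTO_COMPONENTS))
    else:
        p = int(n_components)
        if not 1 <= p <= max_rank:
            raise ValueError(f"n_components must be in [1, {max_rank}]")
    EV = pca.components_[:p].T  # (401, p)
    mean = pca.mean_ if center else np.zeros(N_WAVELENGTHS)
    return SpectralBasis(mean=mean, EV=EV, explained_variance_ratio=evr[:p], centered=center)


def project_scores(basis: SpectralBasis, spectra) -> np.ndarray:
    """Scores = (spectra - mean) . EV, shape (..., p)."""
    X = np.asarray(spectra, dtype=float)
    if X.shape[-1] != N_WAVELENGTHS:
        raise ValueError("spectra must live on the 401-point grid")
    return (X - basis.mean) @ basis.EV


def fit_conversion(
    scores,
    xyz_correct,
    color_spec: PolyExpansionSpec | None = None,
) -> ConversionModel:
    """Fit M = Score . pinv(V_color) by minimum-norm least squares."""
    color_spec = color_spec or PolyExpansionSpec()
    S = np.asarray(scores, dtype=float)
    xyz = np.asarray(xyz_correct, dtype=float)
    if S.ndim != 2 or xyz.ndim != 2 or S.shape[0] != xyz.shape[0]:
        raise ValueError("scores (n, p) and xyz_correct (n, 3) must align")
    if S.shape[0] < color_spec.n_terms:
        warnings.warn(
            f"{S.shape[0]} samples for {color_spec.n_terms} colour terms: "
            "rank-deficient; returning the minimum-norm solution",
            stacklevel=2,
        )
    V = expand_variables(xyz, color_spec).T  # (n_terms, n)
    M = S.T @ np.linalg.pinv(V)
    return ConversionModel(M=M, color_spec=color_spec)


def reconstruct_spectrum(
    basis: SpectralBasis,
    model: ConversionModel,
    xyz_correct,
    clip: bool = True,
) -> np.ndarray:
    """Reconstruct reflectance (..., 401) from corrected XYZ (..., 3)."""
    if model.M.shape[0] != basis.n_components:
        raise ValueError("conversion model and basis have inconsistent component counts")
    V = expand_variables(xyz_correct, model.color_spec)
    scores = V @ model.M.T
    S = basis.mean + scores @ basis.EV.T
    if clip:
        S = np.clip(S, 0.0, 1.0)
    return S


def reconstruct_cube(
    basis: SpectralBasis,
    model: ConversionModel,
    correction: CorrectionModel,
    image,
    fast: bool = True,
) -> np.ndarray:
    """Per-pixel spectral reconstruction of an sRGB image.

    ``image`` is (H, W, 3), either uint8 or float in [0, 1].  Returns a
    float32 cube (H, W, 401).  The default vectorised path precomputes the
    affine map EV.M so each pixel needs one expansion and one matrix
    product; ``fast=False`` runs the literal per-pixel loop (identical
    output, for verification).
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) image")
    if img.dtype == np.uint8:
        img = img.astype(float) / 255.0
    H, W = img.shape[:2]

    xyz = 100.0 * linear_rgb_to_xyz(srgb_decode(img))
    xyz_corr = apply_correction(correction, xyz)

    if fast:
        A = basis.EV @ model.M  # (401, n_colorterms)
        V = expand_variables(xyz_corr.reshape(-1, 3), model.color_spec)
        cube = basis.mean + V @ A.T
        cube = np.clip(cube, 0.0, 1.0).reshape(H, W, N_WAVELENGTHS)
        return cube.astype(np.float32)

    cube = np.empty((H, W, N_WAVELENGTHS), dtype=np.float32)
    for i in range(H):
        for j in range(W):
            cube[i, j] = reconstruct_spectrum(basis, model, xyz_corr[i, j])
    return cube
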