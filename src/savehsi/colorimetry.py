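"""Core colour science on the fixed visible-range wavelength grid.

Everything downstream (camera correction, spectral reconstruction,
narrow-band rendering) works with reflectance spectra sampled on a fixed
grid of 380-780 nm at 1 nm resolution (401 samples).  This module provides
the sRGB gamma codec, the sRGB(D65) RGB<->XYZ matrices, spectral-to-
tristimulus integration with luminance normalisation, CIE L*a*b*
conversion, the CIEDE2000 colour difference and RMSE.

Tristimulus convention: ``spectrum_to_xyz`` normalises so a perfect
reflector has Y = 100 under the active illuminant (the luminance ratio
``k``); the plain 3x3 matrix routines work on the 0-1 scale and callers
scale by 100 where the 0-100 convention is required.

The CIE 1931 2-degree observer and the D65 illuminant are shipped as the
standard 10 nm tabulations and upsampled to the 1 nm grid with a shape-
preserving (PCHIP) interpolant, clipped at zero.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "WAVELENGTHS",
    "N_WAVELENGTHS",
    "CMFSet",
    "cie_1931_cmfs",
    "d65_illuminant",
    "srgb_decode",
    "srgb_encode",
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "spectrum_to_xyz",
    "xyz_to_lab",
    "ciede2000",
    "rmse",
    "load_spectrum_csv",
    "save_spectrum_csv",
]

#: The standard wavelength grid: 380..780 nm inclusive, 1 nm step.
WAVELENGTHS = np.arange(380.0, 781.0)
N_WAVELENGTHS = WAVELENGTHS.size  # 401

# sRGB (IEC 61966-2-1) linear RGB -> CIE 1931 XYZ, D65 white.
SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)


@dataclass(frozen=True)
class CMFSet:
    """Colour-matching functions sampled on :data:`WAVELENGTHS`."""

    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for name in ("xbar", "ybar", "zbar"):
            v = getattr(self, name)
            if v.shape != (N_WAVELENGTHS,):
                raise ValueError(f"{name} must have {N_WAVELENGTHS} samples")
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and non-negative")


def _interp_to_grid(wl: np.ndarray, values: np.ndarray) -> np.ndarray:
    interp = PchipInterpolator(wl, values)
    return np.clip(interp(WAVELENGTHS), 0.0, None)


@functools.lru_cache(maxsize=1)
def cie_1931_cmfs() -> CMFSet:
    """CIE 1931 2-degree standard observer on the 1 nm grid."""
    ref = resources.files("savehsi.data") / "cie_1931_2deg_cmf_10nm.csv"
    table = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    wl = table[:, 0]
    return CMFSet(
        xbar=_interp_to_grid(wl, table[:, 1]),
        ybar=_interp_to_grid(wl, table[:, 2]),
        zbar=_interp_to_grid(wl, table[:, 3]),
    )


@functools.lru_cache(maxsize=1)
def d65_illuminant() -> np.ndarray:
    """CIE D65 relative spectral power on the 1 nm grid."""
    ref = resources.files("savehsi.data") / "illuminant_d65_10nm.csv"
    table = np.loadtxt(str(ref), delimiter=",", skiprows=1)
    return _interp_to_grid(table[:, 0], table[:, 1])


def _check_on_grid(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != N_WAVELENGTHS:
        raise ValueError(
            f"{name} must be sampled on the {N_WAVELENGTHS}-point 380-780 nm grid, "
            f"got trailing dimension {values.shape[-1]}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")
    return values


def srgb_decode(encoded):
    """Decode gamma-encoded sRGB values in [0, 1] to linear intensity.

    8-bit pixel values must be divided by 255 first.  Raises ``ValueError``
    for inputs outside [0, 1].
    """
    x = np.asarray(encoded, dtype=float)
    if np.any(x < 0) or np.any(x > 1) or not np.all(np.isfinite(x)):
        raise ValueError("sRGB-encoded values must lie in [0, 1]")
    out = np.where(x <= 0.04045, x / 12.92, ((x + 0.055) / 1.055) ** 2.4)
    return out if out.ndim else float(out)


def srgb_encode(linear):
    """Encode linear intensity to gamma-encoded sRGB; input clipped to [0, 1]."""
    x = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    out = np.where(x <= 0.0031308, 12.92 * x, 1.055 * x ** (1 / 2.4) - 0.055)
    return out if out.ndim else float(out)


def linear_rgb_to_xyz(rgb):
    """Linear sRGB triples (..., 3) to CIE 1931 XYZ (Y on the 0-1 scale)."""
    rgb = np.asarray(rgb, dtype=float)
    return rgb @ SRGB_TO_XYZ.T


def xyz_to_linear_rgb(xyz):
    """CIE XYZ (0-1 scale) to linear sRGB; may leave [0, 1] out of gamut."""
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ XYZ_TO_SRGB.T


def spectrum_to_xyz(refl, illum=None, cmfs: CMFSet | None = None):
    """Integrate reflectance spectra against illuminant and observer.

    ``refl`` has shape (..., 401).  Returns XYZ with shape (..., 3),
    normalised by the luminance ratio ``k = 100 / sum(illum * ybar)`` so the
    perfect reflector maps to Y = 100.
    """
    refl = _check_on_grid(refl, "reflectance")
    illum = d65_illuminant() if illum is None else _check_on_grid(illum, "illuminant")
    if np.any(illum < 0):
        raise ValueError("illuminant power must be non-negative")
    cmfs = cie_1931_cmfs() if cmfs is None else cmfs
    norm = float(np.sum(illum * cmfs.ybar))
    if norm <= 0:
        raise ValueError("illuminant is identically zero: luminance normaliser undefined")
    k = 100.0 / norm
    weights = illum[:, None] * np.stack([cmfs.xbar, cmfs.ybar, cmfs.zbar], axis=1)
    return k * (refl @ weights)


def illuminant_white(illum=None, cmfs: CMFSet | None = None):
    """XYZ of the perfect reflector under ``illum`` (Y = 100 by construction)."""
    return spectrum_to_xyz(np.ones(N_WAVELENGTHS), illum, cmfs)


def xyz_to_lab(xyz, white):
    """CIE 1976 L*a*b* relative to the ``white`` tristimulus triple."""
    xyz = np.asarray(xyz, dtype=float)
    white = np.asarray(white, dtype=float)
    if np.any(white <= 0):
        raise ValueError("white point must have strictly positive components")
    t = xyz / white
    delta = 6.0 / 29.0
    f = np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def ciede2000(lab1, lab2):
    """CIEDE2000 colour difference between L*a*b* triples (vectorised).

    Implements the full formula with the hue rotation term; symmetric and
    zero exactly when the inputs coincide.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    L1, a1, b1 = lab1[..., 0], lab1[..., 1], lab1[..., 2]
    L2, a2, b2 = lab2[..., 0], lab2[..., 1], lab2[..., 2]

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1 + G) * a1
    a2p = (1 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where(C1p == 0, 0.0, h1p)
    h2p = np.where(C2p == 0, 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)

    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180.0,
            0.5 * hsum,
            np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)),
        ),
    )

    T = (
        1
        - 0.17 * np.cos(np.radians(hbp - 30.0))
        + 0.24 * np.cos(np.radians(2.0 * hbp))
        + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
        - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0))
    )
    dtheta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    return dE if dE.ndim else float(dE)


def rmse(a, b):
    """Root-mean-square difference of two equal-length sequences."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or a.size != b.size:
        raise ValueError("rmse requires two non-empty sequences of equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def load_spectrum_csv(path) -> np.ndarray:
    """Read a two-column (wavelength_nm, value) CSV onto the standard grid."""
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    wl, values = table[:, 0], table[:, 1]
    if wl.shape == WAVELENGTHS.shape and np.allclose(wl, WAVELENGTHS):
        return values
    order = np.argsort(wl)
    return _interp_to_grid(wl[order], values[order])


def save_spectrum_csv(path, values, header: str = "wavelength_nm,value") -> None:
    values = _check_on_grid(np.asarray(values, dtype=float), "spectrum")
    np.savetxt(
        path,
        np.column_stack([WAVELENGTHS, values]),
        delimiter=",",
        header=header,
        comments="",
        fmt="%.6f",
    )
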