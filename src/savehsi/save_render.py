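"""Narrow-band re-rendering of reconstructed spectra.

A reconstructed reflectance cube is re-illuminated through a small set of
narrow spectral bands and recombined into a display RGB image.  Each band
is a Cauchy-Lorentz (Lorentzian) line profile

    f(x; x0, gamma) = (1 / pi) * gamma / ((x - x0)^2 + gamma^2)

centred at x0 with half-width-at-half-maximum gamma.  The band response of
a pixel is the illuminant-weighted mean reflectance under that profile, so
a perfect reflector responds 1.0 in every band.  The default band set
covers 415 and 540 nm (the haemoglobin absorption peaks used by hardware
narrow-band imaging) plus 600, 700 and 780 nm, whose small contributions
to the red display channel reproduce the brownish cast of commercial
narrow-band endoscopy video.

The 5-band-to-3-channel mixing matrix follows the classic narrow-band
display convention — 415 nm drives the blue and green display channels,
540 nm drives red — and is fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    N_WAVELENGTHS,
    WAVELENGTHS,
    d65_illuminant,
    srgb_encode,
)

__all__ = [
    "BandProfile",
    "SAVEConfig",
    "DEFAULT_BANDS",
    "DEFAULT_MIX",
    "cauchy_lorentz",
    "band_response",
    "band_responses",
    "render_save",
    "convert_image",
]


@dataclass(frozen=True)
class BandProfile:
    """Lorentzian band: centre wavelength and HWHM, both in nm."""

    center: float
    hwhm: float

    def __post_init__(self) -> None:
        if not 380.0 <= self.center <= 780.0:
            raise ValueError("band centre must lie within 380-780 nm")
        if self.hwhm <= 0:
            raise ValueError("band half-width must be positive")


def cauchy_lorentz(x, x0: float, gamma: float):
    """Lorentzian density (1/nm); symmetric about x0, maximal at x0."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    x = np.asarray(x, dtype=float)
    out = (gamma / np.pi) / ((x - x0) ** 2 + gamma**2)
    return out if out.ndim else float(out)


# 415/540 nm get ~30 nm FWHM (typical narrow-band filters); the red-side
# anchors are slightly tighter.
DEFAULT_BANDS = (
    BandProfile(415.0, 15.0),
    BandProfile(540.0, 15.0),
    BandProfile(600.0, 10.0),
    BandProfile(700.0, 10.0),
    BandProfile(780.0, 10.0),
)

# Rows: display R, G, B; columns follow the band order above.
DEFAULT_MIX = np.array(
    [
        [0.00, 1.00, 0.15, 0.10, 0.05],  # R: 540 nm plus a brownish long-wave tail
        [1.00, 0.00, 0.00, 0.00, 0.00],  # G: 415 nm
        [1.00, 0.00, 0.00, 0.00, 0.00],  # B: 415 nm
    ]
)


@dataclass
class SAVEConfig:
    """Band set, channel-mixing matrix and illuminant for rendering."""

    bands: tuple[BandProfile, ...] = DEFAULT_BANDS
    mix: np.ndarray = field(default_factory=lambda: DEFAULT_MIX.copy())
    illuminant: np.ndarray | None = None
    white_normalize: bool = True

    def __post_init__(self) -> None:
        self.bands = tuple(self.bands)
        if len(self.bands) < 1:
            raise ValueError("at least one band is required")
        self.mix = np.asarray(self.mix, dtype=float)
        if self.mix.shape != (3, len(self.bands)):
            raise ValueError(f"mix must be 3 x {len(self.bands)}")
        if not np.all(np.isfinite(self.mix)) or np.any(self.mix < 0):
            raise ValueError("mix must be finite and non-negative")
        if self.illuminant is not None:
            self.illuminant = np.asarray(self.illuminant, dtype=float)
            if self.illuminant.shape != (N_WAVELENGTHS,):
                raise ValueError("illuminant must live on the 401-point grid")

    def get_illuminant(self) -> np.ndarray:
        return d65_illuminant() if self.illuminant is None else self.illuminant

    def to_dict(self) -> dict:
        return {
            "bands": [{"center": b.center, "hwhm": b.hwhm} for b in self.bands],
            "mix": self.mix.tolist(),
            "illuminant": None if self.illuminant is None else self.illuminant.tolist(),
            "white_normalize": self.white_normalize,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SAVEConfig":
        return cls(
            bands=tuple(BandProfile(b["center"], b["hwhm"]) for b in d["bands"]),
            mix=np.asarray(d["mix"], dtype=float),
            illuminant=None if d.get("illuminant") is None else np.asarray(d["illuminant"], dtype=float),
            white_normalize=bool(d.get("white_normalize", True)),
        )


def band_response(refl, band: BandProfile, illum=None):
    """Illuminant-weighted mean reflectance under one Lorentzian band.

    ``sum(refl * S * f) / sum(S * f)``: linear in reflectance, 1.0 for the
    perfect reflector, bounded by the reflectance range.
    """
    refl = np.asarray(refl, dtype=float)
    if refl.shape[-1] != N_WAVELENGTHS:
        raise ValueError("reflectance must live on the 401-point grid")
    illum = d65_illuminant() if illum is None else np.asarray(illum, dtype=float)
    weights = illum * cauchy_lorentz(WAVELENGTHS, band.center, band.hwhm)
    denom = float(weights.sum())
    if denom <= 0:
        raise ValueError("band weight integrates to zero under this illuminant")
    return refl @ weights / denom


def band_responses(refl, config: SAVEConfig) -> np.ndarray:
    """Stack of band responses, shape (..., n_bands)."""
    illum = config.get_illuminant()
    return np.stack([band_response(refl, b, illum) for b in config.bands], axis=-1)


def render_save(cube, config: SAVEConfig | None = None) -> np.ndarray:
    """Render a spectral cube (..., 401) to an 8-bit sRGB image (..., 3).

    Per pixel: Lorentzian band responses -> linear RGB via the mixing
    matrix -> optional white normalisation (perfect reflector renders
    neutral white) -> clip -> gamma encode -> uint8.
    """
    config = config or SAVEConfig()
    b = band_responses(cube, config)
    linear = b @ config.mix.T
    if config.white_normalize:
        white = config.mix.sum(axis=1)
        if np.any(white <= 0):
            raise ValueError("white normalisation requires every channel to receive some band weight")
        linear = linear / white
    encoded = srgb_encode(np.clip(linear, 0.0, 1.0))
    return np.round(np.asarray(encoded) * 255.0).astype(np.uint8)


def convert_image(image, correction, basis, conversion, config: SAVEConfig | None = None) -> np.ndarray:
    """Full white-light-to-narrow-band conversion of one sRGB image.

    decode -> polynomial colour correction -> spectral reconstruction ->
    narrow-band rendering; deterministic, preserves height and width.
    """
    from .reconstruction import reconstruct_cube

    for component, name in ((correction, "correction"), (basis, "basis"), (conversion, "conversion")):
        if component is None:
            raise ValueError(f"missing fitted pipeline component: {name}")
    cube = reconstruct_cube(basis, conversion, correction, image)
    return render_save(cube, config)
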