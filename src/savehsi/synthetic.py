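"""Synthetic stand-ins for the spectrometer and clinical data.

The calibration and classification experiments require a measured 24-patch
colour checker (camera RGB plus spectrometer reflectance per patch) and a
labelled endoscopic image set; neither is publicly available, so this
module generates documented synthetic equivalents:

* ``make_macbeth_spectra`` — 24 smooth reflectance spectra laid out like a
  classic 24-patch checker: six flat grays and eighteen chromatic patches
  built from one to three Gaussian bumps.  These are parametric fixtures,
  not measurements of any physical chart.
* ``simulate_camera`` — a virtual distorted camera with channel crosstalk,
  per-channel power-law nonlinearity, dark offset and additive Gaussian
  sensor noise; the degenerate configuration reproduces the ideal
  colorimetric path exactly.
* ``make_phantom_dataset`` — three-class phantom endoscopy images
  (normal / dysplasia / scc) whose colour and texture statistics differ by
  class, each image carrying a patient identifier for leak-free splits.
* ``augment`` — the flip / 90-degree / bounded-rotation augmentation
  scheme, each transform applied with probability 0.5.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage.transform import resize as sk_resize

from .colorimetry import (
    N_WAVELENGTHS,
    WAVELENGTHS,
    d65_illuminant,
    spectrum_to_xyz,
    srgb_encode,
    xyz_to_linear_rgb,
)

__all__ = [
    "CameraModel",
    "PhantomSpec",
    "LabeledImage",
    "make_macbeth_spectra",
    "simulate_camera",
    "make_phantom_dataset",
    "augment",
    "resize_to_limit",
    "DEFAULT_CAMERA",
]

CLASS_NAMES = ("normal", "dysplasia", "scc")


@dataclass(frozen=True)
class CameraModel:
    """Forward model of a distorted RGB camera.

    The pipeline is: true XYZ -> linear sRGB -> ``crosstalk`` channel
    mixing -> per-channel power law ``response_exponent`` -> additive
    ``dark_offset`` -> Gaussian noise of scale ``noise_sigma`` -> clip to
    [0, 1] -> sRGB gamma encoding.
    """

    crosstalk: tuple = (
        (1.0, 0.0, 0.0),
        (0.0, 1.0, 0.0),
        (0.0, 0.0, 1.0),
    )
    response_exponent: float = 1.0
    dark_offset: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        ct = np.asarray(self.crosstalk, dtype=float)
        if ct.shape != (3, 3):
            raise ValueError("crosstalk must be a 3x3 matrix")
        if not np.allclose(ct.sum(axis=1), 1.0, atol=0.05):
            raise ValueError("crosstalk rows must sum to ~1 (energy-preserving mixing)")
        if np.any(np.asarray(self.response_exponent) <= 0):
            raise ValueError("response exponent must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")

    @property
    def crosstalk_matrix(self) -> np.ndarray:
        return np.asarray(self.crosstalk, dtype=float)


#: Distorted camera used by the seeded calibration simulation: mild
#: crosstalk (92% diagonal), slightly super-linear response, 1% dark
#: offset and sigma = 0.005 sensor noise.
DEFAULT_CAMERA = CameraModel(
    crosstalk=((0.92, 0.05, 0.03), (0.03, 0.92, 0.05), (0.05, 0.03, 0.92)),
    response_exponent=1.05,
    dark_offset=0.01,
    noise_sigma=0.005,
    seed=42,
)


def _bump(center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((WAVELENGTHS - center) / sigma) ** 2)


# (name, base level, [(center, sigma, amplitude), ...]); bump centres in nm.
_CHROMATIC_RECIPES = [
    ("dark_skin", 0.06, [(620.0, 80.0, 0.25)]),
    ("light_skin", 0.15, [(600.0, 90.0, 0.45), (480.0, 40.0, 0.08)]),
    ("blue_sky", 0.08, [(460.0, 40.0, 0.35)]),
    ("foliage", 0.05, [(550.0, 35.0, 0.25), (700.0, 60.0, 0.10)]),
    ("blue_flower", 0.10, [(450.0, 35.0, 0.40), (650.0, 80.0, 0.15)]),
    ("bluish_green", 0.10, [(500.0, 45.0, 0.45)]),
    ("orange", 0.05, [(610.0, 55.0, 0.55)]),
    ("purplish_blue", 0.06, [(440.0, 35.0, 0.45)]),
    ("moderate_red", 0.05, [(640.0, 55.0, 0.45)]),
    ("purple", 0.04, [(420.0, 30.0, 0.25), (680.0, 60.0, 0.20)]),
    ("yellow_green", 0.06, [(560.0, 45.0, 0.50)]),
    ("orange_yellow", 0.06, [(590.0, 55.0, 0.55)]),
    ("blue", 0.04, [(450.0, 25.0, 0.40)]),
    ("green", 0.04, [(530.0, 35.0, 0.40)]),
    ("red", 0.04, [(650.0, 45.0, 0.50)]),
    ("yellow", 0.08, [(580.0, 70.0, 0.60)]),
    ("magenta", 0.05, [(440.0, 35.0, 0.30), (660.0, 55.0, 0.40)]),
    ("cyan", 0.06, [(480.0, 40.0, 0.45)]),
]

_GRAY_LEVELS = [("white", 0.950), ("neutral_8", 0.591), ("neutral_65", 0.362),
                ("neutral_5", 0.198), ("neutral_35", 0.090), ("black", 0.031)]


def make_macbeth_spectra(seed: int = 42) -> tuple[np.ndarray, list[str]]:
    """24 smooth checker-like reflectance spectra and their patch names.

    Eighteen chromatic patches (Gaussian-bump recipes, lightly jittered by
    the seed) followed by six flat grays from 0.95 down to 0.031.  Returns
    a (24, 401) array on the standard grid, clipped to [0, 1].
    """
    rng = np.random.default_rng(seed)
    spectra, names = [], []
    for name, base, bumps in _CHROMATIC_RECIPES:
        s = np.full(N_WAVELENGTHS, base * (1 + 0.05 * rng.standard_normal()))
        for center, sigma, amp in bumps:
            s = s + _bump(
                center + rng.uniform(-3.0, 3.0),
                sigma * (1 + 0.05 * rng.standard_normal()),
                amp * (1 + 0.03 * rng.standard_normal()),
            )
        spectra.append(np.clip(s, 0.0, 1.0))
        names.append(name)
    for name, level in _GRAY_LEVELS:
        jittered = np.clip(level * (1 + 0.01 * rng.standard_normal()), 0.0, 1.0)
        spectra.append(np.full(N_WAVELENGTHS, jittered))
        names.append(name)
    return np.asarray(spectra), names


def simulate_camera(spectra, illum=None, cam: CameraModel | None = None) -> np.ndarray:
    """Photograph reflectance spectra with a distorted virtual camera.

    Returns gamma-encoded sRGB values in [0, 1] with shape (..., 3).
    Deterministic given ``cam.seed``.
    """
    cam = cam or CameraModel()
    illum = d65_illuminant() if illum is None else np.asarray(illum, dtype=float)
    if np.all(illum == 0):  # no light: the sensor sees dark current only
        shape = np.asarray(spectra, dtype=float).shape[:-1] + (3,)
        xyz = np.zeros(shape)
    else:
        xyz = spectrum_to_xyz(spectra, illum) / 100.0
    rgb = np.clip(xyz_to_linear_rgb(xyz), 0.0, 1.0)
    rgb = rgb @ cam.crosstalk_matrix.T
    rgb = np.clip(rgb, 0.0, None) ** np.asarray(cam.response_exponent, dtype=float)
    rgb = rgb + cam.dark_offset
    if cam.noise_sigma > 0:
        rng = np.random.default_rng(cam.seed)
        rgb = rgb + rng.normal(0.0, cam.noise_sigma, size=rgb.shape)
    return srgb_encode(np.clip(rgb, 0.0, 1.0))


@dataclass
class LabeledImage:
    """One phantom endoscopy frame with its provenance."""

    image: np.ndarray  # (H, W, 3) uint8
    label: str
    patient_id: str
    augmented: bool = False
    name: str = ""


@dataclass
class PhantomSpec:
    """Generation parameters for the three-class phantom image set."""

    n_per_class: tuple[int, int, int] = (10, 10, 10)
    image_size: int = 64
    seed: int = 0
    # per-class texture: (base RGB, vessel count, lesion blob count, blob irregularity)
    class_params: dict = field(
        default_factory=lambda: {
            "normal": {"base": (0.86, 0.56, 0.50), "vessels": 3, "blobs": 0, "irregularity": 0.0},
            "dysplasia": {"base": (0.80, 0.47, 0.42), "vessels": 8, "blobs": 2, "irregularity": 0.4},
            "scc": {"base": (0.68, 0.38, 0.33), "vessels": 6, "blobs": 4, "irregularity": 0.9},
        }
    )

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be non-negative")
        if self.image_size < 32:
            raise ValueError("image size must be at least 32 pixels")


def _phantom_image(size: int, params: dict, rng: np.random.Generator) -> np.ndarray:
    base = np.asarray(params["base"], dtype=float)
    img = np.ones((size, size, 3)) * base
    # smooth mucosal shading
    shade = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=size / 8)
    shade = shade / (np.abs(shade).max() + 1e-12)
    img *= (1.0 + 0.15 * shade)[:, :, None]
    # vasculature: dark-red random walks
    for _ in range(int(params["vessels"])):
        r, c = rng.integers(0, size, size=2)
        for _ in range(size // 2):
            dr, dc = rng.integers(-2, 3, size=2)
            r2 = int(np.clip(r + dr, 0, size - 1))
            c2 = int(np.clip(c + dc, 0, size - 1))
            rr, cc = skdraw.line(int(r), int(c), r2, c2)
            img[rr, cc] *= np.array([0.75, 0.45, 0.45])
            r, c = r2, c2
    # lesion blobs: darker, brown-shifted ellipses, irregular for carcinoma
    for _ in range(int(params["blobs"])):
        cy, cx = rng.integers(size // 6, 5 * size // 6, size=2)
        ry = rng.integers(size // 12, size // 5)
        rx = int(ry * (1 + params["irregularity"] * rng.uniform(-0.5, 1.0)))
        rot = rng.uniform(0, np.pi)
        rr, cc = skdraw.ellipse(cy, cx, max(ry, 2), max(rx, 2), shape=(size, size), rotation=rot)
        depth = rng.uniform(0.5, 0.8)
        img[rr, cc] *= np.array([depth + 0.1, depth - 0.05, depth - 0.1])
        if params["irregularity"] > 0.5:  # ragged edge for the carcinoma class
            edge = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma=2) > 0.6
            mask = np.zeros((size, size), dtype=bool)
            mask[rr, cc] = True
            img[ndimage.binary_dilation(mask, iterations=2) & edge] *= 0.75
    noise = rng.normal(0.0, 0.015, size=img.shape)
    return (np.clip(img + noise, 0.0, 1.0) * 255).round().astype(np.uint8)


def make_phantom_dataset(spec: PhantomSpec | None = None) -> list[LabeledImage]:
    """Generate the labelled three-class phantom image set.

    Each source image is assigned its own patient identifier, so
    patient-level splitting degenerates gracefully to image-level for the
    phantom while still exercising the leakage bookkeeping.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    items: list[LabeledImage] = []
    for label, n in zip(CLASS_NAMES, spec.n_per_class):
        params = spec.class_params[label]
        for i in range(n):
            img = _phantom_image(spec.image_size, params, rng)
            items.append(
                LabeledImage(
                    image=img,
                    label=label,
                    patient_id=f"{label}_p{i:03d}",
                    augmented=False,
                    name=f"{label}_{i:03d}",
                )
            )
    return items


def _augment_one(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = img
    if rng.random() < 0.5:
        out = out[:, ::-1]  # horizontal flip
    if rng.random() < 0.5:
        out = out[::-1, :]  # vertical flip
    if rng.random() < 0.5:
        out = np.rot90(out)
    if rng.random() < 0.5:
        angle = rng.uniform(-45.0, 45.0)
        out = ndimage.rotate(out.astype(float), angle, axes=(0, 1), reshape=False, mode="reflect", order=1)
        out = np.clip(out, 0, 255).round().astype(np.uint8)
    return np.ascontiguousarray(out)


def augment(items: list[LabeledImage], n_new, seed: int = 0) -> list[LabeledImage]:
    """Append transformed copies: flips, 90-degree rotation and a bounded
    rotation up to 45 degrees, each applied with probability 0.5.

    ``n_new`` is either one count applied to every class or a mapping
    ``{label: count}``.  Augmented copies inherit the source patient
    identifier and are flagged so splits can keep them out of validation
    and test partitions.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[LabeledImage]] = {}
    for it in items:
        by_class.setdefault(it.label, []).append(it)
    if isinstance(n_new, int):
        n_new = {label: n_new for label in by_class}
    out = list(items)
    for label, count in n_new.items():
        if count < 0:
            raise ValueError("augmentation counts must be non-negative")
        sources = [it for it in by_class.get(label, []) if not it.augmented]
        if count > 0 and not sources:
            raise ValueError(f"cannot augment empty class {label!r}")
        for j in range(count):
            src = sources[int(rng.integers(len(sources)))]
            out.append(
                LabeledImage(
                    image=_augment_one(src.image, rng),
                    label=src.label,
                    patient_id=src.patient_id,
                    augmented=True,
                    name=f"{src.name}_aug{j:03d}",
                )
            )
    return out


def resize_to_limit(image: np.ndarray, limit: int = 640) -> np.ndarray:
    """Bound an image to ``limit`` pixels per side.

    Images within the limit pass through untouched.  Larger images are
    first downscaled preserving aspect ratio (until the shorter side hits
    the limit, when both sides exceed it) and then centre-cropped, so a
    1280x960 input becomes exactly limit x limit.
    """
    if limit < 1:
        raise ValueError("limit must be at least 1")
    img = np.asarray(image)
    h, w = img.shape[:2]
    if h <= limit and w <= limit:
        return img
    if min(h, w) > limit:
        scale = limit / min(h, w)
        new_shape = (max(int(round(h * scale)), limit), max(int(round(w * scale)), limit))
        img = sk_resize(img, new_shape + img.shape[2:], anti_aliasing=True, preserve_range=True)
        img = np.clip(img, 0, 255).round().astype(np.uint8)
        h, w = img.shape[:2]
    top = (h - min(h, limit)) // 2
    left = (w - min(w, limit)) // 2
    return np.ascontiguousarray(img[top : top + min(h, limit), left : left + min(w, limit)])
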