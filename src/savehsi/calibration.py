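"""Camera-error correction for colour-checker calibration.

A distorted camera's XYZ readings are mapped onto spectrometer-derived
targets through a polynomial variable expansion: each camera triple
(X, Y, Z) is expanded into the monomial vector V (all monomials up to a
chosen degree, constant last), and a coefficient matrix C is fit by
minimum-norm least squares,

    C = XYZ_target . pinv(V),        XYZ_corrected = C . V.

The expansion terms absorb the familiar camera error sources: the
constant term models dark current, cross terms model colour-filter
crosstalk and colour shift, and squared terms model nonlinear response.
With 24 checker patches a degree-2 expansion (10 terms) is comfortably
over-determined.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import rmse

__all__ = ["PolyExpansionSpec", "CorrectionModel", "expand_variables", "fit_correction", "apply_correction"]


@dataclass(frozen=True)
class PolyExpansionSpec:
    """Monomial expansion of an (X, Y, Z) triple.

    Terms are listed in ascending total degree (1..order); within a degree,
    monomials appear in lexicographic order of their (X, Y, Z) exponent
    triples with X varying slowest — degree 1 is therefore X, Y, Z and
    degree 2 continues X^2, XY, XZ, Y^2, YZ, Z^2.  The constant term, when
    included, comes last.
    """

    order: int = 2
    include_constant: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.order <= 3:
            raise ValueError("expansion order must be 1, 2 or 3")

    @property
    def exponents(self) -> list[tuple[int, int, int]]:
        terms = []
        for degree in range(1, self.order + 1):
            degree_terms = []
            for ex in range(degree, -1, -1):
                for ey in range(degree - ex, -1, -1):
                    degree_terms.append((ex, ey, degree - ex - ey))
            terms.extend(degree_terms)
        if self.include_constant:
            terms.append((0, 0, 0))
        return terms

    @property
    def n_terms(self) -> int:
        return len(self.exponents)

    def term_names(self) -> list[str]:
        names = []
        for ex, ey, ez in self.exponents:
            if ex == ey == ez == 0:
                names.append("1")
            else:
                names.append(
                    "".join(f"{v}^{e}" if e > 1 else v for v, e in zip("XYZ", (ex, ey, ez)) if e)
                )
        return names

    def to_dict(self) -> dict:
        return {"order": self.order, "include_constant": self.include_constant}

    @classmethod
    def from_dict(cls, d: dict) -> "PolyExpansionSpec":
        return cls(order=int(d["order"]), include_constant=bool(d["include_constant"]))


def expand_variables(xyz, spec: PolyExpansionSpec) -> np.ndarray:
    """Expand triples (..., 3) into monomial vectors (..., n_terms)."""
    xyz = np.asarray(xyz, dtype=float)
    if xyz.shape[-1] != 3:
        raise ValueError("expected (..., 3) XYZ input")
    if not np.all(np.isfinite(xyz)):
        raise ValueError("XYZ input contains non-finite values")
    cols = [
        xyz[..., 0] ** ex * xyz[..., 1] ** ey * xyz[..., 2] ** ez
        if (ex, ey, ez) != (0, 0, 0)
        else np.ones(xyz.shape[:-1])
        for ex, ey, ez in spec.exponents
    ]
    return np.stack(cols, axis=-1)


@dataclass
class CorrectionModel:
    """Fitted polynomial colour-correction map."""

    C: np.ndarray  # (3, n_terms)
    spec: PolyExpansionSpec
    fit_rmse: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape != (3, self.spec.n_terms):
            raise ValueError(
                f"C must be 3 x {self.spec.n_terms} for this expansion, got {self.C.shape}"
            )
        if not np.all(np.isfinite(self.C)):
            raise ValueError("C contains non-finite values")

    def to_dict(self) -> dict:
        return {"C": self.C.tolist(), "spec": self.spec.to_dict(), "fit_rmse": float(self.fit_rmse)}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrectionModel":
        return cls(
            C=np.asarray(d["C"], dtype=float),
            spec=PolyExpansionSpec.from_dict(d["spec"]),
            fit_rmse=float(d.get("fit_rmse", np.nan)),
        )


def fit_correction(xyz_camera, xyz_target, spec: PolyExpansionSpec | None = None) -> CorrectionModel:
    """Regress target (spectrometer) XYZ onto expanded camera XYZ.

    Solves ``C = T . pinv(V)`` where V stacks expanded camera colours
    column-wise; the minimum-norm least-squares solution is returned even
    for rank-deficient systems (with a warning when the patch count is
    below the term count).  ``fit_rmse`` is the mean over patches of the
    per-patch RMSE between corrected and target XYZ, on whatever scale the
    inputs use (0-100 by convention).
    """
    spec = spec or PolyExpansionSpec()
    cam = np.asarray(xyz_camera, dtype=float)
    tgt = np.asarray(xyz_target, dtype=float)
    if cam.ndim != 2 or tgt.shape != cam.shape or cam.shape[1] != 3:
        raise ValueError("camera and target XYZ must be matching (n, 3) arrays")
    if not (np.all(np.isfinite(cam)) and np.all(np.isfinite(tgt))):
        raise ValueError("calibration inputs contain non-finite values")
    if cam.shape[0] < spec.n_terms:
        warnings.warn(
            f"{cam.shape[0]} patches for {spec.n_terms} expansion terms: "
            "system is rank-deficient; returning the minimum-norm solution",
            stacklevel=2,
        )
    V = expand_variables(cam, spec).T  # (n_terms, n)
    C = tgt.T @ np.linalg.pinv(V)
    pred = (C @ V).T
    fit = float(np.mean([rmse(p, t) for p, t in zip(pred, tgt)]))
    return CorrectionModel(C=C, spec=spec, fit_rmse=fit)


def apply_correction(model: CorrectionModel, xyz) -> np.ndarray:
    """Apply a fitted correction: corrected = C . V(xyz); shape-preserving."""
    V = expand_variables(xyz, model.spec)
    return V @ model.C.T
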