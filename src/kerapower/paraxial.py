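"""Closed-form paraxial corneal power calculations.

Two estimates of central corneal power are compared throughout the package:

* the **keratometric power** ``Pk = (nk - 1) / r1c``, which uses only the
  anterior corneal radius together with a fictitious keratometric index
  ``nk`` (1.3375 on most topographers);
* the **Gaussian power** of the cornea treated as a thick lens,
  ``Pc = P1c + P2c - (e_c / n_c) * P1c * P2c``, which uses both surface
  curvatures and the central thickness and serves as the reference standard.

Their difference ``dPc = Pk - Pc`` is the keratometric error (positive means
the keratometric approach overestimates true power).  Setting ``dPc = 0``
and solving for ``nk`` yields the geometry-dependent *exact* keratometric
index ``nk_exact = 1 + r1c * Pc`` (radii in metres).

All functions accept radii in millimetres, are vectorised over NumPy arrays,
and return powers in dioptres.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .schematic_eye import (
    CornealGeometry,
    DomainError,
    SchematicEyeModel,
    to_metres,
)

__all__ = [
    "PowerDecomposition",
    "keratometric_power",
    "anterior_power",
    "posterior_power",
    "gaussian_power_value",
    "gaussian_power",
    "k_ratio",
    "delta_pc",
    "delta_pc_k_form",
    "nk_exact",
    "nk_exact_value",
    "nk_exact_rational",
]

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class PowerDecomposition:
    """Surface-by-surface power breakdown for one corneal geometry.

    ``delta_pc = pk - pc_gauss`` and ``pc_gauss = p1c + p2c -
    (e_c/n_c)*p1c*p2c`` hold to machine precision by construction.
    """

    p1c: float
    p2c: float
    pc_gauss: float
    pk: float
    delta_pc: float
    nk_used: float


def _check_radius(r_mm: ArrayLike, name: str) -> np.ndarray:
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise DomainError(f"{name} must be positive (mm), got {r_mm}")
    return r


def _check_nk(nk: ArrayLike) -> np.ndarray:
    nk_arr = np.asarray(nk, dtype=float)
    if np.any((nk_arr <= 1.0) | (nk_arr >= 1.5)):
        raise DomainError(f"keratometric index must lie in (1, 1.5), got {nk}")
    return nk_arr


def _maybe_scalar(x: np.ndarray) -> ArrayLike:
    return float(x) if x.ndim == 0 else x


def keratometric_power(r1c_mm: ArrayLike, nk: ArrayLike) -> ArrayLike:
    """Keratometric corneal power (nk - 1)/r1c in dioptres.

    Parameters
    ----------
    r1c_mm : float or array
        Anterior corneal radius in millimetres.
    nk : float or array
        Keratometric refractive index, in (1, 1.5).
    """
    r1 = _check_radius(r1c_mm, "r1c")
    nk_arr = _check_nk(nk)
    return _maybe_scalar((nk_arr - 1.0) / (r1 / 1000.0))


def anterior_power(r1c_mm: ArrayLike, model: SchematicEyeModel) -> ArrayLike:
    """Anterior-surface power P1c = (n_c - n_a)/r1c in dioptres."""
    r1 = _check_radius(r1c_mm, "r1c")
    return _maybe_scalar((model.n_c - model.n_a) / (r1 / 1000.0))


def posterior_power(r2c_mm: ArrayLike, model: SchematicEyeModel) -> ArrayLike:
    """Posterior-surface power P2c = (n_ha - n_c)/r2c in dioptres (negative)."""
    r2 = _check_radius(r2c_mm, "r2c")
    return _maybe_scalar((model.n_ha - model.n_c) / (r2 / 1000.0))


def gaussian_power_value(
    r1c_mm: ArrayLike,
    r2c_mm: ArrayLike,
    model: SchematicEyeModel,
    e_c_mm: Optional[ArrayLike] = None,
) -> ArrayLike:
    """Total Gaussian (thick-lens) corneal power in dioptres, vectorised.

    ``e_c_mm`` is the central corneal thickness in millimetres; when omitted
    the model's theoretical thickness is used.
    """
    p1 = np.asarray(anterior_power(r1c_mm, model))
    p2 = np.asarray(posterior_power(r2c_mm, model))
    if e_c_mm is None:
        ec_m = model.e_c_model
    else:
        ec = np.asarray(e_c_mm, dtype=float)
        if np.any(ec < 0):
            raise DomainError(f"thickness must be non-negative, got {e_c_mm}")
        ec_m = ec / 1000.0
    out = p1 + p2 - (ec_m / model.n_c) * p1 * p2
    return _maybe_scalar(np.asarray(out))


def gaussian_power(
    geom: CornealGeometry,
    model: SchematicEyeModel,
    nk: Optional[float] = None,
) -> PowerDecomposition:
    """Full power decomposition for a single corneal geometry.

    The keratometric power ``pk`` (and hence ``delta_pc``) is evaluated with
    ``nk``; if omitted, the model's classical index is used.
    """
    nk_used = model.n_k_classic if nk is None else float(_check_nk(nk))
    ec_m = geom.thickness_metres(model)
    p1 = float(anterior_power(geom.r1c, model))
    p2 = float(posterior_power(geom.r2c, model))
    pcg = p1 + p2 - (ec_m / model.n_c) * p1 * p2
    pk = float(keratometric_power(geom.r1c, nk_used))
    return PowerDecomposition(
        p1c=p1, p2c=p2, pc_gauss=pcg, pk=pk, delta_pc=pk - pcg, nk_used=nk_used
    )


def k_ratio(r1c_mm: ArrayLike, r2c_mm: ArrayLike) -> ArrayLike:
    """Anterior-to-posterior corneal radius ratio k = r1c/r2c."""
    r2 = _check_radius(r2c_mm, "r2c")
    r1 = np.asarray(r1c_mm, dtype=float)
    return _maybe_scalar(r1 / r2)


def delta_pc(
    geom: CornealGeometry, nk: ArrayLike, model: SchematicEyeModel
) -> ArrayLike:
    """Keratometric error dPc = Pk(nk) - PcGauss in dioptres.

    Positive values mean the keratometric approach overestimates the
    Gaussian reference power.
    """
    pcg = gaussian_power_value(
        geom.r1c, geom.r2c, model, e_c_mm=1000.0 * geom.thickness_metres(model)
    )
    return keratometric_power(geom.r1c, nk) - pcg


def delta_pc_k_form(
    r1c_mm: ArrayLike,
    k: ArrayLike,
    nk: ArrayLike,
    model: SchematicEyeModel,
    e_c_mm: Optional[ArrayLike] = None,
) -> ArrayLike:
    """Keratometric error written in terms of the k ratio instead of r2c.

    Algebraically identical to :func:`delta_pc` with ``r2c = r1c / k``;
    exposed separately because published domains are often stated as
    (r1c, k) rectangles.
    """
    k_arr = np.asarray(k, dtype=float)
    if np.any(k_arr <= 0):
        raise DomainError(f"k ratio must be positive, got {k}")
    r1 = _check_radius(r1c_mm, "r1c")
    ec_m = model.e_c_model if e_c_mm is None else np.asarray(e_c_mm, dtype=float) / 1000.0
    r1_m = r1 / 1000.0
    p1 = (model.n_c - model.n_a) / r1_m
    p2 = (model.n_ha - model.n_c) * k_arr / r1_m
    pcg = p1 + p2 - (ec_m / model.n_c) * p1 * p2
    pk = (np.asarray(_check_nk(nk)) - 1.0) / r1_m
    return _maybe_scalar(np.asarray(pk - pcg))


def nk_exact_value(
    r1c_mm: ArrayLike,
    r2c_mm: ArrayLike,
    model: SchematicEyeModel,
    e_c_mm: Optional[ArrayLike] = None,
) -> ArrayLike:
    """Exact keratometric index nk_exact = 1 + r1c * PcGauss, vectorised.

    This is the unique index for which the keratometric power reproduces the
    Gaussian power of the given geometry; the identity form is numerically
    stable and unit-invariant.
    """
    pcg = np.asarray(gaussian_power_value(r1c_mm, r2c_mm, model, e_c_mm=e_c_mm))
    r1_m = np.asarray(r1c_mm, dtype=float) / 1000.0
    return _maybe_scalar(np.asarray(1.0 + r1_m * pcg))


def nk_exact(geom: CornealGeometry, model: SchematicEyeModel) -> float:
    """Exact keratometric index for a single geometry (thickness resolved)."""
    return float(
        nk_exact_value(
            geom.r1c, geom.r2c, model, e_c_mm=1000.0 * geom.thickness_metres(model)
        )
    )


def nk_exact_rational(
    r1c_mm: ArrayLike,
    r2c_mm: ArrayLike,
    model: SchematicEyeModel,
    e_c_mm: Optional[ArrayLike] = None,
) -> ArrayLike:
    """Exact keratometric index via the expanded rational expression.

    Independent algebraic form of :func:`nk_exact_value` (numerator expanded
    over ``n_c * r2c``); used to cross-check the identity form.
    """
    r1 = _check_radius(r1c_mm, "r1c") / 1000.0
    r2 = _check_radius(r2c_mm, "r2c") / 1000.0
    ec = model.e_c_model if e_c_mm is None else np.asarray(e_c_mm, dtype=float) / 1000.0
    n_c, n_ha = model.n_c, model.n_ha
    numerator = (
        -ec * n_c
        + ec * n_c**2
        + ec * n_ha
        - ec * n_c * n_ha
        - n_c**2 * r1
        + n_c**2 * r2
        + n_c * n_ha * r1
    )
    return _maybe_scalar(np.asarray(numerator / (n_c * r2)))
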