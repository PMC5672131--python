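"""Schematic eye models and the unit/rounding conventions shared by the package.

The corneal subsystem of a theoretical (schematic) eye is described by four
refractive indices and a central thickness.  Two classical models are built
in — Gullstrand and Le Grand — each with the single-value ("classical")
keratometric index historically derived from it.  The constants live in a
plain-text YAML registry shipped with the package so that alternative models
can be registered without code changes; the two built-ins are immutable.

Conventions used throughout:

* radii and thicknesses cross public interfaces in **millimetres** (clinical
  convention) and are converted to metres internally;
* optical powers are always **dioptres** (inverse metres);
* dioptre quantities are displayed to 1 decimal, refractive indices to 4
  decimals, matching the precision of published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

__all__ = [
    "SchematicEyeModel",
    "CornealGeometry",
    "get_model",
    "register_model",
    "register_models_from_file",
    "available_models",
    "to_metres",
    "to_millimetres",
    "microns_to_metres",
    "microns_to_millimetres",
    "UnknownModelError",
    "DomainError",
    "DIOPTRE_DECIMALS",
    "INDEX_DECIMALS",
]

# Display precision, matching published tables.
DIOPTRE_DECIMALS = 1
INDEX_DECIMALS = 4

_DATA_FILE = Path(__file__).parent / "data" / "eye_models.yaml"


class UnknownModelError(KeyError):
    """Requested schematic eye model is not registered."""


class DomainError(ValueError):
    """Geometric or optical input outside its physical domain."""


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

ArrayLike = Union[float, np.ndarray]


def to_metres(length_mm: ArrayLike) -> ArrayLike:
    """Convert millimetres to metres (the internal unit for radii)."""
    return np.asarray(length_mm, dtype=float) / 1000.0 if np.ndim(length_mm) else float(length_mm) / 1000.0


def to_millimetres(length_m: ArrayLike) -> ArrayLike:
    """Convert metres back to millimetres; exact inverse of :func:`to_metres`."""
    return np.asarray(length_m, dtype=float) * 1000.0 if np.ndim(length_m) else float(length_m) * 1000.0


def microns_to_metres(length_um: ArrayLike) -> ArrayLike:
    """Convert micrometres (pachymetry convention) to metres."""
    return np.asarray(length_um, dtype=float) / 1e6 if np.ndim(length_um) else float(length_um) / 1e6


def microns_to_millimetres(length_um: ArrayLike) -> ArrayLike:
    """Convert micrometres to millimetres."""
    return np.asarray(length_um, dtype=float) / 1000.0 if np.ndim(length_um) else float(length_um) / 1000.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SchematicEyeModel:
    """Corneal constants of a theoretical eye model.

    Parameters
    ----------
    name : str
        Registry key, e.g. ``"gullstrand"``.
    n_a : float
        Refractive index of air; must be exactly 1.0.
    n_c : float
        Corneal refractive index.
    n_ha : float
        Aqueous-humor refractive index.
    e_c_model : float
        Central corneal thickness used for theoretical simulations, metres.
    n_k_classic : float
        The classical single-value keratometric index associated with the
        model (1.3315 for Gullstrand, 1.3304 for Le Grand).
    """

    name: str
    n_a: float
    n_c: float
    n_ha: float
    e_c_model: float
    n_k_classic: float

    def __post_init__(self) -> None:
        if self.n_a != 1.0:
            raise ValueError(f"n_a must be exactly 1.0, got {self.n_a}")
        if not (1.0 < self.n_ha < self.n_c < 1.5):
            raise ValueError(
                f"require 1 < n_ha < n_c < 1.5, got n_ha={self.n_ha}, n_c={self.n_c}"
            )
        if not (0.0 < self.e_c_model < 0.001):
            raise ValueError(
                f"model thickness must lie in (0, 0.001) m, got {self.e_c_model}"
            )
        if not (1.0 < self.n_k_classic < 1.5):
            raise ValueError(f"implausible classical keratometric index {self.n_k_classic}")


@dataclass(frozen=True)
class CornealGeometry:
    """One cornea's paraxial geometry.

    Radii are in millimetres; ``e_c`` is the central thickness in
    millimetres and may be omitted, in which case computations fall back to
    the eye model's theoretical thickness.
    """

    r1c: float
    r2c: float
    e_c: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.r1c > 0 and self.r2c > 0):
            raise DomainError(
                f"corneal radii must be positive, got r1c={self.r1c}, r2c={self.r2c}"
            )
        if self.e_c is not None and self.e_c < 0:
            raise DomainError(f"central thickness must be non-negative, got {self.e_c}")
        if not np.isfinite(self.r1c / self.r2c):
            raise DomainError("k ratio must be finite")

    @property
    def k(self) -> float:
        """Anterior-to-posterior radius ratio r1c/r2c."""
        return self.r1c / self.r2c

    def thickness_metres(self, model: SchematicEyeModel) -> float:
        """Resolved central thickness in metres (own value, else model's)."""
        if self.e_c is None:
            return model.e_c_model
        return to_metres(self.e_c)


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


def _load_registry_file(path: Path) -> dict[str, SchematicEyeModel]:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    models = {}
    for name, entry in raw.items():
        models[name] = SchematicEyeModel(
            name=name,
            n_a=float(entry["n_a"]),
            n_c=float(entry["n_c"]),
            n_ha=float(entry["n_ha"]),
            e_c_model=float(entry["e_c_model_mm"]) / 1000.0,
            n_k_classic=float(entry["n_k_classic"]),
        )
    return models


_REGISTRY: dict[str, SchematicEyeModel] = _load_registry_file(_DATA_FILE)
_BUILTINS = frozenset(_REGISTRY)


def get_model(name: str) -> SchematicEyeModel:
    """Return the frozen constant set registered under ``name``.

    Raises
    ------
    UnknownModelError
        If no model of that name is registered.
    """
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise UnknownModelError(
            f"unknown schematic eye model {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_model(model: SchematicEyeModel, overwrite: bool = False) -> None:
    """Register an additional schematic eye model at run time.

    The built-in models cannot be replaced.
    """
    key = model.name.lower()
    if key in _BUILTINS:
        raise ValueError(f"built-in model {key!r} is immutable")
    if key in _REGISTRY and not overwrite:
        raise ValueError(f"model {key!r} already registered (pass overwrite=True)")
    _REGISTRY[key] = model


def register_models_from_file(path: Union[str, Path]) -> list[str]:
    """Load extra models from a YAML file shaped like the built-in registry."""
    loaded = _load_registry_file(Path(path))
    for model in loaded.values():
        register_model(model, overwrite=True)
    return sorted(loaded)


def available_models() -> list[str]:
    """Names of all registered schematic eye models."""
    return sorted(_REGISTRY)
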