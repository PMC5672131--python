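"""Adjusted keratometric index: banded linear calibrations and evaluation.

A single corneal geometry has a well-defined exact keratometric index, but a
clinician measuring only the anterior radius ``r1c`` does not know the
posterior radius.  The *adjusted* index ``nk_adj(r1c)`` is defined, for each
``r1c``, as the index for which the keratometric error at the two posterior-
radius extremes of the admissible domain is equal in magnitude and opposite
in sign:

    dPc(r2c_lo) = -dPc(r2c_hi)
    <=>  Pk(nk_adj) = [PcGauss(r1c, r2c_lo) + PcGauss(r1c, r2c_hi)] / 2
    <=>  nk_adj = 1 + r1c * (PcGauss_lo + PcGauss_hi) / 2      (r1c in metres)

Because the Gaussian power is affine in 1/r2c at fixed r1c, ``nk_adj`` is
*exactly* linear in ``r1c`` over any band with fixed posterior extremes;
the calibration therefore reduces to three linear equations per eye model,
one for each anterior-radius band of the post-crosslinking keratoconus
domain.  Closed form of the line (thickness ``e_c`` and radii in mm):

    slope     = (P2c(r2c_lo) + P2c(r2c_hi)) / 2 / 1000     [index per mm]
    intercept = n_c - slope * 1000 * e_c * (n_c - 1) / n_c

The three bands and their fixed posterior extremes are (in mm):
r1c in [5.6, 6.8] with r2c extremes (4.4, 5.4); [6.9, 7.2] with (4.8, 6.0);
[7.3, 8.5] with (5.4, 7.0).  Evaluating the band's line and applying
``Pk_adj = (nk_adj - 1)/r1c`` gives the adjusted keratometric power, whose
deviation from the Gaussian reference stays within about +/-0.8 D across
each band whenever the true posterior radius lies between the band extremes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .paraxial import gaussian_power_value, keratometric_power, posterior_power
from .schematic_eye import DomainError, SchematicEyeModel

__all__ = [
    "CalibrationBand",
    "AdjustedIndexResult",
    "BAND_GEOMETRY_MM",
    "default_bands",
    "band_grid",
    "assign_band",
    "nk_adj_from_extremes",
    "band_coefficients_closed_form",
    "fit_band_algorithm",
    "nk_adj_piecewise",
    "pk_adj",
    "bands_to_csv",
    "bands_from_csv",
]

ArrayLike = Union[float, np.ndarray]

#: (r1c_min, r1c_max, r2c_lo, r2c_hi) in millimetres for the three
#: anterior-radius bands of the post-crosslinking keratoconus domain.
#: The posterior extremes are the values that reproduce the published
#: per-band k-ratio intervals via k_min = r1c_min/r2c_hi, k_max = r1c_max/r2c_lo.
BAND_GEOMETRY_MM: tuple[tuple[float, float, float, float], ...] = (
    (5.6, 6.8, 4.4, 5.4),
    (6.9, 7.2, 4.8, 6.0),
    (7.3, 8.5, 5.4, 7.0),
)

#: Midpoint boundaries for assigning a continuous r1c to a band: the
#: published bands are defined on a 0.1 mm grid, so the half-open midpoint
#: rule is the least surprising continuous extension.
_BAND_BOUNDARIES_MM = (6.85, 7.25)

#: Supported r1c domain in millimetres.
R1C_DOMAIN_MM = (5.6, 8.5)

DEFAULT_GRID_STEP_MM = 0.1

# Printed-table rounding of fitted coefficients.
SLOPE_DECIMALS = 5
INTERCEPT_DECIMALS = 4


@dataclass(frozen=True)
class CalibrationBand:
    """One anterior-radius band with its fitted linear nk_adj calibration.

    ``slope`` is in index units per millimetre of r1c; ``intercept`` is the
    (extrapolated) index at r1c = 0.  ``k_min``/``k_max`` are the implied
    k-ratio interval bounds, rounded to 2 decimals as published.
    """

    model: str
    band_id: int
    r1c_min: float
    r1c_max: float
    r2c_lo: float
    r2c_hi: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not self.r1c_min < self.r1c_max:
            raise ValueError("band requires r1c_min < r1c_max")
        if not self.r2c_lo < self.r2c_hi:
            raise ValueError("band requires r2c_lo < r2c_hi")
        if not self.slope < 0:
            raise ValueError("nk_adj must decrease with flatter anterior cornea")

    @property
    def k_min(self) -> float:
        return round(self.r1c_min / self.r2c_hi, 2)

    @property
    def k_max(self) -> float:
        return round(self.r1c_max / self.r2c_lo, 2)

    def evaluate(self, r1c_mm: ArrayLike, printed: bool = False) -> ArrayLike:
        """nk_adj at ``r1c`` from this band's line.

        With ``printed=True`` the coefficients are first rounded to the
        5/4-decimal precision of the published tables (can differ from the
        exact evaluation by one unit in the fourth index decimal).
        """
        slope, intercept = self.slope, self.intercept
        if printed:
            slope = round(slope, SLOPE_DECIMALS)
            intercept = round(intercept, INTERCEPT_DECIMALS)
        return slope * np.asarray(r1c_mm, dtype=float) + intercept

    def algorithm_text(self) -> str:
        """Human-readable line, coefficients at printed precision."""
        return (
            f"{round(self.slope, SLOPE_DECIMALS):+.5f}*r1c "
            f"+ {round(self.intercept, INTERCEPT_DECIMALS):.4f}"
        )


@dataclass(frozen=True)
class AdjustedIndexResult:
    """Adjusted index and power for one anterior radius."""

    nk_adj: float
    band_id: int
    pk_adj: float
    extrapolated: bool = False


# ---------------------------------------------------------------------------
# Core definition
# ---------------------------------------------------------------------------


def nk_adj_from_extremes(
    r1c_mm: ArrayLike,
    r2c_lo_mm: float,
    r2c_hi_mm: float,
    model: SchematicEyeModel,
) -> ArrayLike:
    """Adjusted index from the equal-magnitude-error condition.

    Returns the index for which the keratometric error at ``r2c_lo`` equals
    minus the error at ``r2c_hi``, i.e. the keratometric power matches the
    midpoint of the two extreme Gaussian powers.  Degenerate extremes
    (``r2c_lo == r2c_hi``) reduce to the exact index of that geometry.
    """
    if r2c_lo_mm > r2c_hi_mm:
        raise DomainError(
            f"posterior extremes must satisfy r2c_lo <= r2c_hi, got "
            f"({r2c_lo_mm}, {r2c_hi_mm})"
        )
    pcg_lo = np.asarray(gaussian_power_value(r1c_mm, r2c_lo_mm, model))
    pcg_hi = np.asarray(gaussian_power_value(r1c_mm, r2c_hi_mm, model))
    r1_m = np.asarray(r1c_mm, dtype=float) / 1000.0
    out = np.asarray(1.0 + r1_m * (pcg_lo + pcg_hi) / 2.0)
    return float(out) if out.ndim == 0 else out


def band_coefficients_closed_form(
    r2c_lo_mm: float, r2c_hi_mm: float, model: SchematicEyeModel
) -> tuple[float, float]:
    """Exact (slope, intercept) of nk_adj as a line in r1c (mm).

    Follows from substituting the thick-lens power into the midpoint rule:
    the slope is the mean posterior-surface power per mm, and the intercept
    absorbs the anterior surface and thickness terms.
    """
    p2_mean = (
        float(posterior_power(r2c_lo_mm, model))
        + float(posterior_power(r2c_hi_mm, model))
    ) / 2.0
    slope = p2_mean / 1000.0
    intercept = model.n_c - p2_mean * model.e_c_model * (model.n_c - model.n_a) / model.n_c
    return slope, intercept


def band_grid(
    r1c_min: float, r1c_max: float, step: float = DEFAULT_GRID_STEP_MM
) -> np.ndarray:
    """Inclusive r1c grid over a band, rounded to the step's decimals."""
    n = int(round((r1c_max - r1c_min) / step))
    return np.round(r1c_min + step * np.arange(n + 1), 10)


def fit_band_algorithm(
    band: CalibrationBand,
    model: SchematicEyeModel,
    grid_step: float = DEFAULT_GRID_STEP_MM,
) -> tuple[float, float, float]:
    """Ordinary least squares of nk_adj on r1c over the band grid.

    Returns ``(slope, intercept, r_squared)``.  Because nk_adj is exactly
    linear in r1c, the fit is grid-independent and R^2 equals 1 to machine
    precision; the OLS route is kept as the published procedure and as a
    cross-check of the closed form.
    """
    grid = band_grid(band.r1c_min, band.r1c_max, grid_step)
    if grid.size < 2:
        raise ValueError(
            f"band [{band.r1c_min}, {band.r1c_max}] with step {grid_step} "
            f"yields fewer than 2 grid points"
        )
    y = np.asarray(nk_adj_from_extremes(grid, band.r2c_lo, band.r2c_hi, model))
    slope, intercept = np.polyfit(grid, y, 1)
    fitted = slope * grid + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r_squared


def default_bands(model: SchematicEyeModel) -> list[CalibrationBand]:
    """The three calibration bands for a model, with exact coefficients."""
    bands = []
    for i, (r1_min, r1_max, r2_lo, r2_hi) in enumerate(BAND_GEOMETRY_MM, start=1):
        slope, intercept = band_coefficients_closed_form(r2_lo, r2_hi, model)
        bands.append(
            CalibrationBand(
                model=model.name,
                band_id=i,
                r1c_min=r1_min,
                r1c_max=r1_max,
                r2c_lo=r2_lo,
                r2c_hi=r2_hi,
                slope=slope,
                intercept=intercept,
            )
        )
    return bands


def assign_band(r1c_mm: float, extrapolate: bool = False) -> tuple[int, bool]:
    """Band id (1-based) for an anterior radius; midpoint rule at the seams.

    Outside the supported [5.6, 8.5] mm domain a :class:`DomainError` is
    raised unless ``extrapolate`` is set, in which case the nearest band is
    used and the result flagged.
    """
    lo, hi = R1C_DOMAIN_MM
    extrapolated = False
    if not (lo <= r1c_mm <= hi):
        if not extrapolate:
            raise DomainError(
                f"r1c = {r1c_mm} mm outside supported domain [{lo}, {hi}] mm "
                f"(pass extrapolate=True to use the nearest band)"
            )
        extrapolated = True
    if r1c_mm < _BAND_BOUNDARIES_MM[0]:
        return 1, extrapolated
    if r1c_mm < _BAND_BOUNDARIES_MM[1]:
        return 2, extrapolated
    return 3, extrapolated


def nk_adj_piecewise(
    r1c_mm: float,
    model: SchematicEyeModel,
    extrapolate: bool = False,
    printed_coefficients: bool = False,
    bands: Optional[Sequence[CalibrationBand]] = None,
) -> AdjustedIndexResult:
    """Adjusted index and power for one anterior radius.

    Selects the band containing ``r1c``, evaluates its line (exact
    coefficients by default) and converts to power via
    ``Pk_adj = (nk_adj - 1)/r1c``.
    """
    if bands is None:
        bands = default_bands(model)
    band_id, extrapolated = assign_band(r1c_mm, extrapolate=extrapolate)
    band = bands[band_id - 1]
    nk = float(band.evaluate(r1c_mm, printed=printed_coefficients))
    power = float(keratometric_power(r1c_mm, nk))
    return AdjustedIndexResult(
        nk_adj=nk, band_id=band_id, pk_adj=power, extrapolated=extrapolated
    )


def pk_adj(r1c_mm: ArrayLike, model: SchematicEyeModel) -> ArrayLike:
    """Vectorised adjusted keratometric power over the supported domain."""
    r1 = np.atleast_1d(np.asarray(r1c_mm, dtype=float))
    out = np.empty_like(r1)
    for i, r in enumerate(r1):
        out[i] = nk_adj_piecewise(float(r), model).pk_adj
    return float(out[0]) if np.ndim(r1c_mm) == 0 else out


# ---------------------------------------------------------------------------
# Interchange
# ---------------------------------------------------------------------------

_CSV_COLUMNS = [
    "model",
    "r1c_min",
    "r1c_max",
    "r2c_lo",
    "r2c_hi",
    "k_min",
    "k_max",
    "slope",
    "intercept",
]


def bands_to_csv(bands: Sequence[CalibrationBand], path: Union[str, Path]) -> None:
    """Write band definitions (published-coefficient layout) to CSV."""
    frame = pd.DataFrame(
        [
            {
                "model": b.model,
                "r1c_min": b.r1c_min,
                "r1c_max": b.r1c_max,
                "r2c_lo": b.r2c_lo,
                "r2c_hi": b.r2c_hi,
                "k_min": b.k_min,
                "k_max": b.k_max,
                "slope": b.slope,
                "intercept": b.intercept,
            }
            for b in bands
        ],
        columns=_CSV_COLUMNS,
    )
    frame.to_csv(path, index=False)


def bands_from_csv(path: Union[str, Path]) -> list[CalibrationBand]:
    """Load band definitions previously written by :func:`bands_to_csv`.

    Coefficients are taken verbatim from the file, so published (rounded)
    values can be used in place of refitted ones.
    """
    frame = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - {"k_min", "k_max"} - set(frame.columns)
    if missing:
        raise ValueError(f"band CSV missing columns: {sorted(missing)}")
    bands = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        bands.append(
            CalibrationBand(
                model=str(row.model),
                band_id=i,
                r1c_min=float(row.r1c_min),
                r1c_max=float(row.r1c_max),
                r2c_lo=float(row.r2c_lo),
                r2c_hi=float(row.r2c_hi),
                slope=float(row.slope),
                intercept=float(row.intercept),
            )
        )
    return bands
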