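"""Theoretical simulation study over the post-crosslinking curvature domain.

The study sweeps the curvature domain reported for keratoconus eyes after
collagen crosslinking — anterior radius 5.6–8.5 mm, posterior radius
4.4–7.0 mm, restricted to k-ratio 1.04–1.57 — on a 0.1 mm grid, and

* tabulates the extreme keratometric errors produced by the classical
  single-value indices (1.3375 and each model's own classical index), and
* rebuilds, per eye model, the three-band calibration table: fitted linear
  nk_adj algorithm, nk_adj / nk_exact ranges, Gaussian and adjusted power
  ranges, and the residual error range of the adjusted approach.

Two domain conventions coexist, as in the published study: the classical-
index error extremes scan the banded domain (each anterior-radius band with
the full posterior-radius interval between its extremes), while per-band
table ranges evaluate the band's r1c grid against its two fixed posterior
extremes only.  A plain k-filtered rectangle is also available via
:class:`SweepDomain`; note it admits pairs such as (6.9, 4.4) mm that the
banded domain excludes, and so yields larger extreme errors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .adjusted import (
    BAND_GEOMETRY_MM,
    CalibrationBand,
    band_grid,
    default_bands,
    fit_band_algorithm,
    nk_adj_from_extremes,
)
from .paraxial import gaussian_power_value, keratometric_power, nk_exact_value
from .schematic_eye import DIOPTRE_DECIMALS, INDEX_DECIMALS, SchematicEyeModel

__all__ = [
    "SweepDomain",
    "DeltaPcExtreme",
    "SimulationRow",
    "SimulationTable",
    "EmptyDomainError",
    "enumerate_domain",
    "banded_domain_pairs",
    "delta_pc_extremes",
    "build_table",
]

#: Tie-detection tolerance for extreme argument pairs, dioptres (half the
#: printed 0.1 D resolution).
TIE_TOLERANCE_D = 0.05


class EmptyDomainError(ValueError):
    """The requested sweep domain contains no admissible radius pairs."""


@dataclass(frozen=True)
class SweepDomain:
    """Rectangular (r1c, r2c) grid filtered by an admissible k-ratio range.

    Defaults are the post-crosslinking keratoconus domain: r1c 5.6–8.5 mm,
    r2c 4.4–7.0 mm, k 1.04–1.57, 0.1 mm resolution.  The k filter is applied
    after rounding k to 2 decimals, matching the published convention (so
    e.g. the pair (8.5, 5.4) with k = 1.574 is admitted as k = 1.57).
    """

    r1c_range: tuple[float, float] = (5.6, 8.5)
    r2c_range: tuple[float, float] = (4.4, 7.0)
    k_range: tuple[float, float] = (1.04, 1.57)
    step: float = 0.1

    def __post_init__(self) -> None:
        for name in ("r1c_range", "r2c_range", "k_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} must be an ordered interval, got ({lo}, {hi})")
        if not self.step > 0:
            raise ValueError("step must be positive")


def enumerate_domain(domain: SweepDomain = SweepDomain()) -> np.ndarray:
    """All admissible (r1c, r2c) pairs, r1c-major ascending; shape (n, 2)."""
    r1s = band_grid(*domain.r1c_range, domain.step)
    r2s = band_grid(*domain.r2c_range, domain.step)
    r1g, r2g = np.meshgrid(r1s, r2s, indexing="ij")
    k = np.round(r1g / r2g, 2)
    mask = (k >= domain.k_range[0]) & (k <= domain.k_range[1])
    pairs = np.column_stack([r1g[mask], r2g[mask]])
    if pairs.size == 0:
        raise EmptyDomainError(f"no admissible (r1c, r2c) pairs in {domain}")
    return pairs


def banded_domain_pairs(step: float = 0.1) -> np.ndarray:
    """All (r1c, r2c) pairs of the banded domain, r1c-major; shape (n, 2).

    Each anterior-radius band is crossed with the full posterior-radius
    grid between its two extremes.  This is the domain over which the
    published classical-index error extremes arise.
    """
    blocks = []
    for r1_min, r1_max, r2_lo, r2_hi in BAND_GEOMETRY_MM:
        r1s = band_grid(r1_min, r1_max, step)
        r2s = band_grid(r2_lo, r2_hi, step)
        r1g, r2g = np.meshgrid(r1s, r2s, indexing="ij")
        blocks.append(np.column_stack([r1g.ravel(), r2g.ravel()]))
    return np.concatenate(blocks)


@dataclass(frozen=True)
class DeltaPcExtreme:
    """An extreme keratometric error and every grid pair attaining it.

    ``pairs`` holds all (r1c, r2c) combinations within ``TIE_TOLERANCE_D``
    of the extreme — published extremes are themselves reported with ties.
    """

    value: float
    pairs: tuple[tuple[float, float], ...]


def delta_pc_extremes(
    nk: float,
    model: SchematicEyeModel,
    domain: Optional[SweepDomain] = None,
    tie_tolerance: float = TIE_TOLERANCE_D,
) -> tuple[DeltaPcExtreme, DeltaPcExtreme]:
    """(min, max) keratometric error of a fixed index over the swept domain.

    Exhaustive scan with the model's theoretical thickness; returns each
    extreme with its full set of tied argument pairs.  By default the
    banded domain is scanned (the convention behind the published extreme
    values); pass an explicit :class:`SweepDomain` for a k-filtered
    rectangle instead.
    """
    pairs = banded_domain_pairs() if domain is None else enumerate_domain(domain)
    dpc = np.asarray(
        keratometric_power(pairs[:, 0], nk)
    ) - np.asarray(gaussian_power_value(pairs[:, 0], pairs[:, 1], model))

    def _extreme(idx_value: float) -> DeltaPcExtreme:
        tied = pairs[np.abs(dpc - idx_value) <= tie_tolerance]
        return DeltaPcExtreme(
            value=float(idx_value),
            pairs=tuple((float(a), float(b)) for a, b in tied),
        )

    return _extreme(float(dpc.min())), _extreme(float(dpc.max()))


# ---------------------------------------------------------------------------
# Calibration table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationRow:
    """One calibration-table row (ranges stored ordered, unrounded)."""

    band: CalibrationBand
    slope: float
    intercept: float
    r_squared: float
    nk_adj_range: tuple[float, float]
    nk_exact_range: tuple[float, float]
    pc_gauss_range: tuple[float, float]
    pk_adj_range: tuple[float, float]
    delta_pc_range: tuple[float, float]


@dataclass(frozen=True)
class SimulationTable:
    """Three-band calibration table for one eye model."""

    model: str
    rows: tuple[SimulationRow, ...]

    def global_range(self, attribute: str) -> tuple[float, float]:
        """Global (min, max) of a per-row range attribute across bands."""
        los, his = zip(*(getattr(r, attribute) for r in self.rows))
        return min(los), max(his)

    def to_dataframe(self, rounded: bool = True) -> pd.DataFrame:
        """Tabular rendering; ``rounded`` applies the display convention
        (powers to 1 decimal, indices to 4, coefficients to 5/4)."""

        def _idx(v: float) -> float:
            return round(v, INDEX_DECIMALS) if rounded else v

        def _pw(v: float) -> float:
            return round(v, DIOPTRE_DECIMALS) if rounded else v

        records = []
        for row in self.rows:
            b = row.band
            records.append(
                {
                    "model": self.model,
                    "r1c_min": b.r1c_min,
                    "r1c_max": b.r1c_max,
                    "k_min": b.k_min,
                    "k_max": b.k_max,
                    "algorithm": b.algorithm_text() if rounded else
                        f"{row.slope:+.12g}*r1c + {row.intercept:.12g}",
                    "nk_adj_min": _idx(row.nk_adj_range[0]),
                    "nk_adj_max": _idx(row.nk_adj_range[1]),
                    "nk_exact_min": _idx(row.nk_exact_range[0]),
                    "nk_exact_max": _idx(row.nk_exact_range[1]),
                    "pc_gauss_min": _pw(row.pc_gauss_range[0]),
                    "pc_gauss_max": _pw(row.pc_gauss_range[1]),
                    "pk_adj_min": _pw(row.pk_adj_range[0]),
                    "pk_adj_max": _pw(row.pk_adj_range[1]),
                    "delta_pc_min": _pw(row.delta_pc_range[0]),
                    "delta_pc_max": _pw(row.delta_pc_range[1]),
                }
            )
        return pd.DataFrame.from_records(records)

    def to_csv(self, path: Optional[Union[str, Path]] = None) -> str:
        """CSV rendering (byte-stable for a fixed model and step)."""
        frame = self.to_dataframe(rounded=True)
        text = frame.to_csv(index=False, lineterminator="\n")
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def to_markdown(self, path: Optional[Union[str, Path]] = None) -> str:
        """GitHub-style Markdown rendering of the rounded table."""
        frame = self.to_dataframe(rounded=True)
        cols = {
            "r1c (mm)": [f"[{r.r1c_min}, {r.r1c_max}]" for r in frame.itertuples()],
            "[k_min, k_max]": [f"[{r.k_min:.2f}, {r.k_max:.2f}]" for r in frame.itertuples()],
            "nk_adj algorithm": list(frame["algorithm"]),
            "nk_adj": [f"[{r.nk_adj_min:.4f}, {r.nk_adj_max:.4f}]" for r in frame.itertuples()],
            "nk_exact": [f"[{r.nk_exact_min:.4f}, {r.nk_exact_max:.4f}]" for r in frame.itertuples()],
            "PcGauss (D)": [f"[{r.pc_gauss_min:.1f}, {r.pc_gauss_max:.1f}]" for r in frame.itertuples()],
            "Pk_adj (D)": [f"[{r.pk_adj_min:.1f}, {r.pk_adj_max:.1f}]" for r in frame.itertuples()],
            "dPc (D)": [f"[{r.delta_pc_min:.1f}, {r.delta_pc_max:.1f}]" for r in frame.itertuples()],
        }
        buf = io.StringIO()
        headers = list(cols)
        buf.write("| " + " | ".join(headers) + " |\n")
        buf.write("|" + "|".join(["---"] * len(headers)) + "|\n")
        for i in range(len(frame)):
            buf.write("| " + " | ".join(str(cols[h][i]) for h in headers) + " |\n")
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def build_table(
    model: SchematicEyeModel, step: float = 0.1
) -> SimulationTable:
    """Build the three-row calibration table for an eye model.

    Each row evaluates its band's r1c grid against the band's two fixed
    posterior extremes: nk_exact and Gaussian-power ranges come from the
    grid x {r2c_lo, r2c_hi} corner scheme, nk_adj and Pk_adj from the
    fitted line, and the residual-error range from Pk_adj minus the
    Gaussian power at both extremes.
    """
    rows = []
    for band in default_bands(model):
        slope, intercept, r_squared = fit_band_algorithm(band, model, step)
        grid = band_grid(band.r1c_min, band.r1c_max, step)
        nk_adj = np.asarray(nk_adj_from_extremes(grid, band.r2c_lo, band.r2c_hi, model))
        pk_adj_vals = (nk_adj - 1.0) / (grid / 1000.0)
        nk_ex, pcg, dpc = [], [], []
        for r2 in (band.r2c_lo, band.r2c_hi):
            nk_ex.append(np.asarray(nk_exact_value(grid, r2, model)))
            pcg_r2 = np.asarray(gaussian_power_value(grid, r2, model))
            pcg.append(pcg_r2)
            dpc.append(pk_adj_vals - pcg_r2)
        nk_ex, pcg, dpc = map(np.concatenate, (nk_ex, pcg, dpc))
        rows.append(
            SimulationRow(
                band=band,
                slope=slope,
                intercept=intercept,
                r_squared=r_squared,
                nk_adj_range=(float(nk_adj.min()), float(nk_adj.max())),
                nk_exact_range=(float(nk_ex.min()), float(nk_ex.max())),
                pc_gauss_range=(float(pcg.min()), float(pcg.max())),
                pk_adj_range=(float(pk_adj_vals.min()), float(pk_adj_vals.max())),
                delta_pc_range=(float(dpc.min()), float(dpc.max())),
            )
        )
    return SimulationTable(model=model.name, rows=tuple(rows))
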