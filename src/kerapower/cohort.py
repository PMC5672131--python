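"""Clinical-cohort pipeline: synthetic generation, per-eye powers, agreement.

The clinical validation compares, within each eye, three estimates of
central corneal power — the classical keratometric power Pk(1.3375), the
adjusted keratometric power Pk_adj, and the Gaussian reference PcGauss —
using Bland-Altman limits of agreement, Pearson correlation and paired
tests.

The original 21-eye post-crosslinking keratoconus dataset was never
published per eye, so a synthetic generator stands in for it: independent
truncated-normal draws per field matching the published cohort summary
(r1c 7.1 +/- 0.60 mm in [5.6, 7.8]; r2c 5.6 +/- 0.70 mm in [4.4, 6.6];
central pachymetry 488 +/- 64.6 um in [418, 639]; k ratio constrained to
[1.1404, 1.4719] by rejection).  No r1c–r2c correlation beyond the k
constraint is modelled, because no covariance was ever published; the
methods note discusses what this limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .adjusted import R1C_DOMAIN_MM, nk_adj_piecewise
from .paraxial import gaussian_power_value, keratometric_power, nk_exact_value
from .schematic_eye import SchematicEyeModel, microns_to_millimetres

__all__ = [
    "CohortRecord",
    "FieldProfile",
    "CohortProfile",
    "TABLE_PROFILE",
    "AgreementSummary",
    "PairedTestResult",
    "CohortAnalysis",
    "CohortGenerationError",
    "generate_synthetic_cohort",
    "cohort_to_csv",
    "cohort_from_csv",
    "cohort_to_dataframe",
    "bland_altman",
    "paired_tests",
    "analyze_cohort",
    "results_to_csv",
    "CLASSICAL_NK",
]

#: The classical topographer keratometric index.
CLASSICAL_NK = 1.3375

_CSV_HEADER = [
    "eye_id",
    "r1c_mm",
    "r2c_mm",
    "ec_central_um",
    "ec_min_um",
    "q_anterior",
    "q_posterior",
]


class CohortGenerationError(RuntimeError):
    """Synthetic-cohort rejection sampling failed to converge."""


@dataclass(frozen=True)
class CohortRecord:
    """One eye's measurements.

    Radii in millimetres, pachymetry in micrometres.  Asphericities are
    carried descriptively (they do not enter paraxial power) for the
    correlation analysis.
    """

    eye_id: str
    r1c: float
    r2c: float
    ec_central: float
    ec_min: Optional[float] = None
    q_anterior: Optional[float] = None
    q_posterior: Optional[float] = None

    def __post_init__(self) -> None:
        if self.r1c <= 0 or self.r2c <= 0 or self.ec_central < 0:
            raise ValueError(f"non-physical measurements for eye {self.eye_id!r}")
        if not (1.0 < self.k < 2.0):
            warnings.warn(
                f"eye {self.eye_id!r}: k ratio {self.k:.3f} outside the "
                f"plausible clinical range (1, 2)",
                stacklevel=2,
            )

    @property
    def k(self) -> float:
        return self.r1c / self.r2c


@dataclass(frozen=True)
class FieldProfile:
    """Truncated-normal specification of one measurement field."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.sd > 0 and self.lower < self.upper):
            raise ValueError(f"infeasible field profile {self}")


@dataclass(frozen=True)
class CohortProfile:
    """Distributional profile of a synthetic cohort (one eye = one draw)."""

    r1c: FieldProfile
    r2c: FieldProfile
    ec_central: FieldProfile
    ec_min: FieldProfile
    q_anterior: FieldProfile
    q_posterior: FieldProfile
    k_range: tuple[float, float] = (1.1404, 1.4719)


#: Default profile matching the published post-crosslinking cohort summary.
TABLE_PROFILE = CohortProfile(
    r1c=FieldProfile(7.1, 0.60, 5.6, 7.8),
    r2c=FieldProfile(5.6, 0.70, 4.4, 6.6),
    ec_central=FieldProfile(488.0, 64.6, 418.0, 639.0),
    ec_min=FieldProfile(452.0, 47.2, 384.0, 546.0),
    q_anterior=FieldProfile(-0.7, 0.53, -1.6, 0.3),
    q_posterior=FieldProfile(-0.8, 0.73, -2.0, 0.7),
)


def _draw(rng: np.random.Generator, spec: FieldProfile, size: int) -> np.ndarray:
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    return stats.truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=size, random_state=rng)


def generate_synthetic_cohort(
    n: int,
    seed: int,
    profile: CohortProfile = TABLE_PROFILE,
    max_attempts_per_record: int = 10_000,
) -> list[CohortRecord]:
    """Draw ``n`` synthetic eyes from a cohort profile, reproducibly.

    Each field is an independent truncated-normal draw; records whose
    k = r1c/r2c falls outside ``profile.k_range`` are resampled.  The same
    seed always yields the same cohort.

    Raises
    ------
    CohortGenerationError
        If the k constraint cannot be satisfied within
        ``max_attempts_per_record`` resamples per eye (infeasible profile).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    k_lo, k_hi = profile.k_range
    for i in range(n):
        for _ in range(max_attempts_per_record):
            r1c = float(_draw(rng, profile.r1c, 1)[0])
            r2c = float(_draw(rng, profile.r2c, 1)[0])
            if k_lo <= r1c / r2c <= k_hi:
                break
        else:
            raise CohortGenerationError(
                f"could not satisfy k in [{k_lo}, {k_hi}] after "
                f"{max_attempts_per_record} resamples; profile infeasible?"
            )
        records.append(
            CohortRecord(
                eye_id=f"eye{i + 1:03d}",
                r1c=round(r1c, 4),
                r2c=round(r2c, 4),
                ec_central=round(float(_draw(rng, profile.ec_central, 1)[0]), 1),
                ec_min=round(float(_draw(rng, profile.ec_min, 1)[0]), 1),
                q_anterior=round(float(_draw(rng, profile.q_anterior, 1)[0]), 3),
                q_posterior=round(float(_draw(rng, profile.q_posterior, 1)[0]), 3),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------


def cohort_to_dataframe(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "eye_id": r.eye_id,
                "r1c_mm": r.r1c,
                "r2c_mm": r.r2c,
                "ec_central_um": r.ec_central,
                "ec_min_um": r.ec_min,
                "q_anterior": r.q_anterior,
                "q_posterior": r.q_posterior,
            }
            for r in cohort
        ],
        columns=_CSV_HEADER,
    )


def cohort_to_csv(cohort: Sequence[CohortRecord], path: Union[str, Path]) -> None:
    """Write a cohort to the canonical CSV layout (UTF-8, decimal point)."""
    cohort_to_dataframe(cohort).to_csv(path, index=False, lineterminator="\n")


def cohort_from_csv(path: Union[str, Path]) -> list[CohortRecord]:
    """Read a cohort CSV, reporting the 1-based line number of any bad row."""
    frame = pd.read_csv(path)
    missing = set(_CSV_HEADER[:4]) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            def _opt(value: object) -> Optional[float]:
                return None if value is None or pd.isna(value) else float(value)

            records.append(
                CohortRecord(
                    eye_id=str(row.eye_id),
                    r1c=float(row.r1c_mm),
                    r2c=float(row.r2c_mm),
                    ec_central=float(row.ec_central_um),
                    ec_min=_opt(getattr(row, "ec_min_um", None)),
                    q_anterior=_opt(getattr(row, "q_anterior", None)),
                    q_posterior=_opt(getattr(row, "q_posterior", None)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed cohort row at line {line}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman agreement of two paired dioptre series.

    ``loa_low``/``loa_high`` are mean +/- 1.96 SD of the differences (the
    interval expected to contain 95% of between-method differences).
    ``pearson_r`` is NaN when either series is constant, and ``p_paired``
    (two-sided Wilcoxon signed-rank) is NaN when all differences vanish;
    both cases set ``degenerate``.
    """

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pearson_r: float
    p_paired: float
    n: int
    degenerate: bool = False


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementSummary:
    """Bland-Altman summary of the differences x - y.

    SD uses the n-1 denominator; limits of agreement are mean +/- 1.96 SD.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape or x_arr.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x_arr.size < 2:
        raise ValueError("Bland-Altman requires at least 2 paired observations")
    diff = x_arr - y_arr
    mean = float(diff.mean())
    sd = float(diff.std(ddof=1))
    degenerate = False
    if np.ptp(x_arr) == 0 or np.ptp(y_arr) == 0:
        r = float("nan")
        degenerate = True
    else:
        r = float(stats.pearsonr(x_arr, y_arr).statistic)
    if np.all(diff == 0):
        p = float("nan")
        degenerate = True
    else:
        p = float(stats.wilcoxon(diff, method="auto").pvalue)
    return AgreementSummary(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        pearson_r=r,
        p_paired=p,
        n=int(x_arr.size),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired comparison of two dioptre series.

    ``normality_p`` is the Kolmogorov-Smirnov p-value of the standardised
    differences against the normal distribution (reported as metadata, not
    used to switch tests).  ``degenerate`` flags all-zero differences, for
    which both p-values are NaN.
    """

    wilcoxon_p: float
    t_p: float
    normality_p: float
    degenerate: bool


def paired_tests(
    x: Sequence[float], y: Sequence[float], paired: bool = True
) -> PairedTestResult:
    """Wilcoxon signed-rank and Student t comparison of two series.

    The Wilcoxon test uses the exact null distribution up to n = 25 and the
    normal approximation above.  ``paired=True`` (the default, appropriate
    for within-eye comparisons) runs the paired t-test; ``paired=False``
    runs the unpaired form.
    """
    x_arr = np.asarray(x, dtype=float)
    y_arr = np.asarray(y, dtype=float)
    if x_arr.shape != y_arr.shape:
        raise ValueError("x and y must have equal length")
    if x_arr.size < 5:
        raise ValueError("need at least 5 pairs for a meaningful comparison")
    diff = x_arr - y_arr
    if np.all(diff == 0):
        return PairedTestResult(float("nan"), float("nan"), float("nan"), True)
    method = "exact" if x_arr.size <= 25 and np.all(diff != 0) else "approx"
    wilcoxon_p = float(stats.wilcoxon(diff, method=method).pvalue)
    if paired:
        t_p = float(stats.ttest_rel(x_arr, y_arr).pvalue)
    else:
        t_p = float(stats.ttest_ind(x_arr, y_arr).pvalue)
    if diff.std(ddof=1) == 0:
        normality_p = float("nan")
    else:
        z = (diff - diff.mean()) / diff.std(ddof=1)
        normality_p = float(stats.kstest(z, "norm").pvalue)
    return PairedTestResult(wilcoxon_p, t_p, normality_p, False)


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------

#: Canonical comparison labels, in published-table order.
COMPARISONS = ("pk_vs_pcgauss", "pk_vs_pkadj", "pkadj_vs_pcgauss")


@dataclass(frozen=True)
class CohortAnalysis:
    """Per-eye power table plus the three pairwise agreement summaries."""

    table: pd.DataFrame
    summaries: dict[str, AgreementSummary]
    tests: dict[str, PairedTestResult]
    regression: tuple[float, float, float]  # Pk_adj on PcGauss: slope, intercept, R^2
    correlations: pd.DataFrame
    exclusions: pd.DataFrame
    model: str
    nk_classic: float


def analyze_cohort(
    cohort: Sequence[CohortRecord],
    model: SchematicEyeModel,
    nk_classic: float = CLASSICAL_NK,
    thickness: str = "measured",
) -> CohortAnalysis:
    """Compute per-eye powers and the three pairwise agreement analyses.

    Per eye: Pk(nk_classic) from r1c alone; Pk_adj via the banded adjusted
    index; PcGauss from both radii and the central thickness (measured
    per-eye pachymetry by default, or the model constant with
    ``thickness="model"``).  Eyes whose r1c lies outside the supported
    adjusted-algorithm domain are reported in ``exclusions`` rather than
    silently dropped.

    Returns summaries for the three comparisons (Pk - PcGauss, Pk - Pk_adj,
    Pk_adj - PcGauss), the least-squares line of Pk_adj on PcGauss, and
    Pearson correlations of each difference against r1c, r2c and the two
    asphericities.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if thickness not in ("measured", "model"):
        raise ValueError("thickness must be 'measured' or 'model'")

    rows, excluded = [], []
    lo, hi = R1C_DOMAIN_MM
    for rec in cohort:
        if not (lo <= rec.r1c <= hi):
            excluded.append({"eye_id": rec.eye_id, "r1c_mm": rec.r1c,
                             "reason": f"r1c outside [{lo}, {hi}] mm"})
            continue
        ec_mm = (
            microns_to_millimetres(rec.ec_central)
            if thickness == "measured"
            else 1000.0 * model.e_c_model
        )
        adj = nk_adj_piecewise(rec.r1c, model)
        pcg = float(gaussian_power_value(rec.r1c, rec.r2c, model, e_c_mm=ec_mm))
        rows.append(
            {
                "eye_id": rec.eye_id,
                "r1c_mm": rec.r1c,
                "r2c_mm": rec.r2c,
                "k": rec.k,
                "ec_mm": float(ec_mm),
                "q_anterior": rec.q_anterior,
                "q_posterior": rec.q_posterior,
                "band_id": adj.band_id,
                "nk_adj": adj.nk_adj,
                "nk_exact": float(
                    nk_exact_value(rec.r1c, rec.r2c, model, e_c_mm=ec_mm)
                ),
                "pk": float(keratometric_power(rec.r1c, nk_classic)),
                "pk_adj": adj.pk_adj,
                "pc_gauss": pcg,
            }
        )
    if not rows:
        raise ValueError("no eye in the cohort lies within the supported r1c domain")
    table = pd.DataFrame(rows).sort_values("eye_id", kind="stable").reset_index(drop=True)

    series = {
        "pk_vs_pcgauss": (table["pk"], table["pc_gauss"]),
        "pk_vs_pkadj": (table["pk"], table["pk_adj"]),
        "pkadj_vs_pcgauss": (table["pk_adj"], table["pc_gauss"]),
    }
    summaries = {name: bland_altman(a, b) for name, (a, b) in series.items()}
    tests = {
        name: paired_tests(a, b) for name, (a, b) in series.items() if len(a) >= 5
    }

    slope, intercept = np.polyfit(table["pc_gauss"], table["pk_adj"], 1)
    fitted = slope * table["pc_gauss"] + intercept
    ss_tot = float(np.sum((table["pk_adj"] - table["pk_adj"].mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((table["pk_adj"] - fitted) ** 2)) / ss_tot

    corr_rows = []
    predictors = ("r1c_mm", "r2c_mm", "q_anterior", "q_posterior")
    for name, (a, b) in series.items():
        diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        for pred in predictors:
            vals = table[pred].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            if ok.sum() < 3 or np.ptp(vals[ok]) == 0 or np.ptp(diff[ok]) == 0:
                r, p = float("nan"), float("nan")
            else:
                res = stats.pearsonr(diff[ok], vals[ok])
                r, p = float(res.statistic), float(res.pvalue)
            corr_rows.append({"comparison": name, "predictor": pred, "r": r, "p": p})

    return CohortAnalysis(
        table=table,
        summaries=summaries,
        tests=tests,
        regression=(float(slope), float(intercept), r2),
        correlations=pd.DataFrame(corr_rows),
        exclusions=pd.DataFrame(excluded, columns=["eye_id", "r1c_mm", "reason"]),
        model=model.name,
        nk_classic=nk_classic,
    )


def results_to_csv(analysis: CohortAnalysis, path: Union[str, Path]) -> None:
    """Write the three-comparison agreement summary as CSV."""
    frame = pd.DataFrame(
        [
            {
                "comparison": name,
                "mean_diff": s.mean_diff,
                "sd": s.sd_diff,
                "loa_low": s.loa_low,
                "loa_high": s.loa_high,
                "p_value": s.p_paired,
            }
            for name, s in analysis.summaries.items()
        ]
    )
    frame.to_csv(path, index=False, lineterminator="\n")
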