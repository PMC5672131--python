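# Methods

## Optical model

The cornea is modelled paraxially as a thick lens in air: an anterior
surface of radius `r1c` separating air (`n_a = 1`) from stroma (`n_c`), and
a posterior surface of radius `r2c` separating stroma from aqueous humor
(`n_ha`), a central thickness `e_c` apart. Its Gaussian power is

```
PcGauss = P1c + P2c − (e_c/n_c)·P1c·P2c,
P1c = (n_c − n_a)/r1c,  P2c = (n_ha − n_c)/r2c,
```

with radii and thickness in metres and powers in dioptres. The keratometric
power `Pk = (nk − 1)/r1c` compresses the posterior surface and thickness
into a single fictitious index `nk`. The keratometric error is
`ΔPc = Pk − PcGauss` (positive = overestimation). Asphericity is carried
descriptively in cohort records but deliberately plays no optical role:
the model is paraxial (central power) only.

Two schematic eye models supply the constants, stored in
`src/kerapower/data/eye_models.yaml`:

| model | n_c | n_ha | e_c (mm) | classical nk |
|---|---|---|---|---|
| Gullstrand | 1.376 | 1.336 | 0.50 | 1.3315 |
| Le Grand | 1.3771 | 1.3374 | 0.55 | 1.3304 |

These are the standard corneal subsystems of the two classical theoretical
eyes. The registry is plain text so additional models can be registered at
run time; the two built-ins are immutable. The decisive validation of the
constant choice is numerical: with them the package reproduces every
printed cell of the published banded calibration tables and every extreme
error value (see the acceptance tests).

## Exact and adjusted keratometric index

Setting `ΔPc = 0` gives the geometry's *exact* index,
`nk_exact = 1 + r1c·PcGauss`, implemented in this numerically stable
identity form and cross-checked in tests against the expanded rational
expression `[−e_c n_c + e_c n_c² + e_c n_ha − e_c n_c n_ha − n_c² r1c +
n_c² r2c + n_c n_ha r1c] / (n_c r2c)`.

When `r2c` cannot be measured, the *adjusted* index `nk_adj(r1c)` is
defined, for each `r1c`, by the equal-magnitude-error condition at the two
posterior-radius extremes of the admissible domain:
`ΔPc(r2c_lo) = −ΔPc(r2c_hi)`, equivalently `Pk(nk_adj)` equals the midpoint
of the two extreme Gaussian powers, so

```
nk_adj = 1 + r1c·(PcGauss(r1c, r2c_lo) + PcGauss(r1c, r2c_hi))/2 .
```

Substituting the thick-lens formula shows `nk_adj` is an *exact* affine
function of `r1c` at fixed posterior extremes:

```
slope      = (P2c(r2c_lo) + P2c(r2c_hi))/2        [per metre of r1c]
intercept  = n_c − slope·e_c·(n_c − 1)/n_c
```

which is why the least-squares fits have R² = 1 to machine precision and
why the fitted coefficients are independent of the grid step. The OLS fit
(`numpy.polyfit` over a 0.1 mm grid) is retained both as the published
procedure and as a cross-check of the closed form; a bisection root-finder
on `ΔPc(r2c_lo) + ΔPc(r2c_hi) = 0` serves as an independent oracle in the
tests.

## The banded post-CXL domain

In keratoconus after crosslinking, reported curvatures span r1c 5.6–8.5 mm
and r2c 4.4–7.0 mm with k = r1c/r2c in 1.04–1.57. The calibration uses
three anterior-radius bands with fixed posterior extremes:

| band | r1c (mm) | r2c extremes (mm) | k interval |
|---|---|---|---|
| 1 | 5.6–6.8 | 4.4, 5.4 | [1.04, 1.55] |
| 2 | 6.9–7.2 | 4.8, 6.0 | [1.15, 1.50] |
| 3 | 7.3–8.5 | 5.4, 7.0 | [1.04, 1.57] |

The per-band posterior extremes are reconstructed from the published
k-ratio intervals via `r2c_lo = r1c_max/k_max`, `r2c_hi = r1c_min/k_min`;
this is the unique reconstruction that reproduces every published
coefficient and range. Within each band, the adjusted approach guarantees
`|Pk_adj − PcGauss| ≤ 0.8 D` (printed rounding) *provided the eye's true
r2c lies between the band's extremes*; the extreme error is attained only
at the extremes themselves.

Two sweep conventions are exposed because published results mix both:

- **banded domain** (default for error extremes): each band's r1c grid ×
  the full r2c grid between its extremes. This reproduces the published
  classical-index extremes exactly (e.g. 1.3375 under Gullstrand: +0.3 D to
  +3.2 D).
- **k-filtered rectangle** (`SweepDomain`): the full r1c × r2c grid with k
  (rounded to 2 decimals) inside [1.04, 1.57]. This admits combinations the
  banded domain excludes — e.g. (6.9, 4.4) mm, k = 1.57 after rounding —
  and therefore yields larger extremes (3.33 D there). Use it for
  exploratory scans, not for reproducing the banded tables.

### Numerical conventions

- Radii in millimetres at every interface, converted to metres internally;
  powers in dioptres.
- Display rounding: dioptres to 1 decimal, indices to 4, fitted slope to 5
  and intercept to 4 (table convention). Piecewise evaluation uses exact,
  unrounded coefficients by default; printed-coefficient evaluation (which
  can differ by ~1e−4 in the index) is available via a flag.
- Band assignment for continuous r1c between the 0.1 mm table rows uses the
  half-open midpoint rule: band 1 below 6.85 mm, band 2 in [6.85, 7.25),
  band 3 above. Outside 5.6–8.5 mm evaluation raises unless extrapolation
  is explicitly requested (nearest band, flagged).
- Grid steps of 0.1 mm everywhere, matching the precision of all quoted
  radii; exact linearity makes the fits grid-independent anyway.
- Tie sets for extreme-error argument pairs use a 0.05 D tolerance (half
  the printed resolution). Note that some published ties are ties only at
  printed 1-decimal resolution (values ~0.09 D apart).

### Known table-level discrepancies (documented, not forced)

- Le Grand band-2 intercept: exact closed form 1.3782 vs published 1.3781
  (one rounding unit); the band's nk_adj endpoint cells inherit up to
  2·10⁻⁴ of the same drift.
- The Le Grand banded Gaussian-power maximum computes to ≈60.2 D at
  (5.6, 5.4) mm, whereas the published global maximum is 58.6 D; the origin
  of 58.6 could not be reconstructed from any domain convention. The
  Gullstrand values (36.9–59.9 D) are self-consistent and are the ones
  asserted.
- The published global nk_exact range "1.3140 to 1.3351" conflicts with the
  published band-1 cell maximum 1.3355; the banded computation gives 1.3355
  at (5.6, 5.4) mm (1.3351 is the band-3 maximum).

## Clinical agreement pipeline

Per eye, the pipeline computes `Pk(nk)` (default nk = 1.3375), `Pk_adj` via
the banded algorithm, and `PcGauss` using the eye's measured central
pachymetry by default (a switch uses the model thickness instead — the
original study does not state which was used clinically). Agreement between
each pair is summarised by Bland-Altman limits (mean difference ± 1.96 SD
of differences, SD with n−1 denominator), Pearson correlation, and a
two-sided Wilcoxon signed-rank test (exact null up to n = 25). A paired
Student t-test is the default parametric companion — the comparisons are
within-eye, so the paired form is the statistically appropriate one — with
the unpaired form available. Normality of differences is reported via a
Kolmogorov–Smirnov p-value as metadata. Eyes with r1c outside the supported
band domain are listed in an exclusions report, never silently dropped.

## Synthetic cohort generator

The original 21-eye post-CXL validation sample was never published per eye,
so a generator emulates its summary statistics: independent truncated
normals per field — r1c 7.1 ± 0.60 mm in [5.6, 7.8], r2c 5.6 ± 0.70 mm in
[4.4, 6.6], central pachymetry 488 ± 64.6 µm in [418, 639], minimum
pachymetry 452 ± 47.2 µm, anterior/posterior asphericity −0.7 ± 0.53 /
−0.8 ± 0.73 — with rejection resampling of the (r1c, r2c) pair until
k ∈ [1.1404, 1.4719]. All draws flow through one `numpy` generator seeded
per run; identical seeds give byte-identical cohort CSVs.

**What the generator does not emulate.** Real eyes show strong r1c–r2c
correlation: in the original sample each band's eyes kept their k ratio
well inside the band's calibration extremes (e.g. steep-band eyes had
k 1.26–1.47, i.e. r2c ≤ 5.4 mm). No covariance was ever published, so the
generator draws the radii independently under only the global k constraint.
Consequences for interpreting tests: cohort-level properties that depend
only on marginal distributions (the mean classical overestimation, which
lands at ≈1.7 D inside the reported 0.8–2.9 D clinical envelope) transfer
well, but per-eye properties conditional on the r1c–r2c relationship do
not — roughly a fifth of synthetic eyes carry an r2c outside their band's
calibration extremes, where the ±0.8 D adjusted-error guarantee does not
apply and deviations reach ≈1.5 D. Real post-CXL eyes, whose k tracks the
banded structure, are expected to behave like the original sample (mean
adjusted-vs-Gaussian difference ≈0.1 D, all within ±0.8 D), not like the
uncorrelated synthetic tail. The published clinical agreement numbers
(mean 1.63 D, limits of agreement 0.44–2.82 D, etc.) are therefore treated
as non-reproducible references, not as test targets.

## Problem sizes

The exhaustive sweeps are small by construction: 13 + 4 + 13 grid points
per model across the three bands (two posterior extremes each, 60 Gaussian
evaluations per model), 416 pairs in the banded error-extreme scan, and
570 in the k-filtered rectangle. Identity and property tests draw 10⁴
random geometries. Synthetic-cohort properties use n = 200 eyes, well above
the original n = 21, so cohort means are stable across seeds.

## Limitations

- Paraxial central power only: no asphericity, no ray tracing, no
  total-eye or IOL power formulas.
- Two schematic eye models; others can be registered but the published
  calibrations apply to these two.
- The banded calibration is specific to the post-CXL keratoconus curvature
  domain; untreated keratoconus and post-LASIK corneas need their own
  calibrations.
- Synthetic cohorts share only the published marginal summaries with the
  real sample (see above).
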