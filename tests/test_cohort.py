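"""Synthetic cohort generation and agreement statistics."""

import numpy as np
import pytest

from kerapower import (
    CohortGenerationError,
    CohortProfile,
    CohortRecord,
    FieldProfile,
    TABLE_PROFILE,
    analyze_cohort,
    bland_altman,
    cohort_from_csv,
    cohort_to_csv,
    generate_synthetic_cohort,
    get_model,
    paired_tests,
)


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------


def test_empty_cohort():
    assert generate_synthetic_cohort(0, seed=1) == []


def test_default_profile_respects_published_ranges():
    cohort = generate_synthetic_cohort(21, seed=3)
    assert len(cohort) == 21
    for rec in cohort:
        assert 5.6 <= rec.r1c <= 7.8
        assert 4.4 <= rec.r2c <= 6.6
        assert 1.1404 <= rec.k <= 1.4719
        assert 418 <= rec.ec_central <= 639


def test_generator_is_deterministic(tmp_path):
    a, b = tmp_path / "a.csv", tmp_path / "b.csv"
    cohort_to_csv(generate_synthetic_cohort(21, seed=7), a)
    cohort_to_csv(generate_synthetic_cohort(21, seed=7), b)
    assert a.read_bytes() == b.read_bytes()
    c = tmp_path / "c.csv"
    cohort_to_csv(generate_synthetic_cohort(21, seed=8), c)
    assert a.read_bytes() != c.read_bytes()


def test_infeasible_k_constraint_raises():
    profile = CohortProfile(
        r1c=FieldProfile(7.1, 0.60, 5.6, 7.8),
        r2c=FieldProfile(5.6, 0.70, 4.4, 6.6),
        ec_central=TABLE_PROFILE.ec_central,
        ec_min=TABLE_PROFILE.ec_min,
        q_anterior=TABLE_PROFILE.q_anterior,
        q_posterior=TABLE_PROFILE.q_posterior,
        k_range=(3.0, 4.0),  # unreachable given the radius ranges
    )
    with pytest.raises(CohortGenerationError):
        generate_synthetic_cohort(5, seed=1, profile=profile, max_attempts_per_record=50)


def test_cohort_csv_round_trip(tmp_path):
    cohort = generate_synthetic_cohort(10, seed=5)
    path = tmp_path / "cohort.csv"
    cohort_to_csv(cohort, path)
    assert path.read_text().splitlines()[0] == (
        "eye_id,r1c_mm,r2c_mm,ec_central_um,ec_min_um,q_anterior,q_posterior"
    )
    loaded = cohort_from_csv(path)
    assert [r.eye_id for r in loaded] == [r.eye_id for r in cohort]
    assert all(a.r1c == b.r1c for a, b in zip(loaded, cohort))


def test_malformed_csv_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "eye_id,r1c_mm,r2c_mm,ec_central_um\n"
        "eye001,7.1,5.6,488\n"
        "eye002,oops,5.6,488\n"
    )
    with pytest.raises(ValueError, match="line 3"):
        cohort_from_csv(path)


def test_implausible_k_warns_but_does_not_fail():
    with pytest.warns(UserWarning, match="k ratio"):
        CohortRecord(eye_id="x", r1c=7.0, r2c=7.5, ec_central=500.0)


# ---------------------------------------------------------------------------
# Bland-Altman and paired tests
# ---------------------------------------------------------------------------


def test_bland_altman_hand_computed():
    x = np.array([10.0, 11.0, 12.0])
    summary = bland_altman(x + np.array([1.0, 2.0, 3.0]), x)
    assert summary.mean_diff == pytest.approx(2.0)
    assert summary.sd_diff == pytest.approx(1.0)
    assert summary.loa_low == pytest.approx(0.04)
    assert summary.loa_high == pytest.approx(3.96)
    assert summary.n == 3


def test_bland_altman_identical_vectors_degenerate():
    x = np.array([45.0, 46.0, 47.0, 48.0])
    summary = bland_altman(x, x)
    assert summary.mean_diff == 0.0
    assert summary.sd_diff == 0.0
    assert (summary.loa_low, summary.loa_high) == (0.0, 0.0)
    assert np.isnan(summary.p_paired)
    assert summary.degenerate


def test_bland_altman_constant_offset():
    x = np.array([44.0, 47.5, 50.0, 52.5])
    summary = bland_altman(x + 1.5, x)
    assert summary.mean_diff == pytest.approx(1.5)
    assert summary.sd_diff == pytest.approx(0.0, abs=1e-12)
    assert summary.pearson_r == pytest.approx(1.0)


def test_bland_altman_input_validation():
    with pytest.raises(ValueError):
        bland_altman([1.0, 2.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        bland_altman([1.0], [2.0])


def test_paired_tests_degenerate_flag():
    x = np.full(8, 45.0)
    result = paired_tests(x, x)
    assert result.degenerate
    assert np.isnan(result.wilcoxon_p)


def test_paired_tests_one_sided_shift_is_significant():
    rng = np.random.default_rng(11)
    y = rng.uniform(42.0, 50.0, 21)
    x = y + rng.uniform(0.5, 2.5, 21)  # strictly positive differences
    result = paired_tests(x, y)
    assert result.wilcoxon_p < 0.001
    assert result.t_p < 0.001
    assert not result.degenerate


def test_wilcoxon_depends_only_on_differences():
    rng = np.random.default_rng(4)
    y = rng.uniform(42.0, 50.0, 15)
    d = rng.normal(0.5, 0.8, 15)
    p1 = paired_tests(y + d, y).wilcoxon_p
    perm = rng.permutation(15)
    p2 = paired_tests((y + d)[perm] - y[perm] + 45.0, np.full(15, 45.0)).wilcoxon_p
    assert p1 == pytest.approx(p2)


# ---------------------------------------------------------------------------
# Cohort analysis
# ---------------------------------------------------------------------------


def test_two_eye_toy_cohort_mean_difference(gullstrand):
    cohort = [
        CohortRecord("a", r1c=6.8, r2c=4.4, ec_central=500.0),
        CohortRecord("b", r1c=7.3, r2c=7.0, ec_central=500.0),
    ]
    analysis = analyze_cohort(cohort, gullstrand)
    assert round(analysis.summaries["pk_vs_pcgauss"].mean_diff, 1) == 1.8


def test_spherical_cornea_overestimated_under_gullstrand(gullstrand, legrand):
    """With k = 1 the classical 1.3375 index overestimates the Gaussian
    power across the whole anterior-radius domain under Gullstrand
    constants.  Under Le Grand constants 1.3375 sits a hair above the
    aqueous index, so the thickness term flips the sign: a small
    underestimation everywhere instead."""
    with pytest.warns(UserWarning):  # k = 1 is below the clinical sanity range
        cohort = [
            CohortRecord(f"e{i}", r1c=r, r2c=r, ec_central=500.0)
            for i, r in enumerate(np.arange(5.6, 8.51, 0.1))
        ]
    diffs = analyze_cohort(cohort, gullstrand).table
    assert ((diffs["pk"] - diffs["pc_gauss"]) > 0).all()
    diffs_lg = analyze_cohort(cohort, legrand).table
    lg = diffs_lg["pk"] - diffs_lg["pc_gauss"]
    assert ((lg < 0) & (lg > -0.25)).all()


def test_analysis_invariant_to_row_order(gullstrand):
    cohort = generate_synthetic_cohort(21, seed=13)
    forward = analyze_cohort(cohort, gullstrand)
    backward = analyze_cohort(list(reversed(cohort)), gullstrand)
    for key in forward.summaries:
        assert forward.summaries[key].mean_diff == pytest.approx(
            backward.summaries[key].mean_diff, abs=1e-12
        )
        assert forward.summaries[key].sd_diff == pytest.approx(
            backward.summaries[key].sd_diff, abs=1e-12
        )


def test_out_of_domain_eyes_reported_not_dropped_silently(gullstrand):
    cohort = [
        CohortRecord("ok", r1c=7.0, r2c=5.6, ec_central=500.0),
        CohortRecord("steep", r1c=5.0, r2c=4.2, ec_central=450.0),
        CohortRecord("ok2", r1c=7.2, r2c=5.8, ec_central=500.0),
    ]
    analysis = analyze_cohort(cohort, gullstrand)
    assert list(analysis.exclusions["eye_id"]) == ["steep"]
    assert len(analysis.table) == 2


def test_empty_cohort_rejected(gullstrand):
    with pytest.raises(ValueError, match="empty"):
        analyze_cohort([], gullstrand)


def test_thickness_source_switch(gullstrand):
    cohort = [CohortRecord("a", 7.0, 5.6, ec_central=400.0),
              CohortRecord("b", 7.4, 6.0, ec_central=600.0)]
    measured = analyze_cohort(cohort, gullstrand, thickness="measured")
    modelled = analyze_cohort(cohort, gullstrand, thickness="model")
    assert (measured.table["ec_mm"] == [0.4, 0.6]).all()
    assert (modelled.table["ec_mm"] == 0.5).all()
    assert not np.allclose(measured.table["pc_gauss"], modelled.table["pc_gauss"])


def test_per_eye_indices_within_theoretical_envelope(gullstrand):
    """Clinical-style nk_exact and nk_adj stay inside the simulated global
    ranges for a Table-3-profile cohort (model thickness, as in the
    theoretical sweep)."""
    cohort = generate_synthetic_cohort(100, seed=2)
    analysis = analyze_cohort(cohort, gullstrand, thickness="model")
    # continuous r1c between published grid rows extends the piecewise
    # nk_adj range by up to ~5e-4 near the band-1/band-2 seam
    assert analysis.table["nk_adj"].between(1.3210 - 6e-4, 1.3309 + 6e-4).all()
    assert analysis.table["nk_exact"].between(1.3140 - 5e-5, 1.3355 + 5e-5).all()
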