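"""Index formulas, validity flags, and the negative-value exclusion rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ogttrank.indices import (
    IVGTTProfile,
    OGTTProfile,
    SubjectRecord,
    air_ivgtt,
    apply_negative_exclusion,
    auc_ratio,
    cir,
    classify_glucose_tolerance,
    compute_panel,
    di_oral,
    first_phase_stumvoll,
    homa_b,
    igi1,
    igi2,
    insulin_clearance,
    matsuda_isi,
    panel_frame,
    trapezoid_auc,
    SECRETION_INDICES,
)
from ogttrank.synthetic_data import SimulationConfig, simulate_cohort


def make_profile(glucose=(5.0, 8.0, 7.0, 6.0, 5.5), insulin=(50.0, 450.0, 350.0, 200.0, 120.0),
                 c_peptide=(600.0, 2000.0, 1800.0, 1500.0, 1200.0)):
    return OGTTProfile(glucose=glucose, insulin=insulin, c_peptide=c_peptide)


# ---------------------------------------------------------------------------
# formula examples (hand-evaluated expectations)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "series, expected",
    [((1, 1, 1, 1, 1), 2.0), ((0, 0, 0, 0, 0), 0.0), ((4, 8, 6, 5, 4), 11.5)],
)
def test_trapezoid_auc_values(series, expected):
    assert trapezoid_auc(series) == pytest.approx(expected)


@given(
    x=st.lists(st.floats(0, 1e3), min_size=5, max_size=5),
    y=st.lists(st.floats(0, 1e3), min_size=5, max_size=5),
    a=st.floats(-5, 5),
    b=st.floats(-5, 5),
)
def test_trapezoid_auc_is_linear(x, y, a, b):
    x, y = np.array(x), np.array(y)
    lhs = trapezoid_auc(a * x + b * y)
    rhs = a * trapezoid_auc(x) + b * trapezoid_auc(y)
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)


def test_homa_b_values():
    assert homa_b(5.5, 60.0) == pytest.approx(100.0)  # 10 uU/ml, 20*10/2
    assert homa_b(5.5, 0.0) == 0.0
    assert np.isnan(homa_b(3.5, 60.0))  # singular denominator -> invalid
    assert np.isnan(homa_b(3.0, 60.0))


def test_insulinogenic_indices():
    assert igi1(5, 8, 50, 450) == pytest.approx(400 / 3)
    assert igi2(8, 50, 450) == pytest.approx(50.0)
    assert igi1(5, 8, 100, 100) == 0.0 and igi2(8, 100, 100) == 0.0
    assert np.isnan(igi1(6, 6, 50, 450))  # G30 == G0
    assert igi1(5, 8, 450, 50) < 0  # I30 < I0 propagates the sign


def test_di_oral():
    assert di_oral(5, 8, 50, 450) == pytest.approx((400 / 3) / 50)
    assert np.isnan(di_oral(5, 8, 0, 450))  # I0 == 0
    assert np.isnan(di_oral(6, 6, 50, 450))  # undefined IGI1 propagates


def test_cir():
    assert cir(8, 450) == pytest.approx(100 * 450 / (8 * 4.11))
    assert cir(8, 0) == 0.0
    assert np.isnan(cir(3.89, 450))
    assert np.isnan(cir(3.5, 450))


def test_first_phase_stumvoll():
    assert first_phase_stumvoll(0, 0, 0) == pytest.approx(1283.0)
    assert first_phase_stumvoll(8, 50, 450) == pytest.approx(1185.05)
    low, high = first_phase_stumvoll(8, 50, 450), first_phase_stumvoll(8, 50, 1e4)
    assert high > low  # monotone in I30


def test_auc_ratios():
    prof = make_profile()
    assert auc_ratio(prof, "insulin", "0-30") == pytest.approx(500 / 13)
    assert auc_ratio(prof, "c_peptide", "0-30") == pytest.approx(2600 / 13)
    # constants cancel the trapezoid scaling in either window
    const = make_profile(glucose=(5,) * 5, insulin=(60,) * 5, c_peptide=(600,) * 5)
    assert auc_ratio(const, "insulin", "0-30") == pytest.approx(12.0)
    assert auc_ratio(const, "insulin", "0-120") == pytest.approx(12.0)
    # 0-30 two-point form equals the two-point trapezoid ratio bit-for-bit
    g0, g30, i0, i30 = 5.0, 8.0, 50.0, 450.0
    two_point = (i0 + i30) / (g0 + g30)
    trap = (0.5 * (0.5 * i0 + 0.5 * i30)) / (0.5 * (0.5 * g0 + 0.5 * g30))
    assert auc_ratio(prof, "insulin", "0-30") == two_point == trap


def test_matsuda_isi():
    assert matsuda_isi([5] * 5, [60] * 5) == pytest.approx(10000 / 300)
    base = matsuda_isi([5, 8, 7, 6, 5.5], [50, 450, 350, 200, 120])
    assert base == pytest.approx(16.4722, rel=1e-4)
    doubled = matsuda_isi([5, 8, 7, 6, 5.5], [100, 900, 700, 400, 240])
    assert doubled == pytest.approx(base / 2)  # degree -1 in insulin
    assert np.isnan(matsuda_isi([5, 8, 7, 6, 5.5], [0, 450, 350, 200, 120]))


def test_insulin_clearance():
    prof = make_profile()
    assert insulin_clearance(prof, "fasting") == pytest.approx(12.0)
    same = make_profile(insulin=(600, 2000, 1800, 1500, 1200))
    assert insulin_clearance(same, "ogtt") == pytest.approx(1.0)
    zero_i0 = make_profile(insulin=(0.0, 450, 350, 200, 120))
    assert np.isnan(insulin_clearance(zero_i0, "fasting"))


def test_air_ivgtt():
    const = IVGTTProfile(insulin={m: 100.0 for m in (0, 2, 4, 6, 8, 10)})
    # five unit weights (0.5 + 4*1 + 0.5) halved: 2.5x the constant level
    assert air_ivgtt(const) == pytest.approx(250.0)
    zeros = IVGTTProfile(insulin={m: 0.0 for m in (0, 2, 4, 6, 8, 10)})
    assert air_ivgtt(zeros) == 0.0
    prof = IVGTTProfile(insulin=dict(zip((0, 2, 4, 6, 8, 10), (50, 900, 800, 700, 600, 500))))
    assert air_ivgtt(prof) == pytest.approx(1637.5)
    with pytest.raises(ValueError, match="missing mandatory minutes"):
        IVGTTProfile(insulin={0: 50, 2: 900, 4: 800})


# ---------------------------------------------------------------------------
# profile validation
# ---------------------------------------------------------------------------


def test_profile_validation_errors():
    with pytest.raises(ValueError, match="expected 5 samples"):
        OGTTProfile(glucose=(5, 8, 7, 6), insulin=(1,) * 5, c_peptide=(1,) * 5)
    with pytest.raises(ValueError, match="non-finite"):
        OGTTProfile(glucose=(5, 8, 7, 6, np.nan), insulin=(1,) * 5, c_peptide=(1,) * 5)
    with pytest.raises(ValueError, match="> 0"):
        OGTTProfile(glucose=(0, 8, 7, 6, 5), insulin=(1,) * 5, c_peptide=(1,) * 5)
    with pytest.raises(ValueError, match="non-finite sample"):
        trapezoid_auc([1, 2, np.inf, 4, 5])


def test_subject_validation():
    prof = make_profile()
    with pytest.raises(ValueError, match="sex"):
        SubjectRecord("s", "other", 40, 25, prof)
    with pytest.raises(ValueError, match="genotypes"):
        SubjectRecord("s", "male", 40, 25, prof, genotypes={"snp": 3})


# ---------------------------------------------------------------------------
# panel + exclusion
# ---------------------------------------------------------------------------


def test_compute_panel_retains_positive_responder():
    subj = SubjectRecord("s1", "female", 40.0, 25.0, make_profile())
    panel = compute_panel(subj)
    assert not panel.any_negative
    assert all(panel.valid[name] for name in SECRETION_INDICES)
    assert all(panel.values[name] > 0 for name in SECRETION_INDICES)


def test_compute_panel_flags_negative_igi():
    falling = make_profile(glucose=(8.0, 5.0, 5.5, 5.2, 5.0))  # G30 < G0
    panel = compute_panel(SubjectRecord("s2", "male", 40.0, 25.0, falling))
    assert panel.any_negative


def test_panel_unit_covariance():
    """Scaling all insulin samples scales the insulin-based indices and leaves
    C-peptide ratios unchanged (determinism + unit covariance)."""
    scale = 3.0
    base = compute_panel(SubjectRecord("a", "female", 40, 25, make_profile()))
    scaled_prof = make_profile(insulin=tuple(scale * v for v in (50, 450, 350, 200, 120)))
    scaled = compute_panel(SubjectRecord("a", "female", 40, 25, scaled_prof))
    for name in ("insulin_30", "igi1", "igi2", "cir", "auc_ins_0_30_ratio", "auc_ins_0_120_ratio"):
        assert scaled.values[name] == pytest.approx(scale * base.values[name])
    for name in ("auc_cp_0_30_ratio", "auc_cp_0_120_ratio", "c_peptide_30"):
        assert scaled.values[name] == pytest.approx(base.values[name])


def test_panel_frame_matches_compute_panel(default_cohort):
    cohort, _ = default_cohort
    frame = panel_frame(cohort.head(5))
    for _, row in cohort.head(5).iterrows():
        subj = SubjectRecord(
            row["subject_id"], row["sex"], row["age"], row["bmi"],
            OGTTProfile(
                glucose=tuple(row[f"glc_{m}"] for m in (0, 30, 60, 90, 120)),
                insulin=tuple(row[f"ins_{m}"] for m in (0, 30, 60, 90, 120)),
                c_peptide=tuple(row[f"cpep_{m}"] for m in (0, 30, 60, 90, 120)),
            ),
        )
        panel = compute_panel(subj)
        got = frame.loc[frame["subject_id"] == row["subject_id"]].iloc[0]
        for name in SECRETION_INDICES:
            assert got[name] == pytest.approx(panel.values[name], rel=1e-12)
        assert bool(got["any_negative"]) == panel.any_negative


def test_exclusion_reports_planted_negative_subjects():
    # noise-free so the planted subjects are the only exclusion source
    cfg = SimulationConfig(n_subjects=400, n_planted_negative=7,
                           flat_responder_fraction=0.0, assay_cv_glucose=0.0,
                           assay_cv_insulin=0.0, assay_cv_cpeptide=0.0,
                           biological_cv=0.0, seed=3)
    cohort, truth = simulate_cohort(cfg)
    retained, excluded = apply_negative_exclusion(cohort)
    assert set(excluded["subject_id"]) == set(truth.planted_negative_ids)
    assert len(excluded) == 7
    assert len(retained) + len(excluded) == 400
    assert (excluded["excluded_reason"] == "negative_secretion_index").all()


def test_exclusion_flags_incomplete_profile():
    cfg = SimulationConfig(n_subjects=5, seed=1, flat_responder_fraction=0.0)
    cohort, _ = simulate_cohort(cfg)
    cohort.loc[0, "ins_60"] = np.nan
    retained, excluded = apply_negative_exclusion(cohort)
    assert excluded["subject_id"].tolist() == [cohort.loc[0, "subject_id"]]
    assert excluded["excluded_reason"].iloc[0] == "incomplete_ogtt_profile"


@pytest.mark.parametrize(
    "g0, g120, expected",
    [
        (4.9, 5.6, "NGT"),
        (5.9, 6.2, "IFG"),
        (5.1, 8.7, "IGT"),
        (6.0, 8.5, "IFG+IGT"),
        (7.2, 6.0, "diabetes"),
        (5.0, 11.5, "diabetes"),
    ],
)
def test_classify_glucose_tolerance(g0, g120, expected):
    assert classify_glucose_tolerance(g0, g120) == expected
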