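"""Adjusted association models against a normal-equation oracle and simulations."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_regression_frame
from ogttrank.association import (
    DEFAULT_CONFOUNDERS,
    ModelSpec,
    fit_adjusted_model,
    fit_forward,
    fit_reverse_model,
    partial_r_with_air,
    quartile_nominal_fit,
)
from ogttrank.association import _quartile_codes  # white-box: quartile cut rule


def ols_oracle(y, X):
    """Brute-force normal equations: beta, se, mse, df2."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df2 = len(y) - X.shape[1]
    mse = float(resid @ resid) / df2
    se = np.sqrt(np.diag(mse * np.linalg.inv(XtX)))
    return beta, se, mse, df2


def forward_design(frame, snp="snp", index="igi1"):
    """Independent re-specification of the forward model's design matrix."""
    y = np.log(frame[index].to_numpy(float))
    X = np.column_stack(
        [
            np.ones(len(frame)),
            frame[snp].to_numpy(float),
            (frame["sex"].to_numpy() == "male").astype(float),
            np.log(frame["age"].to_numpy(float)),
            np.log(frame["bmi"].to_numpy(float)),
            np.log(frame["matsuda_isi"].to_numpy(float)),
        ]
    )
    return y, X


def test_fit_matches_normal_equation_oracle():
    """Coefficient/SE/F agreement with (X'X)^-1 X'y on small random tables."""
    rng = np.random.default_rng(123)
    for rep in range(10):
        frame = make_regression_frame(20, beta_per_allele=0.2, rng=rng)
        res = fit_forward(frame, "snp", "igi1")
        y, X = forward_design(frame)
        beta, se, mse, df2 = ols_oracle(y, X)
        assert res.beta == pytest.approx(beta[1], rel=1e-8)
        assert res.se == pytest.approx(se[1], rel=1e-8)
        assert res.ms_error == pytest.approx(mse, rel=1e-8)
        assert res.df2 == df2
        assert res.f_stat == pytest.approx((beta[1] / se[1]) ** 2, rel=1e-8)
        assert res.ss_hypothesis == pytest.approx((beta[1] / se[1]) ** 2 * mse, rel=1e-8)


def test_planted_effect_recovered_within_three_se():
    rng = np.random.default_rng(77)
    truth = 0.15
    frame = make_regression_frame(2000, beta_per_allele=truth, rng=rng)
    res = fit_forward(frame, "snp", "igi1")
    assert abs(res.beta - truth) < 3 * res.se
    assert res.p_value < 0.05
    assert res.n_used == 2000 and res.n_dropped == 0


def test_constant_genotype_is_rank_deficient():
    rng = np.random.default_rng(5)
    frame = make_regression_frame(50, 0.0, rng)
    frame["snp"] = 1
    with pytest.raises(ValueError, match="collinear.*snp"):
        fit_forward(frame, "snp", "igi1")


def test_scale_invariance_of_genotype_term():
    """Multiplying the index by a constant only shifts the intercept."""
    rng = np.random.default_rng(42)
    frame = make_regression_frame(300, 0.1, rng)
    base = fit_forward(frame, "snp", "igi1")
    scaled = frame.assign(igi1=frame["igi1"] * 137.5)
    res = fit_forward(scaled, "snp", "igi1")
    assert res.beta == pytest.approx(base.beta, rel=1e-10)
    assert res.se == pytest.approx(base.se, rel=1e-10)
    assert res.p_value == pytest.approx(base.p_value, rel=1e-10)
    assert res.f_stat == pytest.approx(base.f_stat, rel=1e-10)


def test_listwise_deletion_is_counted():
    rng = np.random.default_rng(8)
    frame = make_regression_frame(100, 0.1, rng)
    frame.loc[:4, "snp"] = np.nan
    frame.loc[5, "igi1"] = -1.0  # not loggable
    res = fit_forward(frame, "snp", "igi1")
    assert res.n_used == 94 and res.n_dropped == 6
    assert res.n_used + res.n_dropped == len(frame)


def test_reverse_model_oracle_and_direction():
    rng = np.random.default_rng(31)
    frame = make_regression_frame(500, 0.3, rng)
    res = fit_reverse_model(frame, "snp", "igi1")
    assert res.direction == "genotype_on_index"
    y = frame["snp"].to_numpy(float)
    X = np.column_stack(
        [
            np.ones(len(frame)),
            np.log(frame["igi1"].to_numpy(float)),
            (frame["sex"].to_numpy() == "male").astype(float),
            np.log(frame["age"].to_numpy(float)),
            np.log(frame["bmi"].to_numpy(float)),
            np.log(frame["matsuda_isi"].to_numpy(float)),
        ]
    )
    beta, se, mse, df2 = ols_oracle(y, X)
    assert res.beta == pytest.approx(beta[1], rel=1e-8)
    assert res.se == pytest.approx(se[1], rel=1e-8)
    # a large effect is detected in both directions
    forward = fit_forward(frame, "snp", "igi1")
    assert forward.p_value < 0.05 and res.p_value < 0.05


def test_reverse_model_type_one_error_under_null():
    rng = np.random.default_rng(99)
    hits = 0
    reps = 300
    for _ in range(reps):
        frame = make_regression_frame(400, 0.0, rng)
        hits += fit_reverse_model(frame, "snp", "igi1").p_value < 0.05
    assert 0.02 <= hits / reps <= 0.08


# ---------------------------------------------------------------------------
# quartile-nominal covariate variant
# ---------------------------------------------------------------------------


def test_quartile_codes_rule():
    codes = _quartile_codes(np.arange(1.0, 9.0))
    assert codes.tolist() == [0, 0, 1, 1, 2, 2, 3, 3]


def test_quartile_fit_close_to_continuous():
    rng = np.random.default_rng(17)
    frame = make_regression_frame(1500, 0.2, rng)
    spec = ModelSpec(
        dependent="igi1", independent="snp", confounders=DEFAULT_CONFOUNDERS,
        genotype_columns=frozenset({"snp"}),
    )
    cont = fit_adjusted_model(frame, spec)
    nom = quartile_nominal_fit(frame, spec)
    assert np.sign(nom.beta) == np.sign(cont.beta)
    assert abs(np.log10(nom.p_value) - np.log10(cont.p_value)) < 1.0
    # three indicator columns per stratified covariate
    assert nom.df2 == cont.df2 - 6  # age, bmi, isi: +2 columns each


def test_quartile_fit_merges_degenerate_covariate():
    rng = np.random.default_rng(23)
    frame = make_regression_frame(200, 0.2, rng)
    frame["age"] = 50.0  # all-equal -> single level, no indicator columns
    spec = ModelSpec(
        dependent="igi1", independent="snp", confounders=DEFAULT_CONFOUNDERS,
        genotype_columns=frozenset({"snp"}),
    )
    with pytest.warns(UserWarning, match="quartile stratification"):
        res = quartile_nominal_fit(frame, spec)
    assert np.isfinite(res.p_value)


def test_model_spec_validation():
    with pytest.raises(ValueError, match="must differ"):
        ModelSpec(dependent="a", independent="a")
    with pytest.raises(ValueError, match="confounders"):
        ModelSpec(dependent="a", independent="b", confounders=("a",))
    with pytest.raises(ValueError, match="covariate_mode"):
        ModelSpec(dependent="a", independent="b", covariate_mode="x")


# ---------------------------------------------------------------------------
# AIR partial correlation
# ---------------------------------------------------------------------------


def air_frame(n, rng, noise=0.0, dependent=True):
    frame = make_regression_frame(n, 0.0, rng, index="igi1")
    if dependent:
        air = frame["igi1"] ** 0.8 * np.exp(rng.normal(0, noise, n))
    else:
        air = np.exp(rng.normal(5.0, 0.5, n))
    return frame.assign(air=air)


def test_partial_r_perfect_dependence_limit():
    rng = np.random.default_rng(3)
    assert partial_r_with_air(air_frame(300, rng, noise=0.0), "igi1") == pytest.approx(1.0)
    noisy = partial_r_with_air(air_frame(300, rng, noise=0.3), "igi1")
    assert 0.7 < noisy < 1.0


def test_partial_r_independent_index_is_small():
    rng = np.random.default_rng(13)
    rs = [
        partial_r_with_air(air_frame(300, rng, dependent=False), "igi1")
        for _ in range(20)
    ]
    assert abs(np.mean(rs)) < 0.05
    assert max(abs(r) for r in rs) < 0.25


def test_partial_r_requires_enough_subjects():
    rng = np.random.default_rng(1)
    frame = air_frame(300, rng)
    frame.loc[8:, "air"] = np.nan
    with pytest.raises(ValueError, match="subjects"):
        partial_r_with_air(frame, "igi1")


def test_early_phase_index_tracks_air_better_than_homa(analysis_frame):
    """In an early-phase-driven cohort the early-window AUC ratio correlates
    with IVGTT AIR more strongly than fasting HOMA-B."""
    frame, _ = analysis_frame
    r_auc = partial_r_with_air(frame, "auc_ins_0_30_ratio")
    r_homa = partial_r_with_air(frame, "homa_b")
    assert r_auc > r_homa > 0
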