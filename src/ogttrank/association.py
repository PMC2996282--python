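"""Confounder-adjusted least-squares association of secretion indices with SNPs.

The workhorse model regresses the loge-transformed secretion index on the SNP
genotype (minor-allele count 0/1/2, entered untransformed as an additive
numeric term) with sex (binary indicator), loge age, loge BMI, and loge
OGTT-derived insulin sensitivity (Matsuda ISI) as confounders. The reverse
direction — genotype as dependent variable, index as independent — is fitted
the same way. Because some confounders are far from normal even after power
transforms, a variant enters age/BMI/ISI as 4-level nominal factors cut at
the sample quartiles instead of as continuous terms.

Every fit reports, for the tested term: the estimate, its SE, the partial F
(= t^2 for a single-df term), the hypothesis sum of squares SSH = F * MSE,
the residual mean square, and the degrees of freedom — the inputs the
post-hoc power / least-significant-number machinery needs. Rows with missing
or non-loggable values in any model variable are removed listwise and
counted, never silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "DEFAULT_CONFOUNDERS",
    "ModelSpec",
    "AssociationResult",
    "fit_adjusted_model",
    "fit_forward",
    "fit_reverse_model",
    "quartile_nominal_fit",
    "partial_r_with_air",
]

#: Confounders of the adjusted model: sex, age, BMI, OGTT-derived sensitivity.
DEFAULT_CONFOUNDERS: tuple[str, ...] = ("sex", "age", "bmi", "matsuda_isi")


@dataclass(frozen=True)
class ModelSpec:
    """One adjusted regression: dependent ~ independent + confounders.

    ``genotype_columns`` names the variables that are additive minor-allele
    counts; they enter untransformed, every other non-sex variable is
    loge-transformed. ``covariate_mode`` switches the continuous confounders
    (all but sex) between loge-continuous terms and quartile-cut nominal
    factors.
    """

    dependent: str
    independent: str
    confounders: tuple[str, ...] = DEFAULT_CONFOUNDERS
    covariate_mode: str = "continuous"
    genotype_columns: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.dependent == self.independent:
            raise ValueError("dependent and independent variables must differ")
        overlap = {self.dependent, self.independent} & set(self.confounders)
        if overlap:
            raise ValueError(f"confounders must exclude the tested variables: {sorted(overlap)}")
        if self.covariate_mode not in ("continuous", "quartile_nominal"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")
        object.__setattr__(self, "confounders", tuple(self.confounders))
        object.__setattr__(self, "genotype_columns", frozenset(self.genotype_columns))


@dataclass(frozen=True)
class AssociationResult:
    """Statistics of the tested term in one adjusted fit."""

    snp_id: str
    index_name: str
    direction: str  # "index_on_genotype" | "genotype_on_index"
    n_used: int
    n_dropped: int
    beta: float
    se: float
    p_value: float
    f_stat: float
    ss_hypothesis: float
    ms_error: float
    df1: int
    df2: int


def _sex_indicator(values: np.ndarray) -> np.ndarray:
    """Female = 0, male = 1; accepts 'female'/'male' strings or 0/1 numerics."""
    if values.dtype.kind in "OUS":
        out = np.full(values.shape, np.nan)
        out[values == "female"] = 0.0
        out[values == "male"] = 1.0
        return out
    vals = values.astype(float)
    bad = ~np.isin(vals[np.isfinite(vals)], (0.0, 1.0))
    if bad.any():
        raise ValueError("numeric sex column must be coded 0 (female) / 1 (male)")
    return vals


def _quartile_codes(x: np.ndarray) -> np.ndarray:
    """4-level quartile codes, cuts at the 25/50/75 percentiles, lower-inclusive."""
    cuts = np.quantile(x, [0.25, 0.5, 0.75])
    return (x[:, None] >= cuts[None, :]).sum(axis=1)


def _quartile_dummies(x: np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    codes = _quartile_codes(x)
    levels = np.unique(codes)
    if levels.size < 4:
        warnings.warn(
            f"quartile stratification of {name!r}: ties leave only {levels.size} "
            "non-empty level(s); merging with neighbours",
            stacklevel=3,
        )
    cols = [(codes == lev).astype(float) for lev in levels[1:]]  # lowest = reference
    names = [f"{name}_q{lev + 1}" for lev in levels[1:]]
    if not cols:
        return np.empty((x.size, 0)), []
    return np.column_stack(cols), names


def _diagnose_collinearity(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that are linearly dependent on the columns before them."""
    bad = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            bad.append(names[j])
        rank = new_rank
    return bad


def _build_design(cohort: pd.DataFrame, spec: ModelSpec):
    """Assemble (y, X, column names, n_dropped) with listwise deletion."""
    variables = (spec.dependent, spec.independent) + spec.confounders
    missing_cols = [v for v in variables if v not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort table lacks column(s) {missing_cols}")

    raw: dict[str, np.ndarray] = {}
    usable = np.ones(len(cohort), dtype=bool)
    for var in variables:
        if var == "sex":
            col = _sex_indicator(cohort[var].to_numpy())
            usable &= np.isfinite(col)
        elif var in spec.genotype_columns:
            col = cohort[var].to_numpy(dtype=float)
            finite = np.isfinite(col)
            if not np.isin(col[finite], (0.0, 1.0, 2.0)).all():
                raise ValueError(f"genotype column {var!r} must hold minor-allele counts 0/1/2")
            usable &= finite
        else:
            col = cohort[var].to_numpy(dtype=float)
            usable &= np.isfinite(col) & (col > 0)  # loge transform needs > 0
        raw[var] = col

    n_dropped = int((~usable).sum())
    raw = {k: v[usable] for k, v in raw.items()}
    n_used = int(usable.sum())

    def term(var: str) -> np.ndarray:
        if var == "sex" or var in spec.genotype_columns:
            return raw[var]
        return np.log(raw[var])

    names = ["intercept", spec.independent]
    columns = [np.ones(n_used), term(spec.independent)]
    for var in spec.confounders:
        if spec.covariate_mode == "quartile_nominal" and var != "sex" and var not in spec.genotype_columns:
            dummies, dnames = _quartile_dummies(raw[var], var)
            if dnames:
                columns.append(dummies)
                names.extend(dnames)
        else:
            columns.append(term(var))
            names.append(var)
    X = np.column_stack(columns)
    y = term(spec.dependent)

    if n_used <= X.shape[1]:
        raise ValueError(
            f"only {n_used} usable rows for {X.shape[1]} coefficients "
            f"({spec.dependent} ~ {spec.independent})"
        )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = _diagnose_collinearity(X, names)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    return y, X, names, n_dropped


def fit_adjusted_model(
    cohort: pd.DataFrame,
    spec: ModelSpec,
    snp_id: Optional[str] = None,
    index_name: Optional[str] = None,
) -> AssociationResult:
    """Ordinary least squares fit of ``spec``; statistics of the tested term.

    The tested term is ``spec.independent`` (single df); its partial F equals
    the squared t statistic and SSH = F * MS_error.
    """
    y, X, names, n_dropped = _build_design(cohort, spec)
    res = sm.OLS(y, X).fit()
    j = names.index(spec.independent)
    beta = float(res.params[j])
    se = float(res.bse[j])
    df2 = int(res.df_resid)
    ms_error = float(res.ssr / df2)
    f_stat = float((beta / se) ** 2)
    p_value = float(stats.f.sf(f_stat, 1, df2))
    direction = (
        "genotype_on_index" if spec.dependent in spec.genotype_columns else "index_on_genotype"
    )
    snp = snp_id or (spec.dependent if direction == "genotype_on_index" else spec.independent)
    idx = index_name or (spec.independent if direction == "genotype_on_index" else spec.dependent)
    return AssociationResult(
        snp_id=snp,
        index_name=idx,
        direction=direction,
        n_used=int(res.nobs),
        n_dropped=n_dropped,
        beta=beta,
        se=se,
        p_value=p_value,
        f_stat=f_stat,
        ss_hypothesis=f_stat * ms_error,
        ms_error=ms_error,
        df1=1,
        df2=df2,
    )


def fit_forward(
    cohort: pd.DataFrame,
    snp: str,
    index: str,
    confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
    covariate_mode: str = "continuous",
) -> AssociationResult:
    """loge(index) ~ genotype + confounders (the primary direction)."""
    spec = ModelSpec(
        dependent=index,
        independent=snp,
        confounders=tuple(confounders),
        covariate_mode=covariate_mode,
        genotype_columns=frozenset({snp}),
    )
    return fit_adjusted_model(cohort, spec)


def fit_reverse_model(
    cohort: pd.DataFrame,
    snp: str,
    index: str,
    confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
    covariate_mode: str = "continuous",
) -> AssociationResult:
    """genotype ~ loge(index) + confounders (linear probability-style fit)."""
    spec = ModelSpec(
        dependent=snp,
        independent=index,
        confounders=tuple(confounders),
        covariate_mode=covariate_mode,
        genotype_columns=frozenset({snp}),
    )
    return fit_adjusted_model(cohort, spec)


def quartile_nominal_fit(cohort: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """Refit ``spec`` with age/BMI/ISI as quartile-cut nominal covariates."""
    return fit_adjusted_model(cohort, replace(spec, covariate_mode="quartile_nominal"))


def partial_r_with_air(
    cohort: pd.DataFrame,
    index: str,
    air_column: str = "air",
    confounders: Sequence[str] = DEFAULT_CONFOUNDERS,
    min_subjects: int = 10,
) -> float:
    """Signed partial correlation of a secretion index with IVGTT-derived AIR.

    Fits loge(AIR) ~ loge(index) + confounders on the IVGTT subset and returns
    sign(beta) * sqrt(SSH / (SSH + SSE)), the partial correlation of the index
    term given the confounders.
    """
    spec = ModelSpec(dependent=air_column, independent=index, confounders=tuple(confounders))
    subset = cohort.loc[pd.to_numeric(cohort[air_column], errors="coerce").notna()]
    if len(subset) < min_subjects:
        raise ValueError(
            f"only {len(subset)} subjects with {air_column!r}; need >= {min_subjects}"
        )
    res = fit_adjusted_model(subset, spec)
    if res.n_used < min_subjects:
        raise ValueError(f"only {res.n_used} usable subjects for {index!r} vs {air_column!r}")
    sse = res.ms_error * res.df2
    r2_partial = res.ss_hypothesis / (res.ss_hypothesis + sse)
    return float(np.sign(res.beta) * np.sqrt(r2_partial))
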