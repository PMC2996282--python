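"""Post-hoc power and least significant number for a tested linear-model term.

Given the hypothesis sum of squares SSH and the residual mean square MSE of a
fitted least-squares model, the retrospective (observed) power of the partial
F test is

    power = P[ F'(df1, n - k, lambda) > F_crit(alpha, df1, n - k) ],
    lambda = SSH / MSE,

with F' the noncentral F distribution and k the number of fitted
coefficients. The least significant number (lsn) is the smallest sample size
m at which the observed effect size would be expected to reach significance:
holding the squared effect size delta^2 = SSH/n and the error variance
sigma^2 = MSE fixed, the expected F at candidate size m is

    F_exp(m) = (m * delta^2 / sigma^2) / df1,   df2(m) = m - k,

and lsn is the smallest integer m > k with F_exp(m) >= F_crit(alpha, df1,
df2(m)). F_exp grows linearly in m while the critical value decreases, so the
crossing is unique and is located by bracketing + integer bisection. df2 is
recomputed at each candidate m (a ``fixed_df2`` switch holds it at the
observed value instead, for sensitivity checks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["PowerResult", "posthoc_power", "lsn", "power_and_lsn", "LSN_CAP"]

#: Largest sample size the lsn search will consider; beyond it the observed
#: effect is treated as practically undetectable.
LSN_CAP = 10**9
_LSN_CAP = LSN_CAP


@dataclass(frozen=True)
class PowerResult:
    """Retrospective power summary for one tested term."""

    alpha: float
    effect_size_sq: float  # SSH / N
    sigma2_hat: float  # MS_error
    power: float
    lsn: int


def _check_args(ss_hyp: float, ms_error: float, n: int, df1: int, n_coefficients: int) -> int:
    if not np.isfinite(ss_hyp) or ss_hyp < 0:
        raise ValueError(f"ss_hyp must be finite and >= 0, got {ss_hyp}")
    if not np.isfinite(ms_error) or ms_error <= 0:
        raise ValueError(f"ms_error must be > 0, got {ms_error}")
    if df1 < 1:
        raise ValueError(f"df1 must be >= 1, got {df1}")
    df2 = int(n) - int(n_coefficients)
    if df2 < 1:
        raise ValueError(f"need n > n_coefficients, got n={n}, k={n_coefficients}")
    return df2


def posthoc_power(
    ss_hyp: float,
    ms_error: float,
    n: int,
    df1: int,
    n_coefficients: int,
    alpha: float = 0.05,
) -> float:
    """Power of the partial F test at the observed sample size.

    With ss_hyp == 0 the noncentrality vanishes and the rejection probability
    equals the level alpha exactly (central case).
    """
    df2 = _check_args(ss_hyp, ms_error, n, df1, n_coefficients)
    lam = ss_hyp / ms_error
    fcrit = stats.f.isf(alpha, df1, df2)
    if lam == 0:
        return float(alpha)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def _expected_f(m: int, delta2_over_sigma2: float, df1: int) -> float:
    return m * delta2_over_sigma2 / df1


def _significant_at(m: int, delta2_over_sigma2: float, df1: int, k: int, alpha: float) -> bool:
    df2 = m - k
    return _expected_f(m, delta2_over_sigma2, df1) >= stats.f.isf(alpha, df1, df2)


def lsn(
    ss_hyp: float,
    ms_error: float,
    n: int,
    df1: int,
    n_coefficients: int,
    alpha: float = 0.05,
    fixed_df2: bool = False,
) -> int:
    """Least significant number: smallest m whose expected F reaches F_crit.

    Raises if the effect is too small to reach significance below 1e9
    subjects. With ``fixed_df2`` the residual df is frozen at the observed
    n - k instead of being recomputed at each candidate size.
    """
    df2_obs = _check_args(ss_hyp, ms_error, n, df1, n_coefficients)
    if ss_hyp == 0:
        raise ValueError("lsn undefined for a zero effect size (ss_hyp == 0)")
    ratio = (ss_hyp / n) / ms_error  # delta^2 / sigma^2
    k = int(n_coefficients)

    if fixed_df2:
        # F_crit constant; closed-form crossing, then ceil
        fcrit = stats.f.isf(alpha, df1, df2_obs)
        m = int(np.ceil(fcrit * df1 / ratio))
        return max(m, k + 1)

    lo = k + 1
    if _significant_at(lo, ratio, df1, k, alpha):
        return lo
    hi = lo
    while not _significant_at(hi, ratio, df1, k, alpha):
        if hi > _LSN_CAP:
            raise ValueError(
                f"lsn did not converge below {_LSN_CAP}: effect size too small "
                f"(delta^2/sigma^2 = {ratio:.3e})"
            )
        hi *= 2
    # invariant: lo not significant, hi significant
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if _significant_at(mid, ratio, df1, k, alpha):
            hi = mid
        else:
            lo = mid
    return hi


def power_and_lsn(
    ss_hyp: float,
    ms_error: float,
    n: int,
    df1: int,
    n_coefficients: int,
    alpha: float = 0.05,
) -> PowerResult:
    """Convenience wrapper returning both quantities as a :class:`PowerResult`."""
    power = posthoc_power(ss_hyp, ms_error, n, df1, n_coefficients, alpha)
    number = lsn(ss_hyp, ms_error, n, df1, n_coefficients, alpha)
    return PowerResult(
        alpha=alpha,
        effect_size_sq=ss_hyp / n,
        sigma2_hat=ms_error,
        power=power,
        lsn=number,
    )
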