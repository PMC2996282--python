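"""Rank aggregation of per-SNP lsn values and Wilcoxon comparison of rankings.

Each (index, SNP) association yields an lsn — the sample size at which the
observed effect would reach significance. Within one SNP column the twelve
indices are competition-ranked by lsn (1 = smallest lsn = most powerful index;
ties share the minimum rank and the following ranks are skipped). Summing an
index's ranks over a SNP subset gives its rank sum, and competition-ranking
the rank sums gives the final ordering of the indices for that subset.
Whether one index's six per-SNP ranks are systematically better than a
reference index's ranks is tested with a two-sample Wilcoxon rank-sum test,
exact by complete enumeration of all C(n_a + n_b, n_a) group assignments with
midranks for ties.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "competition_ranks",
    "rank_by_lsn",
    "rank_sum",
    "final_ranking",
    "wilcoxon_rank_sum",
    "wilcoxon_exact",
    "RankTable",
    "build_rank_table",
]

_MAX_ENUMERATION = 5_000_000


def competition_ranks(values: Sequence[float]) -> np.ndarray:
    """Ascending competition ranking ('1224' style): ties share the minimum rank."""
    return rankdata(np.asarray(values, dtype=float), method="min").astype(int)


def rank_by_lsn(lsn_column: Sequence[float]) -> np.ndarray:
    """Competition ranks of one SNP's lsn values (1 = lowest lsn, best index)."""
    arr = np.asarray(lsn_column, dtype=float)
    if arr.size == 0:
        raise ValueError("rank_by_lsn: empty lsn column")
    if not np.all(np.isfinite(arr) & (arr > 0)):
        raise ValueError(f"rank_by_lsn: lsn values must be finite and positive, got {arr}")
    return competition_ranks(arr)


def rank_sum(rank_matrix: pd.DataFrame, index_name: str, snp_subset: Sequence[str]) -> int:
    """Sum of one index's ranks over a subset of SNP columns."""
    if index_name not in rank_matrix.index:
        raise KeyError(f"unknown index {index_name!r}")
    unknown = [s for s in snp_subset if s not in rank_matrix.columns]
    if unknown:
        raise KeyError(f"unknown SNP id(s) {unknown}")
    return int(rank_matrix.loc[index_name, list(snp_subset)].sum())


def final_ranking(rank_sums: pd.Series) -> pd.DataFrame:
    """Order indices by rank sum with competition ranks.

    Returns a frame indexed by index name with columns ``rank_sum`` and
    ``final_rank``, sorted best-first.
    """
    sums = rank_sums.astype(float)
    ranks = competition_ranks(sums.to_numpy())
    out = pd.DataFrame({"rank_sum": sums, "final_rank": ranks}, index=sums.index)
    return out.sort_values(["rank_sum", "final_rank"]).assign(
        rank_sum=lambda d: d["rank_sum"].astype(int)
    )


@lru_cache(maxsize=32)
def _combination_matrix(n: int, n_a: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n), n_a)), dtype=np.intp)


def wilcoxon_rank_sum(
    ranks_a: Sequence[float], ranks_b: Sequence[float], method: str = "exact"
) -> float:
    """Two-sided two-sample Wilcoxon rank-sum p-value.

    method='exact': complete enumeration of all C(n_a+n_b, n_a) assignments of
    the pooled values (midranks for ties); two-sided p = min(1, 2*min(tail)).
    method='normal': large-sample normal approximation with tie correction and
    continuity correction, the convention of classical statistical packages;
    on small tied samples it is slightly more conservative than enumeration.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("wilcoxon_rank_sum: both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("wilcoxon_rank_sum: non-finite input")
    pooled = np.concatenate([a, b])
    mid = rankdata(pooled, method="average")
    w_obs = mid[: a.size].sum()
    if method == "exact":
        n, n_a = pooled.size, a.size
        if math.comb(n, n_a) > _MAX_ENUMERATION:
            raise ValueError(
                f"exact enumeration of C({n},{n_a}) assignments is infeasible; "
                "use method='normal'"
            )
        combos = _combination_matrix(n, n_a)
        sums = mid[combos].sum(axis=1)
        eps = 1e-9
        p_lo = np.mean(sums <= w_obs + eps)
        p_hi = np.mean(sums >= w_obs - eps)
        return float(min(1.0, 2.0 * min(p_lo, p_hi)))
    if method == "normal":
        n, n_a = pooled.size, a.size
        mean = n_a * (n + 1) / 2.0
        # tie-corrected variance of the rank sum under random assignment
        var = n_a * (n - n_a) / (n * (n - 1)) * np.sum((mid - mid.mean()) ** 2)
        if var == 0:
            return 1.0
        diff = w_obs - mean
        z = (abs(diff) - 0.5) / math.sqrt(var)  # continuity correction
        z = max(z, 0.0)
        from scipy.stats import norm

        return float(min(1.0, 2.0 * norm.sf(z)))
    raise ValueError(f"unknown method {method!r} (expected 'exact' or 'normal')")


def wilcoxon_exact(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Exact two-sided Wilcoxon rank-sum p by complete enumeration."""
    return wilcoxon_rank_sum(ranks_a, ranks_b, method="exact")


@dataclass
class RankTable:
    """Full rank-aggregation result for one lsn matrix.

    ``lsn_matrix`` and ``rank_matrix`` are (index x SNP) frames; ``rank_sums``
    holds one integer per (index, subset); ``final_ranks`` the competition
    rank of each index per subset; ``wilcoxon_p`` the per-index two-sided
    p-value of its ranks against the reference index's ranks, per subset.
    Subset Wilcoxon p-values computed on fewer SNPs than the full panel are
    exploratory (tiny sample sizes) and should be labelled as such in reports.
    """

    lsn_matrix: pd.DataFrame
    rank_matrix: pd.DataFrame
    subsets: Mapping[str, tuple[str, ...]]
    rank_sums: pd.DataFrame
    final_ranks: pd.DataFrame
    reference_index: str
    wilcoxon_p: pd.DataFrame

    @property
    def snp_ids(self) -> list[str]:
        return list(self.lsn_matrix.columns)

    @property
    def index_names(self) -> list[str]:
        return list(self.lsn_matrix.index)

    def ordering(self, subset: str = "ALL") -> pd.DataFrame:
        """Best-first ordering of the indices for one subset."""
        return final_ranking(self.rank_sums[subset])


def build_rank_table(
    lsn_matrix: pd.DataFrame,
    subsets: Optional[Mapping[str, Sequence[str]]] = None,
    reference_index: str = "homa_b",
    wilcoxon_method: str = "exact",
) -> RankTable:
    """Aggregate an (index x SNP) lsn matrix into the full ranking report."""
    if reference_index not in lsn_matrix.index:
        raise KeyError(f"reference index {reference_index!r} not in lsn matrix")
    if subsets is None:
        subsets = {"ALL": tuple(lsn_matrix.columns)}
    subsets = {name: tuple(snps) for name, snps in subsets.items()}
    rank_matrix = lsn_matrix.apply(lambda col: rank_by_lsn(col.to_numpy()), axis=0)
    rank_sums = pd.DataFrame(
        {
            name: {idx: rank_sum(rank_matrix, idx, snps) for idx in rank_matrix.index}
            for name, snps in subsets.items()
        }
    ).loc[list(rank_matrix.index)]
    final_ranks = rank_sums.apply(lambda col: competition_ranks(col.to_numpy()), axis=0)
    ref_ranks = {name: rank_matrix.loc[reference_index, list(snps)] for name, snps in subsets.items()}
    wilcoxon_p = pd.DataFrame(
        {
            name: {
                idx: wilcoxon_rank_sum(
                    rank_matrix.loc[idx, list(snps)], ref_ranks[name], method=wilcoxon_method
                )
                for idx in rank_matrix.index
            }
            for name, snps in subsets.items()
        }
    ).loc[list(rank_matrix.index)]
    return RankTable(
        lsn_matrix=lsn_matrix.copy(),
        rank_matrix=rank_matrix,
        subsets=subsets,
        rank_sums=rank_sums,
        final_ranks=final_ranks,
        reference_index=reference_index,
        wilcoxon_p=wilcoxon_p,
    )
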