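"""Bundled reference data: the published benchmark lsn matrix.

The candidate-SNP study this package's workflow is modelled on evaluated
twelve fasting-/OGTT-derived insulin secretion indices against six confirmed
type-2-diabetes risk SNPs in 1347 OGTT-phenotyped adults and reported, for
every (index, SNP) association, the post-hoc least significant number (lsn)
of the confounder-adjusted regression. That 12 x 6 lsn matrix is the input to
the rank-aggregation layer and is bundled here so the ranking pipeline can be
exercised and validated without access to the underlying cohort.

Three of the six SNPs act on glucose-stimulated insulin secretion (GSIS:
MTNR1B, HHEX, CDKAL1) and three on the incretin axis (ISIS: TCF7L2, WFS1,
KCNQ1); the ALL/GSIS/ISIS subsets defined here follow that mechanistic split.
"""

from __future__ import annotations

import pandas as pd

from .indices import SECRETION_INDICES

__all__ = [
    "SNP_IDS",
    "GSIS_SNPS",
    "ISIS_SNPS",
    "DEFAULT_SUBSETS",
    "REFERENCE_INDEX",
    "reference_lsn_matrix",
]

#: SNP identifiers of the benchmark panel, GSIS loci first.
SNP_IDS: tuple[str, ...] = (
    "MTNR1B_rs10830963",
    "HHEX_rs7923837",
    "CDKAL1_rs7754840",
    "TCF7L2_rs7903146",
    "WFS1_rs10010131",
    "KCNQ1_rs151290",
)

GSIS_SNPS: tuple[str, ...] = SNP_IDS[:3]
ISIS_SNPS: tuple[str, ...] = SNP_IDS[3:]

DEFAULT_SUBSETS: dict[str, tuple[str, ...]] = {
    "ALL": SNP_IDS,
    "GSIS": GSIS_SNPS,
    "ISIS": ISIS_SNPS,
}

#: The fasting-state index all OGTT-derived indices are compared against.
REFERENCE_INDEX: str = "homa_b"

# Published lsn of the adjusted association of each index (rows) with each
# SNP (columns); smaller = the effect would reach significance in a smaller
# sample, i.e. a more powerful index for that locus.
_LSN_ROWS: dict[str, tuple[int, ...]] = {
    "homa_b": (345, 4222, 34337, 2938, 2923, 42551),
    "insulin_30": (196, 587, 779, 4127, 2234, 852),
    "c_peptide_30": (241, 536, 2289, 4800, 1164, 657),
    "igi1": (201, 483, 1914, 2376, 1537, 1046),
    "igi2": (164, 527, 894, 3134, 2001, 797),
    "di_oral": (288, 568, 1715, 3285, 2250, 1127),
    "cir": (164, 447, 1487, 2098, 1824, 1075),
    "first_phase": (208, 468, 936, 4951, 1976, 981),
    "auc_ins_0_30_ratio": (153, 456, 810, 2808, 1855, 803),
    "auc_ins_0_120_ratio": (478, 356, 4465, 1361, 5549, 1023),
    "auc_cp_0_30_ratio": (180, 500, 2993, 2580, 1112, 706),
    "auc_cp_0_120_ratio": (453, 338, 8127, 1109, 1276, 677),
}


def reference_lsn_matrix() -> pd.DataFrame:
    """The benchmark 12 x 6 lsn matrix (index names x SNP ids), as published."""
    frame = pd.DataFrame.from_dict(_LSN_ROWS, orient="index", columns=list(SNP_IDS))
    return frame.loc[list(SECRETION_INDICES)].astype(float)
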