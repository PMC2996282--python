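"""Fasting-, OGTT-, and IVGTT-derived indices of insulin secretion.

The twelve secretion surrogates computed here (HOMA-B, insulin/C-peptide at
30 min, the two insulinogenic indices, the oral disposition index, CIR, the
Stumvoll first-phase estimate, and four AUC ratios) are the standard toolbox
for estimating beta-cell function from a five-point 75-g oral glucose
tolerance test with glucose in mmol/l and insulin/C-peptide in pmol/l.
Alongside them we compute the Matsuda whole-body insulin sensitivity index
(used downstream as a confounder, never as a secretion index) and two insulin
clearance ratios, plus the acute insulin response (AIR) from a frequently
sampled IVGTT where available.

All formula functions accept scalars or numpy arrays and return NaN where a
singular denominator or a domain violation makes the index undefined; the
cohort-level helpers turn NaNs and negative secretion values into explicit
exclusion flags rather than dropping subjects silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OGTT_MINUTES",
    "IVGTT_MINUTES",
    "AIR_MINUTES",
    "PMOL_PER_MICROUNIT",
    "SECRETION_INDICES",
    "AUXILIARY_MEASURES",
    "OGTTProfile",
    "IVGTTProfile",
    "SubjectRecord",
    "IndexPanel",
    "trapezoid_auc",
    "homa_b",
    "igi1",
    "igi2",
    "di_oral",
    "cir",
    "first_phase_stumvoll",
    "auc_ratio",
    "matsuda_isi",
    "insulin_clearance",
    "air_ivgtt",
    "compute_panel",
    "panel_frame",
    "apply_negative_exclusion",
    "classify_glucose_tolerance",
]

#: Fixed OGTT sampling grid (minutes); no interpolation of missing samples.
OGTT_MINUTES: tuple[int, ...] = (0, 30, 60, 90, 120)

#: Full IVGTT sampling grid (minutes after the glucose bolus; negative = baseline).
IVGTT_MINUTES: tuple[int, ...] = (-10, -5, 0, 2, 4, 6, 8, 10, 20, 30, 40, 50, 60)

#: IVGTT minutes that must be present to compute the acute insulin response.
AIR_MINUTES: tuple[int, ...] = (0, 2, 4, 6, 8, 10)

#: Insulin unit conversion, 1 uU/ml = 6.0 pmol/l (standard WHO conversion).
#: Needed only by HOMA-B, whose defining formula expects fasting insulin in uU/ml.
PMOL_PER_MICROUNIT: float = 6.0

#: The twelve secretion indices, in the canonical reporting order.
SECRETION_INDICES: tuple[str, ...] = (
    "homa_b",
    "insulin_30",
    "c_peptide_30",
    "igi1",
    "igi2",
    "di_oral",
    "cir",
    "first_phase",
    "auc_ins_0_30_ratio",
    "auc_ins_0_120_ratio",
    "auc_cp_0_30_ratio",
    "auc_cp_0_120_ratio",
)

#: Non-secretion measures carried on the panel (sensitivity + clearances).
AUXILIARY_MEASURES: tuple[str, ...] = (
    "matsuda_isi",
    "clearance_fasting",
    "clearance_ogtt",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_series(name: str, values: Sequence[float], n: int, positive: bool = False) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) != n:
        raise ValueError(f"{name}: expected {n} samples, got {len(vals)}")
    if not all(np.isfinite(vals)):
        raise ValueError(f"{name}: non-finite concentration in {vals}")
    if positive and not all(v > 0 for v in vals):
        raise ValueError(f"{name}: concentrations must be > 0, got {vals}")
    return vals


@dataclass(frozen=True)
class OGTTProfile:
    """Five-point OGTT concentration profile at minutes 0/30/60/90/120.

    glucose in mmol/l (strictly positive), insulin and C-peptide in pmol/l.
    """

    glucose: tuple[float, ...]
    insulin: tuple[float, ...]
    c_peptide: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "glucose", _check_series("glucose", self.glucose, 5, positive=True))
        object.__setattr__(self, "insulin", _check_series("insulin", self.insulin, 5))
        object.__setattr__(self, "c_peptide", _check_series("c_peptide", self.c_peptide, 5))


@dataclass(frozen=True)
class IVGTTProfile:
    """IVGTT insulin samples (pmol/l) keyed by minute.

    Minutes 0, 2, 4, 6, 8, 10 are mandatory (they define AIR); baseline and
    late samples are optional.
    """

    insulin: Mapping[int, float]

    def __post_init__(self) -> None:
        ins = {int(k): float(v) for k, v in self.insulin.items()}
        missing = [m for m in AIR_MINUTES if m not in ins]
        if missing:
            raise ValueError(f"IVGTT profile missing mandatory minutes {missing}")
        bad = {m: v for m, v in ins.items() if not (np.isfinite(v) and v >= 0)}
        if bad:
            raise ValueError(f"IVGTT insulin must be finite and >= 0, got {bad}")
        object.__setattr__(self, "insulin", ins)


@dataclass(frozen=True)
class SubjectRecord:
    """One participant: covariates, OGTT profile, optional IVGTT, genotypes."""

    subject_id: str
    sex: str  # "female" | "male"
    age: float
    bmi: float
    ogtt: OGTTProfile
    ivgtt: Optional[IVGTTProfile] = None
    genotypes: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.bmi > 0:
            raise ValueError(f"bmi must be > 0, got {self.bmi}")
        bad = {k: v for k, v in self.genotypes.items() if v not in (0, 1, 2)}
        if bad:
            raise ValueError(f"genotypes must be minor-allele counts in {{0,1,2}}, got {bad}")


@dataclass(frozen=True)
class IndexPanel:
    """All secretion indices plus sensitivity/clearance values for one subject.

    ``values`` holds one float per named measure (NaN where undefined),
    ``valid`` one flag per measure, and ``any_negative`` is true iff at least
    one of the twelve secretion indices is finite and negative.
    """

    subject_id: str
    values: Mapping[str, float]
    valid: Mapping[str, bool]
    any_negative: bool

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None


# ---------------------------------------------------------------------------
# formula layer (scalar or array)
# ---------------------------------------------------------------------------


def _guard(value, bad):
    """Replace entries of ``value`` where ``bad`` holds by NaN; keep scalars scalar."""
    out = np.where(bad, np.nan, value)
    if np.ndim(out) == 0:
        return float(out)
    return out


def trapezoid_auc(series):
    """Scaled trapezoid AUC of a five-point series over 0-120 min.

    Returns 0.5*(0.5*c0 + c30 + c60 + c90 + 0.5*c120) in concentration units
    (the 30-min sampling interval is deliberately not multiplied in; all AUC
    quantities are used only inside ratios, where the scaling cancels).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] != 5:
        raise ValueError(f"trapezoid_auc needs 5 samples, got shape {series.shape}")
    if not np.all(np.isfinite(series)):
        raise ValueError("trapezoid_auc: non-finite sample in series")
    c0, c30, c60, c90, c120 = np.moveaxis(series, -1, 0)
    out = 0.5 * (0.5 * c0 + c30 + c60 + c90 + 0.5 * c120)
    return float(out) if np.ndim(out) == 0 else out


def homa_b(g0, i0, pmol_per_microunit: float = PMOL_PER_MICROUNIT):
    """HOMA-B (U/mol): 20*I0/(G0 - 3.5) with I0 converted from pmol/l to uU/ml.

    Undefined (NaN) for fasting glucose at or below 3.5 mmol/l.
    """
    g0 = np.asarray(g0, dtype=float)
    i0_uu = np.asarray(i0, dtype=float) / pmol_per_microunit
    denom = g0 - 3.5
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard(20.0 * i0_uu / denom, denom <= 0)


def igi1(g0, g30, i0, i30):
    """Insulinogenic index 1: (I30 - I0)/(G30 - G0); NaN when G30 == G0."""
    g0, g30 = np.asarray(g0, float), np.asarray(g30, float)
    i0, i30 = np.asarray(i0, float), np.asarray(i30, float)
    denom = g30 - g0
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard((i30 - i0) / denom, denom == 0)


def igi2(g30, i0, i30):
    """Insulinogenic index 2: (I30 - I0)/G30."""
    g30 = np.asarray(g30, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard((np.asarray(i30, float) - np.asarray(i0, float)) / g30, g30 == 0)


def di_oral(g0, g30, i0, i30):
    """Oral disposition index (1/mmol): IGI1/I0; NaN when I0 == 0 or IGI1 undefined."""
    i0 = np.asarray(i0, float)
    base = np.asarray(igi1(g0, g30, i0, i30), float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard(base / i0, (i0 == 0) | ~np.isfinite(base))


def cir(g30, i30):
    """Corrected insulin response (l/mmol): 100*I30/[G30*(G30 - 3.89)].

    NaN when G30 <= 3.89 mmol/l (singular or sign-flipping denominator).
    """
    g30 = np.asarray(g30, float)
    denom = g30 * (g30 - 3.89)
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard(100.0 * np.asarray(i30, float) / denom, g30 <= 3.89)


def first_phase_stumvoll(g30, i0, i30):
    """Stumvoll first-phase insulin secretion (pmol/l).

    1283 + 1.829*I30 - 138.7*G30 + 3.772*I0; may be negative (exclusion path).
    """
    out = (
        1283.0
        + 1.829 * np.asarray(i30, float)
        - 138.7 * np.asarray(g30, float)
        + 3.772 * np.asarray(i0, float)
    )
    return float(out) if np.ndim(out) == 0 else out


def auc_ratio(ogtt: OGTTProfile, analyte: str, window: str):
    """AUC ratio of an analyte over glucose for the 0-30 or 0-120 min window.

    The 0-30 window uses the published two-point form (a0 + a30)/(g0 + g30);
    the 0-120 window uses :func:`trapezoid_auc` for numerator and denominator.
    """
    if analyte == "insulin":
        series = ogtt.insulin
    elif analyte == "c_peptide":
        series = ogtt.c_peptide
    else:
        raise ValueError(f"unknown analyte {analyte!r}")
    if window == "0-30":
        return _ratio_0_30(ogtt.glucose[0], ogtt.glucose[1], series[0], series[1])
    if window == "0-120":
        return _ratio_0_120(np.asarray(ogtt.glucose), np.asarray(series))
    raise ValueError(f"unknown window {window!r} (expected '0-30' or '0-120')")


def _ratio_0_30(g0, g30, a0, a30):
    denom = np.asarray(g0, float) + np.asarray(g30, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard((np.asarray(a0, float) + np.asarray(a30, float)) / denom, denom <= 0)


def _ratio_0_120(glucose, analyte):
    denom = trapezoid_auc(glucose)
    num = trapezoid_auc(analyte)
    denom = np.asarray(denom, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return _guard(np.asarray(num, float) / denom, denom <= 0)


def matsuda_isi(glucose, insulin):
    """Matsuda-DeFronzo composite insulin sensitivity index.

    10000/sqrt(G0*I0*Gmean*Imean) with unweighted means over the five OGTT
    samples, computed in mmol/l and pmol/l. Relative to the original
    mg/dl * uU/ml definition this differs by a fixed multiplicative constant,
    which is absorbed into the intercept after loge transform, so all adjusted
    analyses are invariant to the unit choice. NaN if any sample is <= 0.
    """
    glucose = np.asarray(glucose, dtype=float)
    insulin = np.asarray(insulin, dtype=float)
    if glucose.shape[-1] != 5 or insulin.shape[-1] != 5:
        raise ValueError("matsuda_isi needs the five OGTT samples of each analyte")
    bad = np.any(glucose <= 0, axis=-1) | np.any(insulin <= 0, axis=-1)
    g0, i0 = glucose[..., 0], insulin[..., 0]
    gmean, imean = glucose.mean(axis=-1), insulin.mean(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = g0 * i0 * gmean * imean
        return _guard(10000.0 / np.sqrt(np.where(arg > 0, arg, np.nan)), bad)


def insulin_clearance(ogtt: OGTTProfile, mode: str):
    """Insulin clearance ratio: CP0/I0 (fasting) or AUC_CP(0-120)/AUC_Ins(0-120) (ogtt)."""
    if mode == "fasting":
        i0 = ogtt.insulin[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            return _guard(ogtt.c_peptide[0] / i0 if i0 != 0 else np.nan, i0 <= 0)
    if mode == "ogtt":
        denom = trapezoid_auc(ogtt.insulin)
        with np.errstate(divide="ignore", invalid="ignore"):
            return _guard(trapezoid_auc(ogtt.c_peptide) / denom if denom != 0 else np.nan, denom <= 0)
    raise ValueError(f"unknown clearance mode {mode!r} (expected 'fasting' or 'ogtt')")


def air_ivgtt(ivgtt: IVGTTProfile):
    """Acute insulin response (pmol/l) from IVGTT insulin at minutes 0-10.

    0.5*(0.5*I0 + I2 + I4 + I6 + I8 + 0.5*I10), the first-phase gold standard.
    """
    ins = ivgtt.insulin
    return 0.5 * (
        0.5 * ins[0] + ins[2] + ins[4] + ins[6] + ins[8] + 0.5 * ins[10]
    )


# ---------------------------------------------------------------------------
# panel + exclusion layer
# ---------------------------------------------------------------------------


def _panel_values(g, i, cp) -> dict[str, float]:
    """All panel measures from the three 5-point series (arrays ok)."""
    g = np.asarray(g, float)
    i = np.asarray(i, float)
    cp = np.asarray(cp, float)
    g0, g30 = g[..., 0], g[..., 1]
    i0, i30 = i[..., 0], i[..., 1]
    cp0, cp30 = cp[..., 0], cp[..., 1]
    auc_g = trapezoid_auc(g)
    auc_i = trapezoid_auc(i)
    auc_cp = trapezoid_auc(cp)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = {
            "homa_b": homa_b(g0, i0),
            "insulin_30": float(i30) if np.ndim(i30) == 0 else i30,
            "c_peptide_30": float(cp30) if np.ndim(cp30) == 0 else cp30,
            "igi1": igi1(g0, g30, i0, i30),
            "igi2": igi2(g30, i0, i30),
            "di_oral": di_oral(g0, g30, i0, i30),
            "cir": cir(g30, i30),
            "first_phase": first_phase_stumvoll(g30, i0, i30),
            "auc_ins_0_30_ratio": _ratio_0_30(g0, g30, i0, i30),
            "auc_ins_0_120_ratio": _guard(np.asarray(auc_i, float) / np.asarray(auc_g, float), np.asarray(auc_g) <= 0),
            "auc_cp_0_30_ratio": _ratio_0_30(g0, g30, cp0, cp30),
            "auc_cp_0_120_ratio": _guard(np.asarray(auc_cp, float) / np.asarray(auc_g, float), np.asarray(auc_g) <= 0),
            "matsuda_isi": matsuda_isi(g, i),
            "clearance_fasting": _guard(np.asarray(cp0, float) / np.asarray(i0, float), np.asarray(i0) <= 0),
            "clearance_ogtt": _guard(np.asarray(auc_cp, float) / np.asarray(auc_i, float), np.asarray(auc_i) <= 0),
        }
    return vals


def compute_panel(subject: SubjectRecord, pmol_per_microunit: float = PMOL_PER_MICROUNIT) -> IndexPanel:
    """Compute the full index panel for one subject.

    Singular denominators yield NaN values flagged invalid; finite negative
    secretion values set ``any_negative``. Neither condition raises.
    """
    g = np.asarray(subject.ogtt.glucose)
    i = np.asarray(subject.ogtt.insulin)
    cp = np.asarray(subject.ogtt.c_peptide)
    vals = _panel_values(g, i, cp)
    if pmol_per_microunit != PMOL_PER_MICROUNIT:
        vals["homa_b"] = homa_b(g[0], i[0], pmol_per_microunit)
    vals = {k: float(v) for k, v in vals.items()}
    valid = {k: bool(np.isfinite(v)) for k, v in vals.items()}
    any_negative = any(
        valid[name] and vals[name] < 0 for name in SECRETION_INDICES
    )
    return IndexPanel(subject.subject_id, vals, valid, any_negative)


def panel_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Vectorized panel computation for a cohort table in the standard schema.

    Returns one row per subject with the 15 panel columns plus ``any_negative``
    and ``excluded_reason`` ('' for retained subjects).
    """
    g = cohort[[f"glc_{m}" for m in OGTT_MINUTES]].to_numpy(float)
    i = cohort[[f"ins_{m}" for m in OGTT_MINUTES]].to_numpy(float)
    cp = cohort[[f"cpep_{m}" for m in OGTT_MINUTES]].to_numpy(float)
    missing = ~(np.isfinite(g).all(1) & np.isfinite(i).all(1) & np.isfinite(cp).all(1))
    # guard the formula layer against NaN rows; they are flagged, not computed
    g_safe = np.where(np.isfinite(g) & (g > 0), g, 1.0)
    i_safe = np.where(np.isfinite(i), i, 0.0)
    cp_safe = np.where(np.isfinite(cp), cp, 0.0)
    vals = _panel_values(g_safe, i_safe, cp_safe)
    out = pd.DataFrame({"subject_id": cohort["subject_id"].to_numpy()})
    for name in SECRETION_INDICES + AUXILIARY_MEASURES:
        col = np.asarray(vals[name], float).copy()
        col[missing] = np.nan
        out[name] = col
    sec = out[list(SECRETION_INDICES)].to_numpy(float)
    any_negative = np.nansum(sec < 0, axis=1) > 0
    invalid_sec = ~np.isfinite(sec)
    reason = np.full(len(out), "", dtype=object)
    reason[invalid_sec.any(1)] = "invalid_secretion_index"
    reason[any_negative] = "negative_secretion_index"
    reason[missing] = "incomplete_ogtt_profile"
    out["any_negative"] = any_negative
    out["excluded_reason"] = reason
    return out


def apply_negative_exclusion(
    cohort: pd.DataFrame, panel: Optional[pd.DataFrame] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop subjects with any negative or undefined secretion index.

    Returns ``(retained cohort rows joined with their panel, exclusion log)``;
    the log lists every excluded subject id with its reason.
    """
    if panel is None:
        panel = panel_frame(cohort)
    merged = cohort.merge(panel, on="subject_id", validate="one_to_one")
    excluded = merged.loc[merged["excluded_reason"] != "", ["subject_id", "excluded_reason"]]
    retained = merged.loc[merged["excluded_reason"] == ""].reset_index(drop=True)
    return retained, excluded.reset_index(drop=True)


def classify_glucose_tolerance(g0: float, g120: float) -> str:
    """Classify glucose tolerance from fasting and 2-h glucose (ADA cutoffs).

    Descriptive reporting only; thresholds in mmol/l: diabetes G0 >= 7.0 or
    G120 >= 11.1; IFG 5.6 <= G0 < 7.0; IGT 7.8 <= G120 < 11.1.
    """
    if not (np.isfinite(g0) and np.isfinite(g120)):
        raise ValueError("classify_glucose_tolerance needs finite G0 and G120")
    if g0 >= 7.0 or g120 >= 11.1:
        return "diabetes"
    ifg = g0 >= 5.6
    igt = g120 >= 7.8
    if ifg and igt:
        return "IFG+IGT"
    if ifg:
        return "IFG"
    if igt:
        return "IGT"
    return "NGT"
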