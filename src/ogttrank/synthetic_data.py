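"""Seeded synthetic OGTT cohorts with genetically routed beta-cell effects.

No public cohort with per-subject OGTT curves and candidate-SNP genotypes is
available, so this module generates one with the statistical structure the
analysis assumes. Each subject carries four latent physiological components:

* ``S``  — whole-body insulin sensitivity (lognormal; declines with BMI and age),
* ``B``  — basal secretion, realised as the true fasting insulin,
* ``E``  — early-phase (glucose-stimulated) secretion amplitude,
* ``K``  — incretin potentiation of late-phase secretion.

SNPs are drawn in Hardy-Weinberg equilibrium (genotype ~ Binomial(2, MAF),
no LD) and act multiplicatively: each minor allele multiplies its routed
component (E for ``early_phase``, K for ``incretin_phase``, B for ``basal``)
by a per-allele factor. OGTT glucose rises from fasting to a 30-60 min peak
whose height shrinks with sensitivity and early secretion, insulin is the sum
of a basal level, an early-phase kernel peaking at 30 min scaled by E, and an
incretin kernel plateauing over 60-120 min scaled by K; C-peptide mirrors
insulin with a slower decay (C-peptide's longer circulating half-life) and a
~11x concentration scale. A configured subset of subjects receives an IVGTT
profile whose acute insulin response is proportional to E. All noise is
multiplicative lognormal by default — matching the loge-transformed analysis
model — with an additive-noise switch for misspecification stress tests.

A small fraction of "flat responders" with a nearly absent early phase
produces the occasional measured 30-min insulin below fasting, and with it a
realistic ~1% rate of negative-index exclusions; planted negative-index
subjects can be requested explicitly for exclusion-rule tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .indices import IVGTT_MINUTES, OGTT_MINUTES, IVGTTProfile, OGTTProfile, SubjectRecord

__all__ = [
    "ROUTES",
    "SnpSpec",
    "SimulationConfig",
    "GroundTruth",
    "default_snp_panel",
    "simulate_genotypes",
    "simulate_subject",
    "simulate_cohort",
]

ROUTES: tuple[str, ...] = ("early_phase", "incretin_phase", "basal", "null")

# --- response kernels over the OGTT grid (0, 30, 60, 90, 120 min) ----------
# glucose excursion shape (peak at 30 min, near-baseline by 120 min)
_GLC_SHAPE = np.array([0.0, 1.0, 0.85, 0.45, 0.18])
# insulin: early-phase kernel (30-min peak) and incretin kernel (late plateau)
_INS_EARLY = np.array([0.0, 1.0, 0.50, 0.20, 0.08])
_INS_INCRETIN = np.array([0.0, 0.02, 0.55, 1.00, 0.90])
# C-peptide analogues: slower decay is in the incretin/late weights
_CP_EARLY = np.array([0.0, 1.0, 0.35, 0.12, 0.05])
_CP_INCRETIN = np.array([0.0, 0.08, 0.50, 1.00, 0.95])
# gains: contribution of E and K (each ~1 on average) relative to basal
_INS_EARLY_GAIN = 7.5
_INS_INCRETIN_GAIN = 2.2
_CP_EARLY_GAIN = 2.4
_CP_INCRETIN_GAIN = 2.2
# IVGTT decay kernel at minutes 2..60 after the bolus
_IVGTT_POST_MINUTES = (2, 4, 6, 8, 10, 20, 30, 40, 50, 60)
_IVGTT_KERNEL = np.array([1.0, 0.88, 0.75, 0.62, 0.50, 0.22, 0.12, 0.07, 0.04, 0.02])
_IVGTT_PEAK_GAIN = 6.0

# elasticities tying the latents together (dimensionless exponents)
_SENS_BMI_EXP = -0.9  # d log S / d log BMI
_SENS_AGE_EXP = -0.25
_INS_SENS_EXP = -0.7  # fasting hyperinsulinaemia compensates low sensitivity
_EARLY_BASAL_EXP = 0.35  # early amplitude co-varies with basal secretion
_INCRETIN_BASAL_EXP = 0.25
_RISE_SENS_EXP = -0.2  # glucose excursion grows when S or E are low
_RISE_EARLY_EXP = -0.08
_FLAT_RESPONDER_FACTOR = 0.01


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: HWE frequency, effect route, per-allele factor."""

    snp_id: str
    maf: float
    route: str = "null"
    per_allele_effect: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}, got {self.route!r}")
        if not self.per_allele_effect > 0:
            raise ValueError(f"per_allele_effect must be > 0, got {self.per_allele_effect}")


def default_snp_panel() -> tuple[SnpSpec, ...]:
    """Six-SNP panel emulating the studied loci: three GSIS, three incretin.

    MAFs are literature-typical for European cohorts; per-allele factors are
    modest risk-allele effects (5-10% reduction of the routed component).
    """
    return (
        SnpSpec("MTNR1B_rs10830963", 0.30, "early_phase", 0.90),
        SnpSpec("HHEX_rs7923837", 0.40, "early_phase", 0.93),
        SnpSpec("CDKAL1_rs7754840", 0.31, "early_phase", 0.94),
        SnpSpec("TCF7L2_rs7903146", 0.30, "incretin_phase", 0.93),
        SnpSpec("WFS1_rs10010131", 0.40, "incretin_phase", 0.95),
        SnpSpec("KCNQ1_rs151290", 0.22, "incretin_phase", 0.94),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters (defaults emulate the study cohort).

    Units: age years, BMI kg/m^2, glucose mmol/l, insulin and C-peptide
    pmol/l. Dispersions named ``*_sd`` on latents are standard deviations on
    the loge scale; assay/biological CVs are per-sample coefficients of
    variation combined in quadrature.
    """

    n_subjects: int = 1350
    snps: tuple[SnpSpec, ...] = field(default_factory=default_snp_panel)
    male_fraction: float = 0.33
    age_mean: float = 39.0
    age_sd: float = 12.5
    bmi_median: float = 27.5
    bmi_log_sd: float = 0.23
    fasting_glucose_mean: float = 4.95
    fasting_glucose_sd: float = 0.40
    fasting_glucose_range: tuple[float, float] = (3.9, 6.9)
    fasting_insulin_median: float = 47.0
    cpeptide_insulin_ratio: float = 11.0
    sensitivity_sd: float = 0.35
    secretion_sd: float = 0.35
    early_sd: float = 0.45
    incretin_sd: float = 0.45
    glucose_rise_mean: float = 2.6
    glucose_rise_sd: float = 0.15
    assay_cv_glucose: float = 0.03
    assay_cv_insulin: float = 0.10
    assay_cv_cpeptide: float = 0.08
    biological_cv: float = 0.05
    flat_responder_fraction: float = 0.03
    ivgtt_fraction: float = 0.20
    n_planted_negative: int = 0
    noise_model: str = "multiplicative"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.noise_model not in ("multiplicative", "additive"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        for name in (
            "age_sd", "bmi_log_sd", "fasting_glucose_sd", "sensitivity_sd", "secretion_sd",
            "early_sd", "incretin_sd", "glucose_rise_sd", "assay_cv_glucose",
            "assay_cv_insulin", "assay_cv_cpeptide", "biological_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ivgtt_fraction <= 1.0:
            raise ValueError("ivgtt_fraction must be in [0, 1]")
        if not 0.0 <= self.flat_responder_fraction < 1.0:
            raise ValueError("flat_responder_fraction must be in [0, 1)")
        if self.n_planted_negative < 0 or self.n_planted_negative > self.n_subjects:
            raise ValueError("n_planted_negative must be in [0, n_subjects]")
        object.__setattr__(self, "snps", tuple(self.snps))

    # -- presets ------------------------------------------------------------
    @classmethod
    def ngt_like(cls, n_subjects: int = 1000, seed: int = 0) -> "SimulationConfig":
        """Normal-glucose-tolerance stratum: fasting glucose 4.90, insulin ~53."""
        return cls(
            n_subjects=n_subjects,
            fasting_glucose_mean=4.90,
            fasting_glucose_sd=0.39,
            fasting_glucose_range=(3.9, 6.0),
            bmi_median=27.0,
            seed=seed,
        )

    @classmethod
    def null_study(cls, n_subjects: int = 1500, seed: int = 0) -> "SimulationConfig":
        """Default panel with every genetic effect switched off."""
        snps = tuple(dataclasses.replace(s, per_allele_effect=1.0) for s in default_snp_panel())
        return cls(n_subjects=n_subjects, snps=snps, seed=seed)

    @classmethod
    def route_study(
        cls,
        route: str,
        per_allele_effect: float = 0.9,
        n_subjects: int = 1500,
        seed: int = 0,
    ) -> "SimulationConfig":
        """Default panel with the given route's three SNPs carrying the effect
        and the other three null — the parameter-recovery study design."""
        if route not in ("early_phase", "incretin_phase"):
            raise ValueError("route_study expects 'early_phase' or 'incretin_phase'")
        snps = tuple(
            dataclasses.replace(
                s, per_allele_effect=per_allele_effect if s.route == route else 1.0
            )
            for s in default_snp_panel()
        )
        return cls(n_subjects=n_subjects, snps=snps, seed=seed)

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["snps"] = [dataclasses.asdict(s) for s in self.snps]
        d["fasting_glucose_range"] = list(self.fasting_glucose_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "snps" in d:
            d["snps"] = tuple(
                s if isinstance(s, SnpSpec) else SnpSpec(**s) for s in d["snps"]
            )
        if "fasting_glucose_range" in d:
            d["fasting_glucose_range"] = tuple(d["fasting_glucose_range"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Sidecar record of what was planted: latents, routes, exclusions."""

    snps: tuple[SnpSpec, ...]
    latents: pd.DataFrame  # subject_id, S, B, E, K, flat_responder, has_ivgtt
    planted_negative_ids: tuple[str, ...]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "snps": [dataclasses.asdict(s) for s in self.snps],
            "planted_negative_ids": list(self.planted_negative_ids),
            "latents": {
                col: self.latents[col].tolist() for col in self.latents.columns
            },
        }


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def simulate_genotypes(
    n: int, snps: Sequence[SnpSpec], rng: np.random.Generator
) -> pd.DataFrame:
    """Independent HWE genotypes: minor-allele count ~ Binomial(2, MAF)."""
    return pd.DataFrame(
        {s.snp_id: rng.binomial(2, s.maf, size=n).astype(np.int64) for s in snps}
    )


def _route_log_factors(
    genotypes: pd.DataFrame, snps: Sequence[SnpSpec], n: int
) -> dict[str, np.ndarray]:
    """Per-subject log multiplicative factor on each routed component."""
    out = {r: np.zeros(n) for r in ("early_phase", "incretin_phase", "basal")}
    for s in snps:
        if s.route in out and s.per_allele_effect != 1.0:
            out[s.route] += genotypes[s.snp_id].to_numpy(float) * np.log(s.per_allele_effect)
    return out


def _observe(true: np.ndarray, cv: float, config: SimulationConfig, rng: np.random.Generator, floor: float) -> np.ndarray:
    """Apply measurement + biological noise to a matrix of true concentrations."""
    cv_total = float(np.hypot(cv, config.biological_cv))
    if cv_total == 0:
        return true.copy()
    if config.noise_model == "multiplicative":
        obs = true * np.exp(rng.normal(0.0, cv_total, size=true.shape))
    else:  # additive stress variant: same spread at the typical level
        scale = cv_total * float(np.mean(true))
        obs = true + rng.normal(0.0, scale, size=true.shape)
    return np.maximum(obs, floor)


def _simulate_profiles(
    sex_male: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray,
    genotypes: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Latents + observed OGTT/IVGTT concentration matrices for given covariates."""
    n = age.size
    logf = _route_log_factors(genotypes, config.snps, n)

    S = np.exp(
        _SENS_BMI_EXP * np.log(bmi / config.bmi_median)
        + _SENS_AGE_EXP * np.log(age / config.age_mean)
        + rng.normal(0.0, config.sensitivity_sd, n)
    )
    B = (
        config.fasting_insulin_median
        * S ** _INS_SENS_EXP
        * np.exp(rng.normal(0.0, config.secretion_sd, n) + logf["basal"])
    )
    g0 = np.clip(
        rng.normal(config.fasting_glucose_mean, config.fasting_glucose_sd, n),
        *config.fasting_glucose_range,
    )
    rel_b = B / config.fasting_insulin_median
    E = (
        np.exp(rng.normal(0.0, config.early_sd, n) + logf["early_phase"])
        * rel_b ** _EARLY_BASAL_EXP
    )
    flat = rng.random(n) < config.flat_responder_fraction
    E = np.where(flat, E * _FLAT_RESPONDER_FACTOR, E)
    K = (
        np.exp(rng.normal(0.0, config.incretin_sd, n) + logf["incretin_phase"])
        * rel_b ** _INCRETIN_BASAL_EXP
    )

    rise = np.clip(
        config.glucose_rise_mean
        * S ** _RISE_SENS_EXP
        * E ** _RISE_EARLY_EXP
        * np.exp(rng.normal(0.0, config.glucose_rise_sd, n)),
        0.8,
        9.0,
    )
    glc_true = g0[:, None] + rise[:, None] * _GLC_SHAPE[None, :]
    ins_true = B[:, None] * (
        1.0
        + _INS_EARLY_GAIN * E[:, None] * _INS_EARLY[None, :]
        + _INS_INCRETIN_GAIN * K[:, None] * _INS_INCRETIN[None, :]
    )
    cp0 = config.cpeptide_insulin_ratio * B * np.exp(rng.normal(0.0, 0.15, n))
    cp_true = cp0[:, None] * (
        1.0
        + _CP_EARLY_GAIN * E[:, None] * _CP_EARLY[None, :]
        + _CP_INCRETIN_GAIN * K[:, None] * _CP_INCRETIN[None, :]
    )

    glc = _observe(glc_true, config.assay_cv_glucose, config, rng, floor=1.0)
    ins = _observe(ins_true, config.assay_cv_insulin, config, rng, floor=0.5)
    cp = _observe(cp_true, config.assay_cv_cpeptide, config, rng, floor=5.0)

    has_ivgtt = rng.random(n) < config.ivgtt_fraction
    peak = _IVGTT_PEAK_GAIN * B * E * np.exp(rng.normal(0.0, 0.2, n))
    n_iv = len(IVGTT_MINUTES)
    iv_true = np.tile(B[:, None], (1, n_iv))
    for j, minute in enumerate(IVGTT_MINUTES):
        if minute in _IVGTT_POST_MINUTES:
            iv_true[:, j] = B + peak * _IVGTT_KERNEL[_IVGTT_POST_MINUTES.index(minute)]
    ivgtt = _observe(iv_true, config.assay_cv_insulin, config, rng, floor=0.5)
    ivgtt[~has_ivgtt, :] = np.nan

    arrays = {"glc": glc, "ins": ins, "cpep": cp, "ivgtt_ins": ivgtt}
    latents = pd.DataFrame(
        {"S": S, "B": B, "E": E, "K": K, "flat_responder": flat, "has_ivgtt": has_ivgtt}
    )
    return arrays, latents


def _ivgtt_column_name(minute: int) -> str:
    return f"ivgtt_ins_{minute}" if minute >= 0 else f"ivgtt_ins_m{-minute}"


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a full cohort table in the standard TSV schema plus ground truth.

    The (config, seed) pair fully determines the output; ``seed`` defaults to
    ``config.seed``.
    """
    used_seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(used_seed)
    n = config.n_subjects

    sex_male = rng.random(n) < config.male_fraction
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 20.0, 75.0)
    bmi = np.clip(
        config.bmi_median * np.exp(rng.normal(0.0, config.bmi_log_sd, n)), 18.0, 55.0
    )
    genotypes = simulate_genotypes(n, config.snps, rng)
    arrays, latents = _simulate_profiles(sex_male, age, bmi, genotypes, config, rng)

    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    planted: tuple[str, ...] = ()
    if config.n_planted_negative:
        k = config.n_planted_negative
        # force a negative insulinogenic index: measured 30-min insulin below
        # fasting while the glucose increment stays positive
        arrays["ins"][:k, 1] = 0.8 * arrays["ins"][:k, 0]
        arrays["glc"][:k, 1] = arrays["glc"][:k, 0] + 1.0
        planted = tuple(subject_ids[:k])

    cohort = pd.DataFrame({"subject_id": subject_ids})
    cohort["sex"] = np.where(sex_male, "male", "female")
    cohort["age"] = age
    cohort["bmi"] = bmi
    for j, m in enumerate(OGTT_MINUTES):
        cohort[f"glc_{m}"] = arrays["glc"][:, j]
    for j, m in enumerate(OGTT_MINUTES):
        cohort[f"ins_{m}"] = arrays["ins"][:, j]
    for j, m in enumerate(OGTT_MINUTES):
        cohort[f"cpep_{m}"] = arrays["cpep"][:, j]
    for j, m in enumerate(IVGTT_MINUTES):
        cohort[_ivgtt_column_name(m)] = arrays["ivgtt_ins"][:, j]
    for s in config.snps:
        cohort[s.snp_id] = genotypes[s.snp_id]

    latents = latents.copy()
    latents.insert(0, "subject_id", subject_ids)
    truth = GroundTruth(
        snps=config.snps, latents=latents, planted_negative_ids=planted, seed=used_seed
    )
    return cohort, truth


def simulate_subject(
    covariates: dict,
    genotypes: dict,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SubjectRecord:
    """Generate one :class:`SubjectRecord` for fixed covariates and genotypes.

    ``covariates`` must provide ``sex`` ('female'/'male'), ``age`` and ``bmi``;
    whether the subject receives an IVGTT follows ``config.ivgtt_fraction``
    unless ``covariates['ivgtt']`` forces it.
    """
    sex = covariates["sex"]
    snp_frame = pd.DataFrame({s.snp_id: [int(genotypes.get(s.snp_id, 0))] for s in config.snps})
    force_iv = covariates.get("ivgtt")
    cfg = config
    if force_iv is not None:
        cfg = dataclasses.replace(config, ivgtt_fraction=1.0 if force_iv else 0.0)
    arrays, _ = _simulate_profiles(
        np.array([sex == "male"]),
        np.array([float(covariates["age"])]),
        np.array([float(covariates["bmi"])]),
        snp_frame,
        cfg,
        rng,
    )
    ogtt = OGTTProfile(
        glucose=tuple(arrays["glc"][0]),
        insulin=tuple(arrays["ins"][0]),
        c_peptide=tuple(arrays["cpep"][0]),
    )
    ivgtt = None
    if np.isfinite(arrays["ivgtt_ins"][0]).all():
        ivgtt = IVGTTProfile(
            insulin={m: float(v) for m, v in zip(IVGTT_MINUTES, arrays["ivgtt_ins"][0])}
        )
    return SubjectRecord(
        subject_id=str(covariates.get("subject_id", "S00001")),
        sex=sex,
        age=float(covariates["age"]),
        bmi=float(covariates["bmi"]),
        ogtt=ogtt,
        ivgtt=ivgtt,
        genotypes={s.snp_id: int(snp_frame[s.snp_id][0]) for s in config.snps},
    )
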