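"""Synthetic cohorts with known ground truth.

The generator emulates the three inputs of the locus-characterization
workflow — GWAMA summary statistics, genotype dosages, and a phenotype
table — with the statistical structure the downstream analyses assume:

* genotypes under Hardy-Weinberg equilibrium, with LD proxies produced by a
  haplotype copy-with-mutation scheme so dosages stay integer-valued and
  HWE-consistent (a proxy haplotype inherits the lead allele with
  probability q = sqrt(target r^2), else redraws from the population);
* ln(eGFRcrea) built from age, sex, additive SNP effects and an optional
  SNP-by-TSH interaction, with serum creatinine back-derived by exactly
  inverting the 2009 CKD-EPI equation and then perturbed by instrument and
  participation-period shifts (so the normalization step has work to do);
* quantitative traits generated as trait = alpha*SNP + delta*ln(eGFRcrea)
  + noise, which spans the pure-pleiotropy (delta=0), outcome-downstream
  (alpha=0) and mixed scenarios of the mediation screen;
* TSH log-normal, with FT3/FT4 present only when TSH < 0.4 or > 3.8 uUI/mL
  (missing by design), medication and exclusion flags at realistic rates.

Every quantity is reproducible from ``GroundTruth.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phenoprep import ckd_epi_2009_inverse
from .types import DosageMatrix, VariantRecord

__all__ = [
    "LocusSpec",
    "TraitSpec",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_cohort",
    "meta_summary_from_truth",
    "default_trait_specs",
    "exclusion_fixture",
    "attenuation_noise_sd",
]

# Observed per-flag exclusion rates in a cohort of 10,146 (counts 16, 1,
# 277, 312, 4). Sampled independently by default; the overlapping-union
# fixture lives in exclusion_fixture().
DEFAULT_EXCLUSION_RATES = {
    "thyroid_cancer": 16 / 10146,
    "kidney_cancer": 1 / 10146,
    "goiter": 277 / 10146,
    "thyroid_surgery": 312 / 10146,
    "missing_tsh_and_therapy": 4 / 10146,
}

# Log-normal TSH calibrated so that with a 5.05% levothyroxine rate the
# thyroid categories come out near hyper 1.7% / normal 88.5% / hypo 9.8%.
DEFAULT_TSH_PARAMS = (0.355, 0.596)


@dataclass
class LocusSpec:
    """One locus: lead-variant MAF, LD proxies and effect on ln(eGFRcrea)."""

    name: str
    maf: float
    beta_gfr: float = 0.0
    n_proxies: int = 0
    target_r2: float = 0.9
    chrom: str = "1"
    pos: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.name}: MAF {self.maf} outside (0, 0.5]")
        if not 0.0 < self.target_r2 <= 1.0:
            raise ValueError(f"{self.name}: target r^2 {self.target_r2} outside (0, 1]")
        if self.n_proxies < 0:
            raise ValueError("n_proxies must be >= 0")


@dataclass
class TraitSpec:
    """One quantitative trait: direct SNP path, outcome path, and noise.

    ``alpha_snp`` is the direct SNP->trait effect (applied to the lead
    dosage of ``locus``); ``delta_gfr`` the ln(eGFRcrea)->trait effect;
    ``noise_sd`` the independent Gaussian noise SD in trait units.
    """

    name: str
    alpha_snp: float = 0.0
    delta_gfr: float = 0.0
    noise_sd: float = 1.0
    locus: Optional[str] = None
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError(f"{self.name}: noise_sd must be > 0")

    @classmethod
    def for_attenuation(
        cls,
        name: str,
        locus: str,
        attenuated_fraction: float,
        delta_gfr: float = 1.0,
        y_noise_sd: float = 0.15,
        mean: float = 0.0,
    ) -> "TraitSpec":
        """Trait whose adjustment attenuates the SNP effect by a known fraction.

        With alpha_snp = 0 the step-2 attenuation of the SNP->outcome effect
        equals f = delta^2 s_u^2 / (delta^2 s_u^2 + s_e^2), where s_u is the
        outcome noise SD; solving for the trait noise gives
        s_e = |delta| * s_u * sqrt((1 - f) / f).
        """
        return cls(
            name=name,
            locus=locus,
            alpha_snp=0.0,
            delta_gfr=delta_gfr,
            noise_sd=attenuation_noise_sd(attenuated_fraction, delta_gfr, y_noise_sd),
            mean=mean,
        )


def attenuation_noise_sd(f: float, delta_gfr: float, y_noise_sd: float) -> float:
    """Trait noise SD giving step-2 attenuation f for an outcome-downstream trait."""
    if not 0.0 < f < 1.0:
        raise ValueError("attenuated fraction must be in (0, 1)")
    return abs(delta_gfr) * y_noise_sd * np.sqrt((1.0 - f) / f)


@dataclass
class GroundTruth:
    """All parameters of a synthetic cohort, with the generating seed."""

    n_individuals: int = 10146
    loci: list[LocusSpec] = field(default_factory=list)
    trait_specs: list[TraitSpec] = field(default_factory=list)
    interaction_gamma: float = 0.0
    interaction_locus: Optional[str] = None
    tsh_lognormal_params: tuple[float, float] = DEFAULT_TSH_PARAMS
    ft_measurement_thresholds: tuple[float, float] = (0.4, 3.8)
    exclusion_rates: dict = field(default_factory=lambda: dict(DEFAULT_EXCLUSION_RATES))
    seed: int = 0
    # cohort composition
    age_range: tuple[float, float] = (18.0, 80.0)
    female_rate: float = 0.551
    n_pcs: int = 10
    n_municipalities: int = 13
    # outcome model: ln(eGFRcrea) = intercept + age/sex terms + SNP terms + noise
    ln_egfr_intercept: float = 4.52
    age_slope: float = -0.003       # per year, on ln(eGFRcrea)
    female_effect: float = 0.02     # additive, on ln(eGFRcrea)
    y_noise_sd: float = 0.15
    # creatinine measurement process
    instrument_rates: dict = field(
        default_factory=lambda: {"roche": 4176 / 10146, "abbott": 5970 / 10146}
    )
    instrument_shifts: dict = field(
        default_factory=lambda: {"roche": 0.02, "abbott": -0.02}
    )
    n_periods: int = 8
    period_shift_sd: float = 0.01
    # thyroid medication rates
    levothyroxine_rate: float = 512 / 10146
    thiamazole_rate: float = 3 / 10146
    propylthiouracil_rate: float = 1 / 10146

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        low, high = self.ft_measurement_thresholds
        if not low < high:
            raise ValueError("FT measurement thresholds must satisfy low < high")
        if self.y_noise_sd <= 0:
            raise ValueError("y_noise_sd must be > 0")
        if not 0.0 < self.female_rate < 1.0:
            raise ValueError("female_rate outside (0, 1)")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("locus names must be unique")
        if self.interaction_locus is not None and self.interaction_locus not in names:
            raise ValueError(f"interaction locus {self.interaction_locus!r} not among loci")
        for t in self.trait_specs:
            if t.locus is not None and t.locus not in names:
                raise ValueError(f"trait {t.name}: unknown locus {t.locus!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_genotypes(
    maf: float,
    n_proxies: int,
    target_r2: float,
    n: int,
    seed,
    prefix: str = "sim",
    chrom: str = "1",
    pos: int = 1_000_000,
) -> DosageMatrix:
    """Simulate a lead variant and LD proxies for n individuals.

    The lead dosage is binomial(2, maf) under Hardy-Weinberg. Each proxy is
    built per haplotype by copy-with-mutation: the proxy allele copies the
    lead allele with probability q = sqrt(target_r2) and is otherwise
    redrawn as Bernoulli(maf), which makes the expected haplotype (and
    dosage) correlation q, i.e. r^2 = target_r2, while preserving MAF and
    HWE. target_r2 = 1 yields exact copies.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"MAF {maf} outside (0, 0.5]")
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError(f"target r^2 {target_r2} outside (0, 1]")
    if n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    q = float(np.sqrt(target_r2))
    hap_lead = rng.random((n, 2)) < maf  # two haplotypes per individual
    columns = [hap_lead.sum(axis=1).astype(float)]
    records = [
        VariantRecord(
            rsid=f"{prefix}_lead", chrom=chrom, pos=pos,
            effect_allele="A", other_allele="G", eaf=maf,
        )
    ]
    for k in range(n_proxies):
        copy = rng.random((n, 2)) < q
        novel = rng.random((n, 2)) < maf
        hap_proxy = np.where(copy, hap_lead, novel)
        columns.append(hap_proxy.sum(axis=1).astype(float))
        records.append(
            VariantRecord(
                rsid=f"{prefix}_p{k + 1}", chrom=chrom, pos=pos + 1000 * (k + 1),
                effect_allele="A", other_allele="G", eaf=maf,
            )
        )
    return DosageMatrix(values=np.column_stack(columns), variants=records)


def simulate_cohort(truth: GroundTruth) -> tuple[DosageMatrix, pd.DataFrame]:
    """Generate (dosages, phenotype table) from a :class:`GroundTruth`.

    The phenotype table carries sample_id, demographics, the creatinine
    measurement columns (scr, instrument, period), TSH/FT3/FT4, medication
    and exclusion flags, municipality, genetic PCs, and one column per
    trait spec. Regenerating with the same truth yields identical tables.
    """
    n = truth.n_individuals
    root = np.random.SeedSequence(truth.seed)
    seeds = root.spawn(len(truth.loci) + 1)
    rng = np.random.default_rng(seeds[0])

    # genotypes, locus by locus
    geno: Optional[DosageMatrix] = None
    lead_dosages: dict[str, np.ndarray] = {}
    lead_maf: dict[str, float] = {}
    for spec, seed in zip(truth.loci, seeds[1:]):
        block = simulate_genotypes(
            spec.maf, spec.n_proxies, spec.target_r2, n, seed,
            prefix=spec.name, chrom=spec.chrom, pos=spec.pos,
        )
        lead_dosages[spec.name] = block.values[:, 0]
        lead_maf[spec.name] = spec.maf
        geno = block if geno is None else geno.hstack(block)
    if geno is None:
        geno = DosageMatrix(values=np.empty((n, 0)), variants=[])

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    geno.sample_ids = sample_ids

    age = rng.uniform(*truth.age_range, size=n)
    female = rng.random(n) < truth.female_rate
    sex = np.where(female, "female", "male")
    pcs = rng.standard_normal((n, truth.n_pcs))
    municipality = np.array(
        [f"M{m + 1:02d}" for m in rng.integers(0, truth.n_municipalities, size=n)]
    )

    mu, sigma = truth.tsh_lognormal_params
    tsh = rng.lognormal(mean=mu, sigma=sigma, size=n)
    tsh_mean = float(np.exp(mu + sigma**2 / 2.0))

    levothyroxine = rng.random(n) < truth.levothyroxine_rate
    thiamazole = rng.random(n) < truth.thiamazole_rate
    propylthiouracil = rng.random(n) < truth.propylthiouracil_rate

    # outcome
    mid_age = float(np.mean(truth.age_range))
    ln_egfr = (
        truth.ln_egfr_intercept
        + truth.age_slope * (age - mid_age)
        + truth.female_effect * female
        + rng.normal(0.0, truth.y_noise_sd, size=n)
    )
    for spec in truth.loci:
        ln_egfr += spec.beta_gfr * (lead_dosages[spec.name] - 2.0 * spec.maf)
    if truth.interaction_gamma != 0.0 and truth.interaction_locus is not None:
        d_int = lead_dosages[truth.interaction_locus]
        ln_egfr += truth.interaction_gamma * d_int * (tsh - tsh_mean)

    egfr = np.exp(ln_egfr)
    scr_true = ckd_epi_2009_inverse(egfr, age, sex)

    # creatinine measurement: instrument fixed shifts + period random shifts
    inst_names = list(truth.instrument_rates)
    inst_p = np.array([truth.instrument_rates[k] for k in inst_names], dtype=float)
    inst_p = inst_p / inst_p.sum()
    instrument = rng.choice(inst_names, size=n, p=inst_p)
    periods = [f"P{j + 1}" for j in range(truth.n_periods)]
    period = rng.choice(periods, size=n)
    period_shift = dict(zip(periods, rng.normal(0.0, truth.period_shift_sd, truth.n_periods)))
    scr = (
        scr_true
        + np.array([truth.instrument_shifts[i] for i in instrument])
        + np.array([period_shift[p] for p in period])
    )
    scr = np.clip(scr, 0.05, None)

    low, high = truth.ft_measurement_thresholds
    ft_measured = (tsh < low) | (tsh > high)
    ft3 = np.where(ft_measured, rng.normal(3.0, 0.45, size=n), np.nan)
    ft4 = np.where(ft_measured, rng.normal(0.98, 0.16, size=n), np.nan)

    table = pd.DataFrame({
        "sample_id": sample_ids,
        "age": age,
        "sex": sex,
        "scr": scr,
        "instrument": instrument,
        "period": period,
        "tsh": tsh,
        "ft3": ft3,
        "ft4": ft4,
        "levothyroxine": levothyroxine,
        "thiamazole": thiamazole,
        "propylthiouracil": propylthiouracil,
        "municipality": municipality,
    })
    for flag, rate in truth.exclusion_rates.items():
        table[flag] = rng.random(n) < rate
    for j in range(truth.n_pcs):
        table[f"PC{j + 1}"] = pcs[:, j]

    ln_center = float(ln_egfr.mean())
    for t in truth.trait_specs:
        value = t.mean + rng.normal(0.0, t.noise_sd, size=n)
        if t.locus is not None and t.alpha_snp != 0.0:
            value = value + t.alpha_snp * (
                lead_dosages[t.locus] - 2.0 * lead_maf[t.locus]
            )
        if t.delta_gfr != 0.0:
            value = value + t.delta_gfr * (ln_egfr - ln_center)
        table[t.name] = value

    # true (unobserved) outcome, for recovery tests
    table["true_ln_egfr"] = ln_egfr
    return geno, table


def meta_summary_from_truth(
    truth: GroundTruth,
    n_meta: int = 500_000,
    var_y: Optional[float] = None,
    seed: Optional[int] = None,
) -> list[VariantRecord]:
    """GWAMA-style summary records for the lead variant of every locus.

    The meta effect is the true beta plus sampling noise at the precision a
    meta-analysis of ``n_meta`` individuals would achieve:
    SE = sd(y) / sqrt(2 n p (1-p)). Records are oriented to the generator's
    effect allele 'A'.
    """
    sd_y = float(np.sqrt(var_y)) if var_y is not None else truth.y_noise_sd
    rng = np.random.default_rng(truth.seed + 7 if seed is None else seed)
    from scipy import stats as _st

    records = []
    for spec in truth.loci:
        se = sd_y / np.sqrt(2.0 * n_meta * spec.maf * (1.0 - spec.maf))
        b = float(spec.beta_gfr + rng.normal(0.0, se))
        z = b / se
        records.append(
            VariantRecord(
                rsid=f"{spec.name}_lead", chrom=spec.chrom, pos=spec.pos,
                effect_allele="A", other_allele="G", eaf=spec.maf,
                b=b, se=float(se),
                p_two=float(2.0 * _st.norm.sf(abs(z))) or np.nextafter(0, 1),
                n=n_meta,
            )
        )
    return records


_TRAIT_NAMES = [
    "magnesium", "aptt", "urate", "sodium", "potassium", "calcium_corrected",
    "phosphate", "urinary_creatinine", "urinary_albumin", "uacr", "urine_ph",
    "homocysteine", "cortisol", "lipase", "sbp", "dbp", "pulse_rate", "bmi",
    "waist_hip_ratio", "glucose", "hba1c", "insulin", "cholesterol_total",
    "hdl", "ldl", "triglycerides", "ast", "alt", "ggt", "bilirubin_total",
    "albumin_serum", "total_protein", "crp", "ferritin", "transferrin",
    "iron", "hemoglobin", "hematocrit", "rbc_count", "wbc_count",
    "platelet_count", "mcv", "mch", "mchc", "neutrophils", "lymphocytes",
    "monocytes", "eosinophils", "basophils", "fibrinogen", "pt_inr",
    "amylase", "ck", "ldh", "alp", "folate", "vitamin_b12", "vitamin_d",
    "tsh_repeat", "uric_volume", "chloride", "bicarbonate", "osmolality",
    "creatine_kinase_mb", "troponin", "nt_probnp", "apolipoprotein_a1",
    "apolipoprotein_b", "lipoprotein_a", "leptin",
]


def default_trait_specs(n_traits: int = 70) -> list[TraitSpec]:
    """A panel of ``n_traits`` independent-noise traits with field-typical names.

    All effects default to zero (pure noise); callers attach mediation
    structure by replacing individual entries.
    """
    names = list(_TRAIT_NAMES)
    k = 1
    while len(names) < n_traits:
        names.append(f"biomarker_{k:02d}")
        k += 1
    return [TraitSpec(name=nm) for nm in names[:n_traits]]


def exclusion_fixture(n: int = 10146) -> pd.DataFrame:
    """Exclusion flags with realistic overlap: per-flag counts 312 (thyroid
    surgery), 277 (goiter), 16 (thyroid cancer), 1 (kidney cancer), 4
    (missing TSH+therapy), overlapping so the union is exactly 416.
    """
    if n < 416:
        raise ValueError("fixture needs n >= 416")
    flags = pd.DataFrame(
        False,
        index=range(n),
        columns=list(DEFAULT_EXCLUSION_RATES),
    )
    flags.loc[0:311, "thyroid_surgery"] = True          # 312
    flags.loc[139:415, "goiter"] = True                 # 277, overlap 173
    flags.loc[0:15, "thyroid_cancer"] = True            # 16
    flags.loc[0:0, "kidney_cancer"] = True              # 1
    flags.loc[412:415, "missing_tsh_and_therapy"] = True  # 4
    return flags
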