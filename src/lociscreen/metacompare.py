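"""Cohort vs meta-analysis effect comparison.

Two pieces of algebra: (1) leave-cohort-out subtraction — removing one
cohort's contribution from fixed-effect inverse-variance meta-analysis
summary statistics, used to guarantee sample independence when the cohort
was part of the meta-analysis; (2) per-variant explained variance,
b^2 * 2p(1-p) / var(y), used to put cohort and meta effects on a common
scale together with effect and MAF ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import VariantRecord

__all__ = [
    "meta_subtract",
    "meta_subtract_samplesize",
    "variance_explained",
    "compare_cohorts",
    "CohortComparison",
]


def meta_subtract(
    b_meta: float, se_meta: float, b_cohort: float, se_cohort: float
) -> tuple[float, float]:
    """Remove a cohort from fixed-effect inverse-variance meta statistics.

    With weights w = 1/SE^2, the leave-one-out estimate is

        w' = w_meta - w_cohort
        b' = (b_meta * w_meta - b_cohort * w_cohort) / w'
        SE' = w'^(-1/2)

    Requires the meta-analysis to carry more information than the cohort
    (w_meta > w_cohort); otherwise subtraction is infeasible.
    """
    if se_meta <= 0 or se_cohort <= 0:
        raise ValueError("standard errors must be > 0")
    w_meta = se_meta**-2
    w_cohort = se_cohort**-2
    w_loo = w_meta - w_cohort
    if w_loo <= 0:
        raise ValueError(
            "meta-analysis carries no more information than the cohort: "
            f"1/SE_meta^2={w_meta:.4g} <= 1/SE_cohort^2={w_cohort:.4g}"
        )
    b_loo = (b_meta * w_meta - b_cohort * w_cohort) / w_loo
    return float(b_loo), float(w_loo**-0.5)


def meta_subtract_samplesize(
    z_meta: float, n_meta: float, z_cohort: float, n_cohort: float
) -> tuple[float, float]:
    """Sample-size-weighted leave-one-out subtraction for z-score-only input.

    Returns (z_loo, n_loo) under the sqrt(n)-weighted z-combination
    z_meta = (sqrt(n_c) z_c + sqrt(n_loo) z_loo) / sqrt(n_meta).
    """
    n_loo = n_meta - n_cohort
    if n_loo <= 0:
        raise ValueError("cohort sample size must be smaller than the meta sample size")
    z_loo = (z_meta * np.sqrt(n_meta) - z_cohort * np.sqrt(n_cohort)) / np.sqrt(n_loo)
    return float(z_loo), float(n_loo)


def variance_explained(b: float, eaf: float, var_y: float) -> float:
    """Fraction of outcome variance explained by a variant: b^2 2p(1-p)/var(y)."""
    if not 0.0 < eaf < 1.0:
        raise ValueError("EAF outside (0, 1)")
    if var_y <= 0:
        raise ValueError("var(y) must be > 0")
    return float(b * b * 2.0 * eaf * (1.0 - eaf) / var_y)


@dataclass
class CohortComparison:
    """Effect/MAF ratios and explained variance for one locus, cohort vs meta."""

    locus_name: str
    b_cohort: float
    b_meta: float
    se_cohort: float
    se_meta: float
    eaf_cohort: float
    eaf_meta: float
    effect_ratio: Optional[float]
    maf_ratio: Optional[float]
    var_explained_cohort: float
    var_explained_meta: float


def compare_cohorts(
    cohort: VariantRecord,
    meta: VariantRecord,
    var_y: float,
    locus_name: Optional[str] = None,
) -> CohortComparison:
    """Effect ratio, MAF ratio, and explained variance, cohort vs meta.

    Records must already be harmonized to the same effect allele. MAF ratios
    use min(EAF, 1-EAF). A zero meta effect leaves the effect ratio None.
    """
    for rec, label in ((cohort, "cohort"), (meta, "meta")):
        if rec.b is None or rec.se is None or rec.eaf is None:
            raise ValueError(f"{label} record must carry b, se and eaf")
    effect_ratio = None if meta.b == 0 else cohort.b / meta.b
    maf_ratio = None if meta.maf == 0 else cohort.maf / meta.maf
    return CohortComparison(
        locus_name=locus_name or cohort.rsid,
        b_cohort=cohort.b,
        b_meta=meta.b,
        se_cohort=cohort.se,
        se_meta=meta.se,
        eaf_cohort=cohort.eaf,
        eaf_meta=meta.eaf,
        effect_ratio=None if effect_ratio is None else float(effect_ratio),
        maf_ratio=None if maf_ratio is None else float(maf_ratio),
        var_explained_cohort=variance_explained(cohort.b, cohort.eaf, var_y),
        var_explained_meta=variance_explained(meta.b, meta.eaf, var_y),
    )
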