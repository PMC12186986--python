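"""SNP-by-thyroid-function interaction analysis.

After excluding individuals with thyroid/kidney conditions that could
confound thyroid phenotypes (thyroid cancer, kidney cancer, goiter, thyroid
surgery, or jointly missing TSH and therapy information), each variant is
tested for effect-measure modification by thyroid function:

* a continuous model  ln(eGFRcrea) ~ SNP + TSH + SNP*TSH + covariates, and
* categorical contrasts against broadly defined hyper-/hypothyroidism
  (hyperthyroid: TSH < 0.4 uUI/mL or antithyroid drug; hypothyroid:
  TSH > 3.8 uUI/mL or levothyroxine).

Significance is Bonferroni-corrected for the number of tested loci
(0.05/11 = 0.0045 by default). Two sensitivity checks guard against
missing-by-design artifacts (FT3/FT4 are only measured at extreme TSH):
a genotype-vs-measured-flag rank-sum test and municipality adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "apply_exclusions",
    "classify_thyroid",
    "fit_interaction_continuous",
    "fit_interaction_categorical",
    "interaction_significant",
    "predict_at_tsh_levels",
    "missingness_genotype_check",
    "InteractionResult",
    "ThyroidStatus",
    "EXCLUSION_FLAGS",
    "TSH_LOW",
    "TSH_HIGH",
]

TSH_LOW = 0.4   # uUI/mL; below -> hyperthyroid
TSH_HIGH = 3.8  # uUI/mL; above -> hypothyroid

EXCLUSION_FLAGS = (
    "thyroid_cancer",
    "kidney_cancer",
    "goiter",
    "thyroid_surgery",
    "missing_tsh_and_therapy",
)

ANTITHYROID_DRUGS = ("thiamazole", "propylthiouracil")
DEFAULT_N_LOCI_INTERACTION = 11


def apply_exclusions(
    cohort: pd.DataFrame,
    flags: Sequence[str] = EXCLUSION_FLAGS,
) -> tuple[pd.DataFrame, dict]:
    """Drop individuals with any exclusion flag set.

    Returns the filtered table and a report with per-flag counts, the size
    of the union, and the remaining sample size. Flags may overlap, so the
    union can be smaller than the sum of the per-flag counts.
    """
    flags = [f for f in flags if f in cohort.columns]
    if not flags:
        raise ValueError("no exclusion-flag column found in the cohort table")
    flagged = cohort[flags].fillna(False).astype(bool)
    union = flagged.any(axis=1)
    report = {f: int(flagged[f].sum()) for f in flags}
    report["excluded_union"] = int(union.sum())
    report["n_before"] = int(len(cohort))
    report["n_after"] = int((~union).sum())
    out = cohort.loc[~union].copy()
    if out.empty:
        warnings.warn("all individuals excluded")
    return out, report


@dataclass
class ThyroidStatus:
    """Per-individual thyroid-function category and the basis of the call."""

    category: np.ndarray  # 'hyperthyroid' | 'normal' | 'hypothyroid'
    basis: np.ndarray     # 'medication' | 'tsh_threshold'


def classify_thyroid(
    tsh,
    levothyroxine=None,
    thiamazole=None,
    propylthiouracil=None,
    tsh_low: float = TSH_LOW,
    tsh_high: float = TSH_HIGH,
) -> ThyroidStatus:
    """Classify thyroid function from TSH and medication use.

    Hyperthyroid: antithyroid drug (thiamazole/propylthiouracil) or
    TSH < tsh_low. Hypothyroid: levothyroxine or TSH > tsh_high. Medication
    dominates TSH; thresholds are strict, so TSH exactly at a threshold is
    normal. An individual with missing TSH and no medication flag is
    unclassifiable and raises.
    """
    tsh = np.asarray(tsh, dtype=float)
    n = tsh.shape[0]

    def _flag(x):
        if x is None:
            return np.zeros(n, dtype=bool)
        return np.asarray(pd.Series(x).fillna(False), dtype=bool)

    levo = _flag(levothyroxine)
    anti = _flag(thiamazole) | _flag(propylthiouracil)
    any_med = levo | anti
    if (~np.isfinite(tsh) & ~any_med).any():
        raise ValueError("individuals with missing TSH and no medication flag are unclassifiable")

    category = np.full(n, "normal", dtype=object)
    basis = np.full(n, "tsh_threshold", dtype=object)
    with np.errstate(invalid="ignore"):
        category[tsh < tsh_low] = "hyperthyroid"
        category[tsh > tsh_high] = "hypothyroid"
    category[levo] = "hypothyroid"
    category[anti] = "hyperthyroid"
    basis[any_med] = "medication"
    return ThyroidStatus(category=category.astype(str), basis=basis.astype(str))


@dataclass
class InteractionResult:
    """One fitted interaction model (continuous TSH or a categorical contrast)."""

    rsid: str
    model: str  # 'continuous_tsh' | 'hyper_vs_normal' | 'hypo_vs_normal'
    b_snp: float
    b_env: float
    b_interaction: float
    se_interaction: float
    p_interaction: float
    n: int
    env_mean: Optional[float] = None
    env_sd: Optional[float] = None
    # covariance of (b_snp, b_interaction) for delta-method slope CIs
    cov_snp_inter: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))


def _cov_cols(covariates) -> list[np.ndarray]:
    if covariates is None:
        return []
    cov = pd.DataFrame(covariates)
    cols = []
    for name in cov.columns:
        col = cov[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=str(name), drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    return cols


def _fit_product_model(y, d, env, covariates, rsid, model_name) -> InteractionResult:
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    env = np.asarray(env, dtype=float)
    cols = [d, env, d * env] + _cov_cols(covariates)
    X = np.column_stack([np.ones(len(y))] + cols)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    if X.shape[0] <= X.shape[1] + 3:
        raise ValueError("too few complete cases for the interaction model")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("interaction design is rank-deficient")
    fit = sm.OLS(y, X).fit()
    cov = fit.cov_params()
    return InteractionResult(
        rsid=rsid,
        model=model_name,
        b_snp=float(fit.params[1]),
        b_env=float(fit.params[2]),
        b_interaction=float(fit.params[3]),
        se_interaction=float(fit.bse[3]),
        p_interaction=float(fit.pvalues[3]),
        n=int(mask.sum()),
        env_mean=float(env[mask].mean()) if model_name == "continuous_tsh" else None,
        env_sd=float(env[mask].std(ddof=1)) if model_name == "continuous_tsh" else None,
        cov_snp_inter=np.asarray(cov)[np.ix_([1, 3], [1, 3])],
    )


def fit_interaction_continuous(y, dosage, tsh, covariates=None, rsid: str = "") -> InteractionResult:
    """OLS of ln(eGFRcrea) on SNP, TSH, SNP*TSH and covariates.

    TSH enters untransformed; pass log-TSH explicitly for the log variant.
    The interaction coefficient, SE and two-sided p are reported; its t-test
    is invariant to mean-centering of TSH.
    """
    return _fit_product_model(y, dosage, tsh, covariates, rsid, "continuous_tsh")


def fit_interaction_categorical(
    y,
    dosage,
    status: ThyroidStatus,
    covariates=None,
    rsid: str = "",
) -> list[InteractionResult]:
    """Pairwise contrasts of hyper- and hypothyroidism against normal.

    Each contrast fits a separate model on the two relevant categories with
    a 0/1 indicator, its product with dosage, and the covariates. An empty
    stratum skips that contrast with a warning.
    """
    cat = np.asarray(status.category)
    results = []
    for level, model_name in (("hyperthyroid", "hyper_vs_normal"), ("hypothyroid", "hypo_vs_normal")):
        if (cat == level).sum() == 0 or (cat == "normal").sum() == 0:
            warnings.warn(f"empty stratum for contrast {model_name}; skipped")
            continue
        keep = (cat == level) | (cat == "normal")
        indicator = (cat[keep] == level).astype(float)
        cov = None if covariates is None else pd.DataFrame(covariates).loc[keep]
        results.append(
            _fit_product_model(
                np.asarray(y, dtype=float)[keep],
                np.asarray(dosage, dtype=float)[keep],
                indicator,
                cov,
                rsid,
                model_name,
            )
        )
    return results


def interaction_significant(
    p_interaction: float, n_loci: int = DEFAULT_N_LOCI_INTERACTION, alpha: float = 0.05
) -> bool:
    """True iff p < alpha/n_loci (strict), 0.05/11 = 0.0045 by default."""
    return bool(p_interaction < alpha / n_loci)


def predict_at_tsh_levels(
    fit: InteractionResult,
    levels: Optional[Sequence[float]] = None,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Per-allele SNP slopes at chosen TSH levels with delta-method CIs.

    At TSH level t the slope is b_snp + b_interaction * t, with variance
    Var(b_snp) + t^2 Var(b_int) + 2t Cov. Default levels are the fitted
    sample's mean - SD, mean, mean + SD. With b_interaction = 0 the three
    slopes coincide (parallel prediction lines).
    """
    if levels is None:
        if fit.env_mean is None or fit.env_sd is None:
            raise ValueError("fit carries no TSH mean/SD; supply levels explicitly")
        m, s = fit.env_mean, fit.env_sd
        levels = [m - s, m, m + s]
    zcrit = stats.norm.ppf(0.5 + ci / 2.0)
    V = fit.cov_snp_inter
    rows = []
    for t in levels:
        slope = fit.b_snp + fit.b_interaction * t
        var = V[0, 0] + t * t * V[1, 1] + 2.0 * t * V[0, 1]
        se = float(np.sqrt(max(var, 0.0)))
        rows.append({
            "tsh_level": float(t),
            "snp_slope": float(slope),
            "se": se,
            "ci_low": float(slope - zcrit * se),
            "ci_high": float(slope + zcrit * se),
        })
    return pd.DataFrame(rows)


def missingness_genotype_check(dosage, measured_flag) -> float:
    """Two-sided Wilcoxon rank-sum p comparing genotype dosages between
    individuals with and without measured FT3/FT4.

    Uses the exact distribution for small samples without ties and the
    normal approximation with continuity correction otherwise.
    """
    d = np.asarray(dosage, dtype=float)
    flag = np.asarray(pd.Series(measured_flag).fillna(False), dtype=bool)
    a, b = d[flag], d[~flag]
    if a.size == 0 or b.size == 0:
        raise ValueError("both measured and unmeasured groups must be non-empty")
    method = "exact" if (a.size <= 50 and b.size <= 50) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)
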