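"""Four-step mediation screen across a panel of quantitative traits.

For each (variant, trait) pair, four linear models are fitted, all adjusted
for age, sex, the first 10 genetic PCs and an intercept:

  step 1:  ln(eGFRcrea) ~ SNP                      -> b1  (total effect)
  step 2:  ln(eGFRcrea) ~ SNP + trait              -> b2  (trait-adjusted)
  step 3:  trait        ~ SNP                      -> b3  (SNP-trait path)
  step 4:  trait        ~ SNP + ln(eGFRcrea)       -> b4  (outcome-adjusted)

A trait qualifies as a (at least partial) mediator of a variant when two
criteria hold: (i) adjusting for the trait substantially alters the SNP
effect on the outcome, operationalized as b2 being an outlier of the b2
distribution across the whole trait panel under a stringent variant of
Tukey's rule (bounds P10 - 1.5*IQR and P90 + 1.5*IQR); and (ii) the SNP is
associated with the trait (step 3) at the multiple-testing-corrected level
alpha / (n_traits * n_loci), by default 0.05/(70*11) = 6.5e-5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .types import DosageMatrix

__all__ = [
    "run_four_steps",
    "percent_change",
    "stringent_tukey_outlier",
    "stringent_tukey_bounds",
    "classify_mediator",
    "run_mediation_screen",
    "mediation_threshold",
    "MediationResult",
    "DEFAULT_N_TRAITS",
    "DEFAULT_N_LOCI_MEDIATION",
]

DEFAULT_N_TRAITS = 70
DEFAULT_N_LOCI_MEDIATION = 11
MIN_PANEL_SIZE = 10


def mediation_threshold(
    alpha: float = 0.05,
    n_traits: int = DEFAULT_N_TRAITS,
    n_loci: int = DEFAULT_N_LOCI_MEDIATION,
) -> float:
    """Step-3 significance threshold alpha / (n_traits * n_loci)."""
    return alpha / (n_traits * n_loci)


@dataclass
class MediationResult:
    """Estimates of the four mediation models for one (variant, trait) pair."""

    locus_name: str
    rsid: str
    trait_name: str
    b1: float
    se1: float
    p1: float
    b2: float
    se2: float
    p2: float
    gamma2: float
    b3: float
    se3: float
    p3: float
    b4: float
    se4: float
    p4: float
    delta4: float
    pct_change: Optional[float] = None
    outlier_flag: Optional[bool] = None
    step3_significant: Optional[bool] = None
    mediator_status: str = "none"


def _ols(y: np.ndarray, X_cols: list[np.ndarray]):
    """Complete-case OLS; returns the statsmodels results object."""
    X = np.column_stack([np.ones(len(y))] + X_cols)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    if mask.sum() <= X.shape[1] + 1:
        raise ValueError("too few complete cases for a mediation model")
    return sm.OLS(y[mask], X[mask]).fit()


def _covariate_columns(covariates) -> list[np.ndarray]:
    if covariates is None:
        return []
    cov = pd.DataFrame(covariates)
    cols: list[np.ndarray] = []
    for name in cov.columns:
        col = cov[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=str(name), drop_first=True)
            cols.extend(dummies[c].to_numpy(dtype=float) for c in dummies.columns)
        else:
            cols.append(col.to_numpy(dtype=float))
    return cols


def run_four_steps(
    y,
    dosage,
    trait,
    covariates=None,
    locus_name: str = "",
    rsid: str = "",
    trait_name: str = "",
) -> MediationResult:
    """Fit the four mediation models for one (variant, trait) pair.

    Each model is a complete-case OLS fit; sample sizes may differ across
    steps when the trait has missing values. A constant trait raises.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosage, dtype=float)
    t = np.asarray(trait, dtype=float)
    obs = t[np.isfinite(t)]
    if obs.size == 0 or np.ptp(obs) == 0.0:
        raise ValueError(f"trait {trait_name or '<unnamed>'} is constant or all-missing")
    cov = _covariate_columns(covariates)

    f1 = _ols(y, [d] + cov)
    f2 = _ols(y, [d, t] + cov)
    f3 = _ols(t, [d] + cov)
    f4 = _ols(t, [d, y] + cov)

    b1 = float(f1.params[1])
    res = MediationResult(
        locus_name=locus_name,
        rsid=rsid,
        trait_name=trait_name,
        b1=b1, se1=float(f1.bse[1]), p1=float(f1.pvalues[1]),
        b2=float(f2.params[1]), se2=float(f2.bse[1]), p2=float(f2.pvalues[1]),
        gamma2=float(f2.params[2]),
        b3=float(f3.params[1]), se3=float(f3.bse[1]), p3=float(f3.pvalues[1]),
        b4=float(f4.params[1]), se4=float(f4.bse[1]), p4=float(f4.pvalues[1]),
        delta4=float(f4.params[2]),
    )
    if b1 != 0.0:
        res.pct_change = percent_change(b1, res.b2)
    return res


def percent_change(b1: float, b2: float) -> float:
    """Relative change of the SNP effect upon trait adjustment: 100*(b2-b1)/b1.

    Full precision is kept; round to the nearest integer for display.
    """
    if b1 == 0.0:
        raise ValueError("percent change undefined for b1 = 0")
    return float(100.0 * (b2 - b1) / b1)


def stringent_tukey_bounds(panel) -> tuple[float, float]:
    """Outlier bounds [P10 - 1.5*IQR, P90 + 1.5*IQR] over a panel of b2 values.

    Percentiles use linear interpolation (numpy's default, quantile type 7);
    IQR = P75 - P25. The panel must have at least 10 values for the
    percentiles to be stable.
    """
    panel = np.asarray(panel, dtype=float)
    panel = panel[np.isfinite(panel)]
    if panel.size < MIN_PANEL_SIZE:
        raise ValueError(
            f"stringent Tukey rule needs a panel of >= {MIN_PANEL_SIZE} values, got {panel.size}"
        )
    p10, p25, p75, p90 = np.percentile(panel, [10, 25, 75, 90])
    iqr = p75 - p25
    return float(p10 - 1.5 * iqr), float(p90 + 1.5 * iqr)


def stringent_tukey_outlier(b2_panel, b2_value: float) -> bool:
    """Flag a trait-adjusted effect as an outlier of the panel distribution.

    ``b2_panel`` is the distribution of b2 across all traits for one variant
    (the tested value included). True iff the value falls strictly outside
    [P10 - 1.5*IQR, P90 + 1.5*IQR].
    """
    lo, hi = stringent_tukey_bounds(b2_panel)
    return bool(b2_value < lo or b2_value > hi)


def classify_mediator(
    outlier_flag: bool,
    p3: float,
    alpha: float = 0.05,
    n_traits: int = DEFAULT_N_TRAITS,
    n_loci: int = DEFAULT_N_LOCI_MEDIATION,
) -> str:
    """'partial_mediator' iff both criteria hold: b2 outlier AND step-3 p
    below alpha/(n_traits*n_loci) (strict); otherwise 'none'."""
    if outlier_flag and p3 < mediation_threshold(alpha, n_traits, n_loci):
        return "partial_mediator"
    return "none"


def run_mediation_screen(
    cohort: pd.DataFrame,
    dosages: DosageMatrix,
    trait_cols: Sequence[str],
    covariate_cols: Sequence[str],
    y_col: str = "ln_egfr",
    locus_of: Optional[dict] = None,
    n_traits: Optional[int] = None,
    n_loci: int = DEFAULT_N_LOCI_MEDIATION,
    alpha: float = 0.05,
) -> list[MediationResult]:
    """Run the full mediation screen: every variant against every trait.

    For each variant the four models are fitted per trait, the b2 panel is
    assembled across the whole trait panel, outliers are flagged with the
    stringent Tukey rule, and traits are classified with the two-criterion
    rule. ``locus_of`` maps rsid -> locus name for reporting. ``n_traits``
    for the step-3 Bonferroni correction defaults to the number of traits
    actually screened. Constant traits are skipped with a warning.
    """
    y = cohort[y_col].to_numpy(dtype=float)
    cov = cohort[list(covariate_cols)]
    locus_of = locus_of or {}
    if n_traits is None:
        n_traits = len(trait_cols)
    results: list[MediationResult] = []
    for j, variant in enumerate(dosages.variants):
        d = dosages.values[:, j]
        per_variant: list[MediationResult] = []
        for trait_name in trait_cols:
            try:
                res = run_four_steps(
                    y, d, cohort[trait_name].to_numpy(dtype=float), cov,
                    locus_name=locus_of.get(variant.rsid, ""),
                    rsid=variant.rsid, trait_name=trait_name,
                )
            except ValueError as exc:
                warnings.warn(f"skipping trait {trait_name} for {variant.rsid}: {exc}")
                continue
            per_variant.append(res)
        if not per_variant:
            continue
        panel = np.array([r.b2 for r in per_variant])
        if panel.size >= MIN_PANEL_SIZE:
            for res in per_variant:
                res.outlier_flag = stringent_tukey_outlier(panel, res.b2)
        else:
            warnings.warn(
                f"{variant.rsid}: b2 panel of {panel.size} < {MIN_PANEL_SIZE}; "
                "outlier rule not applied"
            )
        threshold = mediation_threshold(alpha, n_traits, n_loci)
        for res in per_variant:
            res.step3_significant = bool(res.p3 < threshold)
            if res.outlier_flag is not None:
                res.mediator_status = (
                    "partial_mediator"
                    if (res.outlier_flag and res.step3_significant)
                    else "none"
                )
        results.extend(per_variant)
    return results


def results_to_frame(results: Sequence[MediationResult]) -> pd.DataFrame:
    """Long-format table: one row per (locus, variant, trait)."""
    rows = []
    for r in results:
        rows.append({
            "locus": r.locus_name, "rsid": r.rsid, "trait": r.trait_name,
            "b1": r.b1, "se1": r.se1, "p1": r.p1,
            "b2": r.b2, "se2": r.se2, "p2": r.p2, "gamma2": r.gamma2,
            "pct_change": None if r.pct_change is None else round(r.pct_change),
            "b3": r.b3, "se3": r.se3, "p3": r.p3,
            "b4": r.b4, "se4": r.se4, "p4": r.p4, "delta4": r.delta4,
            "outlier": r.outlier_flag,
            "step3_significant": r.step3_significant,
            "mediator_status": r.mediator_status,
        })
    return pd.DataFrame(rows)
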