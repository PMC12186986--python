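"""Locus re-association in a single cohort.

Known loci from a GWAS meta-analysis (GWAMA) are re-tested in the cohort with
covariate-adjusted linear regression on allelic dosage. Because the expected
effect direction is known from the GWAMA, significance uses one-sided tests
at the Bonferroni level alpha/n_loci. Proxies in strong LD (r^2 > 0.8) with
each lead variant are carried along, after harmonizing alleles to the GWAMA
effect allele. Genomic control (lambda) and the effective-number-of-tests
eigenvalue criterion are provided as diagnostics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.linalg import qr

from .types import DosageMatrix, VariantRecord

__all__ = [
    "residualize_outcome",
    "fit_snp_model",
    "one_sided_p",
    "two_sided_from_one",
    "ld_r2",
    "harmonize_to_meta",
    "select_proxies",
    "associate_locus",
    "locus_significant",
    "effective_test_coverage",
    "genomic_lambda",
    "LocusResult",
    "DEFAULT_N_LOCI",
]

logger = logging.getLogger(__name__)

DEFAULT_N_LOCI = 147
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


def residualize_outcome(ln_egfr, age, sex) -> np.ndarray:
    """Residuals of ln(eGFRcrea) regressed on age and sex (mean zero)."""
    y = np.asarray(ln_egfr, dtype=float)
    female = np.asarray(pd.get_dummies(pd.Series(sex), drop_first=True), dtype=float)
    if female.size == 0:  # single-level sex: only adjust for age
        X = np.column_stack([np.ones_like(y), np.asarray(age, dtype=float)])
    else:
        X = np.column_stack([np.ones_like(y), np.asarray(age, dtype=float), female])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _design(dosage: np.ndarray, covariates) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(dosage), dosage]
    names = ["const", "dosage"]
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            col = cov[name]
            if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=str(name), drop_first=True)
                for dname in dummies.columns:
                    cols.append(dummies[dname].to_numpy(dtype=float))
                    names.append(str(dname))
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(str(name))
    return np.column_stack(cols), names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR with column pivoting: columns pivoted beyond the rank are the
        # linearly dependent ones.
        _, _, piv = qr(X, mode="economic", pivoting=True)
        offenders = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank-deficient; collinear column(s): {offenders}")


def fit_snp_model(y, dosage, covariates=None) -> tuple[float, float, float]:
    """OLS of the outcome on allelic dosage plus covariates.

    Returns the dosage slope, its standard error and the two-sided p-value
    from the t distribution with residual degrees of freedom. Categorical
    covariate columns are dummy-expanded. Complete cases only.
    """
    y = np.asarray(y, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    X, names = _design(dosage, covariates)
    mask = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[mask], X[mask]
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("too few complete cases for the model")
    if np.ptp(X[:, 1]) == 0.0:
        raise ValueError("dosage column is constant")
    _check_rank(X, names)
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def one_sided_p(b: float, se: float, expected_sign) -> float:
    """One-sided normal p-value for an effect with a known expected direction.

    ``expected_sign`` is '+'/'-' (or +-1), the GWAMA direction after allele
    harmonization. Effects in the expected direction give p < 0.5; effects in
    the wrong direction give p > 0.5 rather than being mirrored.
    """
    if se <= 0:
        raise ValueError("SE must be > 0")
    sgn = {"-": -1.0, "+": 1.0}.get(expected_sign, None)
    if sgn is None:
        sgn = float(np.sign(expected_sign))
    if sgn == 0:
        raise ValueError("expected_sign must be nonzero")
    z = b / se
    return float(stats.norm.cdf(-sgn * z))


def two_sided_from_one(p_one: float) -> float:
    """Two-sided p from a one-sided p: 2*p for in-direction effects.

    For wrong-direction effects (p_one > 0.5) returns 2*(1 - p_one) with a
    warning, so the value remains a valid two-sided p.
    """
    if not 0.0 < p_one <= 1.0:
        raise ValueError("p_one outside (0, 1]")
    if p_one > 0.5:
        warnings.warn("one-sided p > 0.5: effect is in the unexpected direction")
        return 2.0 * (1.0 - p_one)
    return 2.0 * p_one


def ld_r2(dosage_i, dosage_j) -> float:
    """Squared Pearson correlation between two dosage vectors."""
    x = np.asarray(dosage_i, dtype=float)
    y = np.asarray(dosage_j, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 2:
        raise ValueError("need >= 2 shared non-missing genotypes")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise ValueError("LD undefined for a constant dosage column")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def harmonize_to_meta(
    cohort_variant: VariantRecord,
    dosage: np.ndarray,
    meta_variant: VariantRecord,
) -> Optional[tuple[VariantRecord, np.ndarray]]:
    """Align a cohort variant's dosage to the GWAMA effect allele.

    Returns the (possibly flipped) record and dosage, or None when the
    variant cannot be harmonized: allele mismatch, or a strand-ambiguous
    (A/T, C/G) pair whose MAF is in [0.4, 0.5] so frequency cannot resolve
    the strand.
    """
    ea, oa = meta_variant.effect_allele, meta_variant.other_allele
    cea, coa = cohort_variant.effect_allele, cohort_variant.other_allele
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}

    def _oriented(flip: bool):
        if flip:
            return cohort_variant.flipped(), 2.0 - np.asarray(dosage, dtype=float)
        return cohort_variant, np.asarray(dosage, dtype=float)

    if cohort_variant.is_strand_ambiguous():
        maf = cohort_variant.maf
        meta_maf = meta_variant.maf
        if maf is None or meta_maf is None or maf >= 0.4:
            logger.warning("dropping unresolvable strand-ambiguous variant %s", cohort_variant.rsid)
            return None
        # frequency matching: orient so the cohort EAF sits on the same side
        # of 0.5 as the GWAMA EAF
        same_side = (cohort_variant.eaf < 0.5) == (meta_variant.eaf < 0.5)
        return _oriented(flip=not same_side)

    if (cea, coa) == (ea, oa):
        return _oriented(flip=False)
    if (cea, coa) == (oa, ea):
        return _oriented(flip=True)
    # strand flip (non-ambiguous pairs only)
    if (comp.get(cea), comp.get(coa)) == (ea, oa):
        return _oriented(flip=False)
    if (comp.get(cea), comp.get(coa)) == (oa, ea):
        return _oriented(flip=True)
    logger.warning(
        "allele mismatch for %s: cohort %s/%s vs meta %s/%s",
        cohort_variant.rsid, cea, coa, ea, oa,
    )
    return None


@dataclass
class LocusResult:
    """A locus' lead GWAMA variant, retained LD proxies and test outcome."""

    locus_name: str
    lead: VariantRecord
    proxies: list[VariantRecord] = field(default_factory=list)
    proxy_r2: list[float] = field(default_factory=list)
    dosages: Optional[DosageMatrix] = None
    best_cohort_variant: Optional[VariantRecord] = None
    significant: Optional[bool] = None

    @property
    def min_p_one(self) -> Optional[float]:
        ps = [v.p_one for v in self.proxies if v.p_one is not None]
        return min(ps) if ps else None


def select_proxies(
    lead: VariantRecord,
    candidates: Sequence[VariantRecord],
    dosages: DosageMatrix,
    meta_records: Optional[dict] = None,
    r2_min: float = 0.8,
    maf_min: float = 0.005,
    locus_name: Optional[str] = None,
) -> LocusResult:
    """Retain candidates in strong LD (r^2 > r2_min, strict) with the lead.

    Candidates with cohort MAF < maf_min are removed. Each retained dosage is
    harmonized to the GWAMA effect allele: ``meta_records`` maps rsid to the
    GWAMA :class:`VariantRecord`; the lead's own record is always used for
    the lead. Raises ``KeyError`` when the lead is absent from the cohort.
    """
    meta_records = dict(meta_records or {})
    meta_records.setdefault(lead.rsid, lead)
    rsid_to_idx = {v.rsid: j for j, v in enumerate(dosages.variants)}
    if lead.rsid not in rsid_to_idx:
        raise KeyError(f"lead variant {lead.rsid} not found in cohort dosages")

    lead_h = harmonize_to_meta(
        dosages.variants[rsid_to_idx[lead.rsid]],
        dosages.values[:, rsid_to_idx[lead.rsid]],
        lead,
    )
    if lead_h is None:
        raise ValueError(f"lead variant {lead.rsid} could not be harmonized")
    _, lead_dos = lead_h

    kept, kept_dos, kept_r2 = [], [], []
    for cand in candidates:
        j = rsid_to_idx.get(cand.rsid)
        if j is None:
            continue
        rec, dos = cand, dosages.values[:, j]
        meta = meta_records.get(cand.rsid)
        if meta is not None:
            out = harmonize_to_meta(rec, dos, meta)
            if out is None:
                continue
            rec, dos = out
        elif np.ptp(dos) > 0 and np.ptp(lead_dos) > 0 and np.corrcoef(lead_dos, dos)[0, 1] < 0:
            # no GWAMA record for this proxy: orient it with the lead so the
            # expected one-sided direction carries over
            rec, dos = rec.flipped(), 2.0 - dos
        eaf = float(dos.mean() / 2.0)
        if min(eaf, 1.0 - eaf) < maf_min:
            continue
        if np.ptp(dos) == 0.0:
            continue
        r2 = ld_r2(lead_dos, dos)
        if r2 > r2_min:
            kept.append(replace(rec, eaf=eaf))
            kept_dos.append(dos)
            kept_r2.append(r2)

    mat = DosageMatrix(
        values=np.column_stack(kept_dos) if kept_dos else np.empty((dosages.n_samples, 0)),
        variants=list(kept),
        sample_ids=list(dosages.sample_ids),
    )
    return LocusResult(
        locus_name=locus_name or lead.rsid,
        lead=lead,
        proxies=kept,
        proxy_r2=kept_r2,
        dosages=mat,
    )


def locus_significant(
    locus: LocusResult,
    alpha_family: float = 0.05,
    n_loci: int = DEFAULT_N_LOCI,
) -> bool:
    """True iff the minimum one-sided p over the locus' proxies clears
    the Bonferroni threshold alpha_family / n_loci (strict <)."""
    p = locus.min_p_one
    if p is None:
        raise ValueError(f"locus {locus.locus_name}: no tested proxy")
    return bool(p < alpha_family / n_loci)


def associate_locus(
    locus: LocusResult,
    y_resid: np.ndarray,
    covariates=None,
    expected_sign=None,
    alpha_family: float = 0.05,
    n_loci: int = DEFAULT_N_LOCI,
) -> LocusResult:
    """Fit the SNP model for every retained proxy and flag significance.

    ``expected_sign`` defaults to the sign of the lead GWAMA effect; after
    harmonization all proxies share that expected direction.
    """
    if expected_sign is None:
        if locus.lead.b is None:
            raise ValueError("lead record carries no GWAMA effect to take a direction from")
        expected_sign = "-" if locus.lead.b < 0 else "+"
    tested = []
    for j, rec in enumerate(locus.proxies):
        b, se, p2 = fit_snp_model(y_resid, locus.dosages.values[:, j], covariates)
        p1 = one_sided_p(b, se, expected_sign)
        tested.append(replace(rec, b=b, se=se, p_two=p2, p_one=p1, n=int(np.isfinite(y_resid).sum())))
    locus.proxies = tested
    if tested:
        locus.best_cohort_variant = min(tested, key=lambda v: v.p_one)
        locus.significant = locus_significant(locus, alpha_family, n_loci)
    return locus


def effective_test_coverage(corr: np.ndarray, k: int) -> float:
    """Fraction of total SNP variance covered by the k largest eigenvalues
    of the SNP correlation matrix: sum of top-k eigenvalues divided by m."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    m = corr.shape[0]
    if not 0 < k <= m:
        raise ValueError("k must be in 1..m")
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-6:
        raise ValueError("matrix is not positive semi-definite")
    eig = np.clip(eig, 0.0, None)
    return float(np.sort(eig)[::-1][:k].sum() / m)


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation factor: median of the chi-square(1)
    statistics implied by the p-values, divided by 0.4549 (the null median)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2_stats = stats.chi2.isf(p, df=1)
    return float(np.median(chi2_stats) / CHI2_1_MEDIAN)
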