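"""Shared domain containers.

A :class:`VariantRecord` carries a variant's identity, alleles, frequency and
(optionally) a per-cohort association summary; a :class:`DosageMatrix` holds
individuals x variants allelic dosages in [0, 2] together with the variant
metadata and sample identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["VariantRecord", "DosageMatrix"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class VariantRecord:
    """One variant with alleles, frequency and an optional association summary.

    ``b`` is the per-effect-allele effect on the analysis outcome (here
    ln(eGFRcrea)); ``p_one``/``p_two`` are one- and two-sided p-values.
    """

    rsid: str
    chrom: str = "."
    pos: int = 0
    effect_allele: str = "N"
    other_allele: str = "N"
    eaf: Optional[float] = None
    b: Optional[float] = None
    se: Optional[float] = None
    p_two: Optional[float] = None
    p_one: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.rsid}: effect and other allele are both "
                f"{self.effect_allele!r}"
            )
        if self.eaf is not None and not 0.0 < float(self.eaf) < 1.0:
            raise ValueError(f"{self.rsid}: EAF {self.eaf} outside (0, 1)")
        if self.se is not None and self.se <= 0:
            raise ValueError(f"{self.rsid}: SE {self.se} must be > 0")
        for name in ("p_two", "p_one"):
            p = getattr(self, name)
            if p is not None and not 0.0 < p <= 1.0:
                raise ValueError(f"{self.rsid}: {name}={p} outside (0, 1]")

    @property
    def maf(self) -> Optional[float]:
        if self.eaf is None:
            return None
        return min(self.eaf, 1.0 - self.eaf)

    def is_strand_ambiguous(self) -> bool:
        """A/T and C/G pairs read the same on both strands."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele

    def flipped(self) -> "VariantRecord":
        """Record with effect/other alleles (and summary) swapped."""
        return replace(
            self,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            b=None if self.b is None else -self.b,
        )


@dataclass
class DosageMatrix:
    """n_samples x n_variants allelic dosages in [0, 2]."""

    values: np.ndarray
    variants: list[VariantRecord]
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("dosage values must be a 2-D array")
        if self.values.shape[1] != len(self.variants):
            raise ValueError(
                f"{self.values.shape[1]} dosage columns but "
                f"{len(self.variants)} variant records"
            )
        finite = np.isfinite(self.values)
        if not finite.all():
            raise ValueError("dosages contain non-finite values")
        if (self.values < 0).any() or (self.values > 2).any():
            raise ValueError("dosages outside [0, 2]")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:05d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match row count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def column(self, rsid: str) -> np.ndarray:
        """Dosage vector for one variant, looked up by rsid."""
        try:
            j = self.rsids.index(rsid)
        except ValueError:
            raise KeyError(f"variant {rsid!r} not in dosage matrix") from None
        return self.values[:, j]

    def empirical_eaf(self) -> np.ndarray:
        """Observed effect-allele frequency per column (mean dosage / 2)."""
        return self.values.mean(axis=0) / 2.0

    def subset(self, rsids: Sequence[str]) -> "DosageMatrix":
        idx = [self.rsids.index(r) for r in rsids]
        return DosageMatrix(
            values=self.values[:, idx].copy(),
            variants=[self.variants[j] for j in idx],
            sample_ids=list(self.sample_ids),
        )

    def hstack(self, other: "DosageMatrix") -> "DosageMatrix":
        if self.sample_ids != other.sample_ids:
            raise ValueError("cannot stack dosage matrices with different samples")
        return DosageMatrix(
            values=np.hstack([self.values, other.values]),
            variants=self.variants + other.variants,
            sample_ids=list(self.sample_ids),
        )
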