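"""Readers, writers and pipeline configuration.

File formats are deliberately plain: tab-separated tables for summary
statistics, dosages and phenotypes (the interchange formats of GWAS
follow-up work), VCF with a DS FORMAT field as an optional dosage source,
and YAML for configuration. Coordinates are 1-based (VCF convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .types import DosageMatrix, VariantRecord

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_dosages",
    "write_dosages_tsv",
    "write_dosages_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "PipelineConfig",
]

SUMMARY_COLUMNS = ["rsid", "chr", "pos", "EA", "OA", "EAF", "beta", "se", "p", "n"]


def read_summary_stats(path) -> list[VariantRecord]:
    """Read a GWAMA-style summary-statistics TSV into variant records.

    Requires the header columns rsid, chr, pos, EA, OA, EAF, beta, se, p
    (n optional). Allele strings are uppercased; positions are 1-based.
    Raises a schema error naming any missing column and a row error (with
    line number) for non-numeric or out-of-range values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SUMMARY_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            records.append(
                VariantRecord(
                    rsid=str(row["rsid"]),
                    chrom=str(row["chr"]),
                    pos=int(row["pos"]),
                    effect_allele=str(row["EA"]),
                    other_allele=str(row["OA"]),
                    eaf=float(row["EAF"]),
                    b=float(row["beta"]),
                    se=float(row["se"]),
                    p_two=float(row["p"]),
                    n=int(float(row["n"])) if "n" in df.columns and pd.notna(row.get("n")) else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from None
    return records


def write_summary_stats(records: Sequence[VariantRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "rsid": r.rsid, "chr": r.chrom, "pos": r.pos,
            "EA": r.effect_allele, "OA": r.other_allele,
            "EAF": r.eaf, "beta": r.b, "se": r.se, "p": r.p_two, "n": r.n,
        })
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, sep="\t", index=False)


def write_dosages_tsv(dosages: DosageMatrix, path, meta_path=None) -> None:
    """Rows = samples, columns = variants (header of variant IDs).

    Variant metadata (chr, pos, alleles, EAF) goes to ``meta_path`` when
    given (default: <path> with a .variants.tsv suffix).
    """
    df = pd.DataFrame(dosages.values, columns=dosages.rsids)
    df.insert(0, "sample_id", dosages.sample_ids)
    df.to_csv(path, sep="\t", index=False)
    if meta_path is None:
        meta_path = str(path) + ".variants.tsv"
    meta = pd.DataFrame({
        "rsid": dosages.rsids,
        "chr": [v.chrom for v in dosages.variants],
        "pos": [v.pos for v in dosages.variants],
        "EA": [v.effect_allele for v in dosages.variants],
        "OA": [v.other_allele for v in dosages.variants],
        "EAF": [v.eaf for v in dosages.variants],
    })
    meta.to_csv(meta_path, sep="\t", index=False)


def _read_dosages_tsv(path, meta_path=None) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.empty or df.shape[1] < 2:
        raise ValueError(f"{path}: no dosage columns found")
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    sample_ids = df["sample_id"].astype(str).tolist()
    values = df.drop(columns="sample_id").to_numpy(dtype=float)
    bad = np.argwhere(~((values >= 0) & (values <= 2)))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: dosage {values[i, j]} outside [0, 2] "
            f"(sample {sample_ids[i]}, variant {df.columns[j + 1]})"
        )
    if meta_path is None:
        candidate = Path(str(path) + ".variants.tsv")
        meta_path = candidate if candidate.exists() else None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t").set_index("rsid")
        variants = [
            VariantRecord(
                rsid=r, chrom=str(meta.loc[r, "chr"]), pos=int(meta.loc[r, "pos"]),
                effect_allele=str(meta.loc[r, "EA"]), other_allele=str(meta.loc[r, "OA"]),
                eaf=float(meta.loc[r, "EAF"]) if pd.notna(meta.loc[r, "EAF"]) else None,
            )
            for r in df.columns[1:]
        ]
    else:
        variants = [VariantRecord(rsid=r) for r in df.columns[1:]]
    return DosageMatrix(values=values, variants=variants, sample_ids=sample_ids)


def _read_dosages_vcf(path) -> DosageMatrix:
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    columns, variants = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is None:
            raise ValueError(f"{path}: variant {var.ID or var.POS} has no DS field")
        ds = np.asarray(ds, dtype=float).reshape(len(sample_ids))
        columns.append(ds)
        alts = var.ALT or ["N"]
        variants.append(
            VariantRecord(
                rsid=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=str(var.CHROM), pos=int(var.POS),
                effect_allele=alts[0], other_allele=var.REF,
                eaf=float(np.mean(ds) / 2.0),
            )
        )
    if not columns:
        raise ValueError(f"{path}: no variants found")
    return DosageMatrix(
        values=np.column_stack(columns), variants=variants, sample_ids=sample_ids
    )


def read_dosages(path, fmt: Optional[str] = None, meta_path=None) -> DosageMatrix:
    """Read a dosage matrix from TSV (rows=samples) or VCF (DS field).

    ``fmt`` is inferred from the extension when omitted (.vcf -> vcf,
    anything else -> tsv). The effect allele of a VCF record is ALT.
    """
    if fmt is None:
        fmt = "vcf" if str(path).endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "tsv":
        return _read_dosages_tsv(path, meta_path)
    if fmt == "vcf":
        return _read_dosages_vcf(path)
    raise ValueError(f"unknown dosage format {fmt!r}")


def write_dosages_vcf(dosages: DosageMatrix, path) -> None:
    """Minimal VCF 4.2 with a per-sample DS (dosage) FORMAT field.

    The effect allele is written as ALT so that read_dosages round-trips
    the matrix exactly.
    """
    chroms = sorted({v.chrom for v in dosages.variants})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Allelic dosage">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.sample_ids) + "\n"
        )
        order = np.lexsort(
            ([v.pos for v in dosages.variants], [v.chrom for v in dosages.variants])
        )
        for j in order:
            v = dosages.variants[j]
            ds = "\t".join(f"{x:.6g}" for x in dosages.values[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.rsid}\t{v.other_allele}\t{v.effect_allele}"
                f"\t.\t.\t.\tDS\t{ds}\n"
            )


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing 'sample_id' column")
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs.

    Either the three input paths (summary stats, dosages, phenotypes) or a
    synthetic ground-truth spec must be provided. Thresholds default to the
    analysis constants: locus alpha 0.05/147, mediation 0.05/(70*11),
    interaction 0.05/11, proxy r^2 > 0.8, MAF >= 0.005, winsorization at
    [15, 200] ml/min/1.73m^2, TSH thresholds 0.4/3.8 uUI/mL.
    """

    summary_stats: Optional[str] = None
    dosages: Optional[str] = None
    phenotypes: Optional[str] = None
    synthetic: Optional[dict] = None
    out_dir: str = "lociscreen_out"
    seed: int = 0
    n_loci_family: int = 147
    alpha_family: float = 0.05
    n_traits_mediation: int = 70
    proxy_r2: float = 0.8
    maf_min: float = 0.005
    winsor_bounds: tuple[float, float] = (15.0, 200.0)
    tsh_thresholds: tuple[float, float] = (0.4, 3.8)
    covariates: list[str] = field(
        default_factory=lambda: ["age", "sex"] + [f"PC{i}" for i in range(1, 11)]
    )
    trait_cols: Optional[list[str]] = None

    def __post_init__(self) -> None:
        for name in ("alpha_family", "proxy_r2", "maf_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synthetic is None and not (
            self.summary_stats and self.dosages and self.phenotypes
        ):
            raise ValueError(
                "config needs either the three input paths or a synthetic spec"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("winsor_bounds", "tsh_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["winsor_bounds"] = list(self.winsor_bounds)
        data["tsh_thresholds"] = list(self.tsh_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def write_ground_truth(truth_dict: dict, path) -> None:
    """Persist a ground-truth parameter dict as YAML (or JSON by extension)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(truth_dict, indent=2, default=float))
    else:
        with open(path, "w") as fh:
            yaml.safe_dump(truth_dict, fh, sort_keys=False)
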