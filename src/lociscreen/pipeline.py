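"""End-to-end driver: phenotypes -> association -> comparison -> mediation
-> interaction, from files or from a synthetic ground-truth spec.

The driver chains the library stages in the order of the study design:

1. phenotype preparation (creatinine normalization, CKD-EPI, winsorized
   log eGFR, inverse-normal traits);
2. locus re-association with one-sided tests at alpha/n_loci, LD-proxy
   selection and genomic-control diagnostics;
3. cohort-vs-meta effect comparison (effect/MAF ratios, explained variance);
4. the four-step mediation screen with the stringent Tukey outlier rule
   over the significant loci;
5. SNP-by-TSH interaction analysis with exclusions and sensitivity checks.

Outputs are plain TSV tables plus a JSON report; identical config and seed
give bitwise-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import assoc, interaction, mediation, metacompare, phenoprep, synthdata
from . import io as lio
from .types import DosageMatrix, VariantRecord

__all__ = ["run_pipeline", "PipelineReport", "ground_truth_from_dict"]

logger = logging.getLogger(__name__)

PROXY_WINDOW_BP = 1_000_000


def ground_truth_from_dict(spec: dict) -> synthdata.GroundTruth:
    """Build a :class:`GroundTruth` from a plain (YAML-friendly) dict."""
    spec = dict(spec)
    loci = [synthdata.LocusSpec(**d) for d in spec.pop("loci", [])]
    traits = [synthdata.TraitSpec(**d) for d in spec.pop("trait_specs", [])]
    for key in ("tsh_lognormal_params", "ft_measurement_thresholds", "age_range"):
        if key in spec:
            spec[key] = tuple(spec[key])
    return synthdata.GroundTruth(loci=loci, trait_specs=traits, **spec)


@dataclass
class PipelineReport:
    """Everything the pipeline computed, plus paths of the written tables."""

    loci: list = field(default_factory=list)
    comparisons: list = field(default_factory=list)
    mediation_results: list = field(default_factory=list)
    interaction_results: list = field(default_factory=list)
    genomic_lambda: Optional[float] = None
    effective_coverage: Optional[float] = None
    exclusion_report: dict = field(default_factory=dict)
    significant_loci: list = field(default_factory=list)
    mediators: list = field(default_factory=list)
    output_files: dict = field(default_factory=dict)


def _fmt_p(p) -> str:
    return "" if p is None or not np.isfinite(p) else f"{p:.3g}"


def _fmt_b(b) -> str:
    return "" if b is None or not np.isfinite(b) else f"{b:.5f}"


def _load_inputs(config: lio.PipelineConfig, out: Path):
    if config.synthetic is not None:
        truth = ground_truth_from_dict({**config.synthetic, "seed": config.seed})
        dosages, cohort = synthdata.simulate_cohort(truth)
        meta = synthdata.meta_summary_from_truth(truth)
        lio.write_dosages_tsv(dosages, out / "dosages.tsv")
        lio.write_phenotypes(cohort, out / "phenotypes.tsv")
        lio.write_summary_stats(meta, out / "summary_stats.tsv")
        lio.write_ground_truth(truth.to_dict(), out / "ground_truth.yaml")
        trait_cols = config.trait_cols or [t.name for t in truth.trait_specs]
        return meta, dosages, cohort, trait_cols, truth
    meta = lio.read_summary_stats(config.summary_stats)
    dosages = lio.read_dosages(config.dosages)
    cohort = lio.read_phenotypes(config.phenotypes)
    if config.trait_cols is None:
        raise ValueError("trait_cols must be listed in the config for file inputs")
    return meta, dosages, cohort, config.trait_cols, None


def run_pipeline(config: lio.PipelineConfig) -> PipelineReport:
    """Run every stage and write the report bundle to ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()

    meta, dosages, cohort, trait_cols, truth = _load_inputs(config, out)

    # ---- phenotypes -------------------------------------------------------
    cohort = phenoprep.prepare_outcome(
        cohort,
        winsor_bounds=config.winsor_bounds,
        trait_cols=[c for c in trait_cols if c in cohort.columns],
    )
    y_resid = assoc.residualize_outcome(
        cohort["ln_egfr"].to_numpy(), cohort["age"].to_numpy(), cohort["sex"].to_numpy()
    )
    var_y = float(np.var(y_resid, ddof=1))
    pc_cols = [c for c in config.covariates if c.upper().startswith("PC") and c in cohort.columns]
    snp_covariates = cohort[pc_cols] if pc_cols else None

    # ---- association ------------------------------------------------------
    n_family = max(len(meta), 1) if config.n_loci_family is None else config.n_loci_family
    rsid_to_idx = {v.rsid: j for j, v in enumerate(dosages.variants)}
    for lead in meta:
        if lead.rsid not in rsid_to_idx:
            logger.warning("lead %s missing from cohort dosages; locus skipped", lead.rsid)
            continue
        candidates = [
            v for v in dosages.variants
            if v.chrom == lead.chrom and abs(v.pos - lead.pos) <= PROXY_WINDOW_BP
        ]
        locus = assoc.select_proxies(
            lead, candidates, dosages.subset([v.rsid for v in candidates]),
            r2_min=config.proxy_r2, maf_min=config.maf_min,
            locus_name=lead.rsid.removesuffix("_lead"),
        )
        locus = assoc.associate_locus(
            locus, y_resid, snp_covariates,
            alpha_family=config.alpha_family, n_loci=n_family,
        )
        report.loci.append(locus)
    report.significant_loci = [l.locus_name for l in report.loci if l.significant]

    all_p_two = [v.p_two for l in report.loci for v in l.proxies]
    if all_p_two:
        report.genomic_lambda = assoc.genomic_lambda(all_p_two)
    locus_mats = [l.dosages for l in report.loci if l.dosages is not None and l.dosages.n_variants]
    if locus_mats:
        stacked = locus_mats[0]
        for m in locus_mats[1:]:
            stacked = stacked.hstack(m)
        if stacked.n_variants >= 2:
            corr = np.corrcoef(stacked.values, rowvar=False)
            report.effective_coverage = assoc.effective_test_coverage(
                corr, min(len(report.loci), stacked.n_variants)
            )

    # ---- cohort vs meta comparison ---------------------------------------
    meta_by_rsid = {m.rsid: m for m in meta}
    for locus in report.loci:
        lead_cohort = next((v for v in locus.proxies if v.rsid == locus.lead.rsid), None)
        if lead_cohort is None or lead_cohort.b is None:
            continue
        report.comparisons.append(
            metacompare.compare_cohorts(
                lead_cohort, meta_by_rsid[locus.lead.rsid], var_y,
                locus_name=locus.locus_name,
            )
        )

    # ---- mediation over significant loci ---------------------------------
    sig = [l for l in report.loci if l.significant]
    if sig:
        med_matrix = sig[0].dosages
        locus_of = {v.rsid: sig[0].locus_name for v in sig[0].proxies}
        for l in sig[1:]:
            med_matrix = med_matrix.hstack(l.dosages)
            locus_of.update({v.rsid: l.locus_name for v in l.proxies})
        usable_traits = [c for c in trait_cols if c in cohort.columns]
        cov_cols = [c for c in config.covariates if c in cohort.columns]
        report.mediation_results = mediation.run_mediation_screen(
            cohort, med_matrix, usable_traits, cov_cols,
            n_traits=config.n_traits_mediation or len(usable_traits),
            n_loci=max(len(sig), 1),
        )
        report.mediators = sorted({
            (r.rsid, r.trait_name)
            for r in report.mediation_results
            if r.mediator_status == "partial_mediator"
        })
    else:
        logger.info("no significant locus: mediation and interaction stages are empty")

    # ---- interaction ------------------------------------------------------
    if sig and "tsh" in cohort.columns:
        filtered, report.exclusion_report = interaction.apply_exclusions(cohort)
        cov_cols = [c for c in config.covariates if c in filtered.columns]
        cov = filtered[cov_cols] if cov_cols else None
        status = interaction.classify_thyroid(
            filtered["tsh"].to_numpy(),
            filtered.get("levothyroxine"),
            filtered.get("thiamazole"),
            filtered.get("propylthiouracil"),
            tsh_low=config.tsh_thresholds[0],
            tsh_high=config.tsh_thresholds[1],
        )
        keep_rows = filtered.index.to_numpy()
        row_pos = cohort.index.get_indexer(keep_rows)
        for l in sig:
            d = l.dosages.values[row_pos, 0]
            y = filtered["ln_egfr"].to_numpy()
            res = interaction.fit_interaction_continuous(
                y, d, filtered["tsh"].to_numpy(), cov, rsid=l.proxies[0].rsid
            )
            report.interaction_results.append(res)
            report.interaction_results.extend(
                interaction.fit_interaction_categorical(y, d, status, cov, rsid=l.proxies[0].rsid)
            )

    _write_outputs(report, out, config)
    return report


def _write_outputs(report: PipelineReport, out: Path, config: lio.PipelineConfig) -> None:
    # association table (Table-2-like layout)
    rows = []
    for l in report.loci:
        for v in l.proxies:
            rows.append({
                "locus": l.locus_name, "rsid": v.rsid,
                "chr_pos": f"{v.chrom}:{v.pos}",
                "EA_OA": f"{v.effect_allele}/{v.other_allele}",
                "EAF": "" if v.eaf is None else f"{v.eaf:.4f}",
                "b": _fmt_b(v.b), "se": _fmt_b(v.se),
                "p_one_sided": _fmt_p(v.p_one), "p_two_sided": _fmt_p(v.p_two),
                "is_lead": v.rsid == l.lead.rsid,
                "significant_locus": l.significant,
            })
    assoc_path = out / "assoc_results.tsv"
    pd.DataFrame(rows).to_csv(assoc_path, sep="\t", index=False)

    comp_rows = [{
        "locus": c.locus_name,
        "b_cohort": _fmt_b(c.b_cohort), "b_meta": _fmt_b(c.b_meta),
        "se_cohort": _fmt_b(c.se_cohort), "se_meta": _fmt_b(c.se_meta),
        "eaf_cohort": f"{c.eaf_cohort:.4f}", "eaf_meta": f"{c.eaf_meta:.4f}",
        "effect_ratio": "" if c.effect_ratio is None else f"{c.effect_ratio:.3f}",
        "maf_ratio": "" if c.maf_ratio is None else f"{c.maf_ratio:.3f}",
        "var_explained_cohort": _fmt_p(c.var_explained_cohort),
        "var_explained_meta": _fmt_p(c.var_explained_meta),
    } for c in report.comparisons]
    comp_path = out / "meta_comparison.tsv"
    pd.DataFrame(comp_rows).to_csv(comp_path, sep="\t", index=False)

    med_path = out / "mediation_results.tsv"
    mediation.results_to_frame(report.mediation_results).to_csv(med_path, sep="\t", index=False)

    inter_rows = [{
        "rsid": r.rsid, "model": r.model,
        "b_snp": _fmt_b(r.b_snp), "b_env": _fmt_b(r.b_env),
        "b_interaction": _fmt_b(r.b_interaction),
        "se_interaction": _fmt_b(r.se_interaction),
        "p_interaction": _fmt_p(r.p_interaction), "n": r.n,
        "significant": interaction.interaction_significant(r.p_interaction),
    } for r in report.interaction_results]
    inter_path = out / "interaction_results.tsv"
    pd.DataFrame(inter_rows).to_csv(inter_path, sep="\t", index=False)

    summary = {
        "seed": config.seed,
        "python": sys.version.split()[0],
        "genomic_lambda": report.genomic_lambda,
        "effective_test_coverage": report.effective_coverage,
        "n_loci_tested": len(report.loci),
        "significant_loci": report.significant_loci,
        "mediators": [list(m) for m in report.mediators],
        "exclusions": report.exclusion_report,
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    report.output_files = {
        "assoc": str(assoc_path), "comparison": str(comp_path),
        "mediation": str(med_path), "interaction": str(inter_path),
        "report": str(report_path),
    }
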