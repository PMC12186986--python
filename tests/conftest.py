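import numpy as np
import pytest

from lociscreen import phenoprep, synthdata as sd

PC_COLS = [f"PC{i}" for i in range(1, 11)]
COVARIATES = ["age", "sex"] + PC_COLS


@pytest.fixture(scope="session")
def cohort_with_mediator():
    """A prepared synthetic cohort: one effect locus with an attenuating
    trait (f = 0.4), one null locus, and a 12-trait null panel."""
    truth = sd.GroundTruth(
        n_individuals=3000,
        loci=[
            sd.LocusSpec("L1", maf=0.3, beta_gfr=0.04, n_proxies=2, target_r2=0.95,
                         chrom="1", pos=1_000_000),
            sd.LocusSpec("L2", maf=0.2, beta_gfr=0.0, n_proxies=1, chrom="2",
                         pos=2_000_000),
        ],
        trait_specs=sd.default_trait_specs(12)
        + [sd.TraitSpec.for_attenuation("mediator", "L1", attenuated_fraction=0.4)],
        interaction_gamma=0.01,
        interaction_locus="L1",
        seed=42,
    )
    dosages, cohort = sd.simulate_cohort(truth)
    cohort = phenoprep.prepare_outcome(cohort)
    return truth, dosages, cohort


@pytest.fixture(scope="session")
def covariates(cohort_with_mediator):
    _, _, cohort = cohort_with_mediator
    return cohort[COVARIATES]
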