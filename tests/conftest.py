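import numpy as np
import pandas as pd
import pytest

import grexfine as gf

COVARS = ("age", "sex", "PC1", "PC2", "PC3")


def make_pheno(df: pd.DataFrame) -> gf.PhenotypeTable:
    return gf.PhenotypeTable(df, covariates=COVARS)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one driver gene and one carrier-enriched phecode."""
    cfg = gf.SimConfig(
        n_individuals=2000, n_genes=6, n_blocks=2, snps_per_block=60,
        weights_per_gene=8, cross_gene_sharing=0.5, n_tissues=2,
        driver_genes={"GENE001": 1.0}, heritability=0.05,
        carrier_enriched_codes={"105.1": 20.0}, n_phecodes=30,
        carrier_fraction=0.05, seed=42,
    )
    return gf.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cube(small_cohort):
    cube, _ = gf.predict_expression(small_cohort.dosages, small_cohort.weights)
    cube, _ = gf.drop_degenerate(cube)
    return cube


@pytest.fixture(scope="session")
def small_pheno(small_cohort):
    return make_pheno(small_cohort.phenotype)


@pytest.fixture(scope="session")
def small_cc(small_cohort):
    return gf.build_case_control(
        small_cohort.events, small_cohort.dosages.individuals,
        small_cohort.categories, min_cases=20,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
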