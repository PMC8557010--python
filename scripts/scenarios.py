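"""Shared end-to-end scenarios used by the acceptance tests and the
acceptance report script.

Each function simulates a cohort with a documented configuration, runs the
relevant pipeline stage, and returns plain numbers; no global state."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

import grexfine as gf

# study-wide significance threshold used throughout (5 traits x 127 genes)
STUDY_THRESHOLD = gf.bonferroni_threshold(5, 127)

NULL_MULTIXCAN_CFG = dict(
    n_individuals=2000, n_blocks=10, snps_per_block=50, ld_rho=0.3,
    n_genes=500, n_tissues=2, weights_per_gene=8,
    cross_tissue_sharing=0.8, cross_gene_sharing=0.0,
    binary_trait=False, heritability=0.0,
)

NULL_PHEWAS_CFG = dict(
    n_individuals=2000, n_blocks=2, snps_per_block=50, ld_rho=0.3,
    n_genes=10, n_tissues=2, weights_per_gene=8,
    n_phecodes=200, carrier_fraction=0.5,
    phecode_base_rate=(0.2, 0.5),
)

NULL_CARRIER_CFG = dict(NULL_PHEWAS_CFG, n_phecodes=1531)

FINEMAP_CFG = dict(
    n_individuals=20000, n_genes=10, n_blocks=1, snps_per_block=80,
    weights_per_gene=12, cross_gene_sharing=0.5, cross_tissue_sharing=1.0,
    n_tissues=2, ld_rho=0.3, driver_genes={"GENE004": 1.0},
    prevalence=0.2, heritability=0.02, binary_trait=True,
)

OVERLAP_CFG = dict(
    n_individuals=3000, n_genes=8, n_blocks=2, snps_per_block=60,
    n_tissues=2, weights_per_gene=8, cross_gene_sharing=0.0,
    n_phecodes=100, carrier_fraction=0.02,
    carrier_enriched_codes={f"{100 + j}.1": 4.0 for j in range(10)},
    phecode_base_rate=(0.1, 0.4),
)


def _pheno(df: pd.DataFrame) -> gf.PhenotypeTable:
    return gf.PhenotypeTable(df, covariates=("age", "sex", "PC1", "PC2", "PC3"))


def null_multixcan_and_meta(seed: int) -> dict:
    """Global-null calibration of the joint test and the split-half meta.

    Simulates a driverless quantitative cohort, runs the joint PC test on
    all genes, and additionally meta-analyzes two disjoint halves of the
    cohort.  Returns KS statistics and the type-I fraction at alpha 0.05.
    """
    cfg = gf.SimConfig(seed=seed, **NULL_MULTIXCAN_CFG)
    dm = gf.simulate_genotypes(cfg)
    db, truth = gf.simulate_weight_models(cfg, dm)
    phe = gf.simulate_phenotype(truth, cfg)
    cube, _ = gf.predict_expression(dm, db)
    cube, _ = gf.drop_degenerate(cube)
    pheno = _pheno(phe)
    table = gf.multixcan_all(cube, pheno)
    p = table[table["testable"]]["p"].to_numpy()

    half = cfg.n_individuals // 2
    ids_a, ids_b = dm.individuals[:half], dm.individuals[half:]
    meta_p = []
    tab_halves = []
    for ids in (ids_a, ids_b):
        sub = cube.subset_individuals(ids)
        sub_pheno = _pheno(phe.loc[ids])
        tab_halves.append(gf.multixcan_all(sub, sub_pheno).set_index("gene"))
    for gene in table["gene"]:
        res = []
        for tab in tab_halves:
            r = tab.loc[gene]
            res.append(gf.AssociationResult(gene, int(r["n_tissues"]), int(r["n_components"]),
                                            float(r["statistic"]), float(r["p"]),
                                            int(r["direction"]), float(r["mean_Z"]),
                                            bool(r["testable"])))
        if all(x.testable and x.direction != 0 for x in res):
            meta_p.append(gf.metal_combine(res, [half, cfg.n_individuals - half]).p_meta)
    meta_p = np.array(meta_p)
    return {
        "multixcan_ks": float(stats.kstest(p, "uniform").statistic),
        "multixcan_type1": float((p < 0.05).mean()),
        "multixcan_n": int(len(p)),
        "meta_ks": float(stats.kstest(meta_p, "uniform").statistic),
        "meta_type1": float((meta_p < 0.05).mean()),
        "meta_n": int(len(meta_p)),
    }


def null_gene_phewas(seed: int) -> dict:
    """Global-null calibration of the gene-level PheWAS (10 genes x 200 codes)."""
    cfg = gf.SimConfig(seed=seed, **NULL_PHEWAS_CFG)
    cohort = gf.simulate_cohort(cfg)
    cube, _ = gf.predict_expression(cohort.dosages, cohort.weights)
    cube, _ = gf.drop_degenerate(cube)
    cc = gf.build_case_control(cohort.events, cohort.dosages.individuals, cohort.categories)
    tab = gf.gene_phewas(cube, cc)
    p = tab[~tab["failed"]]["p"].to_numpy()
    return {
        "gene_phewas_ks": float(stats.kstest(p, "uniform").statistic),
        "gene_phewas_type1": float((p < 0.05).mean()),
        "gene_phewas_n": int(len(p)),
    }


def null_carrier_phewas(seed: int) -> dict:
    """Global-null calibration of the carrier PheWAS over 1531 codes."""
    cfg = gf.SimConfig(seed=seed, **NULL_CARRIER_CFG)
    ids = [f"ind{i:06d}" for i in range(cfg.n_individuals)]
    carriers = gf.simulate_carriers(cfg, ids)
    truth = gf.SimTruth()
    events = gf.simulate_phecodes(cfg, carriers, truth=truth)
    cc = gf.build_case_control(events, ids, truth.phecode_categories)
    tab = gf.carrier_phewas(carriers, cc)
    p = tab[~tab["failed"]]["p"].to_numpy()
    return {
        "carrier_phewas_ks": float(stats.kstest(p, "uniform").statistic),
        "carrier_phewas_type1": float((p < 0.05).mean()),
        "carrier_phewas_n": int(len(p)),
    }


def finemap_replicate(seed: int) -> dict:
    """One fine-mapping replicate: driver among correlated passengers.

    Returns the marginal/conditional p landscape, the adjacent-gene GReX
    correlation range, and the lead-eQTL SNP-conditioning outcome under the
    single-causal-SNP variant of the truth.
    """
    cfg = gf.SimConfig(seed=seed, **FINEMAP_CFG)
    dm = gf.simulate_genotypes(cfg)
    db, truth = gf.simulate_weight_models(cfg, dm)
    phe = gf.simulate_phenotype(truth, cfg)
    pheno = _pheno(phe)
    cube, _ = gf.predict_expression(dm, db)
    cube, _ = gf.drop_degenerate(cube)

    corr = truth.true_grex.corr().to_numpy()
    adjacent = [abs(corr[i, i + 1]) for i in range(cfg.n_genes - 1)]

    out = gf.conditional_multixcan([(cube, pheno, cfg.n_individuals)], cube.genes(),
                                   threshold=STUDY_THRESHOLD).set_index("gene")
    driver = "GENE004"
    passengers = [g for g in out.index if g != driver]
    sig_passengers = [g for g in passengers if out.loc[g, "p_marginal"] < STUDY_THRESHOLD]

    # single-causal-eQTL variant: trait mediated by the driver's lead SNP
    w = truth.gene_weights[(driver, "tissue0")]
    lead = w.loc[w["weight"].abs().idxmax(), "variant_id"]
    truth_snp = gf.truth_with_snp_driver(truth, dm, driver, lead)
    phe_snp = gf.simulate_phenotype(truth_snp, cfg)
    pheno_snp = _pheno(phe_snp)
    marg_snp = gf.multixcan_fit(cube, driver, pheno_snp)
    cond_snp = gf.multixcan_fit(cube, driver, gf.condition_on_snps(pheno_snp, dm, [lead]))

    return {
        "driver_p_marginal": float(out.loc[driver, "p_marginal"]),
        "driver_p_cond": float(out.loc[driver, "p_cond"]),
        "driver_retained": bool(out.loc[driver, "p_cond"] < STUDY_THRESHOLD),
        "n_sig_passengers_marginal": len(sig_passengers),
        "worst_passenger_p_cond": float(min(out.loc[g, "p_cond"] for g in passengers)),
        "all_passengers_lost": bool(all(out.loc[g, "p_cond"] >= STUDY_THRESHOLD
                                        for g in passengers)),
        "adjacent_corr_min": float(min(adjacent)),
        "adjacent_corr_max": float(max(adjacent)),
        "snp_p_marginal": float(marg_snp.p),
        "snp_p_cond": float(cond_snp.p),
        "snp_nullified": bool(marg_snp.p < STUDY_THRESHOLD
                              and cond_snp.p >= STUDY_THRESHOLD),
    }


def overlap_replicate(seed: int) -> dict:
    """One overlap replicate: coupled vs decoupled enriched codes.

    Coupled cohorts multiply the carrier-enriched code rates for mimic-group
    individuals too; decoupled cohorts do not.  Returns the rank-overlap p
    of the mimic phenome against the carrier phenome for both."""
    cfg = gf.SimConfig(seed=seed, **OVERLAP_CFG)
    dm = gf.simulate_genotypes(cfg)
    db, truth = gf.simulate_weight_models(cfg, dm)
    cube, _ = gf.predict_expression(dm, db)
    cube, _ = gf.drop_degenerate(cube)
    labels = gf.extreme_labels(cube)
    score = (labels.group == "mimic").astype(float)
    carriers = gf.simulate_carriers(cfg, dm.individuals)

    def one(expression_score):
        t = gf.SimTruth(true_grex=truth.true_grex)
        events = gf.simulate_phecodes(cfg, carriers, truth=t,
                                      expression_score=expression_score)
        cc = gf.build_case_control(events, dm.individuals, t.phecode_categories)
        ref = gf.carrier_phewas(carriers, cc)
        mim = gf.mimic_phewas(labels, cc)
        cands = gf.top_percent(mim, pct=gf.ExtremeConfig().top_trait_fraction)["mimic"]
        return gf.rank_overlap_test(cands, ref)[1]

    p_coupled = one(score)
    p_decoupled = one(None)
    return {
        "p_coupled": float(p_coupled),
        "p_decoupled": float(p_decoupled),
        "coupled_wins": bool(p_coupled < p_decoupled),
    }
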