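"""Synthetic cohorts with the statistical structure the CNV fine-mapping analysis assumes.

The generator emulates the study's inputs without any protected data:

* **Genotypes** — LD-blocked allele dosages from a latent-haplotype AR(1)
  scheme: per individual and block, two latent standard-normal chains with
  lag-one correlation ``ld_rho``; each chain position is thresholded at the
  MAF quantile to give a haplotype allele, and the two alleles sum to a
  dosage in {0, 1, 2}.  Adjacent-variant LD is then a closed-form-checkable
  function of ``ld_rho`` and the MAFs, and blocks are independent.
* **Weight models** — sparse per-(gene, tissue) eQTL weights over a gene's
  block, with configurable SNP sharing across a gene's tissues and between
  adjacent genes; sharing between genes induces correlated GReX, the
  structure conditional fine-mapping must untangle.
* **Phenotypes** — quantitative traits as noisy linear functions of true
  GReX at a set heritability, or binary traits via a liability threshold at
  a set prevalence, with age/sex/ancestry-PC covariates.
* **Phecode streams** — Poisson visit counts per (individual, code) on
  distinct random dates in a 10-year window, with designated codes enriched
  in CNV carriers (and optionally in extreme-GReX individuals).

A single global seed fans out to fixed per-stage child seeds, so each stage
is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grex import DosageMatrix, GReXCube, WeightDB

_STAGE_SEEDS = {"genotypes": 11, "weights": 23, "phenotype": 37, "carriers": 47, "phecodes": 59}


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Counts are positive; ``ld_rho`` in [0, 1); ``maf_range`` within
    (0, 0.5]; sharing fractions in [0, 1]; ``driver_genes`` maps gene id ->
    effect size on the liability (binary) or trait (quantitative) scale;
    enrichment multipliers are >= 1.
    """

    n_individuals: int = 2000
    n_blocks: int = 2
    snps_per_block: int = 50
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 10
    n_tissues: int = 3
    weights_per_gene: int = 8
    cross_tissue_sharing: float = 0.8
    cross_gene_sharing: float = 0.0
    driver_genes: dict[str, float] = field(default_factory=dict)
    prevalence: float = 0.1
    n_phecodes: int = 100
    n_categories: int = 17
    carrier_fraction: float = 0.01
    carrier_enriched_codes: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    # generative knobs referenced by the phenotype contract
    heritability: float = 0.2
    binary_trait: bool = True
    confound_strength: float = 0.0
    phecode_base_rate: tuple[float, float] = (0.1, 0.6)

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_blocks", "snps_per_block", "n_genes",
                     "n_tissues", "weights_per_gene", "n_phecodes", "n_categories"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("cross_tissue_sharing", "cross_gene_sharing"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if not (0 <= self.heritability <= 1):
            raise ValueError("heritability must be in [0, 1]")
        bad = set(self.driver_genes) - set(self.gene_ids())
        if bad:
            raise ValueError(f"driver genes not among simulated genes: {sorted(bad)}")
        if any(m < 1 for m in self.carrier_enriched_codes.values()):
            raise ValueError("enrichment multipliers must be >= 1")
        if self.weights_per_gene > self.snps_per_block:
            raise ValueError("weights_per_gene exceeds snps_per_block")

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:03d}" for i in range(self.n_genes)]

    def phecode_ids(self) -> list[str]:
        return [f"{100 + i}.1" for i in range(self.n_phecodes)]

    def stage_rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng(self.seed * 1000 + _STAGE_SEEDS[stage])


@dataclass
class SimTruth:
    """Ground truth recorded before noise: per-gene effects, per-individual
    true GReX, carrier labels, per-phecode category and baseline rate."""

    gene_effects: dict[str, float] = field(default_factory=dict)
    true_grex: pd.DataFrame | None = None          # individuals x genes (tissue-average)
    gene_weights: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    carriers: pd.Series | None = None              # bool per individual
    phecode_categories: pd.Series | None = None    # phecode -> category
    phecode_base_rates: pd.Series | None = None    # phecode -> Poisson mean


def simulate_genotypes(config: SimConfig) -> DosageMatrix:
    """LD-blocked dosages from the latent-haplotype AR(1) scheme.

    Within a block, two independent latent chains z (one per haplotype)
    follow z_j = rho z_{j-1} + sqrt(1-rho^2) eps_j; allele_j = 1 iff
    z_j < Phi^{-1}(maf_j).  Dosage = sum of the two haplotype alleles.
    Blocks are mutually independent.
    """
    rng = config.stage_rng("genotypes")
    n, m, rho = config.n_individuals, config.snps_per_block, config.ld_rho
    dosage_blocks, meta = [], []
    for b in range(config.n_blocks):
        mafs = rng.uniform(*config.maf_range, size=m)
        thresh = stats.norm.ppf(mafs)
        alleles = np.zeros((n, m), dtype=float)
        for _hap in range(2):
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            eps = rng.standard_normal((n, m - 1)) if m > 1 else None
            for j in range(1, m):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * eps[:, j - 1]
            alleles += (z < thresh)
        dosage_blocks.append(alleles)
        for j in range(m):
            pos = b * 1_000_000 + j * 1000 + 1
            meta.append(("16", f"snp_b{b}_{j}", pos, "A", "G", float(alleles[:, j].mean() / 2)))
    variants = pd.DataFrame(meta, columns=["chromosome", "variant_id", "position", "ref_allele", "effect_allele", "frequency"])
    return DosageMatrix(
        individuals=[f"ind{i:06d}" for i in range(n)],
        variants=variants,
        dosages=np.hstack(dosage_blocks),
    )


def simulate_weight_models(config: SimConfig, dosages: DosageMatrix) -> tuple[WeightDB, SimTruth]:
    """Sparse weight models with cross-tissue and cross-gene SNP sharing.

    Genes are laid out along blocks; adjacent genes within a block share a
    fraction ``cross_gene_sharing`` of their SNPs (with their weights), and
    each gene's tissues share a fraction ``cross_tissue_sharing`` of the
    gene's SNP/weight pairs (the remainder are tissue-specific).  With
    sharing = 1 all tissues carry identical models.  True GReX (the
    tissue-average linear score) is recorded in SimTruth before any
    phenotype noise exists.
    """
    rng = config.stage_rng("weights")
    w = config.weights_per_gene
    n_share_gene = int(round(config.cross_gene_sharing * w))
    genes = config.gene_ids()
    gene_block = [g_i * config.n_blocks // config.n_genes for g_i in range(config.n_genes)]

    # contiguous SNP windows; adjacent same-block genes overlap by n_share_gene
    gene_snp_idx: list[np.ndarray] = []
    starts: list[int] = []
    for g_i in range(config.n_genes):
        b = gene_block[g_i]
        if g_i > 0 and gene_block[g_i - 1] == b:
            start = starts[g_i - 1] + (w - n_share_gene)
        else:
            start = 0
        starts.append(start)
        idx = (start + np.arange(w)) % config.snps_per_block + b * config.snps_per_block
        gene_snp_idx.append(idx)

    rows = []
    qrows = []
    truth = SimTruth()
    grex_sum = {g: np.zeros(dosages.n_individuals) for g in genes}
    vmeta = dosages.variants
    for g_i, gene in enumerate(genes):
        idx = gene_snp_idx[g_i]
        base_w = rng.normal(0, 1, size=w) / np.sqrt(w)
        n_share_t = int(round(config.cross_tissue_sharing * w))
        shared_pos = rng.choice(w, size=n_share_t, replace=False)
        for t_i in range(config.n_tissues):
            tissue = f"tissue{t_i}"
            wvec = base_w.copy()
            if t_i > 0 and n_share_t < w:
                spec = np.setdiff1d(np.arange(w), shared_pos)
                wvec[spec] = rng.normal(0, 1, size=spec.size) / np.sqrt(w)
            tbl = pd.DataFrame({
                "gene": gene,
                "tissue": tissue,
                "variant_id": vmeta["variant_id"].to_numpy()[idx],
                "ref_allele": vmeta["ref_allele"].to_numpy()[idx],
                "effect_allele": vmeta["effect_allele"].to_numpy()[idx],
                "weight": wvec,
            })
            rows.append(tbl)
            qrows.append((gene, tissue, float(rng.uniform(0.05, 0.6)), float(10 ** rng.uniform(-12, -4))))
            truth.gene_weights[(gene, tissue)] = tbl[["variant_id", "weight"]].copy()
            grex_sum[gene] += dosages.dosages[:, idx] @ wvec
    weights = pd.concat(rows, ignore_index=True)
    quality = pd.DataFrame(qrows, columns=["gene", "tissue", "cv_R2", "cv_p"]).set_index(["gene", "tissue"])
    truth.true_grex = pd.DataFrame(
        {g: grex_sum[g] / config.n_tissues for g in genes},
        index=pd.Index(dosages.individuals, name="individual_id"),
    )
    truth.gene_effects = {g: float(config.driver_genes.get(g, 0.0)) for g in genes}
    return WeightDB(weights=weights, quality=quality), truth


def simulate_phenotype(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Trait + covariates from true GReX and driver effects.

    Quantitative: y = sum_g beta_g * standardized trueGReX_g + Gaussian
    noise scaled so the genetic share of variance equals ``heritability``
    (when any driver effect is nonzero).  Binary: the same construction on
    a standard-normal liability, thresholded at Phi^{-1}(1 - prevalence).
    Covariates (age, sex, 3 ancestry PCs) are drawn independently unless
    ``confound_strength`` > 0, in which case the first PC leaks into the
    genetic score's noise channel.
    """
    if truth.true_grex is None:
        raise ValueError("SimTruth lacks true GReX; run simulate_weight_models first")
    rng = config.stage_rng("phenotype")
    n = len(truth.true_grex)
    g = np.zeros(n)
    for gene, beta in truth.gene_effects.items():
        if beta != 0:
            col = truth.true_grex[gene].to_numpy()
            sd = col.std()
            if sd > 0:
                g = g + beta * (col - col.mean()) / sd
    covars = pd.DataFrame({
        "age": rng.uniform(18, 80, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "PC1": rng.standard_normal(n),
        "PC2": rng.standard_normal(n),
        "PC3": rng.standard_normal(n),
    }, index=truth.true_grex.index)
    var_g = g.var()
    h2 = config.heritability
    if var_g > 0 and 0 < h2 < 1:
        scale = np.sqrt(var_g * (1 - h2) / h2)
    elif var_g > 0 and h2 == 1:
        scale = 0.0
    else:
        scale = 1.0
    noise = scale * rng.standard_normal(n) + config.confound_strength * covars["PC1"].to_numpy()
    if config.binary_trait:
        liab = g + noise
        sd = liab.std()
        liab = (liab - liab.mean()) / (sd if sd > 0 else 1.0)
        trait = (liab > stats.norm.ppf(1 - config.prevalence)).astype(int)
    else:
        trait = g + noise
    out = covars.copy()
    out.insert(0, "trait", trait)
    return out


def truth_with_snp_driver(truth: SimTruth, dosages: DosageMatrix, gene: str, snp_id: str) -> SimTruth:
    """Variant truth in which one gene's genetic value is a single causal eQTL.

    The gene's true-GReX column is replaced by the (standardized) dosage of
    ``snp_id``, so any trait simulated from this truth is mediated entirely
    by that SNP — the setting in which conditioning an association test on
    the lead eQTL should remove the gene's whole signal.
    """
    if truth.true_grex is None:
        raise ValueError("truth lacks true GReX")
    vindex = dosages.variant_index()
    if snp_id not in vindex:
        raise KeyError(f"SNP {snp_id!r} absent from dosages")
    d = dosages.dosages[:, vindex[snp_id]].astype(float)
    sd = d.std()
    if sd == 0:
        raise ValueError(f"SNP {snp_id!r} is monomorphic")
    out = SimTruth(
        gene_effects=dict(truth.gene_effects),
        true_grex=truth.true_grex.copy(),
        gene_weights=dict(truth.gene_weights),
        carriers=truth.carriers,
        phecode_categories=truth.phecode_categories,
        phecode_base_rates=truth.phecode_base_rates,
    )
    out.true_grex[gene] = (d - d.mean()) / sd
    return out


def simulate_carriers(config: SimConfig, individuals: list[str]) -> pd.Series:
    """Bernoulli carrier labels at ``carrier_fraction``."""
    rng = config.stage_rng("carriers")
    lab = rng.random(len(individuals)) < config.carrier_fraction
    return pd.Series(lab, index=pd.Index(individuals, name="individual_id"), name="carrier")


def simulate_phecodes(
    config: SimConfig,
    carriers: pd.Series,
    truth: SimTruth | None = None,
    expression_score: pd.Series | None = None,
) -> pd.DataFrame:
    """Phecode event stream: Poisson visit counts on distinct random dates.

    Each (individual, phecode) count is Poisson with a per-code baseline
    mean drawn from ``phecode_base_rate``; carriers' means for
    ``carrier_enriched_codes`` are multiplied by the configured factor.
    When ``expression_score`` is given (any nonnegative per-individual
    score, e.g. an extreme-GReX indicator), the same multipliers also apply
    scaled by that score — this couples the enriched codes to expression.
    Events fall on distinct days drawn uniformly from a 10-year window.
    Categories are assigned to codes round-robin and recorded in ``truth``.
    """
    bad = [c for c, m in config.carrier_enriched_codes.items() if m < 1]
    if bad:
        raise ValueError(f"multiplier < 1 for codes {bad}")
    rng = config.stage_rng("phecodes")
    codes = config.phecode_ids()
    unknown = set(config.carrier_enriched_codes) - set(codes)
    if unknown:
        raise ValueError(f"enriched codes not among simulated phecodes: {sorted(unknown)}")
    individuals = list(carriers.index)
    n = len(individuals)
    base = rng.uniform(*config.phecode_base_rate, size=len(codes))
    categories = pd.Series(
        [f"category{(i % config.n_categories):02d}" for i in range(len(codes))],
        index=pd.Index(codes, name="phecode"), name="category",
    )
    carrier_arr = carriers.to_numpy(dtype=bool)
    if expression_score is not None:
        score = expression_score.reindex(individuals).fillna(0.0).to_numpy(dtype=float)
        if (score < 0).any():
            raise ValueError("expression_score must be nonnegative")
    else:
        score = None
    window_days = 3650
    rows_ind, rows_code, rows_date = [], [], []
    epoch = np.datetime64("2010-01-01")
    for j, code in enumerate(codes):
        lam = np.full(n, base[j])
        mult = config.carrier_enriched_codes.get(code)
        if mult is not None:
            lam = lam * np.where(carrier_arr, mult, 1.0)
            if score is not None:
                lam = lam * mult ** np.minimum(score, 1.0)
        counts = rng.poisson(lam)
        for i in np.nonzero(counts)[0]:
            k = min(int(counts[i]), window_days)
            days = rng.choice(window_days, size=k, replace=False)
            for d in days:
                rows_ind.append(individuals[i])
                rows_code.append(code)
                rows_date.append(epoch + np.timedelta64(int(d), "D"))
    events = pd.DataFrame({
        "individual_id": rows_ind,
        "phecode": rows_code,
        "date": pd.to_datetime(rows_date),
    })
    if truth is not None:
        truth.phecode_categories = categories
        truth.phecode_base_rates = pd.Series(base, index=categories.index, name="base_rate")
        truth.carriers = carriers
    return events


@dataclass
class SimulatedCohort:
    """Everything one synthetic study needs, plus its ground truth."""

    config: SimConfig
    dosages: DosageMatrix
    weights: WeightDB
    phenotype: pd.DataFrame
    carriers: pd.Series
    events: pd.DataFrame
    categories: pd.Series
    truth: SimTruth


def simulate_cohort(config: SimConfig, expression_score: pd.Series | None = None) -> SimulatedCohort:
    """Run every stage under the config's seed fan-out."""
    dosages = simulate_genotypes(config)
    weights, truth = simulate_weight_models(config, dosages)
    phenotype = simulate_phenotype(truth, config)
    carriers = simulate_carriers(config, dosages.individuals)
    events = simulate_phecodes(config, carriers, truth=truth, expression_score=expression_score)
    return SimulatedCohort(config, dosages, weights, phenotype, carriers, events, truth.phecode_categories, truth)
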