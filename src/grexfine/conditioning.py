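"""Conditional fine-mapping of correlated gene signals.

Shared eQTL SNPs make predicted expressions of neighboring genes
correlated, so several genes can carry one association signal.  To test
independence, a target gene's per-tissue predicted expression is replaced
by its least-squares residual on the predicted expressions of the other
candidate genes — but only in tissues where target and conditioning gene
are actually correlated (Spearman p below a gate, default 0.05).  The
conditioned expressions then re-enter the joint PC test (and, across
cohorts, the weighted-Z meta-analysis): a true driver keeps its signal,
a correlated passenger loses it.  SNP-level conditioning (adding a named
dosage column to the covariates) checks that the eQTLs behind the models
explain the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import AssociationResult, PhenotypeTable, metal_combine, multixcan_fit
from .grex import DosageMatrix, GReXCube


@dataclass
class ConditionPlan:
    """Which genes to regress out of a target, and where.

    ``applicability`` (filled by :func:`build_condition_plan`) maps tissue ->
    the subset of conditioning genes whose Spearman correlation with the
    target passes the gate in that tissue.
    """

    target: str
    conditioning: list[str]
    gate_p: float = 0.05
    applicability: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.target in self.conditioning:
            raise ValueError(f"target {self.target!r} appears in its own conditioning set")
        for tissue, genes in self.applicability.items():
            if not set(genes) <= set(self.conditioning):
                raise ValueError(f"applicability for {tissue} not a subset of the conditioning set")


def build_condition_plan(
    cube: GReXCube, target: str, conditioning: list[str], gate_p: float = 0.05
) -> ConditionPlan:
    """Evaluate the pairwise Spearman gate per (conditioning gene, tissue).

    A conditioning gene enters a tissue's regression iff its own pairwise
    Spearman correlation with the target has p < ``gate_p`` in that tissue.
    Tissues that do not model the target, or where no gene passes, get an
    empty applicability set (the target is left unchanged there).
    """
    plan = ConditionPlan(target=target, conditioning=list(conditioning), gate_p=gate_p)
    for tissue, df in cube.tissues.items():
        if target not in df.columns:
            continue
        passed = []
        t_col = df[target].to_numpy(dtype=float)
        for g in conditioning:
            if g not in df.columns:
                continue
            g_col = df[g].to_numpy(dtype=float)
            ok = ~(np.isnan(t_col) | np.isnan(g_col))
            if ok.sum() < 3:
                continue
            import warnings
            with warnings.catch_warnings():
                # a constant column has undefined correlation: treat as no-pass
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                _, p = stats.spearmanr(t_col[ok], g_col[ok])
            if np.isfinite(p) and p < gate_p:
                passed.append(g)
        plan.applicability[tissue] = passed
    return plan


def conditioned_expression(cube: GReXCube, plan: ConditionPlan) -> tuple[GReXCube, pd.DataFrame]:
    """Residualize the target's per-tissue GReX on the gated conditioning genes.

    In each tissue where at least one conditioning gene passes the gate, the
    target column becomes its least-squares residual (with intercept) on
    those genes; rank-deficient conditioning columns are dropped with a
    warning.  Other tissues pass through unchanged.  Returns a cube holding
    the target gene only, plus a per-tissue report of genes regressed out.
    """
    if not plan.applicability:
        built = build_condition_plan(cube, plan.target, plan.conditioning, plan.gate_p)
        plan = built
    out_tissues: dict[str, pd.DataFrame] = {}
    report_rows = []
    for tissue, df in cube.tissues.items():
        if plan.target not in df.columns:
            continue
        y = df[plan.target].to_numpy(dtype=float)
        for g in plan.conditioning:
            if g in df.columns and (df[g].to_numpy() == 0).all():
                raise ValueError(f"conditioning gene {g!r} is degenerate (all-zero) in tissue {tissue}")
        used = plan.applicability.get(tissue, [])
        cols = [df[g].to_numpy(dtype=float) for g in used if g in df.columns]
        if cols:
            X = np.column_stack([np.ones(len(y))] + cols)
            rank = np.linalg.matrix_rank(X)
            if rank < X.shape[1]:
                # drop dependent columns greedily
                keep, kept_genes = [np.ones(len(y))], []
                for g, c in zip(used, cols):
                    trial = np.column_stack(keep + [c])
                    if np.linalg.matrix_rank(trial) > len(keep):
                        keep.append(c)
                        kept_genes.append(g)
                X = np.column_stack(keep)
                used = kept_genes
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
        else:
            resid = y
        out_tissues[tissue] = pd.DataFrame({plan.target: resid}, index=df.index)
        report_rows.append((tissue, ",".join(used)))
    if not out_tissues:
        raise ValueError(f"target {plan.target!r} not modeled in any tissue")
    report = pd.DataFrame(report_rows, columns=["tissue", "genes_regressed_out"])
    return GReXCube(out_tissues, provenance=f"conditioned:{plan.target}"), report


def conditional_multixcan(
    cohorts: list[tuple[GReXCube, PhenotypeTable, int]],
    genes: list[str],
    gate_p: float = 0.05,
    condition_limit: float = 30,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Marginal vs conditioned joint-test p for each gene in a candidate set.

    ``cohorts`` is a list of (cube, phenotype, N).  For each gene, the other
    listed genes form its conditioning set; conditioned expressions are
    built per cohort, the joint PC test is rerun, and with more than one
    cohort both marginal and conditional p are meta-analyzed by the
    weighted-Z scheme.  When ``threshold`` is given, each gene is labeled
    ``independent`` (p_cond below threshold) or ``correlated_passenger``.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for conditional analysis")
    rows = []
    for gene in genes:
        others = [g for g in genes if g != gene]
        marg_res, cond_res, ns = [], [], []
        for cube, pheno, n in cohorts:
            marg = multixcan_fit(cube, gene, pheno, condition_limit)
            plan = build_condition_plan(cube, gene, others, gate_p)
            cond_cube, _ = conditioned_expression(cube, plan)
            cond = multixcan_fit(cond_cube, gene, pheno, condition_limit)
            marg_res.append(marg)
            cond_res.append(cond)
            ns.append(n)
        if len(cohorts) > 1:
            p_marg = metal_combine(marg_res, ns).p_meta
            p_cond = metal_combine(cond_res, ns).p_meta
        else:
            p_marg, p_cond = marg_res[0].p, cond_res[0].p
        label = ""
        if threshold is not None:
            label = "independent" if (np.isfinite(p_cond) and p_cond < threshold) else "correlated_passenger"
        rows.append((gene, p_marg, p_cond, label))
    return pd.DataFrame(rows, columns=["gene", "p_marginal", "p_cond", "label"])


def condition_on_snps(
    pheno: PhenotypeTable, dosages: DosageMatrix, snp_ids: list[str]
) -> PhenotypeTable:
    """Augment the covariate set with named SNP dosage columns.

    Downstream joint tests then measure GReX association conditional on
    those SNPs (the GWAS-style lead-SNP conditioning).  An empty SNP list
    returns the input unchanged; unknown SNPs raise, listing the ids.
    """
    if not snp_ids:
        return pheno
    vindex = dosages.variant_index()
    missing = [s for s in snp_ids if s not in vindex]
    if missing:
        raise KeyError(f"SNPs absent from dosages: {missing}")
    cols = {}
    ind_pos = {ind: i for i, ind in enumerate(dosages.individuals)}
    row_idx = [ind_pos[i] for i in pheno.individuals]
    for s in snp_ids:
        cols[f"snp_{s}"] = dosages.dosages[row_idx, vindex[s]]
    extra = pd.DataFrame(cols, index=pheno.data.index)
    return pheno.with_extra_covariates(extra)
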