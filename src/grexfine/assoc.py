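"""Cross-tissue association testing, meta-analysis, and significance thresholds.

The core test takes the individuals x tissues matrix of one gene's
predicted expression, standardizes it, replaces it by its leading principal
components (discarding components whose eigenvalue ratio to the largest
exceeds a condition-number limit, to tame collinearity among tissues), and
jointly tests the retained components against the trait: a partial F-test
against the covariate-only model for quantitative traits, a likelihood-
ratio chi-square for binary traits.  The joint statistic is unsigned, so a
direction is attached from the sign of the mean single-tissue Wald Z.
Cohorts are combined by the sample-size-weighted Z scheme
Z_meta = sum(sqrt(N_i) Z_i) / sqrt(sum N_i) with Z_i = Phi^{-1}(1 - p_i/2)
signed by each cohort's direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grex import GReXCube

MIN_P = np.finfo(float).tiny


@dataclass
class PhenotypeTable:
    """Trait + covariates per individual.  Binary traits are coded {0, 1}."""

    data: pd.DataFrame                 # index = individual ids
    trait: str = "trait"
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.trait not in self.data.columns:
            raise ValueError(f"trait column {self.trait!r} missing")
        missing = [c for c in self.covariates if c not in self.data.columns]
        if missing:
            raise ValueError(f"covariate columns missing: {missing}")
        y = self.data[self.trait]
        if y.isna().any():
            raise ValueError("missing trait values among analyzed individuals")
        self.is_binary = set(np.unique(y)) <= {0, 1}

    @property
    def individuals(self) -> list[str]:
        return list(self.data.index)

    def trait_values(self) -> np.ndarray:
        return self.data[self.trait].to_numpy(dtype=float)

    def covariate_matrix(self) -> np.ndarray:
        if not self.covariates:
            return np.empty((len(self.data), 0))
        return self.data[list(self.covariates)].to_numpy(dtype=float)

    def with_extra_covariates(self, extra: pd.DataFrame) -> "PhenotypeTable":
        data = self.data.join(extra, how="left")
        return PhenotypeTable(data=data, trait=self.trait,
                              covariates=self.covariates + tuple(extra.columns))


@dataclass
class AssociationResult:
    gene: str
    n_tissues: int
    n_components: int
    statistic: float
    p: float
    direction: int
    mean_z: float
    testable: bool = True


@dataclass
class MetaResult:
    gene: str
    z_meta: float
    p_meta: float
    cohort_ns: list[int]


def _fit_glm(y: np.ndarray, X: np.ndarray, binary: bool):
    """Full-model fit; returns the statsmodels results object."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if binary:
            return sm.Logit(y, X).fit(disp=0, maxiter=100)
        return sm.OLS(y, X).fit()


def single_tissue_assoc(cube: GReXCube, pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-(gene, tissue) Wald Z of the GReX coefficient.

    Logistic regression of the binary trait (linear for quantitative) on
    GReX plus covariates.  Constant GReX columns are skipped; separation or
    non-convergence yields a missing Z with a flag.
    """
    y = pheno.trait_values()
    covars = pheno.covariate_matrix()
    n = len(y)
    rows = []
    for tissue, df in cube.tissues.items():
        sub = df.loc[pheno.individuals]
        for gene in sub.columns:
            x = sub[gene].to_numpy(dtype=float)
            if np.std(x) == 0:
                continue
            X = np.column_stack([np.ones(n), x, covars])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    if pheno.is_binary:
                        res = sm.Logit(y, X).fit(disp=0, maxiter=100)
                        if not res.mle_retvals.get("converged", True):
                            raise RuntimeError("no convergence")
                    else:
                        res = sm.OLS(y, X).fit()
                z = float(res.params[1] / res.bse[1])
                rows.append((gene, tissue, z, False))
            except Exception:
                rows.append((gene, tissue, np.nan, True))
    return pd.DataFrame(rows, columns=["gene", "tissue", "Z", "failed"])


def assign_direction(z_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene direction = sign of the unweighted mean of available
    single-tissue Z; an exact zero mean ties to +1; all-missing genes are
    flagged undefined."""
    rows = []
    for gene, grp in z_table.groupby("gene", sort=False):
        z = grp["Z"].dropna()
        if z.empty:
            rows.append((gene, np.nan, 0, True))
            continue
        mean_z = float(z.mean())
        rows.append((gene, mean_z, 1 if mean_z >= 0 else -1, False))
    return pd.DataFrame(rows, columns=["gene", "mean_Z", "direction", "undefined"])


def _retained_components(M: np.ndarray, condition_limit: float) -> np.ndarray:
    """Standardize columns, return PC scores whose eigenvalue passes the
    lambda_max / lambda_i <= condition_limit rule."""
    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return np.empty((M.shape[0], 0))
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    u, s, _ = np.linalg.svd(Z, full_matrices=False)
    lam = s**2 / max(M.shape[0] - 1, 1)
    pos = lam > 1e-12
    if not pos.any():
        return np.empty((M.shape[0], 0))
    ok = pos & (lam.max() / np.where(pos, lam, np.inf) <= condition_limit)
    return u[:, ok] * s[ok]


def multixcan_fit(
    cube: GReXCube,
    gene: str,
    pheno: PhenotypeTable,
    condition_limit: float = 30,
    z_table: pd.DataFrame | None = None,
) -> AssociationResult:
    """Joint PC test of a gene's multi-tissue GReX against the trait.

    Quantitative traits: partial F-test of the retained components against
    the covariate-only model.  Binary traits: likelihood-ratio chi-square.
    ``z_table`` (from :func:`single_tissue_assoc`) supplies the direction;
    if omitted it is computed for this gene alone.
    """
    gm = cube.gene_matrix(gene).loc[pheno.individuals]
    M = gm.to_numpy(dtype=float)
    y = pheno.trait_values()
    covars = pheno.covariate_matrix()
    n = len(y)
    comps = _retained_components(M, condition_limit)
    if z_table is None:
        sub_cube = GReXCube({t: df[[gene]] for t, df in cube.tissues.items() if gene in df.columns})
        z_table = single_tissue_assoc(sub_cube, pheno)
    dirs = assign_direction(z_table[z_table["gene"] == gene])
    mean_z = float(dirs["mean_Z"].iloc[0]) if len(dirs) else np.nan
    direction = int(dirs["direction"].iloc[0]) if len(dirs) else 0
    if comps.shape[1] == 0:
        return AssociationResult(gene, gm.shape[1], 0, np.nan, np.nan, direction, mean_z, testable=False)
    X_red = np.column_stack([np.ones(n), covars])
    if np.linalg.matrix_rank(X_red) < X_red.shape[1]:
        raise ValueError("covariates collinear (reduced design rank-deficient)")
    # components that are linear combinations of the covariates add nothing
    # testable (e.g. after conditioning on every model SNP); drop them
    base_rank = X_red.shape[1]
    kept = []
    for j in range(comps.shape[1]):
        trial = np.column_stack([X_red] + [comps[:, i] for i in kept] + [comps[:, j]])
        if np.linalg.matrix_rank(trial) == base_rank + len(kept) + 1:
            kept.append(j)
    comps = comps[:, kept]
    if comps.shape[1] == 0:
        return AssociationResult(gene, gm.shape[1], 0, np.nan, np.nan, direction, mean_z, testable=False)
    X_full = np.column_stack([X_red, comps])
    k = comps.shape[1]
    if pheno.is_binary:
        full = _fit_glm(y, X_full, True)
        red = _fit_glm(y, X_red, True)
        lr = 2.0 * (full.llf - red.llf)
        stat = max(float(lr), 0.0)
        p = float(stats.chi2.sf(stat, k))
    else:
        full = _fit_glm(y, X_full, False)
        red = _fit_glm(y, X_red, False)
        df_resid = n - X_full.shape[1]
        f = ((red.ssr - full.ssr) / k) / (full.ssr / df_resid)
        stat = float(f)
        p = float(stats.f.sf(stat, k, df_resid))
    p = min(max(p, MIN_P), 1.0)
    return AssociationResult(gene, gm.shape[1], k, stat, p, direction, mean_z)


def multixcan_all(cube: GReXCube, pheno: PhenotypeTable, condition_limit: float = 30) -> pd.DataFrame:
    """multixcan_fit over every gene in the cube, one row per gene."""
    z_table = single_tissue_assoc(cube, pheno)
    rows = []
    for gene in cube.genes():
        r = multixcan_fit(cube, gene, pheno, condition_limit, z_table=z_table)
        rows.append((r.gene, r.n_tissues, r.n_components, r.statistic, r.p, r.mean_z, r.direction, r.testable))
    return pd.DataFrame(rows, columns=["gene", "n_tissues", "n_components", "statistic", "p", "mean_Z", "direction", "testable"])


def metal_combine(results: list[AssociationResult], ns: list[int]) -> MetaResult:
    """Sample-size-weighted Z combination of per-cohort joint-test p-values.

    Z_i = Phi^{-1}(1 - p_i/2) x direction_i;
    Z_meta = sum(sqrt(N_i) Z_i) / sqrt(sum N_i); p two-sided.
    Cohorts with an undefined direction are dropped with a warning;
    p_i = 0 is clamped to the smallest positive float.
    """
    if not results:
        raise ValueError("no cohorts to combine")
    if len(results) != len(ns):
        raise ValueError("results and ns length mismatch")
    zs, ws, used_ns = [], [], []
    for r, n in zip(results, ns):
        if r.direction == 0 or not np.isfinite(r.p):
            warnings.warn(f"cohort for gene {r.gene} dropped (missing direction or p)")
            continue
        p = r.p
        if p <= 0:
            warnings.warn(f"p = 0 clamped for gene {r.gene}")
            p = MIN_P
        zs.append(stats.norm.isf(p / 2) * r.direction)
        ws.append(np.sqrt(n))
        used_ns.append(n)
    if not zs:
        raise ValueError("all cohorts dropped")
    z_meta = float(np.dot(ws, zs) / np.sqrt(np.sum(np.square(ws))))
    p_meta = float(min(max(2 * stats.norm.sf(abs(z_meta)), MIN_P), 1.0))
    return MetaResult(results[0].gene, z_meta, p_meta, used_ns)


def bonferroni_threshold(n_traits: int, n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / (n_traits x n_genes)."""
    if n_traits <= 0 or n_genes <= 0:
        raise ValueError("counts must be positive")
    return alpha / (n_traits * n_genes)


def permutation_threshold(
    genome_genes: pd.DataFrame,
    region_gene_count: int,
    region_span: float,
    cube: GReXCube,
    pheno: PhenotypeTable,
    n_perm: int = 100,
    seed: int = 0,
    match_tol: float = 0.10,
    orientation: str = "significance",
) -> tuple[float, np.ndarray]:
    """Permutation-based threshold from random windows of adjacent genes.

    ``genome_genes`` is an ordered table (gene, position).  Draws ``n_perm``
    windows of adjacent genes matched to the region on gene count and
    genomic span (both within ``match_tol``), runs the joint PC test on
    every window gene, and pools the null p-values.  With the default
    ``orientation="significance"`` the returned threshold is the 5th
    percentile of the pooled null p (the 95th percentile of significance);
    ``orientation="literal"`` returns the verbatim 95th percentile of p.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be at least 20")
    if len(genome_genes) < 10 * region_gene_count:
        raise ValueError("genome gene list must be at least 10x the region size")
    if orientation not in ("significance", "literal"):
        raise ValueError(f"unknown orientation {orientation!r}")
    rng = np.random.default_rng(seed)
    genes = genome_genes["gene"].to_numpy()
    pos = genome_genes["position"].to_numpy(dtype=float)
    candidates = []
    lo_c = int(np.floor(region_gene_count * (1 - match_tol)))
    hi_c = int(np.ceil(region_gene_count * (1 + match_tol)))
    for start in range(len(genes)):
        for cnt in range(max(lo_c, 1), hi_c + 1):
            end = start + cnt
            if end > len(genes):
                break
            span = pos[end - 1] - pos[start]
            if abs(span - region_span) <= match_tol * region_span:
                candidates.append((start, cnt))
    if len(candidates) < n_perm:
        raise ValueError(f"only {len(candidates)} matched windows found, need {n_perm}")
    picks = rng.choice(len(candidates), size=n_perm, replace=False)
    z_table = single_tissue_assoc(cube, pheno)
    pooled = []
    for ci in picks:
        start, cnt = candidates[ci]
        for gene in genes[start:start + cnt]:
            r = multixcan_fit(cube, gene, pheno, z_table=z_table)
            if r.testable and np.isfinite(r.p):
                pooled.append(r.p)
    pooled = np.array(pooled)
    q = 5.0 if orientation == "significance" else 95.0
    return float(np.percentile(pooled, q)), pooled
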