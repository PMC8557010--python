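"""Genetically regulated expression (GReX): containers, I/O, prediction, normalization.

A GReX value is the linear score ``sum_k w_k * dosage_k`` over the SNPs of a
sparse eQTL weight model for one gene in one tissue.  This module reads the
plain-text dosage dialect (one row per variant: chromosome, variant id,
position, reference allele, effect allele, frequency, then one dosage in
[0, 2] per individual), holds weight models with their cross-validated
quality statistics, applies the quality filter, computes predicted
expression with allele reconciliation, and provides the outlier-filter /
PC-adjust / inverse-normal normalization pipeline and pairwise expression
correlation used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DOSAGE_COLUMNS = ["chromosome", "variant_id", "position", "ref_allele", "effect_allele", "frequency"]
WEIGHT_COLUMNS = ["gene", "tissue", "variant_id", "ref_allele", "effect_allele", "weight", "cv_R2", "cv_p"]


@dataclass
class DosageMatrix:
    """Individuals x variants allele-dosage matrix with variant metadata.

    ``variants`` is a DataFrame with columns ``chromosome, variant_id,
    position, ref_allele, effect_allele, frequency``; ``dosages`` has shape
    (n_individuals, n_variants) with entries in [0, 2].
    """

    individuals: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n_ind, n_var = self.dosages.shape if self.dosages.size else (len(self.individuals), len(self.variants))
        if self.dosages.size == 0:
            self.dosages = self.dosages.reshape(len(self.individuals), len(self.variants))
        if self.dosages.shape != (len(self.individuals), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.variants)} variants"
            )
        if len(set(self.variants["variant_id"])) != len(self.variants):
            raise ValueError("duplicate variant ids in dosage matrix")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variants["variant_id"])}


@dataclass
class WeightDB:
    """Sparse per-(gene, tissue) eQTL weight models with quality statistics.

    ``weights``: DataFrame with columns ``gene, tissue, variant_id,
    ref_allele, effect_allele, weight``.  ``quality``: DataFrame indexed by
    (gene, tissue) with columns ``cv_R2, cv_p``.
    """

    weights: pd.DataFrame
    quality: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.weights.duplicated(subset=["gene", "tissue", "variant_id"])
        if dup.any():
            raise ValueError("duplicate (gene, tissue, variant) triples in weight table")
        if not np.isfinite(self.weights["weight"]).all():
            raise ValueError("non-finite weights")

    def models(self) -> list[tuple[str, str]]:
        return list(self.quality.index)

    def model_weights(self, gene: str, tissue: str) -> pd.DataFrame:
        w = self.weights
        return w[(w["gene"] == gene) & (w["tissue"] == tissue)]


@dataclass
class GReXCube:
    """Tissue-indexed set of individuals x genes predicted-expression matrices.

    ``tissues`` maps tissue name -> DataFrame (index = individual ids, in an
    ordering shared across tissues; columns = genes with a retained model in
    that tissue).
    """

    tissues: dict[str, pd.DataFrame]
    provenance: str = ""

    def __post_init__(self) -> None:
        orders = [tuple(df.index) for df in self.tissues.values()]
        if orders and any(o != orders[0] for o in orders[1:]):
            raise ValueError("individual ordering differs across tissues")

    @property
    def individuals(self) -> list[str]:
        for df in self.tissues.values():
            return list(df.index)
        return []

    def genes(self) -> list[str]:
        out: list[str] = []
        for df in self.tissues.values():
            for g in df.columns:
                if g not in out:
                    out.append(g)
        return out

    def gene_matrix(self, gene: str) -> pd.DataFrame:
        """Individuals x tissues matrix for one gene (tissues that model it)."""
        cols = {t: df[gene] for t, df in self.tissues.items() if gene in df.columns}
        if not cols:
            raise KeyError(f"gene {gene!r} not present in any tissue")
        return pd.DataFrame(cols)

    def subset_individuals(self, ids: list[str]) -> "GReXCube":
        return GReXCube({t: df.loc[ids] for t, df in self.tissues.items()}, self.provenance)

    def copy(self) -> "GReXCube":
        return GReXCube({t: df.copy() for t, df in self.tissues.items()}, self.provenance)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dosage(path: str | Path, individuals: list[str] | None = None) -> DosageMatrix:
    """Parse a whitespace-delimited text dosage file.

    Each line: chromosome, variant id, position, ref allele, effect allele,
    frequency, then one dosage per individual.  Raises on ragged rows and on
    dosages outside [0, 2], naming the offending line/variant.
    """
    path = Path(path)
    meta_rows = []
    dosage_rows = []
    n_ind = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected at least 6 metadata fields")
            chrom, vid, pos, ref, eff, freq = parts[:6]
            vals = parts[6:]
            if n_ind is None:
                n_ind = len(vals)
            elif len(vals) != n_ind:
                raise ValueError(f"{path}:{lineno}: ragged row ({len(vals)} dosages, expected {n_ind})")
            try:
                row = np.array(vals, dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric dosage for variant {vid}") from exc
            if row.size and (row.min() < 0 or row.max() > 2):
                raise ValueError(f"{path}:{lineno}: dosage outside [0, 2] for variant {vid}")
            meta_rows.append((chrom, vid, int(pos), ref, eff, float(freq)))
            dosage_rows.append(row)
    if n_ind is None:
        n_ind = 0 if individuals is None else len(individuals)
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n_ind)]
    elif len(individuals) != n_ind and meta_rows:
        raise ValueError(f"{len(individuals)} individual ids for {n_ind} dosage columns")
    variants = pd.DataFrame(meta_rows, columns=DOSAGE_COLUMNS)
    dosages = (np.vstack(dosage_rows).T if dosage_rows else np.empty((len(individuals), 0)))
    return DosageMatrix(individuals=list(individuals), variants=variants, dosages=dosages)


def write_dosage(dm: DosageMatrix, path: str | Path) -> None:
    """Write the text dosage format (round-trips bit-exactly through read_dosage)."""
    with open(path, "w") as fh:
        for j in range(dm.n_variants):
            meta = dm.variants.iloc[j]
            vals = " ".join(repr(float(x)) for x in dm.dosages[:, j])
            fh.write(
                f"{meta['chromosome']} {meta['variant_id']} {meta['position']} "
                f"{meta['ref_allele']} {meta['effect_allele']} {float(meta['frequency'])!r}"
                + (" " + vals if vals else "")
                + "\n"
            )


def read_weights(path: str | Path) -> WeightDB:
    """Read the weight-model TSV (header: gene tissue variant_id ref_allele effect_allele weight cv_R2 cv_p)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str, "variant_id": str})
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    quality = df.groupby(["gene", "tissue"])[["cv_R2", "cv_p"]].first()
    weights = df[["gene", "tissue", "variant_id", "ref_allele", "effect_allele", "weight"]].copy()
    return WeightDB(weights=weights, quality=quality)


def write_weights(db: WeightDB, path: str | Path) -> None:
    df = db.weights.merge(db.quality.reset_index(), on=["gene", "tissue"])
    df[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def write_grex(cube: GReXCube, outdir: str | Path) -> None:
    """One TSV per tissue (rows = individuals, columns = genes)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for tissue, df in cube.tissues.items():
        df.to_csv(outdir / f"grex_{tissue}.tsv", sep="\t", index_label="individual_id")


def read_grex(outdir: str | Path) -> GReXCube:
    outdir = Path(outdir)
    tissues = {}
    for f in sorted(outdir.glob("grex_*.tsv")):
        tissue = f.stem[len("grex_"):]
        tissues[tissue] = pd.read_csv(f, sep="\t", index_col="individual_id")
    return GReXCube(tissues=tissues, provenance=str(outdir))


# ---------------------------------------------------------------------------
# Model filtering and prediction
# ---------------------------------------------------------------------------

def filter_models(db: WeightDB, r2_min: float = 0.01, p_max: float = 0.05) -> WeightDB:
    """Keep models with cross-validated R² strictly above ``r2_min`` and
    cross-validated p strictly below ``p_max`` (both inequalities strict)."""
    if db.quality[["cv_R2", "cv_p"]].isna().any().any():
        bad = db.quality[db.quality[["cv_R2", "cv_p"]].isna().any(axis=1)]
        raise ValueError(f"missing quality record for models: {list(bad.index)}")
    keep = db.quality[(db.quality["cv_R2"] > r2_min) & (db.quality["cv_p"] < p_max)]
    kept_keys = set(keep.index)
    mask = [
        (g, t) in kept_keys
        for g, t in zip(db.weights["gene"], db.weights["tissue"])
    ]
    return WeightDB(weights=db.weights[mask].reset_index(drop=True), quality=keep)


@dataclass
class PredictionReport:
    """Per-model accounting of how many model variants could be used."""

    rows: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene", "tissue", "n_model_snps", "n_used", "n_flipped", "n_missing", "n_skipped"]))


def predict_expression(dosages: DosageMatrix, db: WeightDB) -> tuple[GReXCube, PredictionReport]:
    """Compute GReX = sum of weight x effective dosage per (individual, gene, tissue).

    Allele reconciliation per variant: if the model's (ref, effect) alleles
    equal the dosage file's, the stored dosage counts the effect allele and
    is used as-is; if they are exactly swapped, the effective dosage is
    ``2 - dosage``; anything else is irreconcilable and the variant is
    skipped with a warning.  Model variants absent from the dosage file
    contribute 0.
    """
    vindex = dosages.variant_index()
    vmeta = dosages.variants.set_index("variant_id")
    tissues: dict[str, dict[str, np.ndarray]] = {}
    report_rows = []
    for (gene, tissue), _ in db.quality.iterrows():
        mw = db.model_weights(gene, tissue)
        score = np.zeros(dosages.n_individuals)
        n_used = n_flip = n_missing = n_skip = 0
        for _, row in mw.iterrows():
            vid = row["variant_id"]
            if vid not in vindex:
                n_missing += 1
                continue
            d = dosages.dosages[:, vindex[vid]]
            ref_d, eff_d = vmeta.loc[vid, "ref_allele"], vmeta.loc[vid, "effect_allele"]
            if (row["ref_allele"], row["effect_allele"]) == (ref_d, eff_d):
                score = score + row["weight"] * d
                n_used += 1
            elif (row["ref_allele"], row["effect_allele"]) == (eff_d, ref_d):
                score = score + row["weight"] * (2.0 - d)
                n_used += 1
                n_flip += 1
            else:
                logger.warning("irreconcilable alleles for %s in model (%s, %s); variant skipped", vid, gene, tissue)
                n_skip += 1
        tissues.setdefault(tissue, {})[gene] = score
        report_rows.append((gene, tissue, len(mw), n_used, n_flip, n_missing, n_skip))
    cube = GReXCube(
        tissues={
            t: pd.DataFrame(cols, index=pd.Index(dosages.individuals, name="individual_id"))
            for t, cols in tissues.items()
        },
        provenance="predict_expression",
    )
    report = PredictionReport(pd.DataFrame(
        report_rows, columns=["gene", "tissue", "n_model_snps", "n_used", "n_flipped", "n_missing", "n_skipped"]))
    return cube, report


def drop_degenerate(cube: GReXCube) -> tuple[GReXCube, list[tuple[str, str]]]:
    """Remove (gene, tissue) columns whose prediction is exactly 0 for every
    individual; returns the pruned cube and the removal log."""
    removed: list[tuple[str, str]] = []
    tissues = {}
    for tissue, df in cube.tissues.items():
        keep = []
        for gene in df.columns:
            if (df[gene].to_numpy() == 0).all():
                removed.append((gene, tissue))
            else:
                keep.append(gene)
        tissues[tissue] = df[keep]
    return GReXCube(tissues=tissues, provenance=cube.provenance), removed


# ---------------------------------------------------------------------------
# Normalization and correlation
# ---------------------------------------------------------------------------

def _tukey_mask(col: np.ndarray) -> np.ndarray:
    """True where a value lies beyond [Q1 - 1.5 IQR, Q3 + 1.5 IQR] (computed on non-missing values)."""
    ok = ~np.isnan(col)
    q1, q3 = np.percentile(col[ok], [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    out = np.zeros_like(col, dtype=bool)
    out[ok] = (col[ok] < lo) | (col[ok] > hi)
    return out


def _residualize(mat: np.ndarray, covars: np.ndarray | None) -> np.ndarray:
    """Column-wise least-squares residual on [1, covars]; NaNs propagate."""
    out = mat.copy()
    n = mat.shape[0]
    design = np.ones((n, 1)) if covars is None or covars.size == 0 else np.column_stack([np.ones(n), covars])
    for j in range(mat.shape[1]):
        col = mat[:, j]
        ok = ~np.isnan(col)
        if ok.sum() <= design.shape[1]:
            continue
        X = design[ok]
        beta, *_ = np.linalg.lstsq(X, col[ok], rcond=None)
        out[ok, j] = col[ok] - X @ beta
    return out


def _expression_pcs(mat: np.ndarray, n_pcs: int) -> np.ndarray:
    """Leading principal-component scores of a (possibly NaN-holding) matrix,
    NaNs mean-imputed for the decomposition only."""
    if n_pcs <= 0:
        return np.empty((mat.shape[0], 0))
    filled = mat.copy()
    mu = np.nanmean(filled, axis=0)
    idx = np.where(np.isnan(filled))
    filled[idx] = np.take(mu, idx[1])
    filled = filled - filled.mean(axis=0)
    u, s, _ = np.linalg.svd(filled, full_matrices=False)
    k = min(n_pcs, (s > 1e-12).sum())
    return u[:, :k] * s[:k]


def inverse_normal_transform(col: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform; ranks use the (r)/(n+1) offset,
    ties averaged; NaNs propagate."""
    out = np.full_like(col, np.nan, dtype=float)
    ok = ~np.isnan(col)
    r = stats.rankdata(col[ok])
    out[ok] = stats.norm.ppf(r / (ok.sum() + 1))
    return out


def normalize_expression(
    matrix: pd.DataFrame,
    covariate_pcs: np.ndarray | None = None,
    n_expr_pcs: int = 20,
) -> pd.DataFrame:
    """Outlier-filter / PC-adjust / inverse-normal pipeline for expression columns.

    Column-wise, in order: (1) values beyond the Tukey fences
    [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are set missing; (2) columns are
    residualized on the leading expression PCs plus any supplied genotype
    PCs; (3) rank-based inverse-normal transform; (4) residualized again
    (normalization re-introduces PC correlation, hence the second pass);
    (5) the outlier rule re-applied.  Missing values propagate throughout.

    Raises on constant columns (the IQR fence is undefined as a filter) and
    on columns with fewer than 10 non-missing values.
    """
    vals = matrix.to_numpy(dtype=float, copy=True)
    for j, name in enumerate(matrix.columns):
        col = vals[:, j]
        ok = ~np.isnan(col)
        if ok.sum() < 10:
            raise ValueError(f"column {name!r} has fewer than 10 non-missing values")
        if np.nanstd(col) == 0:
            raise ValueError(f"column {name!r} is constant")
    n_pcs = min(n_expr_pcs, vals.shape[1] - 1)

    vals[_tukey_mask_matrix(vals)] = np.nan
    covars = _stack_pcs(_expression_pcs(vals, n_pcs), covariate_pcs)
    vals = _residualize(vals, covars)
    vals = np.column_stack([inverse_normal_transform(vals[:, j]) for j in range(vals.shape[1])])
    covars = _stack_pcs(_expression_pcs(vals, n_pcs), covariate_pcs)
    vals = _residualize(vals, covars)
    vals[_tukey_mask_matrix(vals)] = np.nan
    return pd.DataFrame(vals, index=matrix.index, columns=matrix.columns)


def _tukey_mask_matrix(vals: np.ndarray) -> np.ndarray:
    return np.column_stack([_tukey_mask(vals[:, j]) for j in range(vals.shape[1])])


def _stack_pcs(expr_pcs: np.ndarray, covariate_pcs: np.ndarray | None) -> np.ndarray:
    if covariate_pcs is None or np.size(covariate_pcs) == 0:
        return expr_pcs
    return np.column_stack([expr_pcs, np.asarray(covariate_pcs, dtype=float)])


def correlate_expression(cube_a: GReXCube, cube_b: GReXCube, method: str = "spearman") -> pd.DataFrame:
    """Pairwise per-tissue correlations between the genes of two cubes.

    Returns rows (gene_a, gene_b, tissue, rho, p); pairs with fewer than 3
    paired non-missing observations are emitted with NaN rho/p and
    ``skipped=True``.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    rows = []
    shared = [t for t in cube_a.tissues if t in cube_b.tissues]
    for tissue in shared:
        da, db_ = cube_a.tissues[tissue], cube_b.tissues[tissue]
        if tuple(da.index) != tuple(db_.index):
            raise ValueError(f"individual ordering differs between cubes in tissue {tissue}")
        for ga in da.columns:
            for gb in db_.columns:
                x, y = da[ga].to_numpy(float), db_[gb].to_numpy(float)
                ok = ~(np.isnan(x) | np.isnan(y))
                if ok.sum() < 3:
                    rows.append((ga, gb, tissue, np.nan, np.nan, True))
                    continue
                if method == "spearman":
                    rho, p = stats.spearmanr(x[ok], y[ok])
                else:
                    rho, p = stats.pearsonr(x[ok], y[ok])
                rows.append((ga, gb, tissue, rho, p, False))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "tissue", "rho", "p", "skipped"])
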