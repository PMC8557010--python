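"""Comparing gene-level phenomes to the carrier phenome.

Two complementary checks that small expression shifts in CNV-region genes
echo carrier biology:

* **Rank overlap** — the carrier-vs-non-carrier PheWAS is ranked by p
  (rank 1 = most carrier-associated); each candidate trait set (e.g. the
  pooled top-1% traits of the region's genes) maps to its carrier ranks,
  and a one-tailed Wilcoxon rank-sum test asks whether those ranks sit
  closer to the top than a uniform draw would.
* **Extreme-expression mimicking** — non-carriers whose predicted
  expression across the region's genes is in the far tails (top/bottom 2nd
  percentile per gene-tissue measurement, high and low pooled because eQTL
  direction can be tissue-specific) are labeled per gene, aggregated, and
  the top 2% become a "mimic" group; the half of the cohort with the
  fewest extreme and most normal (25th–75th percentile) gene labels is the
  control group.  A mimic-vs-control PheWAS then stands in for the
  carrier-vs-non-carrier comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grex import GReXCube
from .phewas import PhecodeCaseControl, carrier_phewas


@dataclass
class ExtremeConfig:
    """Percentile machinery of the mimicking procedure (fractions in (0, 1))."""

    extreme_tail: float = 0.02
    normal_band: tuple[float, float] = (0.25, 0.75)
    mimic_fraction: float = 0.02
    control_fraction: float = 0.50
    top_trait_fraction: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.normal_band
        for v in (self.extreme_tail, lo, hi, self.mimic_fraction, self.control_fraction, self.top_trait_fraction):
            if not (0 < v < 1):
                raise ValueError("all fractions must lie in (0, 1)")
        if lo >= hi:
            raise ValueError("normal band empty")
        if self.extreme_tail >= lo or (1 - self.extreme_tail) <= hi:
            raise ValueError("extreme tails overlap the normal band")


@dataclass
class LabelAssignment:
    """Per-(individual, gene) labels and the derived mimic/control groups."""

    gene_labels: pd.DataFrame      # individuals x genes, values {extreme, normal, neither}
    n_extreme_genes: pd.Series
    n_normal_genes: pd.Series
    group: pd.Series               # {mimic, control, neither} per individual


def _measurement_labels(col: np.ndarray, cfg: ExtremeConfig) -> np.ndarray:
    """Label one (gene, tissue) measurement column by cohort percentile."""
    ranks = stats.rankdata(col, method="average") / len(col)
    out = np.full(len(col), "neither", dtype=object)
    out[(ranks > 1 - cfg.extreme_tail) | (ranks <= cfg.extreme_tail)] = "extreme"
    lo, hi = cfg.normal_band
    normal = (ranks > lo) & (ranks <= hi) & (out != "extreme")
    out[normal] = "normal"
    return out


def extreme_labels(cube: GReXCube, config: ExtremeConfig | None = None) -> LabelAssignment:
    """Label individuals per gene as extreme / normal / neither, then group.

    Measurement level: each (individual, gene, tissue) value is "extreme"
    beyond the 2nd-percentile tails (both directions pooled), "normal"
    inside the 25th–75th band, else "neither".  Gene level: single-tissue
    genes inherit the tissue label; multi-tissue genes rank individuals by
    extreme-tissue count and the top ``mimic_fraction`` quantile of that
    count (among those with at least one extreme tissue) are "extreme",
    while "normal" requires zero extreme tissues and goes to the half of
    the cohort with the most normal tissues.  Individual level: rank by
    number of extreme genes; top ``mimic_fraction`` become the mimic group;
    the control group is the ~``control_fraction`` with fewest extreme and
    (tie-broken) most normal genes.  All ranking ties break by individual
    id order, so groups are deterministic.
    """
    cfg = config or ExtremeConfig()
    individuals = cube.individuals
    n = len(individuals)
    if n < 100:
        raise ValueError("need at least 100 individuals for percentile labels")
    genes = cube.genes()
    gene_labels = pd.DataFrame(index=pd.Index(individuals, name="individual_id"), columns=genes, dtype=object)
    for gene in genes:
        gm = cube.gene_matrix(gene)
        tl = np.column_stack([_measurement_labels(gm[t].to_numpy(float), cfg) for t in gm.columns])
        n_ext = (tl == "extreme").sum(axis=1)
        n_norm = (tl == "normal").sum(axis=1)
        if tl.shape[1] == 1:
            gene_labels[gene] = tl[:, 0]
            continue
        labels = np.full(n, "neither", dtype=object)
        # extreme: top mimic-fraction quantile of the extreme-tissue count, count >= 1
        k_ext = max(int(np.floor(cfg.mimic_fraction * n)), 1)
        order = np.lexsort((np.arange(n), -n_ext))  # count desc, id-order ties
        chosen = [i for i in order[:k_ext] if n_ext[i] >= 1]
        labels[chosen] = "extreme"
        # normal: zero extreme tissues, most normal tissues, half the cohort
        k_norm = int(np.floor(0.5 * n))
        eligible = np.where((n_ext == 0) & (labels == "neither"))[0]
        e_order = eligible[np.lexsort((eligible, -n_norm[eligible]))]
        labels[e_order[:k_norm]] = "normal"
        gene_labels[gene] = labels
    n_extreme = (gene_labels == "extreme").sum(axis=1)
    n_normal = (gene_labels == "normal").sum(axis=1)
    group = pd.Series("neither", index=gene_labels.index, name="group", dtype=object)
    k_mimic = max(int(np.floor(cfg.mimic_fraction * n)), 1)
    order = np.lexsort((np.arange(n), -n_extreme.to_numpy()))
    mimic_idx = [i for i in order[:k_mimic] if n_extreme.iloc[i] >= 1]
    group.iloc[mimic_idx] = "mimic"
    k_ctrl = int(np.floor(cfg.control_fraction * n))
    rest = np.array([i for i in range(n) if group.iloc[i] != "mimic"])
    # ascending extreme count, then descending normal count, then id order
    r_order = rest[np.lexsort((rest, -n_normal.to_numpy()[rest], n_extreme.to_numpy()[rest]))]
    group.iloc[r_order[:k_ctrl]] = "control"
    return LabelAssignment(gene_labels, n_extreme, n_normal, group)


def mimic_phewas(
    labels: LabelAssignment,
    cc: PhecodeCaseControl,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic PheWAS of mimic-vs-control membership ("neither" omitted)."""
    grp = labels.group
    mimics = grp[grp == "mimic"].index
    controls = grp[grp == "control"].index
    if len(mimics) == 0:
        raise ValueError("mimic group is empty")
    if len(controls) == 0:
        raise ValueError("control group is empty")
    keep = [i for i in cc.individuals if grp.get(i, "neither") != "neither"]
    sub_cc = PhecodeCaseControl(
        status=cc.status.loc[keep],
        categories=cc.categories,
        case_counts=cc.case_counts,
        dropped=cc.dropped,
    )
    flag = pd.Series(grp.loc[keep] == "mimic", name="mimic")
    table = carrier_phewas(flag, sub_cc, covariates)
    table = table.assign(predictor="mimic")
    return table


def rank_overlap_test(
    candidate_traits: list[str],
    reference: pd.DataFrame,
    alternative: str = "top",
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum of candidate traits' carrier-PheWAS ranks.

    The reference PheWAS table is ranked by p ascending (rank 1 = most
    carrier-associated, average ranks on ties); candidates map to their
    ranks and are tested against the remaining ranks with the alternative
    that candidates sit at smaller ranks (``"top"``).  Returns (mean
    candidate rank, p).  Candidates absent from the reference raise,
    listing the traits.
    """
    if alternative != "top":
        raise ValueError("only the 'top' (smaller-rank) alternative is defined")
    ref = reference[np.isfinite(reference["p"])]
    ranks = pd.Series(stats.rankdata(ref["p"].to_numpy(), method="average"), index=ref["phecode"].to_numpy())
    missing = [t for t in candidate_traits if t not in ranks.index]
    if missing:
        raise ValueError(f"candidate traits absent from reference: {missing[:10]}")
    cand = ranks.loc[candidate_traits].to_numpy(dtype=float)
    other = ranks.drop(index=candidate_traits).to_numpy(dtype=float)
    if other.size == 0:
        return float(cand.mean()), 0.5
    method = "exact" if (len(cand) <= 25 and len(other) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(cand, other, alternative="less", method=method)
    return float(cand.mean()), float(res.pvalue)
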