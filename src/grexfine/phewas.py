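"""Phecode-based phenome-wide association studies.

Phecodes aggregate ICD billing codes into clinical phenotypes; here they
are the input unit.  Case/control status follows the phecode convention:
an individual is a case for a code given at least two events on distinct
visit days, a control given zero events for the code and for any code in
its exclusion set, and excluded otherwise; codes with fewer than a minimum
number of cases (default 20) are dropped from analysis.  A gene-level
PheWAS runs the cross-tissue joint PC test of the gene's predicted
expression against every analyzed code; a carrier-level PheWAS runs a
logistic regression of each code on CNV-carrier status.  Top-percentile
phenomes and a binomial clinical-category enrichment test summarize the
results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .assoc import MIN_P, PhenotypeTable, multixcan_fit, single_tissue_assoc
from .grex import GReXCube


@dataclass
class PhecodeCaseControl:
    """Individuals x phecodes status matrix: 1 case, 0 control, NaN excluded.

    Only phecodes that survived the minimum-case filter appear in
    ``status``; dropped codes are logged in ``dropped``.  ``categories``
    maps every analyzed phecode to its clinical category.
    """

    status: pd.DataFrame
    categories: pd.Series
    case_counts: pd.Series
    dropped: list[str] = field(default_factory=list)

    @property
    def phecodes(self) -> list[str]:
        return list(self.status.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.status.index)


def build_case_control(
    events: pd.DataFrame,
    individuals: list[str],
    categories: pd.Series,
    min_cases: int = 20,
    exclusions: dict[str, set[str]] | None = None,
) -> PhecodeCaseControl:
    """Apply the two-distinct-days case rule and the minimum-case filter.

    ``events`` has columns (individual_id, phecode, date); duplicate rows on
    the same day collapse.  ``individuals`` is the full cohort roster (an
    individual with no events at all is a control for every code).  Every
    phecode appearing in the events must be present in ``categories``.
    """
    exclusions = exclusions or {}
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"]).dt.normalize()
    ev = ev.drop_duplicates(subset=["individual_id", "phecode", "date"])
    seen_codes = ev["phecode"].unique()
    missing = [c for c in seen_codes if c not in categories.index]
    if missing:
        raise ValueError(f"phecodes missing from category map: {missing[:10]}")
    codes = list(categories.index)
    day_counts = ev.groupby(["individual_id", "phecode"]).size().unstack(fill_value=0)
    day_counts = day_counts.reindex(index=individuals, columns=codes, fill_value=0)
    any_event = day_counts > 0
    status = pd.DataFrame(0.0, index=day_counts.index, columns=codes)
    status[day_counts >= 2] = 1.0
    status[(day_counts == 1)] = np.nan  # one visit day: neither case nor control
    for code in codes:
        excl = exclusions.get(code)
        if not excl:
            continue
        excl_cols = [c for c in excl if c in any_event.columns]
        if not excl_cols:
            continue
        hit = any_event[excl_cols].any(axis=1)
        mask = hit & (status[code] != 1.0)
        status.loc[mask, code] = np.nan
    case_counts = (status == 1.0).sum()
    keep = case_counts[case_counts >= min_cases].index
    dropped = [c for c in codes if c not in set(keep)]
    return PhecodeCaseControl(
        status=status[list(keep)],
        categories=categories.loc[list(keep)],
        case_counts=case_counts.loc[list(keep)],
        dropped=dropped,
    )


def _logistic_phewas_row(y: np.ndarray, x: np.ndarray, covars: np.ndarray):
    """One logistic fit; returns (stat, p, direction) or None on failure."""
    X = np.column_stack([np.ones(len(y)), x, covars])
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
        z = float(res.params[1] / res.bse[1])
        p = float(min(max(2 * stats.norm.sf(abs(z)), MIN_P), 1.0))
        return z, p, (1 if res.params[1] >= 0 else -1)
    except Exception:
        return None


def gene_phewas(
    cube: GReXCube,
    cc: PhecodeCaseControl,
    covariates: pd.DataFrame | None = None,
    condition_limit: float = 30,
) -> pd.DataFrame:
    """Cross-tissue joint PC test of every gene against every analyzed phecode.

    Individuals excluded for a phecode are omitted from that code's fit.
    Fits that fail are flagged (``failed``), never silently dropped.
    """
    shared = [i for i in cc.individuals if i in set(cube.individuals)]
    if not shared:
        raise ValueError("no overlapping individuals between cube and case/control matrix")
    cube = cube.subset_individuals(shared)
    status = cc.status.loc[shared]
    cov = covariates.loc[shared] if covariates is not None else None
    rows = []
    for gene in cube.genes():
        gm = cube.gene_matrix(gene)
        for code in cc.phecodes:
            s = status[code]
            ok = s.notna()
            ids = list(s.index[ok])
            y = s[ok]
            n_cases = int((y == 1).sum())
            n_controls = int((y == 0).sum())
            if n_cases == 0 or n_controls == 0:
                rows.append((gene, code, n_cases, n_controls, np.nan, np.nan, 0, True))
                continue
            data = pd.DataFrame({"trait": y.astype(int)})
            covnames: tuple[str, ...] = ()
            if cov is not None:
                data = data.join(cov)
                covnames = tuple(cov.columns)
            pheno = PhenotypeTable(data=data, trait="trait", covariates=covnames)
            sub = GReXCube({t: df.loc[ids] for t, df in cube.tissues.items() if gene in df.columns})
            try:
                r = multixcan_fit(sub, gene, pheno, condition_limit)
                failed = not (r.testable and np.isfinite(r.p))
                rows.append((gene, code, n_cases, n_controls, r.statistic, r.p, r.direction, failed))
            except Exception:
                rows.append((gene, code, n_cases, n_controls, np.nan, np.nan, 0, True))
    return pd.DataFrame(rows, columns=["predictor", "phecode", "n_cases", "n_controls", "statistic", "p", "direction", "failed"])


def _fisher_fallback(y: np.ndarray, x: np.ndarray):
    """Exact 2x2 test for a binary predictor when the logistic fit separates."""
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    d = int(((x == 0) & (y == 0)).sum())
    p = float(min(max(stats.fisher_exact([[a, b], [c, d]])[1], MIN_P), 1.0))
    # direction from the sign of the observed association in the table
    direction = 1 if a * d >= b * c else -1
    z = float(stats.norm.isf(p / 2)) * direction
    return z, p, direction


def carrier_phewas(
    carriers: pd.Series,
    cc: PhecodeCaseControl,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic regression of each analyzed phecode on carrier status.

    Direction is the sign of the carrier coefficient.  A code whose logistic
    fit is unusable because carrier status perfectly separates case status
    falls back to Fisher's exact test on the 2x2 carrier-by-case table
    (ignoring covariates); phecodes degenerate beyond that (e.g. no cases at
    all) are flagged inestimable rather than dropped.
    """
    carriers = carriers.astype(bool)
    if not carriers.any():
        raise ValueError("carrier set is empty")
    shared = [i for i in cc.individuals if i in set(carriers.index)]
    status = cc.status.loc[shared]
    car = carriers.loc[shared].to_numpy(dtype=float)
    cov = covariates.loc[shared] if covariates is not None else None
    rows = []
    for code in cc.phecodes:
        s = status[code]
        ok = s.notna().to_numpy()
        y = s.to_numpy(dtype=float)[ok]
        x = car[ok]
        n_cases, n_controls = int((y == 1).sum()), int((y == 0).sum())
        cv = cov.to_numpy(dtype=float)[ok] if cov is not None else np.empty((ok.sum(), 0))
        fit = None
        if n_cases and n_controls and x.std() > 0:
            cells = [((y == yi) & (x == xi)).sum() for yi in (0, 1) for xi in (0, 1)]
            if min(cells) == 0:  # perfect separation: Logit is unusable
                fit = _fisher_fallback(y, x)
            else:
                fit = _logistic_phewas_row(y, x, cv) or _fisher_fallback(y, x)
        if fit is None:
            rows.append(("carrier", code, n_cases, n_controls, np.nan, np.nan, 0, True))
        else:
            z, p, d = fit
            rows.append(("carrier", code, n_cases, n_controls, z, p, d, False))
    return pd.DataFrame(rows, columns=["predictor", "phecode", "n_cases", "n_controls", "statistic", "p", "direction", "failed"])


def top_percent(table: pd.DataFrame, pct: float = 0.01) -> dict[str, list[str]]:
    """Per predictor, the floor(pct x n_traits) smallest-p phecodes.

    Ordered by p ascending; ties broken by phecode string order (stable).
    """
    if not (0 < pct < 1):
        raise ValueError("pct must be in (0, 1)")
    out: dict[str, list[str]] = {}
    for predictor, grp in table.groupby("predictor", sort=False):
        grp = grp[np.isfinite(grp["p"])]
        n = len(grp)
        k = math.floor(pct * n)
        if k < 1:
            raise ValueError(f"fewer than 1/pct analyzed traits for predictor {predictor!r}")
        ordered = grp.sort_values(["p", "phecode"], kind="mergesort")
        out[predictor] = list(ordered["phecode"].head(k))
    return out


@dataclass
class EnrichmentResult:
    category: str
    observed: int
    expected: float
    p_i: float
    p: float
    significant: bool


def category_enrichment(
    top_lists: dict[str, list[str]],
    cc: PhecodeCaseControl,
    alpha_categories: int = 17,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Binomial test for clinical-category over-representation in pooled top lists.

    Pooled draw count n = sum of top-list lengths (top_k x n_predictors);
    category probability p_i = (analyzed codes in category i) / (codes
    analyzed); the test is one-sided upper tail (over-representation), with
    significance at ``alpha / alpha_categories``.
    """
    cat_of = cc.categories
    tested = list(cat_of.index)
    n_tested = len(tested)
    counts_by_cat = cat_of.value_counts()
    pooled = [code for lst in top_lists.values() for code in lst]
    missing = [c for c in pooled if c not in cat_of.index]
    if missing:
        raise ValueError(f"top-list phecodes lack a category: {missing[:10]}")
    n = len(pooled)
    observed = pd.Series(pooled).map(cat_of).value_counts()
    results = []
    thresh = alpha / alpha_categories
    for cat in counts_by_cat.index:
        p_i = counts_by_cat[cat] / n_tested
        obs = int(observed.get(cat, 0))
        if p_i == 0 and obs > 0:
            raise ValueError(f"category {cat!r} has p_i = 0 but observed {obs}")
        p = float(stats.binomtest(obs, n, p_i, alternative="greater").pvalue) if n else 1.0
        results.append(EnrichmentResult(cat, obs, n * p_i, p_i, p, p < thresh))
    return results


def prevalence_filter(
    table: pd.DataFrame,
    carriers: pd.Series,
    cc: PhecodeCaseControl,
    min_frac: float = 0.05,
) -> pd.DataFrame:
    """Drop rows whose phecode is a case in strictly less than ``min_frac``
    of carriers (rare-in-carrier traits are not interpreted further)."""
    carriers = carriers.astype(bool)
    carrier_ids = [i for i in carriers.index[carriers] if i in set(cc.individuals)]
    if not carrier_ids:
        raise ValueError("zero carriers")
    frac = (cc.status.loc[carrier_ids] == 1.0).mean()
    keep = [code for code in table["phecode"] if frac.get(code, 0.0) >= min_frac]
    return table[table["phecode"].isin(set(keep))].reset_index(drop=True)


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (secondary reporting threshold)."""
    p = np.asarray(pvals, dtype=float)
    n = np.isfinite(p).sum()
    order = np.argsort(np.where(np.isfinite(p), p, np.inf))
    adj = np.full_like(p, np.nan)
    prev = 1.0
    ranked = [(i, p[i]) for i in order if np.isfinite(p[i])]
    for rank_from_end, (i, pi) in enumerate(reversed(ranked)):
        rank = n - rank_from_end
        val = min(prev, pi * n / rank)
        adj[i] = val
        prev = val
    return adj
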