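"""Candidate prioritization: co-expression, differential essentiality,
expression-stratified survival, drug-response tails, and the ledger that
tracks provenance and exclusions.

Median dichotomizations assign values equal to the median to the "high"
group throughout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import restricted_mean_survival_time
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import DataError


def spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation; NaN when either vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def coexpression_screen(
    cohorts: dict[str, pd.DataFrame],
    anchor: str,
    candidates,
    r_min: float = 0.4,
    majority_rule: float = 0.5,
) -> dict:
    """Anchor co-expression across cohorts with a majority-vote cutoff.

    A candidate is selected iff its Spearman r with the anchor is
    >= r_min in more than ``majority_rule`` of the cohorts. Undefined
    correlations (constant expression) fail the cutoff. The returned r
    matrix is row-ordered by complete-linkage clustering on Euclidean
    distance of the per-cohort r vectors.
    """
    if not cohorts:
        raise DataError("at least one cohort required")
    candidates = list(candidates)
    rmat = pd.DataFrame(index=pd.Index(candidates, name="gene"), columns=list(cohorts), dtype=float)
    for name, expr in cohorts.items():
        if anchor not in expr.columns:
            raise DataError(f"anchor '{anchor}' absent from cohort '{name}'")
        a = expr[anchor].to_numpy(float)
        for gene in candidates:
            if gene not in expr.columns:
                rmat.loc[gene, name] = np.nan
                continue
            rmat.loc[gene, name] = spearman_r(a, expr[gene].to_numpy(float))
    passes = (rmat >= r_min).fillna(False)
    frac = passes.sum(axis=1) / len(cohorts)
    selected = set(frac.index[frac > majority_rule])
    if len(rmat) > 2:
        filled = rmat.fillna(0.0).to_numpy(float)
        order = leaves_list(linkage(filled, method="complete", metric="euclidean"))
        rmat = rmat.iloc[order]
    return {"r_matrix": rmat, "selected": selected, "pass_fraction": frac}


def expression_filter(
    cell_line_expr: pd.DataFrame,
    line: str,
    threshold_log2: float = 5.0,
) -> list:
    """Genes expressed in the designated line (log2 value >= threshold;
    the boundary is kept)."""
    if line not in cell_line_expr.index:
        raise DataError(f"cell line '{line}' absent from expression matrix")
    row = cell_line_expr.loc[line]
    return sorted(row.index[row >= threshold_log2])


def essential_gene_filter(candidates, essential_reference) -> set:
    """Drop candidates present in the essential-gene reference."""
    return set(candidates) - set(essential_reference)


def differential_essentiality(
    essentiality: pd.DataFrame,
    expression: pd.DataFrame,
    anchor: str,
    candidates,
    top_frac: float = 0.25,
    bottom_frac: float = 0.25,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney differential dependency between anchor-high and
    anchor-low cell-line groups.

    Lines are ranked by anchor expression; the top and bottom fractions
    form the groups. A candidate is selected iff p < alpha AND its median
    essentiality is more negative (more essential) in the anchor-high
    group.
    """
    shared = essentiality.index.intersection(expression.index)
    if len(shared) == 0:
        raise DataError("no shared cell lines between matrices")
    if anchor not in expression.columns:
        raise DataError(f"anchor '{anchor}' absent from expression matrix")
    ranked = expression.loc[shared, anchor].sort_values(ascending=False)
    n = len(ranked)
    n_top = max(1, int(round(top_frac * n)))
    n_bot = max(1, int(round(bottom_frac * n)))
    high = ranked.index[:n_top]
    low = ranked.index[-n_bot:]
    rows = []
    for gene in candidates:
        if gene not in essentiality.columns:
            rows.append({"gene": gene, "p": np.nan, "selected": False, "testable": False})
            continue
        a = essentiality.loc[high, gene].dropna().to_numpy(float)
        b = essentiality.loc[low, gene].dropna().to_numpy(float)
        if len(a) < 3 or len(b) < 3:
            rows.append({"gene": gene, "p": np.nan, "selected": False, "testable": False})
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction = np.median(a) < np.median(b)  # more essential when anchor high
        rows.append(
            {"gene": gene, "p": p, "selected": bool(p < alpha and direction), "testable": True}
        )
    return pd.DataFrame(rows).set_index("gene")


def natural_sdl_survival(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    anchor: str,
    partner: str,
    alpha: float = 0.05,
) -> dict:
    """Kaplan-Meier / log-rank contrast of the natural-SDL stratum.

    Patients are split at the median of both genes (ties to "high"); the
    natural-SDL group is anchor-high & partner-low, compared against
    anchor-high & partner-high. Selected iff log-rank p < alpha AND the
    natural-SDL group has the better restricted-mean survival.
    """
    shared = expression.index.intersection(survival.index)
    if len(shared) == 0:
        raise DataError("no shared patients between tables")
    expr = expression.loc[shared]
    surv = survival.loc[shared]
    a_high = expr[anchor] >= expr[anchor].median()
    p_high = expr[partner] >= expr[partner].median()
    sdl_mask = a_high & ~p_high
    cmp_mask = a_high & p_high
    if sdl_mask.sum() == 0 or cmp_mask.sum() == 0:
        return {"testable": False, "selected": False, "p": np.nan}
    t1, e1 = surv.loc[sdl_mask, "time"], surv.loc[sdl_mask, "event"]
    t2, e2 = surv.loc[cmp_mask, "time"], surv.loc[cmp_mask, "event"]
    if e1.sum() == 0 and e2.sum() == 0:
        return {"testable": False, "selected": False, "p": np.nan}
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    km_sdl, km_cmp = KaplanMeierFitter(), KaplanMeierFitter()
    km_sdl.fit(t1, e1, label="natural_sdl")
    km_cmp.fit(t2, e2, label="comparison")
    horizon = float(min(t1.max(), t2.max()))
    rmst_sdl = float(restricted_mean_survival_time(km_sdl, t=horizon))
    rmst_cmp = float(restricted_mean_survival_time(km_cmp, t=horizon))
    p = float(res.p_value)
    return {
        "testable": True,
        "p": p,
        "rmst_sdl": rmst_sdl,
        "rmst_comparison": rmst_cmp,
        "selected": bool(p < alpha and rmst_sdl > rmst_cmp),
        "km_sdl": km_sdl,
        "km_comparison": km_cmp,
        "n_sdl": int(sdl_mask.sum()),
        "n_comparison": int(cmp_mask.sum()),
    }


def drug_sensitivity_differential(
    ic50: pd.DataFrame,
    expression: pd.DataFrame,
    anchor: str,
    tail_frac: float = 0.01,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney on log IC50 between anchor-expression tail groups.

    Cell lines in the top and bottom ``tail_frac`` of anchor expression
    (at least 3 lines each) are compared per drug; selected iff p < alpha
    AND the anchor-high tail has the lower median IC50.
    """
    shared = ic50.columns.intersection(expression.index)
    if len(shared) == 0:
        raise DataError("no shared cell lines between IC50 and expression")
    ranked = expression.loc[shared, anchor].sort_values(ascending=False)
    n_tail = max(3, int(np.ceil(tail_frac * len(ranked))))
    high = ranked.index[:n_tail]
    low = ranked.index[-n_tail:]
    rows = []
    for drug in ic50.index:
        a = ic50.loc[drug, high].dropna().to_numpy(float)
        b = ic50.loc[drug, low].dropna().to_numpy(float)
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"drug '{drug}' skipped: no IC50 values in a tail group")
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        direction = np.median(a) < np.median(b)
        rows.append(
            {"drug": drug, "p": p, "selected": bool(p < alpha and direction)}
        )
    return pd.DataFrame(rows, columns=["drug", "p", "selected"]).set_index("drug")


STRATEGY_COLUMNS = (
    "coexpression",
    "essentiality_marcotte",
    "essentiality_achilles",
    "survival",
    "locus_19p13",
    "toppgene",
    "surfaceome",
)


def build_ledger(
    strategy_outputs: dict,
    fixed_lists: dict | None = None,
    clone_failures=(),
) -> pd.DataFrame:
    """Union the strategy selections with per-strategy provenance flags.

    ``strategy_outputs`` and ``fixed_lists`` map strategy name -> gene
    set. Genes in ``clone_failures`` are marked excluded; active = flagged
    and not excluded.
    """
    sources = dict(strategy_outputs)
    sources.update(fixed_lists or {})
    union = sorted(set().union(*sources.values())) if sources else []
    ledger = pd.DataFrame(index=pd.Index(union, name="gene"))
    for name in STRATEGY_COLUMNS:
        genes = set(sources.get(name, set()))
        ledger[name] = [g in genes for g in union]
    for name in sources:
        if name not in STRATEGY_COLUMNS:
            ledger[name] = [g in set(sources[name]) for g in union]
    failures = set(clone_failures)
    ledger["excluded_reason"] = ["clone_failure" if g in failures else "" for g in union]
    ledger["active"] = ledger["excluded_reason"] == ""
    return ledger


def ledger_counts(ledger: pd.DataFrame) -> dict:
    return {
        "n_total": int(len(ledger)),
        "n_excluded": int((~ledger["active"]).sum()),
        "n_active": int(ledger["active"].sum()),
    }
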