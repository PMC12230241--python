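"""Pooled and arrayed CRISPR validation screens.

sgRNA counting from reads (exact / 1-mismatch spacer matching), WDC-style
scoring of endpoint dropout against a no-Cas9 baseline, and the arrayed
confluency-reduction hit rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, LibraryError
from .shrna import WDCConfig, permutation_pvalues, wdc_gene
from .synthdata import random_spacers

_AMBIGUOUS = object()


@dataclass
class GuideLibrary:
    """sgRNA library: guide id, gene id, spacer sequence."""

    table: pd.DataFrame  # index guide, columns gene, spacer

    def __post_init__(self) -> None:
        if not {"gene", "spacer"} <= set(self.table.columns):
            raise LibraryError("library needs 'gene' and 'spacer' columns")
        if self.table.index.has_duplicates:
            raise LibraryError("duplicate guide ids")
        spacers = self.table["spacer"]
        if spacers.duplicated().any():
            raise LibraryError("duplicate spacer sequences")
        lengths = spacers.str.len().unique()
        if len(lengths) > 1:
            raise LibraryError("variable-length spacers")
        if not spacers.str.fullmatch("[ACGT]+").all():
            raise LibraryError("spacers must be uppercase ACGT")

    @property
    def spacer_length(self) -> int:
        return int(self.table["spacer"].str.len().iloc[0])

    def __len__(self) -> int:
        return len(self.table)


def build_library(
    genes,
    guides_per_gene: int = 2,
    n_positive_controls: int = 0,
    n_non_targeting: int = 0,
    spacer_length: int = 20,
    seed: int = 0,
) -> GuideLibrary:
    """Assemble a validation library with random unique spacers.

    Targeting guides (guides_per_gene per gene) plus positive-control and
    non-targeting guides.
    """
    genes = list(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for g in genes:
        for j in range(guides_per_gene):
            rows.append((f"{g}_sg{j + 1}", g, "target"))
    for i in range(n_positive_controls):
        rows.append((f"POS{i + 1:02d}_sg1", f"POSCTRL{i + 1:02d}", "positive_control"))
    for i in range(n_non_targeting):
        rows.append((f"NT{i + 1:02d}_sg1", f"NONTARGET{i + 1:02d}", "non_targeting"))
    spacers = random_spacers(len(rows), spacer_length, rng)
    table = pd.DataFrame(
        {
            "guide": [r[0] for r in rows],
            "gene": [r[1] for r in rows],
            "class": [r[2] for r in rows],
            "spacer": spacers,
        }
    ).set_index("guide")
    return GuideLibrary(table)


def per_guide_representation(n_cells: float, n_guides: int) -> float:
    """Fold representation: cells per library guide."""
    if n_guides <= 0:
        raise ConfigError("n_guides must be positive")
    return n_cells / n_guides


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def _one_mismatch_index(library: GuideLibrary) -> dict:
    """Map every 1-mismatch variant of every spacer to its guide (or an
    ambiguity sentinel when two guides collide)."""
    index: dict = {}
    for guide, spacer in library.table["spacer"].items():
        for pos in range(len(spacer)):
            for base in "ACGT":
                if base == spacer[pos]:
                    continue
                variant = spacer[:pos] + base + spacer[pos + 1:]
                if variant in index and index[variant] != guide:
                    index[variant] = _AMBIGUOUS
                else:
                    index.setdefault(variant, guide)
    return index


def count_guides(
    reads,
    library: GuideLibrary,
    max_mismatch: int = 0,
) -> tuple[pd.Series, dict]:
    """Assign reads to guides by unique best spacer match.

    A read maps to a guide iff some window matches its spacer with at most
    ``max_mismatch`` substitutions and the best-scoring match is unique.
    Conservation: assigned + ambiguous + unmatched == total.
    """
    if max_mismatch not in (0, 1):
        raise ConfigError("max_mismatch must be 0 or 1")
    length = library.spacer_length
    exact = {s: g for g, s in library.table["spacer"].items()}
    near = _one_mismatch_index(library) if max_mismatch == 1 else {}
    counts = pd.Series(0, index=library.table.index, dtype=np.int64)
    ambiguous = unmatched = total = 0
    for read in reads:
        seq = str(getattr(read, "seq", read)).upper()
        total += 1
        hits = {exact[w] for w in _windows(seq, length) if w in exact}
        if not hits and max_mismatch == 1:
            hits = {near[w] for w in _windows(seq, length) if w in near}
        if _AMBIGUOUS in hits:  # a variant shared by two spacers matched
            ambiguous += 1
            continue
        if len(hits) == 1:
            counts[hits.pop()] += 1
        elif len(hits) > 1:
            ambiguous += 1
        else:
            unmatched += 1
    stats_out = {
        "assigned": int(counts.sum()),
        "ambiguous": ambiguous,
        "unmatched": unmatched,
        "total": total,
    }
    return counts, stats_out


def _windows(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield seq[i: i + k]


# ---------------------------------------------------------------------------
# in vivo endpoint scoring
# ---------------------------------------------------------------------------

def log2_cpm(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudocount), column-wise."""
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise DataError("sample with zero total counts")
    return np.log2(counts / totals * 1e6 + pseudocount)


def score_invivo(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    library: GuideLibrary | pd.DataFrame,
    config: WDCConfig,
    pseudocount: float = 1.0,
    arm_treatment: str = "cas9",
    arm_control: str = "no_cas9",
) -> dict:
    """Endpoint dropout scoring against the no-Cas9 baseline.

    The control-arm mean log2 CPM serves as the shared T0, so the
    two-timepoint WDC reduces to epsilon * [(cas9 - baseline) -
    (no_cas9 - baseline)] averaged over samples. Gene aggregation, the
    permutation null and the hit rule reuse the shRNA engine with
    k_aggregate = min(config.k_aggregate, guides per gene).
    """
    lib = library.table if isinstance(library, GuideLibrary) else library
    for arm in (arm_treatment, arm_control):
        if arm not in set(samples["arm"]):
            raise DataError(f"arm '{arm}' missing from sample annotation")
    x = log2_cpm(counts, pseudocount)
    cols_t = samples.index[samples["arm"] == arm_treatment]
    cols_c = samples.index[samples["arm"] == arm_control]
    baseline = x[cols_c].mean(axis=1)
    wcc_t = config.epsilon * x[cols_t].sub(baseline, axis=0)
    wcc_c = config.epsilon * x[cols_c].sub(baseline, axis=0)
    guide_scores = pd.DataFrame(
        {"gene": lib.loc[counts.index, "gene"], "wdc": wcc_t.mean(axis=1) - wcc_c.mean(axis=1)}
    )
    gene_table = wdc_gene(guide_scores, config)
    rng = np.random.default_rng(config.seed)
    gene_table["p_perm"] = permutation_pvalues(guide_scores, gene_table, config, rng)
    # t test per gene over per-sample weighted changes
    p_t = {}
    for gene, grp in guide_scores.groupby("gene"):
        a = wcc_t.loc[grp.index].to_numpy(float).ravel()
        b = wcc_c.loc[grp.index].to_numpy(float).ravel()
        if a.size < 2 or b.size < 2 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            p_t[gene] = np.nan
        else:
            p_t[gene] = float(stats.ttest_ind(a, b).pvalue)
    gene_table["p_ttest"] = pd.Series(p_t)
    hit = gene_table["wdc"] <= config.fold_threshold_log2
    if config.require_permutation:
        hit &= gene_table["p_perm"].notna() & (gene_table["p_perm"] < config.alpha)
    if config.require_ttest:
        hit &= gene_table["p_ttest"].notna() & (gene_table["p_ttest"] < config.alpha)
    gene_table["hit"] = hit
    return {"guide_scores": guide_scores, "gene_scores": gene_table}


# ---------------------------------------------------------------------------
# arrayed screen
# ---------------------------------------------------------------------------

def arrayed_growth_reduction(
    table: pd.DataFrame,
    baseline_day: int = 2,
    final_day: int = 6,
    reduction_threshold: float = 0.40,
    alpha: float = 0.05,
    arm_treatment: str = "cas9",
    arm_control: str = "no_cas9",
) -> pd.DataFrame:
    """Per-gene confluency growth reduction with a t-test hit rule.

    Growth per well = confluency(final) / confluency(baseline); reduction
    = 1 - mean(growth, treatment) / mean(growth, control); hit iff
    reduction >= threshold and two-sample t-test p < alpha.
    """
    need = {"well", "gene", "arm", "day", "confluency"}
    if not need <= set(table.columns):
        raise DataError(f"arrayed table needs columns {sorted(need)}")
    days = set(table["day"])
    if baseline_day not in days or final_day not in days:
        raise DataError("baseline or final day absent from table")
    wide = table.pivot_table(
        index=["well", "gene", "arm"], columns="day", values="confluency"
    ).reset_index()
    zero_base = wide[baseline_day] == 0
    if zero_base.any():
        warnings.warn(f"excluding {int(zero_base.sum())} wells with zero baseline confluency")
        wide = wide[~zero_base]
    wide["growth"] = wide[final_day] / wide[baseline_day]
    rows = []
    for gene, grp in wide.groupby("gene", sort=True):
        g_t = grp.loc[grp["arm"] == arm_treatment, "growth"].to_numpy(float)
        g_c = grp.loc[grp["arm"] == arm_control, "growth"].to_numpy(float)
        if len(g_t) == 0 or len(g_c) == 0:
            continue
        reduction = 1.0 - g_t.mean() / g_c.mean()
        if len(g_t) < 2 or len(g_c) < 2 or (np.ptp(g_t) == 0 and np.ptp(g_c) == 0):
            p = np.nan
        else:
            p = float(stats.ttest_ind(g_t, g_c).pvalue)
        hit = bool(reduction >= reduction_threshold and np.isfinite(p) and p < alpha)
        rows.append({"gene": gene, "reduction": reduction, "p": p, "hit": hit})
    return pd.DataFrame(rows).set_index("gene")


def intersect_screens(hits_arrayed, hits_invivo) -> dict:
    """Set algebra over the two validation hit sets with provenance."""
    a, b = set(hits_arrayed), set(hits_invivo)
    union = sorted(a | b)
    prov = pd.DataFrame(
        {
            "gene": union,
            "arrayed": [g in a for g in union],
            "invivo": [g in b for g in union],
        }
    ).set_index("gene")
    return {
        "union": set(union),
        "intersection": a & b,
        "n_union": len(union),
        "n_intersection": len(a & b),
        "provenance": prov,
    }
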