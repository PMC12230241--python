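"""Single-cell CRISPR triage: guide-based cell QC, knockout-efficiency
checks, knockout-by-cluster composition, and anchor-high cell tracing."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import ConfigError, DataError


@dataclass
class QCConfig:
    min_umis: int = 5000
    guide_umi_min: int = 3
    k_clusters: int = 10
    n_pca: int = 50
    anchor: str = "PLK1"
    anchor_high_quantile: float = 0.9
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_umis < 0:
            raise ConfigError("min_umis must be >= 0")
        if not 0 < self.anchor_high_quantile < 1:
            raise ConfigError("anchor_high_quantile must be in (0, 1)")


@dataclass
class CellPopulation:
    """Cell x gene UMI matrix plus guide assignments and a target map.

    ``target_map`` is indexed by guide with columns ``target`` (empty for
    non-targeting) and ``class``.
    """

    umi: pd.DataFrame
    guides: pd.DataFrame  # columns cell, guide, umis
    target_map: pd.DataFrame
    clusters: pd.Series | None = None
    normalized: pd.DataFrame | None = None
    cell_guide: pd.Series | None = field(default=None)  # retained cell -> guide

    def __post_init__(self) -> None:
        if self.umi.index.has_duplicates:
            raise DataError("duplicate cell barcodes")
        unknown = set(self.guides["guide"]) - set(self.target_map.index)
        if unknown:
            raise DataError(f"guides missing from target map: {sorted(unknown)}")

    def knockout_of(self, guide: str) -> str:
        """Readable knockout label for a guide."""
        tgt = self.target_map.loc[guide, "target"]
        return tgt if isinstance(tgt, str) and tgt else str(guide)


def qc_cells(pop: CellPopulation, cfg: QCConfig) -> tuple[CellPopulation, dict]:
    """Retain cells with >= min_umis total UMIs and exactly one detected
    guide (UMI support >= guide_umi_min).

    Removal reasons partition removed cells with priority low_umi >
    no_guide > multi_guide.
    """
    totals = pop.umi.sum(axis=1)
    detected = pop.guides[pop.guides["umis"] >= cfg.guide_umi_min]
    per_cell = detected.groupby("cell")["guide"].agg(list)
    n_guides = pop.umi.index.to_series().map(lambda c: len(per_cell.get(c, []))).astype(int)

    low_umi = totals < cfg.min_umis
    no_guide = ~low_umi & (n_guides == 0)
    multi_guide = ~low_umi & (n_guides >= 2)
    keep = ~(low_umi | no_guide | multi_guide)

    kept_cells = pop.umi.index[keep]
    cell_guide = pd.Series(
        {c: per_cell[c][0] for c in kept_cells}, name="guide", dtype=object
    )
    report = {
        "n_input": int(len(pop.umi)),
        "n_retained": int(keep.sum()),
        "removed_low_umi": int(low_umi.sum()),
        "removed_no_guide": int(no_guide.sum()),
        "removed_multi_guide": int(multi_guide.sum()),
    }
    filtered = CellPopulation(
        umi=pop.umi.loc[kept_cells],
        guides=pop.guides[pop.guides["cell"].isin(set(kept_cells))].reset_index(drop=True),
        target_map=pop.target_map,
        cell_guide=cell_guide.loc[kept_cells] if len(kept_cells) else cell_guide,
    )
    return filtered, report


def normalize_cells(pop: CellPopulation) -> CellPopulation:
    """Scale each cell to the median per-cell total, then log2(1 + x)."""
    totals = pop.umi.sum(axis=1)
    if (totals == 0).any():
        raise DataError("zero-UMI cell present; run qc_cells first")
    target = float(totals.median())
    scaled = pop.umi.div(totals, axis=0) * target
    return replace(pop, normalized=np.log2(1.0 + scaled))


def _require_normalized(pop: CellPopulation) -> pd.DataFrame:
    if pop.normalized is None:
        raise DataError("normalized matrix missing; run normalize_cells first")
    return pop.normalized


def ko_efficiency(pop: CellPopulation, cfg: QCConfig) -> pd.DataFrame:
    """One-sided rank-sum check that each knockout reduces its own target.

    Compares normalized target expression in that knockout's cells against
    non-targeting control cells; pass iff p < alpha.
    """
    norm = _require_normalized(pop)
    if pop.cell_guide is None:
        raise DataError("cell-guide assignment missing; run qc_cells first")
    nt_guides = set(pop.target_map.index[pop.target_map["class"] == "non_targeting"])
    if not nt_guides:
        raise DataError("no non-targeting guides in target map")
    control_cells = pop.cell_guide.index[pop.cell_guide.isin(nt_guides)]
    if len(control_cells) == 0:
        raise DataError("no non-targeting control cells retained")
    rows = []
    for guide in pop.target_map.index:
        cls = pop.target_map.loc[guide, "class"]
        if cls == "non_targeting":
            continue
        target = pop.target_map.loc[guide, "target"]
        cells = pop.cell_guide.index[pop.cell_guide == guide]
        if not target or target not in norm.columns:
            rows.append(
                {"guide": guide, "target": target, "n_cells": len(cells),
                 "mean_ko": np.nan, "mean_control": np.nan, "p": np.nan,
                 "testable": False, "passed": False}
            )
            continue
        if len(cells) == 0:
            rows.append(
                {"guide": guide, "target": target, "n_cells": 0,
                 "mean_ko": np.nan, "mean_control": np.nan, "p": np.nan,
                 "testable": False, "passed": False}
            )
            continue
        ko = norm.loc[cells, target].to_numpy(float)
        ctrl = norm.loc[control_cells, target].to_numpy(float)
        p = float(stats.mannwhitneyu(ko, ctrl, alternative="less").pvalue)
        rows.append(
            {"guide": guide, "target": target, "n_cells": len(cells),
             "mean_ko": float(ko.mean()), "mean_control": float(ctrl.mean()),
             "p": p, "testable": True, "passed": bool(p < cfg.alpha)}
        )
    return pd.DataFrame(rows).set_index("guide")


def cluster_cells(pop: CellPopulation, cfg: QCConfig) -> CellPopulation:
    """PCA + k-means clustering of the normalized matrix (deterministic
    given the config seed). Labels are 1..k."""
    norm = _require_normalized(pop)
    if cfg.k_clusters > len(norm):
        raise DataError("more clusters requested than cells")
    x = norm.to_numpy(float)
    n_comp = min(cfg.n_pca, x.shape[0] - 1, x.shape[1])
    if n_comp >= 2:
        x = PCA(n_components=n_comp, random_state=cfg.seed).fit_transform(x)
    km = KMeans(n_clusters=cfg.k_clusters, random_state=cfg.seed, n_init=10)
    labels = km.fit_predict(x) + 1
    return replace(pop, clusters=pd.Series(labels, index=norm.index, name="cluster"))


def ko_cluster_composition(pop: CellPopulation) -> pd.DataFrame:
    """Knockout-percentage matrix: entry (g, c) is the percentage of
    knockout g's cells that fall in cluster c. Rows sum to 100 and are
    ordered by average-linkage clustering on 1 - Pearson r."""
    if pop.clusters is None:
        raise DataError("clusters missing; run cluster_cells first")
    if pop.cell_guide is None:
        raise DataError("cell-guide assignment missing; run qc_cells first")
    ko = pop.cell_guide.map(pop.knockout_of)
    tab = pd.crosstab(ko, pop.clusters.loc[ko.index])
    empty = tab.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"knockouts with zero cells omitted: {sorted(tab.index[empty])}")
        tab = tab[~empty]
    comp = tab.div(tab.sum(axis=1), axis=0) * 100.0
    if len(comp) > 2:
        arr = comp.to_numpy(float)
        sd = arr.std(axis=1)
        corr = np.corrcoef(arr)
        corr = np.nan_to_num(corr, nan=0.0)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        if np.all(sd > 0):
            from scipy.spatial.distance import squareform

            order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
            comp = comp.iloc[order]
    comp.index.name = "knockout"
    return comp


def trace_anchor_high(pop: CellPopulation, cfg: QCConfig) -> pd.DataFrame:
    """Fraction of each knockout's cells in the anchor-high population.

    Anchor-high = normalized anchor expression strictly above the
    ``anchor_high_quantile`` across retained cells. Knockouts are ranked
    ascending by that fraction (most depleted first).
    """
    norm = _require_normalized(pop)
    if pop.cell_guide is None:
        raise DataError("cell-guide assignment missing; run qc_cells first")
    if cfg.anchor not in norm.columns:
        raise DataError(f"anchor gene '{cfg.anchor}' absent from matrix")
    anchor_expr = norm[cfg.anchor]
    cutoff = float(anchor_expr.quantile(cfg.anchor_high_quantile))
    high = anchor_expr > cutoff
    if high.sum() == 0:
        raise DataError("no anchor-high cells at the configured quantile")
    ko = pop.cell_guide.map(pop.knockout_of)
    rows = []
    for knockout, cells in ko.groupby(ko):
        idx = cells.index
        n_high = int(high.loc[idx].sum())
        rows.append(
            {"knockout": knockout, "n_cells": len(idx), "n_anchor_high": n_high,
             "fraction_anchor_high": n_high / len(idx)}
        )
    out = pd.DataFrame(rows).set_index("knockout")
    out = out.sort_values(["fraction_anchor_high", "n_anchor_high"], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def target_expression_summary(
    pop: CellPopulation, gene: str, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-knockout distribution summary of one gene's normalized
    expression; knockouts with median below the non-targeting median and
    rank-sum p < alpha are flagged."""
    norm = _require_normalized(pop)
    if gene not in norm.columns:
        raise DataError(f"gene '{gene}' absent from matrix")
    if pop.cell_guide is None:
        raise DataError("cell-guide assignment missing; run qc_cells first")
    nt_guides = set(pop.target_map.index[pop.target_map["class"] == "non_targeting"])
    control_cells = pop.cell_guide.index[pop.cell_guide.isin(nt_guides)]
    ctrl = norm.loc[control_cells, gene].to_numpy(float) if len(control_cells) else np.array([])
    ctrl_median = float(np.median(ctrl)) if ctrl.size else np.nan
    ko = pop.cell_guide.map(pop.knockout_of)
    rows = []
    for knockout, cells in ko.groupby(ko):
        vals = norm.loc[cells.index, gene].to_numpy(float)
        if vals.size == 0:
            continue
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        if ctrl.size and vals.size:
            p = float(stats.mannwhitneyu(vals, ctrl, alternative="less").pvalue)
        else:
            p = np.nan
        rows.append(
            {"knockout": knockout, "n_cells": int(vals.size), "mean": float(vals.mean()),
             "median": float(med), "q25": float(q25), "q75": float(q75), "p": p,
             "reduced": bool(np.isfinite(p) and med < ctrl_median and p < alpha)}
        )
    return pd.DataFrame(rows).set_index("knockout")
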