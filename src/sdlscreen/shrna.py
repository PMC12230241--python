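"""Two-arm time-course dropout screen scoring.

The central statistic is the weighted differential cumulative change (WDC):
for each hairpin the epsilon-weighted sum of per-interval log2-signal
changes in the treatment arm minus the same sum in the control arm.
Negative values mean preferential dropout under treatment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

ARM_TREATMENT = "induced"
ARM_CONTROL = "uninduced"

_SAMPLE_RE = re.compile(r"^(?P<arm>.+)_T(?P<timepoint>\d+)_R(?P<replicate>\d+)$")


def sample_name(arm: str, timepoint: int, replicate: int) -> str:
    return f"{arm}_T{timepoint}_R{replicate}"


@dataclass
class ScreenTensor:
    """Hairpin x sample matrix of log2 signal with sample/hairpin annotation.

    Parameters
    ----------
    values
        DataFrame indexed by hairpin id, one column per sample.
    samples
        DataFrame indexed by sample name with columns ``arm``,
        ``timepoint`` (integer label) and ``replicate`` (integer).
    genes
        Series mapping hairpin id -> gene id, same index as ``values``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.genes.index):
            raise DataError("hairpin annotation does not match the value matrix")
        if self.values.index.has_duplicates:
            raise DataError("duplicate hairpin ids")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise DataError(f"samples without annotation: {sorted(missing)}")
        tps = self.timepoints
        if len(tps) < 2:
            raise DataError("at least two timepoints required")
        # full (arm, timepoint, replicate) grid
        for arm in self.arms:
            for t in tps:
                for r in self.replicates(arm):
                    if sample_name(arm, t, r) not in self.values.columns:
                        raise DataError(f"missing sample {sample_name(arm, t, r)}")

    # -- accessors ---------------------------------------------------------
    @property
    def arms(self) -> list[str]:
        return sorted(self.samples["arm"].unique())

    @property
    def timepoints(self) -> list[int]:
        return sorted(self.samples["timepoint"].unique())

    def replicates(self, arm: str) -> list[int]:
        return sorted(self.samples.loc[self.samples["arm"] == arm, "replicate"].unique())

    def column(self, arm: str, timepoint: int, replicate: int) -> pd.Series:
        return self.values[sample_name(arm, timepoint, replicate)]

    def subset(self, hairpins: pd.Index) -> "ScreenTensor":
        return ScreenTensor(
            self.values.loc[hairpins], self.samples.copy(), self.genes.loc[hairpins]
        )

    # -- interchange -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"hairpin": self.values.index, "gene": self.genes.values})
        out = pd.concat([out.set_index(self.values.index), self.values], axis=1)
        return out.reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ScreenTensor":
        for col in ("hairpin", "gene"):
            if col not in frame.columns:
                raise DataError(f"missing required column '{col}'")
        sample_cols, rows = [], []
        for col in frame.columns:
            m = _SAMPLE_RE.match(str(col))
            if m:
                sample_cols.append(col)
                rows.append(
                    (col, m["arm"], int(m["timepoint"]), int(m["replicate"]))
                )
        if not sample_cols:
            raise DataError("no sample columns matching '<arm>_T<t>_R<r>'")
        samples = pd.DataFrame(
            rows, columns=["sample", "arm", "timepoint", "replicate"]
        ).set_index("sample")
        values = frame.set_index("hairpin")[sample_cols].astype(float)
        genes = frame.set_index("hairpin")["gene"]
        return cls(values, samples, genes)


@dataclass
class WDCConfig:
    """Scoring parameters for the WDC pipeline."""

    epsilon: float = 0.5
    k_aggregate: int = 2
    n_permutations: int = 1000
    alpha: float = 0.05
    fold_threshold_log2: float = -1.0
    seed: int = 0
    require_ttest: bool = True
    require_permutation: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ConfigError("epsilon must be in (0, 1]")
        if self.k_aggregate < 1:
            raise ConfigError("k_aggregate must be >= 1")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class ReferenceGeneSets:
    essential: set = field(default_factory=set)
    non_essential: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.essential = set(self.essential)
        self.non_essential = set(self.non_essential)
        if self.essential & self.non_essential:
            raise ConfigError("reference sets must be disjoint")


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------

def quantile_normalize(tensor: ScreenTensor) -> ScreenTensor:
    """Force every column onto the distribution of row-rank means.

    Ties within a column receive the mean of the implicated row means
    (the standard convention).
    """
    vals = tensor.values
    if vals.isna().any().any():
        raise DataError("missing values in signal matrix")
    arr = vals.to_numpy(float)
    ref = np.sort(arr, axis=0).mean(axis=1)  # reference distribution
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col = np.empty(arr.shape[0])
        col[order] = ref
        # average the mapped values over tied input values
        s = pd.Series(col).groupby(pd.Series(arr[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    values = pd.DataFrame(out, index=vals.index, columns=vals.columns)
    return ScreenTensor(values, tensor.samples.copy(), tensor.genes.copy())


def filter_hairpins(
    tensor: ScreenTensor,
    t0_floor: float = 8.0,
    later_floor: float = 0.0,
) -> tuple[ScreenTensor, pd.DataFrame]:
    """Drop hairpins with sub-background signal.

    A hairpin is removed iff any sample at the first timepoint is below
    ``t0_floor`` or any sample at a later timepoint is below
    ``later_floor``. Returns the retained tensor and a table of dropped
    hairpins with reasons.
    """
    tps = tensor.timepoints
    t0 = tps[0]
    t0_cols = [c for c in tensor.values.columns if tensor.samples.loc[c, "timepoint"] == t0]
    later_cols = [c for c in tensor.values.columns if tensor.samples.loc[c, "timepoint"] != t0]
    below_t0 = (tensor.values[t0_cols] < t0_floor).any(axis=1)
    below_later = (tensor.values[later_cols] < later_floor).any(axis=1)
    reasons = []
    for hp in tensor.values.index:
        rs = []
        if below_t0[hp]:
            rs.append("T0 below background")
        if below_later[hp]:
            rs.append("later timepoint below floor")
        if rs:
            reasons.append((hp, tensor.genes[hp], "; ".join(rs)))
    dropped = pd.DataFrame(reasons, columns=["hairpin", "gene", "reason"])
    keep = tensor.values.index[~(below_t0 | below_later)]
    return tensor.subset(keep), dropped


# ---------------------------------------------------------------------------
# WDC scoring
# ---------------------------------------------------------------------------

def weighted_cumulative_change(
    tensor: ScreenTensor, epsilon: float
) -> pd.DataFrame:
    """Per (hairpin, arm, replicate) weighted cumulative log2 change.

    wcc = sum_{t=0}^{T-1} epsilon^{t+1} (x_{t+1} - x_t) where t indexes
    consecutive timepoints in order.
    """
    tps = tensor.timepoints
    weights = epsilon ** np.arange(1, len(tps))
    cols = {}
    for arm in tensor.arms:
        for r in tensor.replicates(arm):
            traj = np.column_stack(
                [tensor.column(arm, t, r).to_numpy(float) for t in tps]
            )
            diffs = np.diff(traj, axis=1)
            cols[(arm, r)] = diffs @ weights
    out = pd.DataFrame(cols, index=tensor.values.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["arm", "replicate"])
    return out


def wdc_hairpin(
    tensor: ScreenTensor,
    config: WDCConfig,
    arm_treatment: str = ARM_TREATMENT,
    arm_control: str = ARM_CONTROL,
) -> pd.DataFrame:
    """Hairpin-level WDC: per-replicate treatment-minus-control weighted
    cumulative change, averaged over replicates."""
    for arm in (arm_treatment, arm_control):
        if arm not in tensor.arms:
            raise DataError(f"arm '{arm}' absent from tensor")
    wcc = weighted_cumulative_change(tensor, config.epsilon)
    reps_t = tensor.replicates(arm_treatment)
    reps_c = tensor.replicates(arm_control)
    if len(reps_t) != len(reps_c):
        raise DataError("arms have different replicate counts")
    comp = {
        f"component_R{rt}": wcc[(arm_treatment, rt)] - wcc[(arm_control, rc)]
        for rt, rc in zip(reps_t, reps_c)
    }
    table = pd.DataFrame(comp, index=tensor.values.index)
    table.insert(0, "gene", tensor.genes)
    table["wdc"] = table[[c for c in table.columns if c.startswith("component_")]].mean(axis=1)
    return table


def wdc_gene(hairpin_scores: pd.DataFrame, config: WDCConfig) -> pd.DataFrame:
    """Gene-level score: mean of the k most negative hairpin WDCs.

    Genes with fewer than ``k_aggregate`` hairpins use all available and
    are flagged ``underpowered``. Ties are broken by (score, hairpin id)
    stable order.
    """
    rows = []
    ordered = hairpin_scores.sort_index().sort_values("wdc", kind="stable")
    for gene, grp in ordered.groupby("gene", sort=True):
        k = min(config.k_aggregate, len(grp))
        rows.append(
            {
                "gene": gene,
                "wdc": float(grp["wdc"].iloc[:k].mean()),
                "n_hairpins": int(len(grp)),
                "n_used": int(k),
                "underpowered": len(grp) < config.k_aggregate,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def _aggregate_k_smallest(matrix: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean of the k smallest entries."""
    if matrix.shape[1] <= k:
        return matrix.mean(axis=1)
    part = np.partition(matrix, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def permutation_pvalues(
    hairpin_scores: pd.DataFrame,
    gene_table: pd.DataFrame,
    config: WDCConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Permutation p per gene against a pool-resampling null.

    For a gene with m hairpins, each null draw takes m scores without
    replacement from the global hairpin pool and aggregates them with the
    same k-most-negative rule; p = (1 + #{null <= observed}) / (1 + B).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    pool = hairpin_scores["wdc"].to_numpy(float)
    n_pool = pool.size
    pvals = pd.Series(np.nan, index=gene_table.index, name="p_perm")
    for m in sorted(gene_table["n_hairpins"].unique()):
        m = int(m)
        if m > n_pool:
            raise DataError(f"gene has {m} hairpins but pool holds only {n_pool}")
        u = rng.random((config.n_permutations, n_pool))
        idx = np.argpartition(u, min(m, n_pool - 1), axis=1)[:, :m]
        null = _aggregate_k_smallest(pool[idx], min(config.k_aggregate, m))
        null_sorted = np.sort(null)
        genes_m = gene_table.index[gene_table["n_hairpins"] == m]
        obs = gene_table.loc[genes_m, "wdc"].to_numpy(float)
        b = np.searchsorted(null_sorted, obs, side="right")
        pvals.loc[genes_m] = (1.0 + b) / (1.0 + config.n_permutations)
    return pvals


def ttest_pvalues(
    tensor: ScreenTensor,
    hairpin_scores: pd.DataFrame,
    config: WDCConfig,
    arm_treatment: str = ARM_TREATMENT,
    arm_control: str = ARM_CONTROL,
) -> pd.Series:
    """Two-sided t-test per gene of weighted cumulative changes between arms.

    Observations are the per-(hairpin, replicate) weighted cumulative
    changes of the gene's retained hairpins. Degenerate cases (fewer than
    two observations per arm, or zero variance in both arms) yield NaN.
    """
    wcc = weighted_cumulative_change(tensor, config.epsilon)
    genes = tensor.genes.loc[hairpin_scores.index]
    t_cols = [c for c in wcc.columns if c[0] == arm_treatment]
    c_cols = [c for c in wcc.columns if c[0] == arm_control]
    out = {}
    for gene, hps in genes.groupby(genes):
        sub = wcc.loc[hps.index]
        a = sub[t_cols].to_numpy(float).ravel()
        b = sub[c_cols].to_numpy(float).ravel()
        if a.size < 2 or b.size < 2:
            out[gene] = np.nan
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            out[gene] = np.nan  # zero variance in both arms: not computable
            continue
        out[gene] = float(stats.ttest_ind(a, b).pvalue)
    return pd.Series(out, name="p_ttest")


def call_hits(gene_table: pd.DataFrame, config: WDCConfig) -> pd.DataFrame:
    """Flag hits: wdc <= fold threshold and both p values below alpha.

    Genes whose p values are flagged not-computable (NaN) are never hits.
    """
    tbl = gene_table.copy()
    hit = tbl["wdc"] <= config.fold_threshold_log2
    if config.require_permutation:
        hit &= tbl["p_perm"].notna() & (tbl["p_perm"] < config.alpha)
    if config.require_ttest:
        hit &= tbl["p_ttest"].notna() & (tbl["p_ttest"] < config.alpha)
    tbl["hit"] = hit
    return tbl


def score_screen(
    tensor: ScreenTensor,
    config: WDCConfig,
    arm_treatment: str = ARM_TREATMENT,
    arm_control: str = ARM_CONTROL,
    normalize: bool = True,
    t0_floor: float = 8.0,
    later_floor: float = 0.0,
) -> dict:
    """Full pipeline: normalize -> filter -> WDC -> p values -> hit calls."""
    work = quantile_normalize(tensor) if normalize else tensor
    work, dropped = filter_hairpins(work, t0_floor=t0_floor, later_floor=later_floor)
    hp = wdc_hairpin(work, config, arm_treatment, arm_control)
    genes = wdc_gene(hp, config)
    rng = np.random.default_rng(config.seed)
    genes["p_perm"] = permutation_pvalues(hp, genes, config, rng)
    genes["p_ttest"] = ttest_pvalues(work, hp, config, arm_treatment, arm_control)
    genes = call_hits(genes, config)
    return {
        "tensor": work,
        "dropped": dropped,
        "hairpin_scores": hp,
        "gene_scores": genes,
    }


# ---------------------------------------------------------------------------
# QC and evaluation
# ---------------------------------------------------------------------------

def replicate_correlation(tensor: ScreenTensor) -> pd.DataFrame:
    """Pairwise Pearson r between replicate columns per (arm, timepoint)."""
    rows = []
    for arm in tensor.arms:
        reps = tensor.replicates(arm)
        if len(reps) < 2:
            raise DataError(f"arm '{arm}' has fewer than 2 replicates")
        for t in tensor.timepoints:
            for i, r1 in enumerate(reps):
                for r2 in reps[i + 1:]:
                    a = tensor.column(arm, t, r1).to_numpy(float)
                    b = tensor.column(arm, t, r2).to_numpy(float)
                    if np.ptp(a) == 0 or np.ptp(b) == 0:
                        r = np.nan
                    else:
                        r = float(np.corrcoef(a, b)[0, 1])
                    rows.append((arm, t, r1, r2, r, not np.isfinite(r)))
    return pd.DataFrame(
        rows, columns=["arm", "timepoint", "rep1", "rep2", "pearson_r", "undefined"]
    )


def evaluate_performance(
    gene_table: pd.DataFrame, refs: ReferenceGeneSets
) -> dict:
    """Precision-recall over the ascending-WDC ranking.

    ``essential`` genes are positives, ``non_essential`` negatives; genes
    outside both sets are ignored. Returns the PR curve and max F-measure.
    """
    labeled = gene_table.index[
        gene_table.index.isin(refs.essential | refs.non_essential)
    ]
    if len(labeled) == 0 or not (set(labeled) & refs.essential):
        raise DataError("reference sets do not overlap scored genes")
    sub = gene_table.loc[labeled].sort_values("wdc", kind="stable")
    y = np.asarray(sub.index.isin(refs.essential), dtype=int)
    tp = np.cumsum(y)
    ranks = np.arange(1, len(y) + 1)
    precision = tp / ranks
    recall = tp / y.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
    curve = pd.DataFrame(
        {"rank": ranks, "gene": sub.index, "precision": precision, "recall": recall, "f": f}
    )
    return {"curve": curve, "f_max": float(f.max())}


def cumulative_signal_comparison(
    tensor: ScreenTensor, gene_set: set
) -> pd.DataFrame:
    """Summed linear-signal fold change T0 -> final per arm + KS test.

    The linear signal of a hairpin is 2**log2 value averaged over
    replicates; fold = sum at T0 / sum at the final timepoint. The KS test
    compares the per-hairpin linear signal distributions at T0 vs final.
    """
    gene_set = set(gene_set)
    hps = tensor.genes.index[tensor.genes.isin(gene_set)]
    if len(hps) == 0:
        raise DataError("gene set has no hairpins in the tensor")
    tps = tensor.timepoints
    t0, tf = tps[0], tps[-1]
    rows = []
    for arm in tensor.arms:
        reps = tensor.replicates(arm)
        lin0 = np.mean(
            [2.0 ** tensor.column(arm, t0, r).loc[hps].to_numpy(float) for r in reps],
            axis=0,
        )
        linf = np.mean(
            [2.0 ** tensor.column(arm, tf, r).loc[hps].to_numpy(float) for r in reps],
            axis=0,
        )
        ks = stats.ks_2samp(lin0, linf)
        rows.append(
            {
                "arm": arm,
                "fold_change": float(lin0.sum() / linf.sum()),
                "ks_stat": float(ks.statistic),
                "ks_p": float(ks.pvalue),
            }
        )
    return pd.DataFrame(rows).set_index("arm")
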