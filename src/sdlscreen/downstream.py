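"""Remaining quantitative analyses: tumor growth kinetics, PDX group
comparison, mito-stress metrics, and RNA motif counting."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError

DEFAULT_MOTIFS = ("UGGA", "AGGU")


def tumor_volume(a_mm: float, b_mm: float) -> float:
    """Caliper volume (A * B^2) / 2 with A the long and B the short
    diameter; swapped inputs are corrected with a warning."""
    if a_mm <= 0 or b_mm <= 0:
        raise DataError("caliper measurements must be positive")
    if a_mm < b_mm:
        warnings.warn("long diameter smaller than short diameter; swapping")
        a_mm, b_mm = b_mm, a_mm
    return a_mm * b_mm ** 2 / 2.0


def growth_kinetics(series: pd.DataFrame) -> dict:
    """Least-squares slope of log2(volume) vs time and the implied
    doubling time (1 / slope; undefined for non-positive slopes).

    ``series`` needs columns ``day`` and either ``volume`` or calipers
    ``A``/``B``.
    """
    if "volume" in series.columns:
        vol = series["volume"].to_numpy(float)
    elif {"A", "B"} <= set(series.columns):
        vol = np.array(
            [tumor_volume(a, b) for a, b in zip(series["A"], series["B"])], float
        )
    else:
        raise DataError("growth series needs 'volume' or caliper columns 'A','B'")
    day = series["day"].to_numpy(float)
    if len(day) < 3:
        raise DataError("need at least 3 timepoints")
    if np.any(vol <= 0):
        raise DataError("volumes must be positive")
    fit = stats.linregress(day, np.log2(vol))
    slope = float(fit.slope)
    if slope > 0:
        doubling = 1.0 / slope
        undefined = False
    else:
        doubling = float("inf")
        undefined = True
    return {
        "slope": slope,
        "doubling_time": doubling,
        "doubling_undefined": undefined,
        "r_squared": float(fit.rvalue ** 2) if np.isfinite(fit.rvalue) else float("nan"),
        "intercept_log2": float(fit.intercept),
    }


def pdx_group_compare(
    table: pd.DataFrame,
    low_fpkm: float = 20.0,
    high_fpkm: float = 30.0,
    alpha: float = 0.05,
) -> dict:
    """Assign PDX models to expression groups and Welch-compare kinetics.

    ``table`` has columns anchor_fpkm, partner_fpkm, slope, doubling_time.
    Groups (anchor must be high in both): sdl_like = partner < low_fpkm;
    both_high = partner > high_fpkm; partner in [low, high] -> unassigned.
    Welch two-sample t-tests on slope and doubling time between groups.
    """
    need = {"anchor_fpkm", "partner_fpkm", "slope", "doubling_time"}
    if not need <= set(table.columns):
        raise DataError(f"PDX table needs columns {sorted(need)}")
    anchor_high = table["anchor_fpkm"] > high_fpkm
    group = np.where(
        anchor_high & (table["partner_fpkm"] < low_fpkm),
        "sdl_like",
        np.where(anchor_high & (table["partner_fpkm"] > high_fpkm), "both_high", "unassigned"),
    )
    out = table.copy()
    out["group"] = group
    tests = {}
    g1 = out[out["group"] == "sdl_like"]
    g2 = out[out["group"] == "both_high"]
    for metric in ("slope", "doubling_time"):
        a = g1[metric].replace([np.inf, -np.inf], np.nan).dropna().to_numpy(float)
        b = g2[metric].replace([np.inf, -np.inf], np.nan).dropna().to_numpy(float)
        if len(a) < 3 or len(b) < 3:
            tests[metric] = {"p": np.nan, "computable": False}
            continue
        res = stats.ttest_ind(a, b, equal_var=False)  # Welch
        tests[metric] = {
            "p": float(res.pvalue),
            "computable": True,
            "mean_sdl_like": float(a.mean()),
            "mean_both_high": float(b.mean()),
            "significant": bool(res.pvalue < alpha),
        }
    return {"table": out, "tests": tests}


def mito_metrics(trace: dict) -> dict:
    """Mito-stress test metrics from phase-wise OCR measurements.

    ``trace`` maps phase in {basal, post_oligomycin, post_fccp,
    post_rot_aa} to a sequence of OCR values. The additivity identity
    atp_linked + proton_leak == basal_resp holds exactly.
    """
    phases = ("basal", "post_oligomycin", "post_fccp", "post_rot_aa")
    for ph in phases:
        if ph not in trace or len(trace[ph]) == 0:
            raise DataError(f"missing mito-stress phase '{ph}'")
    basal = np.asarray(trace["basal"], float)
    oligo = np.asarray(trace["post_oligomycin"], float)
    fccp = np.asarray(trace["post_fccp"], float)
    rot = np.asarray(trace["post_rot_aa"], float)
    non_mito = float(rot.mean())
    basal_resp = float(basal[-1] - non_mito)
    atp_linked = float(basal[-1] - oligo.min())
    proton_leak = float(oligo.min() - non_mito)
    maximal_resp = float(fccp.max() - non_mito)
    spare = maximal_resp - basal_resp
    return {
        "non_mito": non_mito,
        "basal_resp": basal_resp,
        "atp_linked": atp_linked,
        "proton_leak": proton_leak,
        "maximal_resp": maximal_resp,
        "spare_capacity": spare,
        "spare_negative": spare < 0,
    }


def count_motifs_in_seq(sequence: str, motifs=DEFAULT_MOTIFS) -> dict:
    """Sliding-window motif counts (overlaps counted; T read as U; N never
    matches)."""
    seq = str(sequence).upper().replace("T", "U")
    out = {}
    for motif in motifs:
        m = motif.upper().replace("T", "U")
        k = len(m)
        out[motif] = sum(1 for i in range(len(seq) - k + 1) if seq[i: i + k] == m)
    return out


def count_motifs(records, motifs=DEFAULT_MOTIFS) -> pd.DataFrame:
    """Per-sequence and total motif counts over FASTA records (Biopython
    SeqRecords or (id, sequence) pairs)."""
    rows = []
    for rec in records:
        if hasattr(rec, "seq"):
            name, seq = rec.id, str(rec.seq)
        else:
            name, seq = rec
        rows.append({"sequence": name, **count_motifs_in_seq(seq, motifs)})
    table = pd.DataFrame(rows).set_index("sequence") if rows else pd.DataFrame(
        columns=list(motifs)
    )
    table.loc["__total__"] = table.sum(axis=0) if len(table) else 0
    return table
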