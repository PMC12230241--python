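"""Readers and writers for the plain-text interchange formats.

TSV/CSV via pandas, FASTA/FASTQ via Biopython, sparse UMI matrices as MTX
triplets with features/barcodes sidecars, plus JSON provenance records.
"""

from __future__ import annotations

import gzip
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from Bio import SeqIO

from .errors import DataError
from .shrna import ScreenTensor


# -- screen tensors ---------------------------------------------------------

def write_intensity_tsv(tensor: ScreenTensor, path) -> None:
    tensor.to_frame().to_csv(path, sep="\t", index=False)


def read_intensity_tsv(path) -> ScreenTensor:
    frame = pd.read_csv(path, sep="\t")
    return ScreenTensor.from_frame(frame)


# -- count matrices ---------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("guide").to_csv(path, sep="\t")


def read_counts_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts TSV with columns named '<arm>_S<n>'; returns (counts, sample
    annotation)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    rows = []
    for col in counts.columns:
        arm, _, rep = str(col).rpartition("_S")
        if not arm or not rep.isdigit():
            raise DataError(f"sample column '{col}' does not match '<arm>_S<n>'")
        rows.append((col, arm, int(rep)))
    samples = pd.DataFrame(rows, columns=["sample", "arm", "replicate"]).set_index("sample")
    return counts, samples


# -- guide libraries --------------------------------------------------------

def write_library_csv(table: pd.DataFrame, path) -> None:
    table.rename_axis("guide").to_csv(path)


def read_library_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path).set_index("guide")
    if not {"gene", "spacer"} <= set(table.columns):
        raise DataError("library CSV needs columns guide,gene,spacer")
    return table


# -- sequence files ---------------------------------------------------------

def _open_maybe_gz(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def write_fastq(records, path) -> None:
    with _open_maybe_gz(path, "wt") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path):
    with _open_maybe_gz(path) as fh:
        yield from SeqIO.parse(fh, "fastq")


def write_fasta(records, path, wrap: int = 60) -> None:
    writer = SeqIO.FastaIO.FastaWriter(path, wrap=wrap)
    writer.write_file(records)


def read_fasta(path):
    return list(SeqIO.parse(path, "fasta"))


# -- UMI matrices -----------------------------------------------------------

def write_mtx_dir(umi: pd.DataFrame, outdir) -> None:
    """MTX triplet (genes x cells, matrix-market) with features.tsv and
    barcodes.tsv sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(umi.to_numpy().T)  # genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sparse)
    pd.Series(umi.columns).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(umi.index).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx_dir(indir) -> pd.DataFrame:
    indir = Path(indir)
    mat = scipy.io.mmread(str(indir / "matrix.mtx")).toarray().T  # cells x genes
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0].tolist()
    cells = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(
        np.asarray(mat, dtype=np.int64), index=pd.Index(cells, name="cell"), columns=genes
    )


def write_guide_table_csv(guides: pd.DataFrame, path) -> None:
    guides.to_csv(path, index=False)


def read_guide_table_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if not {"cell", "guide", "umis"} <= set(table.columns):
        raise DataError("guide table CSV needs columns cell,guide,umis")
    return table


def read_target_map_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=False).set_index("guide")
    if not {"target", "class"} <= set(table.columns):
        raise DataError("target map CSV needs columns guide,target,class")
    return table


# -- truth sidecars and provenance ------------------------------------------

def write_truth_json(truth: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        if isinstance(obj, pd.Series):
            return obj.to_dict()
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="index")
        if isinstance(obj, (set, tuple, np.ndarray)):
            return list(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=_default, sort_keys=True)


def write_provenance(outdir, subcommand: str, params: dict) -> Path:
    """Machine-readable record of how a run was produced."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = {
        "subcommand": subcommand,
        "params": params,
        "versions": {
            "sdlscreen": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "provenance.json"
    write_truth_json(record, path)
    return path
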