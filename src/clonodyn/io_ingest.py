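"""Readers and writers for the pipeline's canonical tables.

Two V(D)J contig dialects are supported: the 10x Genomics
``filtered_contig_annotations.csv`` layout and the AIRR-C rearrangement
TSV. Both are mapped onto one canonical contig table so that everything
downstream is dialect-agnostic. Sample identity (patient, cycle,
compartment) is deliberately *not* inferred from file names; it is
supplied by the caller or by a YAML manifest, which keeps provenance
explicit and reproducible.

Column-name mappings are fixed in code (below); unknown extra columns are
ignored with a logged warning so that future dialect revisions do not
break ingestion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .types import (
    NONE_GENE,
    SAMPLE_COLS,
    FormatError,
    IntegrityError,
    SampleKey,
    ValidationError,
)

log = logging.getLogger(__name__)

#: Canonical contig-table columns, in output order.
CONTIG_COLUMNS = SAMPLE_COLS + [
    "barcode",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "cdr3_nt",
    "cdr3_aa",
    "reads",
    "umis",
    "productive",
    "is_cell",
]

#: Canonical per-cell metadata columns.
CELL_COLUMNS = SAMPLE_COLS + [
    "barcode",
    "cell_type",
    "t_state",
    "car_reads",
    "n_genes",
    "n_counts",
    "pct_mito",
]

# dialect column -> canonical column
TENX_MAP = {
    "barcode": "barcode",
    "is_cell": "is_cell",
    "chain": "chain",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "c_gene": "c_gene",
    "cdr3_nt": "cdr3_nt",
    "cdr3": "cdr3_aa",
    "reads": "reads",
    "umis": "umis",
    "productive": "productive",
}
TENX_REQUIRED = ["barcode", "chain", "v_gene", "j_gene", "cdr3", "cdr3_nt", "reads", "umis", "productive"]

AIRR_MAP = {
    "cell_id": "barcode",
    "is_cell": "is_cell",
    "locus": "chain",
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "c_call": "c_gene",
    "junction": "cdr3_nt",
    "junction_aa": "cdr3_aa",
    "consensus_count": "reads",
    "duplicate_count": "umis",
    "productive": "productive",
}
AIRR_REQUIRED = [
    "cell_id",
    "locus",
    "v_call",
    "j_call",
    "junction",
    "junction_aa",
    "consensus_count",
    "duplicate_count",
    "productive",
]

#: Standard dialect columns we do not consume; present in normal exports,
#: so their appearance is not worth a warning.
KNOWN_EXTRA = {
    "contig_id", "high_confidence", "length", "full_length",
    "raw_clonotype_id", "raw_consensus_id", "exact_subclonotype_id",
    "sequence_id", "sequence", "rev_comp", "sequence_alignment",
    "germline_alignment", "clone_id", "cell_id_suffix",
}

_DIALECTS = {
    "tenx_csv": (TENX_MAP, TENX_REQUIRED, ","),
    "airr_tsv": (AIRR_MAP, AIRR_REQUIRED, "\t"),
}

_TRUE = {"true", "t", "1", "yes"}
_FALSE = {"false", "f", "0", "no", "none", ""}


def _parse_bool(series: pd.Series, column: str) -> pd.Series:
    if series.dtype == bool:
        return series
    as_str = series.astype(str).str.strip().str.lower()
    bad = ~(as_str.isin(_TRUE) | as_str.isin(_FALSE))
    if bad.any():
        rows = list(series.index[bad][:5])
        raise FormatError(f"unparseable boolean in column {column!r} at rows {rows}")
    return as_str.isin(_TRUE)


def _parse_int(series: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_numeric(series, errors="coerce")
    bad = parsed.isna()
    if bad.any():
        rows = list(series.index[bad][:5])
        raise FormatError(f"unparseable integer in column {column!r} at rows {rows}")
    return parsed.astype(np.int64)


def _clean_gene(series: pd.Series) -> pd.Series:
    out = series.astype("string").fillna(NONE_GENE).astype(str).str.strip()
    out = out.replace({"": NONE_GENE, "nan": NONE_GENE, "NA": NONE_GENE})
    return out


def read_contigs(
    path: str | Path,
    dialect: str = "tenx_csv",
    sample: SampleKey | None = None,
) -> pd.DataFrame:
    """Read one sample's V(D)J contig annotations into the canonical table.

    Non-cell and non-productive rows are retained but flagged; filtering
    happens downstream at clonotype calling. Chains other than TRA/TRB
    (e.g. IGH from ambient B-cell material) are mapped to ``"other"``.

    Parameters
    ----------
    path
        Contig annotation file.
    dialect
        ``"tenx_csv"`` (filtered_contig_annotations.csv) or
        ``"airr_tsv"`` (AIRR-C rearrangement TSV).
    sample
        Sample identity to stamp on every row. If omitted, the file must
        itself carry ``upn``/``cycle``/``compartment`` columns.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    colmap, required, sep = _DIALECTS[dialect]
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing} for dialect {dialect!r}")
    extra = [c for c in raw.columns
             if c not in colmap and c not in SAMPLE_COLS and c not in KNOWN_EXTRA]
    if extra:
        log.warning("%s: ignoring %d unrecognised column(s): %s", path.name, len(extra), extra)

    df = pd.DataFrame(index=raw.index)
    for src, dst in colmap.items():
        if src in raw.columns:
            df[dst] = raw[src]

    if sample is not None:
        for k, v in sample.as_dict().items():
            df[k] = v
    elif all(c in raw.columns for c in SAMPLE_COLS):
        for c in SAMPLE_COLS:
            df[c] = raw[c]
        df["cycle"] = _parse_int(df["cycle"], "cycle")
    else:
        raise FormatError(
            f"{path.name}: no sample key given and file lacks {SAMPLE_COLS} columns"
        )

    df["chain"] = df["chain"].astype(str).str.strip().str.upper()
    df.loc[~df["chain"].isin(["TRA", "TRB"]), "chain"] = "other"
    for col in ("v_gene", "d_gene", "j_gene", "c_gene"):
        df[col] = _clean_gene(df[col]) if col in df.columns else NONE_GENE
    for col in ("reads", "umis"):
        df[col] = _parse_int(df[col], col)
    df["productive"] = _parse_bool(df["productive"], "productive")
    if "is_cell" in df.columns:
        df["is_cell"] = _parse_bool(df["is_cell"], "is_cell")
    else:
        df["is_cell"] = True
    df["cdr3_nt"] = df["cdr3_nt"].astype(str).str.upper()
    df["cdr3_aa"] = df["cdr3_aa"].astype(str)

    if (df["reads"] < 0).any() or (df["umis"] < 0).any():
        raise ValidationError(f"{path.name}: negative reads/umis counts")
    return df[CONTIG_COLUMNS].reset_index(drop=True)


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV into the canonical cell table.

    Enforces: unique (barcode, sample) keys, ``car_reads >= 0`` and
    ``pct_mito`` within [0, 100].
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in CELL_COLUMNS if c != "t_state"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")
    if "t_state" not in df.columns:
        df["t_state"] = pd.NA
    else:
        df["t_state"] = df["t_state"].replace("", pd.NA)

    df["cycle"] = _parse_int(df["cycle"], "cycle")
    for col in ("car_reads", "n_genes", "n_counts"):
        df[col] = _parse_int(df[col], col)
    df["pct_mito"] = pd.to_numeric(df["pct_mito"], errors="coerce")
    if df["pct_mito"].isna().any():
        rows = list(df.index[df["pct_mito"].isna()][:5])
        raise FormatError(f"{path.name}: unparseable pct_mito at rows {rows}")
    return validate_cells(df[CELL_COLUMNS], name=path.name)


def validate_cells(df: pd.DataFrame, name: str = "cell metadata") -> pd.DataFrame:
    """Check domain constraints on a canonical cell table."""
    key = df[SAMPLE_COLS + ["barcode"]]
    dup = key.duplicated()
    if dup.any():
        offenders = df.loc[dup, "barcode"].head(5).tolist()
        raise IntegrityError(f"{name}: duplicate (barcode, sample) keys, e.g. {offenders}")
    if (df["car_reads"] < 0).any():
        raise ValidationError(f"{name}: negative car_reads")
    bad_mito = (df["pct_mito"] < 0) | (df["pct_mito"] > 100)
    if bad_mito.any():
        vals = df.loc[bad_mito, "pct_mito"].head(5).tolist()
        raise ValidationError(f"{name}: pct_mito outside [0, 100], e.g. {vals}")
    return df.reset_index(drop=True)


@dataclass
class CountMatrix:
    """A genes x cells sparse count matrix with its sidecar name lists."""

    genes: list
    barcodes: list
    matrix: sp.csr_matrix  # genes x cells, non-negative integers

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"count matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.genes)} genes x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValidationError("count matrix has negative entries")

    @property
    def shape(self):
        return self.matrix.shape

    def select_barcodes(self, barcodes) -> "CountMatrix":
        """Column-subset to the given barcodes (kept in the given order)."""
        pos = {b: i for i, b in enumerate(self.barcodes)}
        idx = [pos[b] for b in barcodes if b in pos]
        return CountMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in idx],
            matrix=self.matrix[:, idx],
        )


def read_counts(
    mtx_path: str | Path, features_path: str | Path, barcodes_path: str | Path
) -> CountMatrix:
    """Read a MatrixMarket triplet (matrix.mtx + features/barcodes TSV)."""
    matrix = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    features = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    genes = features[0].tolist()
    cells = barcodes[0].tolist()
    if matrix.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX header says {matrix.shape} but sidecars list "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    return CountMatrix(genes=genes, barcodes=cells, matrix=matrix)


# ---------------------------------------------------------------- writers

def write_contigs_tenx(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical contig table in the 10x contig-annotation dialect."""
    out = pd.DataFrame(
        {
            "barcode": df["barcode"],
            "is_cell": df["is_cell"].map({True: "True", False: "False"}),
            "contig_id": [
                f"{b}_contig_{i}" for i, b in enumerate(df["barcode"], start=1)
            ],
            "high_confidence": "True",
            "length": df["cdr3_nt"].str.len() + 450,
            "chain": df["chain"],
            "v_gene": df["v_gene"],
            "d_gene": df["d_gene"],
            "j_gene": df["j_gene"],
            "c_gene": df["c_gene"],
            "full_length": "True",
            "productive": df["productive"].map({True: "True", False: "False"}),
            "cdr3": df["cdr3_aa"],
            "cdr3_nt": df["cdr3_nt"],
            "reads": df["reads"],
            "umis": df["umis"],
            "raw_clonotype_id": "None",
            "raw_consensus_id": "None",
        }
    )
    out.to_csv(path, index=False)


def write_contigs_airr(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical contig table as an AIRR-C rearrangement TSV."""
    out = pd.DataFrame(
        {
            "cell_id": df["barcode"],
            "is_cell": df["is_cell"].map({True: "T", False: "F"}),
            "locus": df["chain"],
            "v_call": df["v_gene"],
            "d_call": df["d_gene"],
            "j_call": df["j_gene"],
            "c_call": df["c_gene"],
            "junction": df["cdr3_nt"],
            "junction_aa": df["cdr3_aa"],
            "consensus_count": df["reads"],
            "duplicate_count": df["umis"],
            "productive": df["productive"].map({True: "T", False: "F"}),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_cell_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df[CELL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_counts(
    cm: CountMatrix,
    mtx_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    out = sp.coo_matrix(cm.matrix)
    out.data = out.data.astype(np.int64)
    scipy.io.mmwrite(str(mtx_path), out)
    pd.Series(cm.genes).to_csv(features_path, sep="\t", index=False, header=False)
    pd.Series(cm.barcodes).to_csv(barcodes_path, sep="\t", index=False, header=False)
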