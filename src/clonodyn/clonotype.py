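"""Strict paired-chain clonotype calling and per-sample frequency tables.

A clonotype is defined at the *strict* level: the exact V, D, J and C
gene segments together with the CDR3 nucleotide sequence, on **both** the
alpha and the beta chain. Two cells share a clonotype iff both full keys
match exactly; a single synonymous nucleotide substitution in either CDR3
yields a different clonotype. A barcode is assigned a clonotype only if
it has at least one productive, cell-associated TRA *and* TRB contig.

When a barcode carries multiple productive contigs for one locus (real
dual-TCR cells, ambient contamination, or doublets), the contig with the
highest UMI count is selected; ties break by highest read count, then
lexicographically smallest CDR3 nucleotide sequence, then gene names —
a deterministic rule, so shuffling input rows never changes the calls.
"""

from __future__ import annotations

import hashlib
import logging

import numpy as np
import pandas as pd

from .types import SAMPLE_COLS, IntegrityError

log = logging.getLogger(__name__)

ALPHA_KEY_FIELDS = ["v_gene", "j_gene", "c_gene", "cdr3_nt"]  # TRA has no D segment
BETA_KEY_FIELDS = ["v_gene", "d_gene", "j_gene", "c_gene", "cdr3_nt"]


def make_clonotype_id(alpha_key: str, beta_key: str) -> str:
    """Stable 16-hex-digit id for a paired strict clonotype key."""
    return hashlib.sha1(f"{alpha_key}&{beta_key}".encode()).hexdigest()[:16]


def _chain_key(df: pd.DataFrame, fields: list[str]) -> pd.Series:
    key = df[fields[0]].astype(str)
    for f in fields[1:]:
        key = key + "|" + df[f].astype(str)
    return key


def call_clonotypes(contigs: pd.DataFrame, cells: pd.DataFrame) -> pd.DataFrame:
    """Assign a strict paired clonotype to each barcode that supports one.

    Parameters
    ----------
    contigs
        Canonical contig table (may include non-productive / non-cell /
        non-TR rows; they are filtered here).
    cells
        Canonical cell metadata; contigs whose (barcode, sample) is not
        annotated are skipped (count logged and reported in
        ``result.attrs["n_orphan_contigs"]``).

    Returns
    -------
    DataFrame with one row per assigned barcode: sample-key columns,
    ``barcode``, ``alpha_key``, ``beta_key``, ``clonotype_id``. Barcodes
    lacking a productive TRA/TRB pair are absent (mapped to none);
    ``attrs["n_unpaired"]`` counts them.
    """
    key_cols = SAMPLE_COLS + ["barcode"]
    known = cells[key_cols].drop_duplicates()
    merged = contigs.merge(known, on=key_cols, how="left", indicator=True)
    n_orphans = int((merged["_merge"] == "left_only").sum())
    if n_orphans:
        log.warning("skipping %d contig(s) whose barcode is absent from cell metadata", n_orphans)
    usable = merged[
        (merged["_merge"] == "both")
        & merged["productive"]
        & merged["is_cell"]
        & merged["chain"].isin(["TRA", "TRB"])
    ].drop(columns="_merge")

    # Deterministic per-locus contig selection: top UMIs, then reads, then
    # lexicographic CDR3nt / gene names. Stable under input permutation.
    ordered = usable.sort_values(
        ["umis", "reads", "cdr3_nt", "v_gene", "d_gene", "j_gene", "c_gene"],
        ascending=[False, False, True, True, True, True, True],
        kind="mergesort",
    )
    best = ordered.groupby(key_cols + ["chain"], as_index=False, sort=False).head(1)

    alpha = best[best["chain"] == "TRA"].copy()
    beta = best[best["chain"] == "TRB"].copy()
    alpha["alpha_key"] = _chain_key(alpha, ALPHA_KEY_FIELDS)
    beta["beta_key"] = _chain_key(beta, BETA_KEY_FIELDS)

    paired = alpha[key_cols + ["alpha_key"]].merge(
        beta[key_cols + ["beta_key"]], on=key_cols, how="inner"
    )
    n_with_any = best[key_cols].drop_duplicates().shape[0]
    n_unpaired = n_with_any - len(paired)

    pair_keys = paired["alpha_key"] + "&" + paired["beta_key"]
    unique_pairs = pd.unique(pair_keys)
    id_map = {k: hashlib.sha1(k.encode()).hexdigest()[:16] for k in unique_pairs}
    paired["clonotype_id"] = pair_keys.map(id_map)

    out = (
        paired[key_cols + ["alpha_key", "beta_key", "clonotype_id"]]
        .sort_values(key_cols, kind="mergesort")
        .reset_index(drop=True)
    )
    out.attrs["n_orphan_contigs"] = n_orphans
    out.attrs["n_unpaired"] = int(n_unpaired)
    return out


def tabulate_frequencies(
    assignments: pd.DataFrame,
    cells: pd.DataFrame,
    t_cell_types: tuple[str, ...] = ("T",),
    denominator: str = "all_t_cells",
) -> pd.DataFrame:
    """Per-sample clonotype counts and normalized frequencies.

    ``count`` is the number of cells carrying the clonotype in that
    sample. ``normalized_freq`` divides by the sample's total number of
    annotated T cells (``denominator="all_t_cells"``, the default — T
    cells without a recovered TCR still contribute to the denominator) or
    by the number of cells with a called clonotype
    (``denominator="tcr_recovered"``).
    """
    if denominator not in ("all_t_cells", "tcr_recovered"):
        raise ValueError(f"unknown denominator rule {denominator!r}")

    counts = (
        assignments.groupby(SAMPLE_COLS + ["clonotype_id"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    if denominator == "all_t_cells":
        t_cells = cells[cells["cell_type"].isin(t_cell_types)]
        totals = t_cells.groupby(SAMPLE_COLS, as_index=False).size().rename(columns={"size": "n_t_cells"})
    else:
        totals = (
            assignments.groupby(SAMPLE_COLS, as_index=False).size().rename(columns={"size": "n_t_cells"})
        )

    freqs = counts.merge(totals, on=SAMPLE_COLS, how="left")
    bad = freqs["n_t_cells"].isna() | (freqs["n_t_cells"] == 0)
    if bad.any():
        offenders = freqs.loc[bad, SAMPLE_COLS].drop_duplicates().to_dict("records")
        raise IntegrityError(
            f"sample(s) with clonotype assignments but zero annotated T cells: {offenders}"
        )
    freqs["n_t_cells"] = freqs["n_t_cells"].astype(np.int64)
    freqs["normalized_freq"] = freqs["count"] / freqs["n_t_cells"]
    return freqs.sort_values(SAMPLE_COLS + ["clonotype_id"], kind="mergesort").reset_index(drop=True)
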