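"""Cross-compartment expression concordance: is blood a proxy for CSF?

The question: does higher expression of a gene in a patient's PBMCs (for
a given cell type) predict higher expression of that gene in the same
patient's CSF? The procedure:

1. *Pseudobulk* — collapse single-cell counts to the arithmetic mean
   count per (patient, cycle, compartment, cell type) group. Counts are
   used raw by default; an optional log1p transform is available.
2. *Filters*, applied in this order (order matters and is asserted by
   tests): (a) any group with fewer than 10 cells is dropped; (b) any
   cell type with fewer than three (patient, cycle)-matched PBMC-CSF
   sample pairs is excluded entirely — cycles present in only one
   compartment are unmatched and excluded; (c) within each retained cell
   type, genes with zero mean count in at least half of the retained
   samples (both compartments pooled) are dropped.
3. *Fit* — per gene and cell type, ordinary least squares of the CSF
   pseudobulk values on the PBMC pseudobulk values over the matched
   pairs, with a two-sided t-test on the slope. Genes whose PBMC
   predictor has zero variance are flagged untestable and excluded from
   multiple-testing correction. Benjamini-Hochberg FDR is applied
   within each cell type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_ingest import CountMatrix
from .types import CSF, PBMC, SAMPLE_COLS, IntegrityError

GROUP_COLS = SAMPLE_COLS + ["cell_type"]
PAIR_COLS = ["upn", "cycle"]


def pseudobulk(counts: CountMatrix, cells: pd.DataFrame, log1p: bool = False) -> pd.DataFrame:
    """Mean count per gene per (patient, cycle, compartment, cell type).

    Every barcode in ``counts`` must be annotated in ``cells`` (barcodes
    must be globally unique for this join); groups with zero cells are
    simply absent. Returns a long table (gene, upn, cycle, compartment,
    cell_type, mean_count, n_cells).
    """
    meta = cells.set_index("barcode")
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()][:5].tolist()
        raise IntegrityError(f"cell metadata barcodes not globally unique, e.g. {dups}")
    missing = [b for b in counts.barcodes if b not in meta.index]
    if missing:
        raise IntegrityError(
            f"{len(missing)} count-matrix barcode(s) absent from cell metadata, "
            f"e.g. {missing[:5]}"
        )
    aligned = meta.loc[counts.barcodes, GROUP_COLS].reset_index()
    groups = aligned.groupby(GROUP_COLS, sort=True)
    mat = counts.matrix.tocsc()
    if log1p:
        mat = mat.copy()
        mat.data = np.log1p(mat.data)

    records = []
    gene_arr = np.asarray(counts.genes)
    for key, idx in groups.indices.items():
        sums = np.asarray(mat[:, idx].sum(axis=1)).ravel()
        means = sums / len(idx)
        block = pd.DataFrame({"gene": gene_arr, "mean_count": means})
        for col, val in zip(GROUP_COLS, key):
            block[col] = val
        block["n_cells"] = len(idx)
        records.append(block)
    out = pd.concat(records, ignore_index=True)
    return out[["gene"] + GROUP_COLS + ["mean_count", "n_cells"]]


@dataclass
class FilterResult:
    table: pd.DataFrame  # filtered pseudobulk
    pairs: pd.DataFrame  # matched (cell_type, upn, cycle) PBMC-CSF pairs
    audit: dict = field(default_factory=dict)


def filter_for_concordance(
    pb: pd.DataFrame,
    min_cells: int = 10,
    min_pairs: int = 3,
    zero_fraction: float = 0.5,
) -> FilterResult:
    """Apply the three concordance filters (cells -> pairs -> genes).

    ``zero_fraction``: a gene is dropped within a cell type when the
    share of retained samples with zero mean count is at least this
    fraction ("at least half" by default).
    """
    audit: dict = {"n_rows_in": len(pb)}

    # (a) group cell-count floor
    pb1 = pb[pb["n_cells"] >= min_cells]
    audit["n_rows_after_cell_filter"] = len(pb1)

    # (b) matched-pair floor per cell type; unmatched groups excluded
    groups = pb1[GROUP_COLS + ["n_cells"]].drop_duplicates(GROUP_COLS)
    present = groups.pivot_table(
        index=["cell_type"] + PAIR_COLS, columns="compartment", values="n_cells", aggfunc="size"
    ).reindex(columns=[CSF, PBMC])
    has_both = present[CSF].notna() & present[PBMC].notna()
    pairs = present.index[has_both].to_frame(index=False)
    pair_counts = pairs.groupby("cell_type").size()
    kept_types = pair_counts.index[pair_counts >= min_pairs]
    pairs = pairs[pairs["cell_type"].isin(kept_types)].reset_index(drop=True)
    audit["cell_types_kept"] = sorted(kept_types)

    pb2 = pb1.merge(pairs, on=["cell_type"] + PAIR_COLS, how="inner")
    pb2 = pb2[pb2["compartment"].isin([CSF, PBMC])]
    audit["n_rows_after_pair_filter"] = len(pb2)

    # (c) half-zero gene rule within each retained cell type
    kept_blocks = []
    for ct, block in pb2.groupby("cell_type", sort=True):
        n_samples = block[GROUP_COLS].drop_duplicates().shape[0]
        zeros = block.groupby("gene")["mean_count"].apply(lambda s: (s == 0).sum())
        drop_genes = zeros.index[zeros >= zero_fraction * n_samples]
        kept_blocks.append(block[~block["gene"].isin(drop_genes)])
        audit[f"n_genes_dropped_{ct}"] = int(len(drop_genes))
    pb3 = pd.concat(kept_blocks, ignore_index=True) if kept_blocks else pb2.iloc[:0]
    audit["n_rows_out"] = len(pb3)
    return FilterResult(table=pb3.reset_index(drop=True), pairs=pairs, audit=audit)


def fit_cross_compartment(filtered: FilterResult) -> pd.DataFrame:
    """OLS of CSF pseudobulk on PBMC pseudobulk, per gene per cell type.

    Returns one row per (cell_type, gene): ``slope``, ``intercept``,
    ``p_value`` (two-sided, on the slope), ``fdr`` (BH within cell
    type), ``n_pairs``, ``untestable``.
    """
    pb, pairs = filtered.table, filtered.pairs
    rows = []
    for ct in sorted(pairs["cell_type"].unique()):
        block = pb[pb["cell_type"] == ct]
        wide = block.pivot_table(
            index="gene", columns=["compartment", "upn", "cycle"], values="mean_count"
        )
        if wide.empty:
            continue
        csf = wide[CSF]
        pbm = wide[PBMC]
        # align pair columns (upn, cycle) across the two compartments
        common = csf.columns.intersection(pbm.columns)
        csf, pbm = csf[common], pbm[common]
        n_pairs = len(common)
        for gene in wide.index:
            x = pbm.loc[gene].to_numpy(dtype=float)
            y = csf.loc[gene].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if len(x) < 3 or np.ptp(x) == 0:
                rows.append(
                    dict(cell_type=ct, gene=gene, slope=np.nan, intercept=np.nan,
                         p_value=np.nan, n_pairs=len(x), untestable=True)
                )
                continue
            fit = stats.linregress(x, y)
            rows.append(
                dict(cell_type=ct, gene=gene, slope=fit.slope, intercept=fit.intercept,
                     p_value=fit.pvalue, n_pairs=len(x), untestable=False)
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["cell_type", "gene", "slope", "intercept", "p_value", "fdr", "n_pairs", "untestable"]
        )
    out["fdr"] = np.nan
    for ct, block in out.groupby("cell_type"):
        testable = block.index[~block["untestable"]]
        if len(testable):
            out.loc[testable, "fdr"] = multipletests(
                out.loc[testable, "p_value"], method="fdr_bh"
            )[1]
    return out.reset_index(drop=True)
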