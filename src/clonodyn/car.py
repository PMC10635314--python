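"""CAR-transgene positivity calls from per-cell construct read counts.

A T cell is called CAR-positive when three or more reads support the CAR
construct (the IL13-targeting transgene, enriched by nested PCR in the
library protocol); the threshold is configurable. The wet-lab enrichment
chemistry is represented only by its outcome — a per-cell read count —
and whether that count came from the enrichment library, the gene
expression library, or their union is up to the caller.
"""

from __future__ import annotations

import logging

import pandas as pd

from .types import SAMPLE_COLS

log = logging.getLogger(__name__)

DEFAULT_CAR_READ_THRESHOLD = 3


def classify_car(
    cells: pd.DataFrame,
    threshold: int = DEFAULT_CAR_READ_THRESHOLD,
    t_cell_types: tuple[str, ...] = ("T",),
) -> pd.DataFrame:
    """Classify annotated T cells as CAR+ / CAR-.

    Non-T cells are skipped (their count is logged and reported in
    ``attrs["n_skipped_non_t"]``); every annotated T cell appears exactly
    once in the output, so downstream composition tests see a clean
    partition.
    """
    is_t = cells["cell_type"].isin(t_cell_types)
    n_skipped = int((~is_t).sum())
    if n_skipped:
        log.info("classify_car: skipped %d non-T cell(s)", n_skipped)
    calls = cells.loc[is_t, SAMPLE_COLS + ["barcode", "car_reads"]].copy()
    calls["is_car_positive"] = calls["car_reads"] >= threshold
    calls = calls.reset_index(drop=True)
    calls.attrs["n_skipped_non_t"] = n_skipped
    calls.attrs["threshold"] = threshold
    return calls


def car_fraction_by_sample(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-sample CAR+ cell fractions.

    ``n_t`` and ``n_car_pos`` are exact integers (the rational fraction
    n_car_pos / n_t is the report's ground truth); ``fraction`` is their
    floating-point quotient for convenience.
    """
    out = calls.groupby(SAMPLE_COLS, as_index=False).agg(
        n_t=("is_car_positive", "size"), n_car_pos=("is_car_positive", "sum")
    )
    out["fraction"] = out["n_car_pos"] / out["n_t"]
    return out.sort_values(SAMPLE_COLS, kind="mergesort").reset_index(drop=True)
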