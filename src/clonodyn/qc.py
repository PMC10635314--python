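"""Sample-type-specific cell quality-control filtering.

Default thresholds (per compartment) are the trial's published settings:
mitochondrial-read percentage cap 10 for every compartment, with minimum
detected-gene / total-count floors of 650/1200 for CSF and PBMC, 1300/2500
for the engineered product, and 1500/2300 for tumor. Boundary semantics
are fixed as: ``pct_mito`` strictly below the cap, ``n_genes`` and
``n_counts`` at-or-above their floors — the prevailing convention for
these cutoffs; all boundaries are overridable in config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .types import CSF, PBMC, PRODUCT, TUMOR, SAMPLE_COLS, ConfigError


@dataclass(frozen=True)
class QcThresholds:
    compartment: str
    pct_mt_max: float
    n_feature_min: int
    n_count_min: int


DEFAULT_QC_THRESHOLDS: Mapping[str, QcThresholds] = {
    CSF: QcThresholds(CSF, 10.0, 650, 1200),
    PBMC: QcThresholds(PBMC, 10.0, 650, 1200),
    PRODUCT: QcThresholds(PRODUCT, 10.0, 1300, 2500),
    TUMOR: QcThresholds(TUMOR, 10.0, 1500, 2300),
}


def apply_qc(
    cells: pd.DataFrame,
    thresholds: Mapping[str, QcThresholds] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter cells by their compartment's QC thresholds.

    A cell is kept iff ``pct_mito < pct_mt_max`` and
    ``n_genes >= n_feature_min`` and ``n_counts >= n_count_min``.

    Returns
    -------
    kept, report
        ``kept`` is the surviving subset (original row order preserved);
        ``report`` counts input/kept/dropped cells per sample, with
        ``n_input == n_kept + n_dropped`` for every sample.
    """
    if thresholds is None:
        thresholds = DEFAULT_QC_THRESHOLDS
    missing = set(cells["compartment"].unique()) - set(thresholds)
    if missing:
        raise ConfigError(f"no QC thresholds configured for compartment(s) {sorted(missing)}")

    thr = pd.DataFrame(
        [
            {
                "compartment": t.compartment,
                "pct_mt_max": t.pct_mt_max,
                "n_feature_min": t.n_feature_min,
                "n_count_min": t.n_count_min,
            }
            for t in thresholds.values()
        ]
    )
    merged = cells.merge(thr, on="compartment", how="left")
    keep = (
        (merged["pct_mito"] < merged["pct_mt_max"])
        & (merged["n_genes"] >= merged["n_feature_min"])
        & (merged["n_counts"] >= merged["n_count_min"])
    ).to_numpy()

    kept = cells.loc[keep].reset_index(drop=True)
    report = (
        cells.assign(_kept=keep)
        .groupby(SAMPLE_COLS, as_index=False)
        .agg(n_input=("_kept", "size"), n_kept=("_kept", "sum"))
    )
    report["n_dropped"] = report["n_input"] - report["n_kept"]
    return kept, report
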