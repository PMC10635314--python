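"""Clonal-expansion tiers from the pooled normalized-frequency distribution.

A clonotype-sample row is *expanded* when its cell count exceeds one AND
its normalized frequency reaches the 80th percentile of normalized
frequencies pooled across **all** samples of the study. Expanded rows are
banded further: top 20-5% of the distribution ("expanded"), top 5-1%
("more expanded"), and top 1% ("most expanded"). Rows with count = 1 are
never tiered, regardless of frequency — a single cell is no evidence of
clonal expansion however small its sample.

Numerical conventions (documented because "top X%" phrasing leaves them
open): percentile cutoffs use linear-interpolation empirical quantiles;
band membership is inclusive (``>=`` the cutoff), so ties at a cutoff
fall in the higher band. Cutoffs are computed over (clonotype, sample)
rows — frequencies are normalized per sample before pooling — and
count-1 rows are part of the pooled distribution by default (they are
observed frequencies of the study) even though they cannot be tiered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import SAMPLE_COLS, ValidationError

UNEXPANDED = "unexpanded"
EXPANDED = "expanded"
MORE_EXPANDED = "more_expanded"
MOST_EXPANDED = "most_expanded"
TIER_ORDER = [UNEXPANDED, EXPANDED, MORE_EXPANDED, MOST_EXPANDED]

DEFAULT_QUANTILES = (0.80, 0.95, 0.99)


@dataclass
class TierResult:
    """Tier assignments plus the global cutoffs that produced them."""

    table: pd.DataFrame  # frequency table + "tier" column
    cutoffs: tuple[float, float, float]
    quantiles: tuple[float, float, float]


def assign_tiers(
    freqs: pd.DataFrame,
    quantiles: tuple[float, float, float] = DEFAULT_QUANTILES,
    pool_singletons: bool = True,
    cutoffs: tuple[float, float, float] | None = None,
) -> TierResult:
    """Assign expansion tiers to every (clonotype, sample) row.

    Parameters
    ----------
    freqs
        Frequency table from :func:`clonodyn.clonotype.tabulate_frequencies`.
    quantiles
        The three pooled quantiles defining the bands (default 0.80,
        0.95, 0.99, i.e. top 20/5/1%). Must be non-decreasing.
    pool_singletons
        Whether count-1 rows enter the pooled distribution used for the
        cutoffs (they can never be tiered either way).
    cutoffs
        Pre-computed cutoff values; when given, quantile computation is
        skipped and these are reused (e.g. to re-tier a subset under the
        original study-wide thresholds).
    """
    if freqs.empty:
        raise ValidationError("cannot assign tiers on an empty frequency table")
    if list(quantiles) != sorted(quantiles):
        raise ValidationError(f"quantiles must be non-decreasing, got {quantiles}")

    if cutoffs is None:
        pool = freqs["normalized_freq"]
        if not pool_singletons:
            pool = pool[freqs["count"] > 1]
        if pool.empty:  # all-singleton study with singletons excluded
            cutoffs = (np.inf, np.inf, np.inf)
        else:
            cutoffs = tuple(np.quantile(pool.to_numpy(), quantiles))
    c80, c95, c99 = cutoffs

    nf = freqs["normalized_freq"].to_numpy()
    eligible = freqs["count"].to_numpy() > 1
    tier = np.select(
        [eligible & (nf >= c99), eligible & (nf >= c95), eligible & (nf >= c80)],
        [MOST_EXPANDED, MORE_EXPANDED, EXPANDED],
        default=UNEXPANDED,
    )
    table = freqs.copy()
    table["tier"] = pd.Categorical(tier, categories=TIER_ORDER, ordered=True)
    return TierResult(table=table, cutoffs=(float(c80), float(c95), float(c99)), quantiles=tuple(quantiles))


def expansion_trajectory(
    tiers: TierResult | pd.DataFrame,
    cells: pd.DataFrame,
    assignments: pd.DataFrame,
    t_cell_types: tuple[str, ...] = ("T",),
) -> pd.DataFrame:
    """Per-sample proportion of T cells carrying a clonotype of each tier.

    Denominator: all annotated T cells in the sample; T cells without a
    called clonotype contribute to the denominator only. One row per
    sample with one proportion column per tier (``prop_<tier>``) plus
    ``n_t_cells``; proportions over the listed tiers sum to at most 1.
    """
    table = tiers.table if isinstance(tiers, TierResult) else tiers
    t_cells = cells[cells["cell_type"].isin(t_cell_types)]
    totals = t_cells.groupby(SAMPLE_COLS, as_index=False).size().rename(columns={"size": "n_t_cells"})

    per_cell = assignments.merge(
        table[SAMPLE_COLS + ["clonotype_id", "tier"]],
        on=SAMPLE_COLS + ["clonotype_id"],
        how="inner",
    )
    tier_counts = (
        per_cell.groupby(SAMPLE_COLS + ["tier"], as_index=False, observed=False)
        .size()
        .pivot_table(index=SAMPLE_COLS, columns="tier", values="size", fill_value=0, observed=False)
        .reindex(columns=TIER_ORDER, fill_value=0)
    )
    tier_counts.columns = [f"n_{t}" for t in tier_counts.columns]
    out = totals.merge(tier_counts.reset_index(), on=SAMPLE_COLS, how="left").fillna(0)
    for t in TIER_ORDER:
        out[f"n_{t}"] = out[f"n_{t}"].astype(int)
        out[f"prop_{t}"] = out[f"n_{t}"] / out["n_t_cells"]
    return out.sort_values(SAMPLE_COLS, kind="mergesort").reset_index(drop=True)
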