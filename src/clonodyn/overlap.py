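"""Cross-compartment clonotype sharing and tumor enrichment.

Upset-style membership analysis: for one patient, each clonotype is
scored for membership in five named sets — expanded in CSF (non-baseline
tier in *any* CSF sample of that patient), unexpanded in CSF (observed
in CSF but never expanded), and observed in PBMC, product, or tumor.
The two CSF sets are disjoint by construction. Overlaps are computed
within patient only; the strict clonotype key makes ids comparable
across compartments.

Tumor enrichment asks whether CSF-expanded clonotypes reach the tumor
more often than CSF-unexpanded ones: a 2x2 table (expanded/unexpanded x
in-tumor/not-in-tumor), its odds ratio (Haldane-Anscombe 0.5 correction
when any cell is zero; defined as 1 when the tumor column is entirely
empty or entirely full, which carries no information either way), a
two-sided Fisher exact p-value, and a Woolf logit confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .types import CSF, PBMC, PRODUCT, TUMOR, ValidationError
from .expansion import UNEXPANDED, TierResult

SET_NAMES = ["CSF_expanded", "CSF_unexpanded", "PBMC", "PRODUCT", "TUMOR"]


@dataclass
class MembershipMatrix:
    upn: str
    matrix: pd.DataFrame  # bool, index clonotype_id, columns SET_NAMES


def build_membership(
    tiers: TierResult | pd.DataFrame, freqs: pd.DataFrame, upn: str
) -> MembershipMatrix:
    """Score every clonotype of one patient for compartment membership.

    ``freqs`` supplies presence (a clonotype is "in" a compartment iff it
    has a frequency row there for this patient); ``tiers`` supplies the
    expansion calls. Expansion aggregates over cycles by an any-cycle
    rule: one expanded CSF sample suffices.
    """
    table = tiers.table if isinstance(tiers, TierResult) else tiers
    f = freqs[freqs["upn"] == upn]
    t = table[table["upn"] == upn]

    def present(compartment: str) -> set:
        return set(f.loc[f["compartment"] == compartment, "clonotype_id"])

    csf_all = present(CSF)
    expanded = set(
        t.loc[(t["compartment"] == CSF) & (t["tier"].astype(str) != UNEXPANDED), "clonotype_id"]
    )
    csf_expanded = expanded & csf_all
    sets = {
        "CSF_expanded": csf_expanded,
        "CSF_unexpanded": csf_all - csf_expanded,
        "PBMC": present(PBMC),
        "PRODUCT": present(PRODUCT),
        "TUMOR": present(TUMOR),
    }
    universe = sorted(set().union(*sets.values()))
    matrix = pd.DataFrame(
        {name: [cid in members for cid in universe] for name, members in sets.items()},
        index=pd.Index(universe, name="clonotype_id"),
    )[SET_NAMES]
    return MembershipMatrix(upn=upn, matrix=matrix)


def intersection_counts(membership: MembershipMatrix) -> pd.DataFrame:
    """Exact count of clonotypes for every observed set combination."""
    m = membership.matrix
    out = m.groupby(SET_NAMES).size().rename("count").reset_index()
    return out.sort_values("count", ascending=False, kind="mergesort").reset_index(drop=True)


@dataclass
class EnrichmentResult:
    table: np.ndarray  # 2x2: [[exp&tumor, exp&~tumor], [unexp&tumor, unexp&~tumor]]
    odds_ratio: float
    p_value: float
    ci_low: float
    ci_high: float
    proportions: tuple[Fraction, Fraction]  # tumor-overlap share of (expanded, unexpanded)


def enrichment_from_table(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """Odds ratio, Fisher exact p and Woolf CI for a 2x2 overlap table.

    ``a``/``b``: CSF-expanded clonotypes in / not in tumor; ``c``/``d``:
    CSF-unexpanded in / not in tumor.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (a + b) == 0 and (c + d) == 0:
        raise ValidationError("both CSF strata are empty; enrichment undefined")
    p_value = float(stats.fisher_exact(table, alternative="two-sided")[1])
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        # a fully empty (or fully saturated) tumor column is uninformative
        odds_ratio, ci_low, ci_high = 1.0, np.nan, np.nan
    else:
        cells = table.astype(float)
        if (cells == 0).any():
            cells = cells + 0.5  # Haldane-Anscombe
        odds_ratio = float(cells[0, 0] * cells[1, 1] / (cells[0, 1] * cells[1, 0]))
        se = float(np.sqrt((1.0 / cells).sum()))
        ci_low = float(np.exp(np.log(odds_ratio) - 1.96 * se))
        ci_high = float(np.exp(np.log(odds_ratio) + 1.96 * se))
    props = (
        Fraction(int(a), int(a + b)) if (a + b) else Fraction(0),
        Fraction(int(c), int(c + d)) if (c + d) else Fraction(0),
    )
    return EnrichmentResult(
        table=table, odds_ratio=odds_ratio, p_value=p_value,
        ci_low=ci_low, ci_high=ci_high, proportions=props,
    )


def tumor_enrichment(membership: MembershipMatrix) -> EnrichmentResult:
    """Enrichment of CSF-expanded vs CSF-unexpanded clonotypes in tumor."""
    m = membership.matrix
    exp = m["CSF_expanded"]
    unexp = m["CSF_unexpanded"]
    tum = m["TUMOR"]
    a = int((exp & tum).sum())
    b = int((exp & ~tum).sum())
    c = int((unexp & tum).sum())
    d = int((unexp & ~tum).sum())
    return enrichment_from_table(a, b, c, d)
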