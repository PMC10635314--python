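import math
from fractions import Fraction
from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonodyn import clonotype, expansion, overlap
from clonodyn.types import CSF, PBMC, PRODUCT, TUMOR, ValidationError


def _freqs(rows):
    return pd.DataFrame(
        [
            dict(upn=u, cycle=cy, compartment=co, clonotype_id=cid, count=n,
                 n_t_cells=100, normalized_freq=n / 100)
            for (u, cy, co, cid, n) in rows
        ]
    )


def toy_membership():
    freqs = _freqs(
        [
            ("U1", 1, CSF, "expA", 30),
            ("U1", 1, CSF, "soloB", 1),
            ("U1", 1, CSF, "soloC", 1),
            ("U1", 1, PBMC, "expA", 2),
            ("U1", 0, PRODUCT, "prodD", 10),
            ("U1", 3, TUMOR, "expA", 4),
            ("U1", 3, TUMOR, "soloC", 1),
            ("U1", 3, TUMOR, "tumE", 5),
        ]
    )
    tiers = expansion.assign_tiers(freqs)
    return overlap.build_membership(tiers, freqs, "U1"), freqs


def test_membership_sets_and_disjointness():
    m, _ = toy_membership()
    mat = m.matrix
    assert mat.loc["expA"].to_dict() == {
        "CSF_expanded": True, "CSF_unexpanded": False, "PBMC": True,
        "PRODUCT": False, "TUMOR": True,
    }
    assert mat.loc["soloC", "CSF_unexpanded"] and mat.loc["soloC", "TUMOR"]
    assert mat.loc["tumE", ["CSF_expanded", "CSF_unexpanded", "PBMC", "PRODUCT"]].sum() == 0
    # CSF_expanded and CSF_unexpanded are disjoint
    assert not (mat["CSF_expanded"] & mat["CSF_unexpanded"]).any()


def test_intersection_counts_match_brute_force():
    m, _ = toy_membership()
    counts = overlap.intersection_counts(m)
    # nested-loop recount over every possible set combination
    for combo in product([False, True], repeat=len(overlap.SET_NAMES)):
        expected = sum(
            1 for _, row in m.matrix.iterrows() if tuple(row[overlap.SET_NAMES]) == combo
        )
        block = counts
        for name, val in zip(overlap.SET_NAMES, combo):
            block = block[block[name] == val]
        got = int(block["count"].sum()) if len(block) else 0
        assert got == expected
    assert counts["count"].sum() == len(m.matrix)


def test_empty_tumor_is_valid():
    freqs = _freqs([("U1", 1, CSF, "a", 5), ("U1", 1, CSF, "b", 1)])
    tiers = expansion.assign_tiers(freqs)
    m = overlap.build_membership(tiers, freqs, "U1")
    assert not m.matrix["TUMOR"].any()
    counts = overlap.intersection_counts(m)
    assert counts[counts["TUMOR"]].empty


def test_generated_product_pool_disjoint_from_expanded_csf(small_trial):
    """The generator builds the infused product from a separate clone
    pool, so CSF-expanded clonotypes never appear in the product."""
    a = clonotype.call_clonotypes(small_trial.contigs, small_trial.cells)
    freqs = clonotype.tabulate_frequencies(a, small_trial.cells)
    tiers = expansion.assign_tiers(freqs)
    for upn in ("UPN01", "UPN02"):
        m = overlap.build_membership(tiers, freqs, upn)
        assert not (m.matrix["CSF_expanded"] & m.matrix["PRODUCT"]).any()


class TestEnrichment:
    def test_reported_margins_odds_ratio_and_fisher_p(self):
        """On the trial's published 2x2 margins (11 of 69 expanded vs 12
        of 6128 unexpanded CSF clonotypes found in tumor) the odds ratio
        follows the closed form and the p-value matches a direct
        hypergeometric-tail oracle."""
        res = overlap.enrichment_from_table(11, 58, 12, 6116)
        assert res.odds_ratio == pytest.approx((11 * 6116) / (58 * 12), rel=1e-12)
        assert res.proportions == (Fraction(11, 69), Fraction(12, 6128))
        assert res.p_value < 1e-3

        # two-sided Fisher oracle: sum hypergeometric pmfs <= pmf(observed)
        n, k1, k2 = 11 + 58 + 12 + 6116, 11 + 58, 11 + 12
        pmf = [stats.hypergeom.pmf(x, n, k1, k2) for x in range(k2 + 1)]
        obs = pmf[11]
        oracle = sum(p for p in pmf if p <= obs * (1 + 1e-9))
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_zero_tumor_column_is_uninformative(self):
        res = overlap.enrichment_from_table(0, 30, 0, 500)
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0

    def test_haldane_correction_applied_on_single_zero(self):
        res = overlap.enrichment_from_table(5, 0, 3, 40)
        expected = (5.5 * 40.5) / (0.5 * 3.5)
        assert res.odds_ratio == pytest.approx(expected)
        assert math.isfinite(res.ci_low) and math.isfinite(res.ci_high)

    def test_both_strata_empty_is_error(self):
        with pytest.raises(ValidationError):
            overlap.enrichment_from_table(0, 0, 0, 0)

    def test_margins_conserved_from_membership(self):
        m, _ = toy_membership()
        res = overlap.tumor_enrichment(m)
        assert res.table.sum() == int(
            (m.matrix["CSF_expanded"] | m.matrix["CSF_unexpanded"]).sum()
        )
        assert res.table[0].sum() == int(m.matrix["CSF_expanded"].sum())
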