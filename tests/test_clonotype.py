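import numpy as np
import pandas as pd
import pytest

from clonodyn import clonotype, validation
from clonodyn.types import IntegrityError

from conftest import cells_frame, contigs_frame


def _paired(barcode, a_cdr3="TGTGCAGCC", b_cdr3="TGCGCAGCA", **kw):
    return [
        dict(barcode=barcode, chain="TRA", cdr3_nt=a_cdr3, **kw),
        dict(barcode=barcode, chain="TRB", v_gene="TRBV2", d_gene="TRBD1",
             j_gene="TRBJ1", c_gene="TRBC1", cdr3_nt=b_cdr3, **kw),
    ]


def test_pairing_requirement():
    """A clonotype needs a productive cell-associated TRA and TRB."""
    contigs = contigs_frame(
        _paired("both")
        + [dict(barcode="beta_only", chain="TRB", v_gene="TRBV2", d_gene="TRBD1",
                j_gene="TRBJ1", c_gene="TRBC1", cdr3_nt="TGCAAA")]
        + _paired("nonprod", productive=False)
        + _paired("ambient", is_cell=False)
    )
    cells = cells_frame([dict(barcode=b) for b in ["both", "beta_only", "nonprod", "ambient"]])
    out = clonotype.call_clonotypes(contigs, cells)
    assert out["barcode"].tolist() == ["both"]
    assert out.attrs["n_unpaired"] == 1  # beta_only had a usable chain but no pair


def test_multi_contig_selection_prefers_top_umis_then_reads():
    contigs = contigs_frame(
        [
            dict(barcode="B", chain="TRA", cdr3_nt="TGTAAAAAA", umis=3, reads=900),
            dict(barcode="B", chain="TRA", cdr3_nt="TGTCCCCCC", umis=7, reads=10),
            dict(barcode="B", chain="TRB", v_gene="TRBV2", d_gene="TRBD1",
                 j_gene="TRBJ1", c_gene="TRBC1", cdr3_nt="TGCGCAGCA"),
            # tie on umis broken by reads
            dict(barcode="C", chain="TRA", cdr3_nt="TGTGGGGGG", umis=5, reads=10),
            dict(barcode="C", chain="TRA", cdr3_nt="TGTTTTTTT", umis=5, reads=90),
            dict(barcode="C", chain="TRB", v_gene="TRBV2", d_gene="TRBD1",
                 j_gene="TRBJ1", c_gene="TRBC1", cdr3_nt="TGCGCAGCA"),
        ]
    )
    cells = cells_frame([dict(barcode="B"), dict(barcode="C")])
    out = clonotype.call_clonotypes(contigs, cells).set_index("barcode")
    assert "TGTCCCCCC" in out.loc["B", "alpha_key"]
    assert "TGTTTTTTT" in out.loc["C", "alpha_key"]


def test_strict_key_distinguishes_synonymous_substitution():
    """Same gene segments, one synonymous CDR3nt substitution => distinct
    clonotypes; identical keys => identical id."""
    contigs = contigs_frame(
        _paired("b1", a_cdr3="TGTGCAGCC")
        + _paired("b2", a_cdr3="TGTGCAGCC")
        + _paired("b3", a_cdr3="TGTGCAGCG")  # synonymous A>G change
    )
    cells = cells_frame([dict(barcode=b) for b in ["b1", "b2", "b3"]])
    out = clonotype.call_clonotypes(contigs, cells).set_index("barcode")
    assert out.loc["b1", "clonotype_id"] == out.loc["b2", "clonotype_id"]
    assert out.loc["b1", "clonotype_id"] != out.loc["b3", "clonotype_id"]


def test_orphan_contigs_skipped_with_count():
    contigs = contigs_frame(_paired("known") + _paired("unknown"))
    cells = cells_frame([dict(barcode="known")])
    out = clonotype.call_clonotypes(contigs, cells)
    assert out["barcode"].tolist() == ["known"]
    assert out.attrs["n_orphan_contigs"] == 2


def test_row_order_permutation_invariance():
    rng = np.random.default_rng(3)
    contigs, cells = validation.random_toy_repertoire(rng, max_cells=40)
    a = clonotype.call_clonotypes(contigs, cells)
    shuffled = contigs.sample(frac=1.0, random_state=9).reset_index(drop=True)
    b = clonotype.call_clonotypes(shuffled, cells)
    pd.testing.assert_frame_equal(a, b)


def test_partition_matches_string_equality_oracle():
    res = validation.clonotype_oracle_trial(n_repertoires=100, seed=5)
    assert res["agreement"] == 1.0
    assert res["pairing_violations"] == 0


class TestFrequencies:
    def _trial(self, n_cells, clone_sizes):
        """n_cells T cells; the first clones cover `clone_sizes` cells."""
        rows, cell_rows = [], []
        i = 0
        for ci, size in enumerate(clone_sizes):
            for _ in range(size):
                rows += _paired(f"B{i}", a_cdr3="TGT" + "GCA" * (ci + 1))
                cell_rows.append(dict(barcode=f"B{i}"))
                i += 1
        while i < n_cells:  # T cells without recovered TCR
            cell_rows.append(dict(barcode=f"B{i}"))
            i += 1
        return contigs_frame(rows), cells_frame(cell_rows)

    def test_normalized_by_all_annotated_t_cells(self):
        contigs, cells = self._trial(10, [2])
        out = clonotype.call_clonotypes(contigs, cells)
        freqs = clonotype.tabulate_frequencies(out, cells)
        assert freqs["count"].tolist() == [2]
        assert freqs["normalized_freq"].tolist() == [0.2]

    def test_tcr_recovered_denominator_switch(self):
        contigs, cells = self._trial(10, [2, 2])
        out = clonotype.call_clonotypes(contigs, cells)
        freqs = clonotype.tabulate_frequencies(out, cells, denominator="tcr_recovered")
        assert freqs["normalized_freq"].tolist() == [0.5, 0.5]

    def test_all_unique_clonotypes(self):
        contigs, cells = self._trial(5, [1] * 5)
        out = clonotype.call_clonotypes(contigs, cells)
        freqs = clonotype.tabulate_frequencies(out, cells)
        assert freqs["count"].tolist() == [1] * 5
        assert np.allclose(freqs["normalized_freq"], 0.2)

    def test_conservation_of_counts(self, small_trial):
        out = clonotype.call_clonotypes(small_trial.contigs, small_trial.cells)
        freqs = clonotype.tabulate_frequencies(out, small_trial.cells)
        per_sample_counts = freqs.groupby(["upn", "cycle", "compartment"])["count"].sum()
        per_sample_assigned = out.groupby(["upn", "cycle", "compartment"]).size()
        pd.testing.assert_series_equal(
            per_sample_counts, per_sample_assigned, check_names=False
        )

    def test_zero_t_cell_sample_with_assignment_is_integrity_error(self):
        contigs, cells = self._trial(2, [2])
        out = clonotype.call_clonotypes(contigs, cells)
        cells["cell_type"] = "NK"  # nobody annotated as T
        with pytest.raises(IntegrityError):
            clonotype.tabulate_frequencies(out, cells)
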