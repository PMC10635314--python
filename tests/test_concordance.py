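import numpy as np
import pandas as pd
import pytest

from clonodyn import concordance
from clonodyn.io_ingest import CountMatrix
from clonodyn.types import CSF, PBMC, IntegrityError

from conftest import cells_frame


def _pb_row(gene, upn, cycle, compartment, cell_type, mean_count, n_cells):
    return dict(gene=gene, upn=upn, cycle=cycle, compartment=compartment,
                cell_type=cell_type, mean_count=mean_count, n_cells=n_cells)


def test_pseudobulk_means_match_hand_computation():
    genes = ["g1", "g2"]
    barcodes = ["a", "b", "c"]
    mat = np.array([[4, 6, 1], [0, 0, 9]])
    counts = CountMatrix(genes=genes, barcodes=barcodes, matrix=mat)
    cells = cells_frame(
        [
            dict(barcode="a"), dict(barcode="b"),
            dict(barcode="c", compartment=PBMC),
        ]
    )
    pb = concordance.pseudobulk(counts, cells).set_index(["gene", "compartment"])
    assert pb.loc[("g1", CSF), "mean_count"] == pytest.approx(5.0)
    assert pb.loc[("g1", CSF), "n_cells"] == 2
    assert pb.loc[("g2", CSF), "mean_count"] == 0.0
    assert pb.loc[("g2", PBMC), "mean_count"] == pytest.approx(9.0)


def test_pseudobulk_unknown_barcode_is_error():
    counts = CountMatrix(genes=["g"], barcodes=["a", "mystery"], matrix=np.ones((1, 2)))
    cells = cells_frame([dict(barcode="a")])
    with pytest.raises(IntegrityError, match="mystery"):
        concordance.pseudobulk(counts, cells)


class TestFilters:
    def _pb(self, pairs, n_cells_csf=20, gene_values=None):
        """Build a pseudobulk table with `pairs` matched (upn, cycle)
        groups for one cell type, one gene unless gene_values given."""
        rows = []
        genes = gene_values or {"g0": None}
        for gene, vals in genes.items():
            for i, (u, c) in enumerate(pairs):
                v = 1.0 if vals is None else vals[i]
                rows.append(_pb_row(gene, u, c, CSF, "T", v, n_cells_csf))
                rows.append(_pb_row(gene, u, c, PBMC, "T", v, 20))
        return pd.DataFrame(rows)

    def test_cell_floor_boundary(self):
        pairs = [("U1", 1), ("U1", 2), ("U2", 1), ("U2", 2)]
        pb9 = self._pb(pairs, n_cells_csf=9)
        pb10 = self._pb(pairs, n_cells_csf=10)
        assert concordance.filter_for_concordance(pb9).table.empty  # CSF side all dropped
        assert not concordance.filter_for_concordance(pb10).table.empty

    def test_pair_floor_excludes_cell_type(self):
        pb = self._pb([("U1", 1), ("U1", 2)])  # only two matched pairs
        res = concordance.filter_for_concordance(pb)
        assert res.table.empty
        assert res.pairs.empty

    def test_unmatched_cycles_are_excluded(self):
        pairs = [("U1", 1), ("U1", 2), ("U2", 1)]
        pb = self._pb(pairs)
        # a CSF-only cycle: present in one compartment, must not count
        pb = pd.concat([pb, pd.DataFrame([_pb_row("g0", "U2", 9, CSF, "T", 1.0, 20)])])
        res = concordance.filter_for_concordance(pb)
        assert len(res.pairs) == 3
        assert (res.table["cycle"] != 9).all()

    def test_half_zero_gene_rule(self):
        """A gene at zero in 4 of 8 retained samples (half) is dropped;
        3 of 8 survives."""
        pairs = [("U1", 1), ("U1", 2), ("U2", 1), ("U2", 2)]  # 8 samples
        gene_values = {
            "dropped": [0, 0, 1, 1],   # zero in both compartments => 4 zero samples
            "kept": [0, 1, 1, 1],      # CSF+PBMC zero in pair 0 => wait: both rows share v
        }
        # build manually for asymmetric compartment values
        rows = []
        for gene, csf_vals, pb_vals in [
            ("dropped", [0, 0, 1, 1], [0, 0, 2, 2]),  # 4 of 8 zero
            ("kept", [0, 1, 1, 1], [0, 2, 2, 2]),     # 2 of 8 zero
        ]:
            for i, (u, c) in enumerate(pairs):
                rows.append(_pb_row(gene, u, c, CSF, "T", csf_vals[i], 20))
                rows.append(_pb_row(gene, u, c, PBMC, "T", pb_vals[i], 20))
        res = concordance.filter_for_concordance(pd.DataFrame(rows))
        assert set(res.table["gene"]) == {"kept"}

    def test_survivor_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        rows = []
        for gene in [f"g{i}" for i in range(8)]:
            for u in ["U1", "U2", "U3"]:
                for c in [1, 2]:
                    for comp in (CSF, PBMC):
                        rows.append(
                            _pb_row(gene, u, c, comp,
                                    "T", float(rng.integers(0, 3)),
                                    int(rng.integers(5, 30)))
                        )
        pb = pd.DataFrame(rows)
        res = concordance.filter_for_concordance(pb)

        # independent brute-force recount
        ok = pb[pb.n_cells >= 10]
        groups = ok[["upn", "cycle", "compartment"]].drop_duplicates()
        matched = []
        for (u, c), blk in groups.groupby(["upn", "cycle"]):
            if {CSF, PBMC} <= set(blk["compartment"]):
                matched.append((u, c))
        if len(matched) < 3:
            assert res.table.empty
            return
        retained = ok[ok[["upn", "cycle"]].apply(tuple, axis=1).isin(matched)]
        n_samples = retained[["upn", "cycle", "compartment"]].drop_duplicates().shape[0]
        survivors = set()
        for gene, blk in retained.groupby("gene"):
            if (blk["mean_count"] == 0).sum() < 0.5 * n_samples:
                survivors.add(gene)
        assert set(res.table["gene"]) == survivors


class TestFit:
    def _matched_pb(self, x_by_pair, y_fn, gene="g", cell_type="T"):
        rows = []
        for i, ((u, c), x) in enumerate(x_by_pair.items()):
            rows.append(_pb_row(gene, u, c, PBMC, cell_type, x, 20))
            rows.append(_pb_row(gene, u, c, CSF, cell_type, y_fn(x, i), 20))
        pb = pd.DataFrame(rows)
        return concordance.filter_for_concordance(pb, zero_fraction=1.01)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(1)
        pairs = {(f"U{i}", c): float(rng.uniform(1, 10)) for i in range(5) for c in (1, 2)}
        filtered = self._matched_pb(pairs, lambda x, i: 2.0 * x + rng.normal(0, 0.05))
        fits = concordance.fit_cross_compartment(filtered)
        row = fits.iloc[0]
        assert row["slope"] == pytest.approx(2.0, abs=0.1)
        assert row["fdr"] < 0.05
        assert row["n_pairs"] == 10

    def test_three_collinear_pairs(self):
        filtered = self._matched_pb({("U1", 1): 1.0, ("U2", 1): 2.0, ("U3", 1): 3.0},
                                    lambda x, i: 3.0 * x + 1.0)
        fits = concordance.fit_cross_compartment(filtered)
        row = fits.iloc[0]
        assert row["slope"] == pytest.approx(3.0, abs=1e-9)
        assert row["n_pairs"] == 3
        assert row["p_value"] < 1e-6  # machine floor for an exact fit

    def test_zero_variance_predictor_flagged_untestable(self):
        filtered = self._matched_pb(
            {("U1", 1): 2.0, ("U2", 1): 2.0, ("U3", 1): 2.0}, lambda x, i: float(i)
        )
        fits = concordance.fit_cross_compartment(filtered)
        assert bool(fits.iloc[0]["untestable"])
        assert np.isnan(fits.iloc[0]["fdr"])


def test_filter_order_matters():
    """Running the gene zero-rule before the pair filter would judge
    zero-shares against unmatched samples too — and can keep a gene the
    fixed order drops. This documents why the order matters."""
    pairs = [("U1", 1), ("U1", 2), ("U2", 1)]
    rows = []
    for i, (u, c) in enumerate(pairs):
        rows.append(_pb_row("g", u, c, CSF, "T", [0, 0, 1][i], 20))
        rows.append(_pb_row("g", u, c, PBMC, "T", [0, 1, 1][i], 20))
    # three extra unmatched PBMC-only samples, all expressing the gene
    for c in (7, 8, 9):
        rows.append(_pb_row("g", "U9", c, PBMC, "T", 5.0, 20))
    pb = pd.DataFrame(rows)

    res = concordance.filter_for_concordance(pb)
    assert res.table.empty  # 3/6 zeros among matched samples: dropped

    # gene rule applied first (against all 9 samples): 3/9 zeros, gene kept
    n_all = pb[["upn", "cycle", "compartment"]].drop_duplicates().shape[0]
    zeros = (pb["mean_count"] == 0).sum()
    assert zeros < 0.5 * n_all  # the reordered filter would have kept it
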