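import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonodyn import clonotype, io_ingest, simulate
from clonodyn.simulate import GeneratorConfig, generate_trial, read_bundle, write_bundle
from clonodyn.types import CSF, TUMOR, ValidationError

from conftest import small_config


def test_fixed_seed_reproduces_outputs_exactly(small_trial):
    again = generate_trial(small_config())
    pd.testing.assert_frame_equal(small_trial.cells, again.cells)
    pd.testing.assert_frame_equal(small_trial.contigs, again.contigs)
    assert (small_trial.counts.matrix != again.counts.matrix).nnz == 0


@pytest.mark.parametrize(
    "overrides",
    [
        dict(planted_initial_freq=0.05, n_planted_expanders=10, growth_factor=3.0),
        dict(growth_factor=0.5),
        dict(car_neg_read_probs=(0.5, 0.2, 0.2)),
        dict(car_pos_schedule_csf=(0.4,)),
        dict(chain_dropout=1.5),
    ],
)
def test_infeasible_configs_rejected(overrides):
    with pytest.raises(ValidationError):
        generate_trial(small_config(**overrides))


def test_bundle_roundtrip_through_ingest(small_trial, tmp_path):
    """write_bundle emits the formats the ingest layer reads; record
    counts and content survive the round trip."""
    manifest_path = write_bundle(small_trial, tmp_path / "bundle")
    contigs, cells, counts, manifest = read_bundle(tmp_path / "bundle")
    assert len(cells) == len(small_trial.cells)
    assert len(contigs) == len(small_trial.contigs)
    assert counts.shape == small_trial.counts.shape
    assert (counts.matrix != small_trial.counts.matrix).nnz == 0
    assert manifest["config_hash"] == small_trial.config.hash()
    # clonotype calls identical from disk and from memory
    a = clonotype.call_clonotypes(small_trial.contigs, small_trial.cells)
    b = clonotype.call_clonotypes(
        contigs.sort_values(list(contigs.columns)).reset_index(drop=True), cells
    )
    pd.testing.assert_frame_equal(a, b)


def test_bundle_refuses_nonempty_dir(small_trial, tmp_path):
    write_bundle(small_trial, tmp_path / "b")
    with pytest.raises(ValidationError):
        write_bundle(small_trial, tmp_path / "b")
    write_bundle(small_trial, tmp_path / "b", force=True)  # ok


def test_config_hash_changes_iff_config_changes():
    a, b = small_config(), small_config()
    assert a.hash() == b.hash()
    assert small_config(seed=43).hash() != a.hash()
    assert small_config(growth_factor=1.5).hash() != a.hash()


def test_heavy_tail_clone_size_distribution():
    """Under the default config the top 1% of clones hold at least 10% of
    TCR-assigned cells (pooled over the study)."""
    trial = generate_trial(GeneratorConfig(seed=7))
    a = clonotype.call_clonotypes(trial.contigs, trial.cells)
    sizes = a.groupby("clonotype_id").size().sort_values(ascending=False)
    k = max(1, int(np.ceil(0.01 * len(sizes))))
    assert sizes.head(k).sum() / sizes.sum() >= 0.10


def test_growth_factor_one_shows_no_trend():
    """With growth 1.0 the planted clones' CSF frequency has no slope
    across cycles (pooled over replicates, CI covers 0)."""
    slopes = []
    for i in range(12):
        trial = generate_trial(small_config(seed=100 + i, growth_factor=1.0))
        a = clonotype.call_clonotypes(trial.contigs, trial.cells)
        freqs = clonotype.tabulate_frequencies(a, trial.cells)
        planted = {cid for ids in trial.truth.planted_expanders.values() for cid in ids}
        block = freqs[(freqs["compartment"] == CSF) & freqs["clonotype_id"].isin(planted)]
        per_cycle = block.groupby("cycle")["normalized_freq"].sum()
        slopes.append(stats.linregress(per_cycle.index, per_cycle.values).slope)
    slopes = np.asarray(slopes)
    sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
    assert abs(slopes.mean()) <= 3 * sem + 1e-9


def test_car_read_supports(small_trial):
    t = small_trial.cells[small_trial.cells["cell_type"] == "T"]
    truth = small_trial.truth.true_car.set_index("barcode")
    merged = t.join(truth, on="barcode")
    neg = merged[~merged["is_car_positive"]]
    pos = merged[merged["is_car_positive"]]
    assert set(neg["car_reads"].unique()) <= {0, 1, 2}
    assert (pos["car_reads"] >= 3).all()


def test_tumor_seeded_clones_appear_only_after_csf_observation(small_trial):
    seeding = small_trial.truth.tumor_seeding["UPN01"]
    assert (~seeding["seeded"] | seeding["observed_in_csf"]).all()
    # expanded stratum covers the planted set plus realized-expanded clones
    planted = set(small_trial.truth.planted_expanders["UPN01"])
    expanded = set(seeding.loc[seeding["stratum"] == "expanded", "clonotype_id"])
    assert planted <= expanded


def test_chain_dropout_produces_unpaired_cells(small_trial):
    a = clonotype.call_clonotypes(small_trial.contigs, small_trial.cells)
    assert a.attrs["n_unpaired"] > 0  # the pairing filter is exercised
    n_t = (small_trial.cells["cell_type"] == "T").sum()
    assert len(a) < n_t
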