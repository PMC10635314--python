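import numpy as np
import pandas as pd
import pytest

from clonodyn import proportions, validation
from clonodyn.types import ValidationError


def labels_from_counts(counts: dict) -> pd.DataFrame:
    """counts: {(cluster, condition): n}."""
    rows = []
    for (cl, cond), n in counts.items():
        rows += [{"cluster": cl, "condition": cond}] * n
    return pd.DataFrame(rows)


def test_observed_log2fd_matches_closed_form():
    """Proportions 0.2 vs 0.3 give log2(1.5) ~ 0.585, just over the 0.58
    significance threshold."""
    labels = labels_from_counts(
        {("k", "A"): 20, ("o", "A"): 80, ("k", "B"): 30, ("o", "B"): 70}
    )
    res = proportions.permutation_proportion_test(labels, n_bootstrap=0, seed=0)
    obs = res.set_index("cluster").loc["k", "obs_log2fd"]
    assert obs == pytest.approx(np.log2(1.5), abs=1e-12)
    called = proportions.significance_call(res, fd_threshold=0.58)
    assert abs(obs) > 0.58  # the boundary case the threshold was printed for


@pytest.mark.parametrize("counts", [
    {("x", "A"): 2, ("x", "B"): 1, ("y", "A"): 1, ("y", "B"): 2},
    {("x", "A"): 3, ("y", "A"): 1, ("x", "B"): 1, ("y", "B"): 3},
    {("x", "A"): 2, ("y", "A"): 3, ("x", "B"): 4, ("y", "B"): 1},
])
def test_exact_enumeration_equals_brute_force_oracle(counts):
    labels = labels_from_counts(counts)
    res = proportions.permutation_proportion_test(labels, method="exact", n_bootstrap=0)
    oracle = validation.oracle_exact_permutation_p(labels, ("A", "B"))
    assert np.allclose(res["p_perm"].to_numpy(), oracle, atol=1e-12)


def test_identical_composition_yields_no_calls():
    rng = np.random.default_rng(0)
    base = {}
    for cl in "abcde":
        base[(cl, "A")] = 40
        base[(cl, "B")] = 40
    labels = labels_from_counts(base)
    res = proportions.permutation_proportion_test(labels, seed=1, n_bootstrap=200)
    called = proportions.significance_call(res)
    assert not called["significant"].any()
    assert (res["p_perm"] > 0.5).all()  # exchangeable null, identical groups


def test_seed_determinism_and_symmetry():
    rng = np.random.default_rng(2)
    labels = pd.DataFrame(
        {
            "cluster": rng.integers(0, 6, 400).astype(str),
            "condition": np.where(rng.random(400) < 0.5, "A", "B"),
        }
    )
    r1 = proportions.permutation_proportion_test(labels, seed=11)
    r2 = proportions.permutation_proportion_test(labels, seed=11)
    pd.testing.assert_frame_equal(r1, r2)
    flipped = proportions.permutation_proportion_test(
        labels, seed=11, conditions=("B", "A"), n_bootstrap=0
    )
    assert np.array_equal(flipped["obs_log2fd"].to_numpy(), -r1["obs_log2fd"].to_numpy())


def test_zero_count_cluster_uses_pseudocount():
    labels = labels_from_counts({("x", "A"): 10, ("y", "A"): 10, ("x", "B"): 20})
    res = proportions.permutation_proportion_test(labels, n_bootstrap=0, seed=0)
    y = res.set_index("cluster").loc["y"]
    assert np.isfinite(y["obs_log2fd"])  # no division by zero / -inf
    assert y["n_group2"] == 0


def test_single_condition_is_an_error():
    labels = labels_from_counts({("x", "A"): 5})
    with pytest.raises(ValidationError):
        proportions.permutation_proportion_test(labels)


@pytest.mark.parametrize(
    "fdr,log2fd,threshold,expect",
    [
        (0.01, 0.60, 0.58, True),
        (0.01, 0.60, 1.1, False),
        (0.06, 2.00, 0.58, False),
        (0.01, -1.29, 1.3, False),
        (0.01, -1.31, 1.3, True),
    ],
)
def test_significance_conjunction_rule(fdr, log2fd, threshold, expect):
    res = pd.DataFrame({"cluster": ["c"], "obs_log2fd": [log2fd], "fdr": [fdr]})
    out = proportions.significance_call(res, alpha=0.05, fd_threshold=threshold)
    assert bool(out.loc[0, "significant"]) is expect


def test_bootstrap_ci_brackets_observed_statistic():
    labels = labels_from_counts(
        {("k", "A"): 30, ("o", "A"): 170, ("k", "B"): 60, ("o", "B"): 140}
    )
    res = proportions.permutation_proportion_test(labels, seed=4, n_bootstrap=2000)
    k = res.set_index("cluster").loc["k"]
    assert k["ci_low"] <= k["obs_log2fd"] <= k["ci_high"]
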