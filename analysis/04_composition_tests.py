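"""Permutation tests for cell-composition differences.

Three comparisons on the reference trial:

1. CSF vs PBMC cell-type composition (pooled over patients/cycles) —
   the compartment contrast.
2. Response-window (late cycles) vs non-response CSF samples — the
   generator plants a 2x monocyte shift in the response windows, which
   this comparison should recover.
3. CAR+ vs CAR- T-cell *state* composition in CSF — the planted
   structure puts CAR+ cells preferentially in exhausted/proliferating
   states and CAR- cells in effector/memory states.

Each uses 1,000 label permutations, 1,000 bootstrap CIs, BH-FDR over
clusters, and the conjunction significance rule FDR<0.05 AND
|log2FD|>0.58. Writes
results/composition_{compartment,response,car_state}.tsv.
"""

from clonodyn import car, proportions, qc
from common import RESULTS_DIR, ensure_bundle

SEED = 1


def report(res, label):
    sig = res[res["significant"]]
    print(f"\n{label}: {len(sig)} of {len(res)} clusters significant")
    cols = ["cluster", "obs_log2fd", "p_perm", "fdr", "ci_low", "ci_high", "significant"]
    print(res[cols].round(4).to_string(index=False))


def main() -> None:
    _, cells, _, _ = ensure_bundle()
    kept, _ = qc.apply_qc(cells)

    labels = kept[kept["compartment"].isin(["PBMC", "CSF"])][["cell_type", "compartment"]]
    labels = labels.rename(columns={"cell_type": "cluster", "compartment": "condition"})
    res = proportions.significance_call(
        proportions.permutation_proportion_test(
            labels, seed=SEED, conditions=("PBMC", "CSF")
        )
    )
    res.to_csv(RESULTS_DIR / "composition_compartment.tsv", sep="\t", index=False)
    report(res, "CSF vs PBMC cell types")

    csf = kept[kept["compartment"] == "CSF"]
    resp_labels = csf[["cell_type", "cycle"]].rename(columns={"cell_type": "cluster"})
    resp_labels["condition"] = resp_labels.pop("cycle").map(
        lambda c: "response" if c >= 3 else "non_response"
    )
    res_r = proportions.significance_call(
        proportions.permutation_proportion_test(
            resp_labels, seed=SEED, conditions=("non_response", "response")
        )
    )
    res_r.to_csv(RESULTS_DIR / "composition_response.tsv", sep="\t", index=False)
    report(res_r, "response vs non-response windows in CSF (planted Mono x2)")

    csf_t = kept[(kept["compartment"] == "CSF") & (kept["cell_type"] == "T")]
    calls = car.classify_car(csf_t).merge(csf_t, on=["upn", "cycle", "compartment", "barcode"])
    state_labels = calls[["t_state", "is_car_positive"]].rename(
        columns={"t_state": "cluster"}
    )
    state_labels["condition"] = state_labels.pop("is_car_positive").map(
        {False: "CAR_neg", True: "CAR_pos"}
    )
    res2 = proportions.significance_call(
        proportions.permutation_proportion_test(
            state_labels, seed=SEED, conditions=("CAR_neg", "CAR_pos")
        )
    )
    res2.to_csv(RESULTS_DIR / "composition_car_state.tsv", sep="\t", index=False)
    report(res2, "CAR+ vs CAR- T-cell states in CSF")


if __name__ == "__main__":
    main()
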