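"""Independent oracles and replicate experiments for self-validation.

This module holds (a) deliberately naive reference implementations —
pure-Python brute force, independent of the vectorized production code
paths — used to cross-check clonotype partitioning, tier assignment and
permutation p-values; and (b) the replicate experiments that measure
recovery of the synthetic generator's planted structure (expansion
recall, CAR schedule coverage, composition-test calibration and power,
concordance recovery, overlap enrichment coverage). Both the test suite
and ``scripts/acceptance.py`` drive their checks through here so the
measured quantities are computed one way only.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from . import clonotype, concordance, expansion, overlap, proportions
from .simulate import GeneratorConfig, generate_trial
from .types import CSF, PBMC, SAMPLE_COLS


def _child_seed(seed: int, i: int) -> int:
    return (seed * 100_003 + 7 * i + 1) % (2**31 - 1)


# ------------------------------------------------ strict clonotype oracle

def random_toy_repertoire(rng: np.random.Generator, max_cells: int = 60) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A small random repertoire with a tiny key alphabet, so that exact
    key collisions (same clonotype) and near-misses (one-symbol
    differences) both occur often."""
    n_cells = int(rng.integers(2, max_cells + 1))
    barcodes = [f"BC{i:03d}" for i in range(n_cells)]
    cells = pd.DataFrame(
        {
            "upn": "U1", "cycle": 1, "compartment": CSF,
            "barcode": barcodes, "cell_type": "T", "t_state": "CD8_effector",
            "car_reads": 0, "n_genes": 1000, "n_counts": 3000, "pct_mito": 1.0,
        }
    )
    vs = ["TRAV1", "TRAV2"]
    js = ["TRAJ1", "TRAJ2"]
    cdr3s = ["TGTGCA", "TGTGCC", "TGTGCG", "TGTAAA"]
    rows = []
    for bc in barcodes:
        for chain in ("TRA", "TRB"):
            n_contigs = int(rng.choice([0, 1, 1, 1, 2], p=[0.15, 0.25, 0.25, 0.25, 0.1]))
            for _ in range(n_contigs):
                rows.append(
                    dict(
                        upn="U1", cycle=1, compartment=CSF, barcode=bc, chain=chain,
                        v_gene=str(rng.choice(vs)), d_gene="None" if chain == "TRA" else "TRBD1",
                        j_gene=str(rng.choice(js)), c_gene="TRAC" if chain == "TRA" else "TRBC1",
                        cdr3_nt=str(rng.choice(cdr3s)), cdr3_aa="CA",
                        reads=int(rng.integers(1, 100)), umis=int(rng.integers(1, 10)),
                        productive=bool(rng.random() < 0.9), is_cell=bool(rng.random() < 0.95),
                    )
                )
    contigs = pd.DataFrame(rows)
    if not contigs.empty:
        contigs = contigs.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1)))
    return contigs.reset_index(drop=True), cells


def oracle_clonotype_partition(contigs: pd.DataFrame, cells: pd.DataFrame) -> dict:
    """Brute-force strict calls: barcode -> concatenated key string.

    Pure-Python re-derivation of the pairing and selection rules; the
    partition induced by exact string equality of the concatenated
    VDJC+CDR3nt keys is the reference."""
    known = {
        (r.upn, r.cycle, r.compartment, r.barcode) for r in cells.itertuples()
    }
    per_barcode: dict = {}
    for r in contigs.itertuples():
        key = (r.upn, r.cycle, r.compartment, r.barcode)
        if key not in known or not r.productive or not r.is_cell:
            continue
        if r.chain not in ("TRA", "TRB"):
            continue
        per_barcode.setdefault(key, {"TRA": [], "TRB": []})[r.chain].append(r)
    out = {}
    for key, chains in per_barcode.items():
        if not chains["TRA"] or not chains["TRB"]:
            continue
        pick = {}
        for chain in ("TRA", "TRB"):
            pick[chain] = sorted(
                chains[chain],
                key=lambda r: (-r.umis, -r.reads, r.cdr3_nt, r.v_gene, r.d_gene, r.j_gene, r.c_gene),
            )[0]
        a, b = pick["TRA"], pick["TRB"]
        out[key] = (
            f"{a.v_gene}|{a.j_gene}|{a.c_gene}|{a.cdr3_nt}"
            f"&{b.v_gene}|{b.d_gene}|{b.j_gene}|{b.c_gene}|{b.cdr3_nt}"
        )
    return out


def clonotype_oracle_trial(n_repertoires: int = 1000, seed: int = 0, max_cells: int = 60) -> dict:
    """Compare production clonotype partitions with the brute-force oracle
    over many random repertoires. Returns agreement fraction and the
    number of pairing violations (cells assigned without both chains)."""
    rng = np.random.default_rng(seed)
    agree = 0
    violations = 0
    for _ in range(n_repertoires):
        contigs, cells = random_toy_repertoire(rng, max_cells=max_cells)
        if contigs.empty:
            agree += 1
            continue
        calls = clonotype.call_clonotypes(contigs, cells)
        got = {
            (r.upn, r.cycle, r.compartment, r.barcode): r.alpha_key + "&" + r.beta_key
            for r in calls.itertuples()
        }
        expected = oracle_clonotype_partition(contigs, cells)
        # same barcodes assigned, and the same partition (ids equal iff keys equal)
        if set(got) != set(expected):
            continue
        if all(got[k] == expected[k] for k in got):
            agree += 1
        # pairing violation check: every assigned barcode has both chains
        usable = contigs[contigs.productive & contigs.is_cell]
        for key in got:
            sub = usable[
                (usable.upn == key[0]) & (usable.cycle == key[1])
                & (usable.compartment == key[2]) & (usable.barcode == key[3])
            ]
            if not (set(sub.chain) >= {"TRA", "TRB"}):
                violations += 1
    return {"agreement": agree / n_repertoires, "pairing_violations": violations,
            "n": n_repertoires}


# ------------------------------------------------------------ tier oracle

def oracle_tier_labels(freqs: pd.DataFrame, quantiles=(0.80, 0.95, 0.99)) -> list[str]:
    """Sort-and-slice tier labels, independent of numpy's quantile code.

    Interpolated empirical quantiles computed by hand on the sorted
    pooled frequencies; labels by inclusive comparison against the three
    cutoffs, count-1 rows always unexpanded."""
    vals = sorted(freqs["normalized_freq"].tolist())
    n = len(vals)

    def q(p: float) -> float:
        if n == 1:
            return vals[0]
        h = (n - 1) * p
        lo = int(h)
        hi = min(lo + 1, n - 1)
        return vals[lo] + (h - lo) * (vals[hi] - vals[lo])

    c80, c95, c99 = q(quantiles[0]), q(quantiles[1]), q(quantiles[2])
    labels = []
    for cnt, f in zip(freqs["count"], freqs["normalized_freq"]):
        if cnt <= 1:
            labels.append(expansion.UNEXPANDED)
        elif f >= c99:
            labels.append(expansion.MOST_EXPANDED)
        elif f >= c95:
            labels.append(expansion.MORE_EXPANDED)
        elif f >= c80:
            labels.append(expansion.EXPANDED)
        else:
            labels.append(expansion.UNEXPANDED)
    return labels


def random_frequency_table(rng: np.random.Generator) -> pd.DataFrame:
    """Random frequency tables, including degenerate shapes (all-ties,
    all-singletons, tiny tables)."""
    kind = rng.choice(["generic", "ties", "singletons", "tiny"])
    if kind == "tiny":
        n = int(rng.integers(1, 4))
    else:
        n = int(rng.integers(5, 120))
    if kind == "ties":
        freq = np.full(n, float(rng.uniform(0.01, 0.5)))
        count = rng.integers(2, 10, n)
    elif kind == "singletons":
        freq = rng.uniform(0.001, 0.5, n)
        count = np.ones(n, dtype=int)
    else:
        count = rng.integers(1, 30, n)
        freq = rng.uniform(0.0005, 0.6, n)
    return pd.DataFrame(
        {
            "upn": "U1", "cycle": 1, "compartment": CSF,
            "clonotype_id": [f"c{i}" for i in range(n)],
            "count": count, "n_t_cells": 1000, "normalized_freq": freq,
        }
    )


def tier_oracle_trial(n_tables: int = 1000, seed: int = 0) -> dict:
    """Agreement between assign_tiers and the sort-and-slice oracle, plus
    a count of tiered singletons (must stay zero)."""
    rng = np.random.default_rng(seed)
    agree = 0
    tiered_singletons = 0
    for _ in range(n_tables):
        freqs = random_frequency_table(rng)
        result = expansion.assign_tiers(freqs)
        got = result.table["tier"].astype(str).tolist()
        want = oracle_tier_labels(freqs)
        if got == want:
            agree += 1
        bad = (result.table["count"] <= 1) & (result.table["tier"].astype(str) != expansion.UNEXPANDED)
        tiered_singletons += int(bad.sum())
    return {"agreement": agree / n_tables, "tiered_singletons": tiered_singletons, "n": n_tables}


# -------------------------------------- expansion + CAR replicate recovery

def expansion_and_car_recovery(n_replicates: int = 100, seed: int = 0,
                               config: GeneratorConfig | None = None) -> dict:
    """Generate replicate trials and measure, per replicate:

    * recall of planted expanders into the top two tiers (any CSF sample);
    * whether the study-level CSF top-5% tier cell-proportion trajectory
      (mean over patients) is non-decreasing across cycles — the
      replicate-level metric — plus the per-patient trajectory fraction;
    * the per-patient PBMC trajectory slope (should be centred on zero);
    * whether each CSF sample's CAR+ fraction estimate has the planted
      schedule value inside its 95% Clopper-Pearson interval.
    """
    base = config or GeneratorConfig()
    recalls = []
    monotone = []
    monotone_study = []
    pbmc_slopes = []
    car_cover = []
    n_cells_total = 0
    for i in range(n_replicates):
        cfg = GeneratorConfig.from_dict({**base.to_dict(), "seed": _child_seed(seed, i)})
        trial = generate_trial(cfg)
        n_cells_total += len(trial.cells)
        assignments = clonotype.call_clonotypes(trial.contigs, trial.cells)
        freqs = clonotype.tabulate_frequencies(assignments, trial.cells)
        tiers = expansion.assign_tiers(freqs)
        top = tiers.table[
            tiers.table["tier"].isin([expansion.MORE_EXPANDED, expansion.MOST_EXPANDED])
            & (tiers.table["compartment"] == CSF)
        ]
        recovered = set(top["clonotype_id"])
        planted = [cid for ids in trial.truth.planted_expanders.values() for cid in ids]
        recalls.append(np.mean([cid in recovered for cid in planted]))

        traj = expansion.expansion_trajectory(tiers, trial.cells, assignments)
        traj["top"] = traj[f"prop_{expansion.MORE_EXPANDED}"] + traj[f"prop_{expansion.MOST_EXPANDED}"]
        patient_trajs = []
        for upn, block in traj[traj["compartment"] == CSF].groupby("upn"):
            vals = block.sort_values("cycle")["top"].to_numpy()
            monotone.append(bool(np.all(np.diff(vals) >= 0)))
            patient_trajs.append(vals)
        study = np.mean(patient_trajs, axis=0)
        monotone_study.append(bool(np.all(np.diff(study) >= 0)))
        for upn, block in traj[traj["compartment"] == PBMC].groupby("upn"):
            b = block.sort_values("cycle")
            pbmc_slopes.append(stats.linregress(b["cycle"], b["top"]).slope)

        # CAR schedule coverage on CSF samples (truth == schedule value)
        t_cells = trial.cells[
            (trial.cells["cell_type"] == "T") & (trial.cells["compartment"] == CSF)
        ]
        grp = t_cells.groupby(["upn", "cycle"])["car_reads"].agg(
            n="size", pos=lambda s: int((s >= 3).sum())
        )
        for (upn, cycle), row in grp.iterrows():
            lo, hi = proportion_confint(row["pos"], row["n"], alpha=0.05, method="beta")
            truth_frac = cfg.car_pos_schedule_csf[int(cycle) - 1]
            car_cover.append(bool(lo <= truth_frac <= hi))

    slopes = np.asarray(pbmc_slopes)
    sem = slopes.std(ddof=1) / np.sqrt(len(slopes))
    return {
        "recall_top_tiers": float(np.mean(recalls)),
        "csf_monotone_fraction": float(np.mean(monotone_study)),
        "csf_monotone_fraction_per_patient": float(np.mean(monotone)),
        "pbmc_slope_mean": float(slopes.mean()),
        "pbmc_slope_ci": (float(slopes.mean() - 1.96 * sem), float(slopes.mean() + 1.96 * sem)),
        "car_ci_coverage": float(np.mean(car_cover)),
        "n_replicates": n_replicates,
        "n_cells_total": n_cells_total,
    }


# ------------------------------------------------- composition experiments

def composition_calibration(n_replicates: int = 500, n_cells: int = 2000,
                            n_clusters: int = 20, n_permutations: int = 1000,
                            seed: int = 0) -> dict:
    """Type-I error of the permutation test under an exchangeable null."""
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_tests = 0
    for i in range(n_replicates):
        labels = pd.DataFrame(
            {
                "cluster": rng.integers(0, n_clusters, n_cells).astype(str),
                "condition": np.where(rng.random(n_cells) < 0.5, "A", "B"),
            }
        )
        res = proportions.permutation_proportion_test(
            labels, n_permutations=n_permutations, n_bootstrap=0,
            seed=_child_seed(seed, i),
        )
        n_sig += int((res["p_perm"] < 0.05).sum())
        n_tests += len(res)
    return {"type1_rate": n_sig / n_tests, "n_tests": n_tests, "n_replicates": n_replicates}


def composition_power(n_replicates: int = 100, n_cells: int = 2000, n_clusters: int = 20,
                      fold: float = 2.0, planted_base: float = 0.15,
                      n_permutations: int = 1000, seed: int = 0) -> dict:
    """Detection rate for a planted fold-change in one cluster's proportion.

    The shifted cluster starts at a monocyte-like 15% of cells (the
    abundance class where the trial reported 2x composition shifts); the
    remaining clusters share the rest uniformly.
    """
    rng = np.random.default_rng(seed)
    base = np.empty(n_clusters)
    base[0] = planted_base
    base[1:] = (1.0 - planted_base) / (n_clusters - 1)
    shifted = base.copy()
    shifted[0] *= fold
    shifted /= shifted.sum()
    detected = 0
    for i in range(n_replicates):
        n1 = n2 = n_cells // 2
        c1 = rng.choice(n_clusters, n1, p=base).astype(str)
        c2 = rng.choice(n_clusters, n2, p=shifted).astype(str)
        labels = pd.DataFrame(
            {
                "cluster": np.concatenate([c1, c2]),
                "condition": ["A"] * n1 + ["B"] * n2,
            }
        )
        res = proportions.permutation_proportion_test(
            labels, n_permutations=n_permutations, n_bootstrap=0, seed=_child_seed(seed, i)
        )
        res = proportions.significance_call(res)
        detected += bool(res.loc[res["cluster"] == "0", "significant"].iloc[0])
    return {"power": detected / n_replicates, "n_replicates": n_replicates}


def oracle_exact_permutation_p(labels: pd.DataFrame, conditions: tuple[str, str]) -> np.ndarray:
    """Exhaustive-enumeration p-values by direct itertools brute force,
    independent of the production enumeration."""
    sub = labels.reset_index(drop=True)
    clusters = sorted(sub["cluster"].unique())
    g2_cells = sub.index[sub["condition"] == conditions[1]].tolist()
    n2 = len(g2_cells)
    n = len(sub)
    n1 = n - n2

    def stat(g2_set: set) -> dict:
        out = {}
        for cl in clusters:
            members = sub.index[sub["cluster"] == cl]
            c2 = sum(1 for m in members if m in g2_set)
            c1 = len(members) - c2
            if c1 == 0 or c2 == 0:
                p1 = (c1 + 0.5) / (n1 + 0.5)
                p2 = (c2 + 0.5) / (n2 + 0.5)
            else:
                p1, p2 = c1 / n1, c2 / n2
            out[cl] = np.log2(p2 / p1)
        return out

    obs = stat(set(g2_cells))
    hits = {cl: 0 for cl in clusters}
    total = 0
    for pick in combinations(range(n), n2):
        s = stat(set(pick))
        for cl in clusters:
            if abs(s[cl]) >= abs(obs[cl]) - 1e-12:
                hits[cl] += 1
        total += 1
    return np.array([hits[cl] / total for cl in clusters])


# ------------------------------------------------ concordance experiment

def concordance_experiment(seed: int = 0, n_patients: int = 5, n_cycles: int = 2) -> dict:
    """Recovery of planted PBMC->CSF coupled genes (and null calibration)
    on a trial sized to give ``n_patients * n_cycles`` matched pairs."""
    cfg = GeneratorConfig.from_dict(
        {**GeneratorConfig().to_dict(), "seed": seed, "n_patients": n_patients,
         "n_cycles": n_cycles, "patients_with_tumor": 0,
         "car_pos_schedule_csf": (0.4, 0.3, 0.2, 0.1)[:max(n_cycles, 4)]}
    )
    trial = generate_trial(cfg)
    pb = concordance.pseudobulk(trial.counts, trial.cells)
    filtered = concordance.filter_for_concordance(pb)
    fits = concordance.fit_cross_compartment(filtered)
    t_fits = fits[(fits["cell_type"] == "T") & ~fits["untestable"]]
    coupled = set(trial.truth.coupled_genes)
    in_coupled = t_fits["gene"].isin(coupled)
    sig = (t_fits["fdr"] < 0.05) & (t_fits["slope"] > 0)
    n_coupled_tested = int(in_coupled.sum())
    null_block = t_fits[~in_coupled]
    return {
        "coupled_recall": float((sig & in_coupled).sum() / n_coupled_tested)
        if n_coupled_tested else float("nan"),
        "null_sig_fraction": float((null_block["fdr"] < 0.05).mean()) if len(null_block) else 0.0,
        "n_pairs": int(filtered.pairs[filtered.pairs["cell_type"] == "T"].shape[0]),
        "n_null_genes": int(len(null_block)),
        "slope_mean_coupled": float(t_fits.loc[in_coupled, "slope"].mean()),
    }


# ------------------------------------------------------ overlap experiments

def overlap_null_coverage(n_replicates: int = 200, seed: int = 0,
                          n_expanded: int = 80, n_unexpanded: int = 2000,
                          rate: float = 0.05) -> dict:
    """When expanded and unexpanded clones reach tumor at the same rate,
    the OR confidence interval should cover 1 (nominally >= 95%)."""
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        a = rng.binomial(n_expanded, rate)
        c = rng.binomial(n_unexpanded, rate)
        res = overlap.enrichment_from_table(a, n_expanded - a, c, n_unexpanded - c)
        if np.isnan(res.ci_low) or (res.ci_low <= 1.0 <= res.ci_high):
            covered += 1
    return {"coverage": covered / n_replicates, "n_replicates": n_replicates}


def overlap_recovery(n_replicates: int = 200, seed: int = 0,
                     n_expanded: int = 80, n_unexpanded: int = 2000,
                     r1: float = 0.15, r2: float = 0.02) -> dict:
    """Mean log odds-ratio across replicates vs the seeding-rate truth."""
    rng = np.random.default_rng(seed)
    logs = []
    for _ in range(n_replicates):
        a = rng.binomial(n_expanded, r1)
        c = rng.binomial(n_unexpanded, r2)
        res = overlap.enrichment_from_table(a, n_expanded - a, c, n_unexpanded - c)
        logs.append(np.log(res.odds_ratio))
    logs = np.asarray(logs)
    target = np.log((r1 / (1 - r1)) / (r2 / (1 - r2)))
    sem = logs.std(ddof=1) / np.sqrt(len(logs))
    return {
        "mean_log_or": float(logs.mean()),
        "target_log_or": float(target),
        "se_mean": float(sem),
        "n_replicates": n_replicates,
    }
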