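"""Permutation test for cell-composition differences between two groups.

For each cluster (cell type or T-cell state) the statistic is the log2
fold difference of the cluster's cell proportion between two condition
groups, ``log2(p2 / p1)``. The null distribution is built by shuffling
the condition labels over cells and recomputing the statistic; the
p-value uses the standard +1 correction, ``(1 + #{|null| >= |obs|}) /
(1 + n_permutations)``, so it is never zero. Bootstrap confidence
intervals resample cells with replacement within each condition.
Benjamini-Hochberg FDR is applied across clusters, and a cluster is
called significant when ``fdr < alpha`` AND ``|log2FD|`` exceeds a
fold-difference threshold (0.58 by default, i.e. a 1.5-fold shift;
stricter analyses use 1.1 or 1.3).

Zero-count handling: when a cluster has zero cells in either group, a
pseudocount of 0.5 cells is added to both groups (numerator and
denominator) for that cluster before the ratio, preventing infinite
fold differences. The same rule is applied inside the permutation and
bootstrap loops, so observed and null statistics are comparable.

For small inputs the null can be enumerated exhaustively
(``method="exact"``): every assignment of cells to groups of the
observed sizes is visited once and the p-value is the exact proportion
of assignments at least as extreme as the observed one.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .types import ValidationError

DEFAULT_ALPHA = 0.05
DEFAULT_FD_THRESHOLD = 0.58  # |log2 FD| for a 1.5-fold proportion shift

_EXACT_LIMIT = 200_000


def _log2fd(c1, c2, n1: float, n2: float) -> np.ndarray:
    """log2 fold difference of proportions, group2 vs group1.

    ``c1``/``c2`` may be vectors (clusters) or matrices (replicates x
    clusters). The 0.5 pseudocount is applied per cluster entry only
    where a zero occurs.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    zero = (c1 == 0) | (c2 == 0)
    a1 = np.where(zero, c1 + 0.5, c1)
    a2 = np.where(zero, c2 + 0.5, c2)
    d1 = np.where(zero, n1 + 0.5, n1)
    d2 = np.where(zero, n2 + 0.5, n2)
    # difference of logs: swapping the two groups negates the statistic
    # bit-exactly, which the symmetry contract requires
    return np.log2(a2 / d2) - np.log2(a1 / d1)


def permutation_proportion_test(
    labels: pd.DataFrame,
    n_permutations: int = 1000,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    conditions: tuple[str, str] | None = None,
    method: str = "shuffle",
) -> pd.DataFrame:
    """Test per-cluster proportion differences between two conditions.

    Parameters
    ----------
    labels
        One row per cell with columns ``cluster`` and ``condition``.
    n_permutations
        Number of label shuffles for the null (ignored for
        ``method="exact"``).
    n_bootstrap
        Bootstrap resamples for the CI; 0 skips CIs (NaN bounds).
    seed
        RNG seed; identical seeds give identical p-values and CIs.
    conditions
        The (group1, group2) labels; defaults to sorted order. The
        statistic is group2 relative to group1.
    method
        ``"shuffle"`` (Monte-Carlo label permutation) or ``"exact"``
        (full enumeration of label assignments; small inputs only).

    Returns
    -------
    DataFrame with one row per cluster: counts, ``obs_log2fd``,
    ``p_perm``, ``fdr``, ``ci_low``, ``ci_high``.
    """
    if conditions is None:
        conditions = tuple(sorted(labels["condition"].unique()))
    if len(conditions) != 2:
        raise ValidationError(f"exactly two conditions required, got {conditions}")
    cond1, cond2 = conditions
    mask = labels["condition"].isin(conditions)
    sub = labels.loc[mask]
    clusters = sorted(sub["cluster"].unique())
    cluster_idx = pd.Categorical(sub["cluster"], categories=clusters).codes
    k = len(clusters)
    in_g2 = (sub["condition"] == cond2).to_numpy()
    n2 = int(in_g2.sum())
    n1 = int(len(sub) - n2)
    if n1 == 0 or n2 == 0:
        raise ValidationError(f"condition with zero cells among {conditions}")

    totals = np.bincount(cluster_idx, minlength=k)
    c2 = np.bincount(cluster_idx[in_g2], minlength=k)
    c1 = totals - c2
    obs = _log2fd(c1, c2, n1, n2)

    rng = np.random.default_rng(seed)
    if method == "exact":
        n = n1 + n2
        if comb(n, n2) > _EXACT_LIMIT:
            raise ValidationError(f"exact enumeration infeasible: C({n},{n2}) assignments")
        hits = np.zeros(k, dtype=np.int64)
        total = 0
        idx = np.asarray(cluster_idx)
        for pick in combinations(range(n), n2):
            pc2 = np.bincount(idx[list(pick)], minlength=k)
            stat = _log2fd(totals - pc2, pc2, n1, n2)
            hits += np.abs(stat) >= np.abs(obs) - 1e-12
            total += 1
        p_perm = hits / total
    elif method == "shuffle":
        perm = np.broadcast_to(in_g2, (n_permutations, len(in_g2))).copy()
        rng.permuted(perm, axis=1, out=perm)
        onehot = np.zeros((len(in_g2), k), dtype=np.float32)
        onehot[np.arange(len(in_g2)), cluster_idx] = 1.0
        pc2 = perm.astype(np.float32) @ onehot  # permutations x clusters
        null = _log2fd(totals[None, :] - pc2, pc2, n1, n2)
        exceed = (np.abs(null) >= np.abs(obs)[None, :] - 1e-12).sum(axis=0)
        p_perm = (1 + exceed) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown method {method!r}")

    if n_bootstrap > 0:
        b1 = rng.multinomial(n1, c1 / n1, size=n_bootstrap)
        b2 = rng.multinomial(n2, c2 / n2, size=n_bootstrap)
        boots = _log2fd(b1, b2, n1, n2)
        ci_low = np.percentile(boots, 2.5, axis=0)
        ci_high = np.percentile(boots, 97.5, axis=0)
    else:
        ci_low = np.full(k, np.nan)
        ci_high = np.full(k, np.nan)

    fdr = multipletests(p_perm, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "cluster": clusters,
            "n_group1": c1,
            "n_group2": c2,
            "obs_log2fd": obs,
            "p_perm": p_perm,
            "fdr": fdr,
            "ci_low": ci_low,
            "ci_high": ci_high,
        }
    )


def significance_call(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    fd_threshold: float = DEFAULT_FD_THRESHOLD,
) -> pd.DataFrame:
    """Flag clusters passing both the FDR gate and the fold-difference gate."""
    out = results.copy()
    out["significant"] = (out["fdr"] < alpha) & (out["obs_log2fd"].abs() > fd_threshold)
    return out
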