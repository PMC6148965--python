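"""Pooled permutation null for the empirical-Bayes LRT, and Storey FDR.

The shrunken-dispersion statistic has no analytic null distribution, so it is
calibrated by permuting group labels: genes that look null under the
asymptotic chi-square screen (p >= 0.1) contribute their permuted statistics
to one pooled null, and each gene's permutation p-value is the add-one tail
fraction of its observed statistic in that pool. Parameters and hyperpriors
are re-estimated from ALL genes within every permutation. Storey's q-value
procedure (single lambda = 0.5) converts the permutation p-values to FDR
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import ebayes, nbmodel

DEFAULT_NULL_CUTOFF = 0.1
DEFAULT_MAX_PERMS = 200


@dataclass
class PermutationNull:
    values: np.ndarray  # pooled LR^B(m) over null-like genes and permutations
    M: int
    n_null_like: int
    cutoff: float
    n_failures: int = 0


def select_null_like(p_chi2, cutoff: float = DEFAULT_NULL_CUTOFF) -> np.ndarray:
    """Indices of null-like genes: chi-square p-value >= cutoff."""
    p = np.asarray(p_chi2, dtype=float)
    idx = np.nonzero(p >= cutoff)[0]
    if len(idx) == 0:
        raise ValueError(
            "no gene has p >= cutoff; the pooled null cannot be built "
            "(increase the cutoff)"
        )
    return idx


def enumerate_permutations(n1: int, n2: int,
                           max_permutations: int = DEFAULT_MAX_PERMS,
                           seed: int = 0,
                           observed_group1=None) -> list:
    """Distinct relabelings of n1+n2 samples into groups of sizes (n1, n2).

    Each relabeling is returned as a sorted tuple of group-1 sample indices.
    The observed labeling is excluded, and when n1 == n2 a partition and its
    label swap are counted once (the statistic is label-symmetric). If more
    than max_permutations remain, a seeded uniform subsample is returned.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two replicates per group")
    n = n1 + n2
    if observed_group1 is None:
        observed_group1 = tuple(range(n1))
    observed_group1 = tuple(sorted(observed_group1))

    def canon(g1):
        # for balanced designs, represent the unordered partition by the side
        # containing sample 0
        if n1 == n2 and 0 not in g1:
            return tuple(sorted(set(range(n)) - set(g1)))
        return g1

    obs = canon(observed_group1)
    perms = []
    seen = set()
    for comb in combinations(range(n), n1):
        c = canon(comb)
        if c in seen or c == obs:
            continue
        seen.add(c)
        perms.append(c)
    if not perms:
        raise ValueError("no non-trivial permutations exist for this design")
    if len(perms) > max_permutations:
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(perms), size=max_permutations, replace=False)
        perms = [perms[i] for i in sorted(pick)]
    return perms


def eb_statistics(Y1: np.ndarray, Y2: np.ndarray, pooled_fit: dict | None = None):
    """Fit both groups, estimate the three hyperpriors, shrink, and return
    the empirical-Bayes LRT statistics.

    The pooled-context fit does not depend on the grouping, so callers
    evaluating many relabelings of the same matrix pass it in once.
    """
    Y = np.concatenate([Y1, Y2], axis=1)
    if pooled_fit is None:
        pooled_fit = nbmodel.fit_genes_batch(Y, "pooled")
    f1 = nbmodel.fit_genes_batch(Y1, "group1")
    f2 = nbmodel.fit_genes_batch(Y2, "group2")

    hps = {}
    phiB = {}
    for ctx, f in (("pooled", pooled_fit), ("group1", f1), ("group2", f2)):
        phi = np.where(f["ok"], f["phi"], np.nan)
        hps[ctx] = ebayes.estimate_hyperprior(phi, f["tau2"], ctx)
        phiB[ctx] = ebayes.shrink_dispersion_batch(
            np.where(f["ok"], f["phi"], hps[ctx].phi0), f["tau2"], hps[ctx]
        )
    lr_eb = nbmodel.lrt_eb_batch(Y1, Y2, phiB["pooled"], phiB["group1"],
                                 phiB["group2"])
    ok = pooled_fit["ok"]
    lr_eb = np.where(ok, lr_eb, np.nan)
    return {
        "lr_eb": lr_eb,
        "fits": {"pooled": pooled_fit, "group1": f1, "group2": f2},
        "hyperpriors": hps,
        "phiB": phiB,
        "ok": ok,
    }


def build_null(counts: np.ndarray, null_like: np.ndarray,
               permutations: list,
               cutoff: float = DEFAULT_NULL_CUTOFF) -> PermutationNull:
    """Pooled permutation null of LR^B over the null-like genes.

    For each permutation the whole empirical-Bayes machinery (per-gene fits
    for all genes, the three hyperpriors, shrinkage) is recomputed under the
    permuted labels; only the null-like genes' statistics enter the pool.
    """
    if len(permutations) == 0:
        raise ValueError("permutation list is empty")
    if len(null_like) == 0:
        raise ValueError("null-like gene set is empty")
    counts = np.asarray(counts, dtype=float)
    n = counts.shape[1]
    pooled_fit = nbmodel.fit_genes_batch(counts, "pooled")
    values = []
    n_fail = 0
    for g1_idx in permutations:
        g1 = np.array(g1_idx, dtype=int)
        g2 = np.setdiff1d(np.arange(n), g1)
        stats = eb_statistics(counts[:, g1], counts[:, g2], pooled_fit)
        v = stats["lr_eb"][null_like]
        bad = ~np.isfinite(v)
        if bad.mean() > 0.5:
            raise ValueError(
                "more than half of the null-like genes failed to fit in a "
                "permutation; the data look pathological"
            )
        n_fail += int(bad.sum())
        values.append(v[~bad])
    pooled = np.concatenate(values)
    return PermutationNull(pooled, M=len(permutations),
                           n_null_like=len(null_like), cutoff=cutoff,
                           n_failures=n_fail)


def empirical_pvalue(lr_eb_g: float, null: PermutationNull) -> float:
    """Add-one permutation p-value: (1 + #{null >= stat}) / (N + 1)."""
    if len(null.values) == 0:
        raise ValueError("empty permutation null")
    N = len(null.values)
    return (1.0 + float(np.sum(null.values >= lr_eb_g))) / (N + 1.0)


def empirical_pvalues(lr_eb, null: PermutationNull) -> np.ndarray:
    """Vectorized add-one tail fractions; NaN statistics map to NaN."""
    if len(null.values) == 0:
        raise ValueError("empty permutation null")
    s = np.sort(null.values)
    N = len(s)
    lr = np.asarray(lr_eb, dtype=float)
    out = np.full(lr.shape, np.nan)
    fin = np.isfinite(lr)
    # #{null >= x} = N - #{null < x}
    ge = N - np.searchsorted(s, lr[fin], side="left")
    out[fin] = (1.0 + ge) / (N + 1.0)
    return out


def storey_qvalues(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single tuning parameter lambda.

    pi0_hat = min(1, #{p > lambda} / ((1 - lambda) * G)); q-values are the
    running minima of pi0_hat * G * p_(j) / j from the largest p downward,
    capped at 1 and mapped back to input order. NaN p-values propagate and
    are excluded from G.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    fin = np.isfinite(p)
    pv = p[fin]
    if pv.size == 0:
        raise ValueError("no finite p-values")
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    G = pv.size
    pi0 = min(1.0, np.sum(pv > lam) / ((1.0 - lam) * G))
    order = np.argsort(pv, kind="mergesort")
    ps = pv[order]
    q = pi0 * G * ps / np.arange(1, G + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    qs = np.empty(G)
    qs[order] = q
    out = np.full(p.shape, np.nan)
    out[fin] = qs
    return out
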