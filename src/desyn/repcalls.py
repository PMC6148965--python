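"""Per-replicate classification of DE genes via NB prediction intervals.

For each declared DE gene, an equal-tailed interval for a single new
observation is built from the normal group's estimated mean and shrunken
dispersion, and each disease replicate is compared against it. A Bonferroni
split of the family-wise error rate across the disease replicates within a
gene keeps the per-gene FWER at the requested level. Genes can then be
summarized by the exact subset of disease replicates in which they are
aberrant (the Venn-diagram layout of unique and shared DE genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .nbmodel import _POISSON_EPS

CALL_NORMAL = "normal"
CALL_HIGH = "aberrant_high"
CALL_LOW = "aberrant_low"


@dataclass
class ReplicateCallMatrix:
    gene_ids: list
    replicate_ids: list
    calls: np.ndarray  # (n_genes, n2) of call strings
    lo: np.ndarray  # per-gene interval lower bound
    hi: np.ndarray
    observed: np.ndarray  # (n_genes, n2) rounded normalized counts
    alpha_family: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, g in enumerate(self.gene_ids):
            for j, r in enumerate(self.replicate_ids):
                rows.append((g, r, self.calls[i, j], self.lo[i], self.hi[i],
                             self.observed[i, j]))
        return pd.DataFrame(rows, columns=["gene_id", "replicate_id", "call",
                                           "lo", "hi", "observed"])


def _nb_dist(mu: float, phi: float):
    if phi < _POISSON_EPS:
        return stats.poisson(mu)
    r = 1.0 / phi
    return stats.nbinom(r, r / (r + mu))


def nb_interval(mu: float, phi: float, alpha: float) -> tuple:
    """Equal-tailed prediction interval for one NB(mu, phi) observation.

    lo is the largest integer with P(Y < lo) <= alpha/2; hi is the smallest
    integer with P(Y > hi) <= alpha/2.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if mu <= 0:
        raise ValueError("mu must be positive")
    dist = _nb_dist(mu, phi)
    half = alpha / 2.0
    # P(Y < lo) = cdf(lo - 1) <= half: ppf gives smallest k with cdf(k) >= half
    k = int(dist.ppf(half))
    # walk to the exact boundary (guards against cdf/ppf rounding)
    while k > 0 and dist.cdf(k - 1) > half:
        k -= 1
    while dist.cdf(k) <= half:
        k += 1
    lo = k
    # P(Y > hi) = sf(hi) <= half
    k = int(dist.isf(half))
    while k > 0 and dist.sf(k - 1) <= half:
        k -= 1
    while dist.sf(k) > half:
        k += 1
    hi = k
    return lo, hi


def classify_replicates(de_genes, fits_g1: dict, disease_obs: np.ndarray,
                        replicate_ids=None, fwer: float = 0.05) -> ReplicateCallMatrix:
    """Call each disease replicate of each DE gene against the normal group.

    fits_g1 maps gene id -> (mu_hat_g1, phiB_g1); disease_obs is the
    (n_de_genes, n2) matrix of normalized disease counts aligned with
    de_genes. Per-comparison alpha is fwer / n2 (Bonferroni within gene).
    """
    de_genes = list(de_genes)
    disease_obs = np.asarray(disease_obs, dtype=float)
    n2 = disease_obs.shape[1]
    if replicate_ids is None:
        replicate_ids = [f"disease_{j + 1}" for j in range(n2)]
    missing = [g for g in de_genes if g not in fits_g1]
    if missing:
        raise ValueError(f"no normal-group fit for DE genes: {missing}")
    alpha = fwer / n2
    lo = np.empty(len(de_genes))
    hi = np.empty(len(de_genes))
    calls = np.empty((len(de_genes), n2), dtype=object)
    obs = np.round(disease_obs)
    for i, g in enumerate(de_genes):
        mu, phi = fits_g1[g]
        lo[i], hi[i] = nb_interval(mu, phi, alpha)
        for j in range(n2):
            if obs[i, j] > hi[i]:
                calls[i, j] = CALL_HIGH
            elif obs[i, j] < lo[i]:
                calls[i, j] = CALL_LOW
            else:
                calls[i, j] = CALL_NORMAL
    return ReplicateCallMatrix(de_genes, list(replicate_ids), calls, lo, hi,
                               obs, alpha_family=fwer)


def share_summary(calls: ReplicateCallMatrix) -> pd.DataFrame:
    """Counts of DE genes by the exact subset of aberrant disease replicates.

    One row per non-empty replicate subset plus the zero-aberrant row; also
    per-replicate totals. Rows partition the DE genes:
    sum over subsets + zero-aberrant = total DE genes.
    """
    reps = calls.replicate_ids
    aberrant = calls.calls != CALL_NORMAL
    exact = {}
    n_zero = 0
    for i in range(len(calls.gene_ids)):
        s = tuple(r for r, a in zip(reps, aberrant[i]) if a)
        if not s:
            n_zero += 1
        else:
            exact[s] = exact.get(s, 0) + 1
    rows = [{"subset": "(none)", "kind": "exact", "count": n_zero}]
    for k in range(1, len(reps) + 1):
        for s in combinations(reps, k):
            if s in exact:
                rows.append({"subset": "+".join(s), "kind": "exact",
                             "count": exact[s]})
    for j, r in enumerate(reps):
        rows.append({"subset": r, "kind": "replicate_total",
                     "count": int(aberrant[:, j].sum())})
    rows.append({"subset": "+".join(reps), "kind": "all_replicates",
                 "count": int(aberrant.all(axis=1).sum())})
    return pd.DataFrame(rows)
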