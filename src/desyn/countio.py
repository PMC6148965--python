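"""Count-matrix I/O, low-count filtering, and TMM normalization.

The container is a light dataclass around a genes x samples numpy matrix with
group labels (1 = normal, 2 = disease). TMM (trimmed mean of M-values)
normalization is implemented from its published definition: per-sample
log-ratios (M) against a reference sample are trimmed by 30% each tail and
log-abundances (A) by 5% each tail, the surviving M-values are averaged with
inverse-asymptotic-variance weights, and the exponentiated means are centered
to geometric mean one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    counts: np.ndarray  # (G, n), non-negative
    gene_ids: list
    sample_ids: list
    group: np.ndarray  # (n,), values in {1, 2}

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.group = np.asarray(self.group, dtype=int)
        G, n = self.counts.shape
        if len(self.gene_ids) != G or len(self.sample_ids) != n:
            raise ValueError("gene/sample label lengths do not match the matrix")
        if len(self.group) != n:
            raise ValueError("group vector length does not match sample count")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")
        if not set(np.unique(self.group)) <= {1, 2}:
            raise ValueError("group labels must be 1 (normal) or 2 (disease)")
        if self.n1 == 0 or self.n2 == 0:
            raise ValueError("both groups must be non-empty")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.group == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.group == 2))

    def group_counts(self, which: int) -> np.ndarray:
        return self.counts[:, self.group == which]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class NormFactors:
    sample_ids: list
    library_size: np.ndarray
    factor: np.ndarray
    reference_sample: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"library_size": self.library_size, "tmm_factor": self.factor},
            index=self.sample_ids,
        )


def read_counts(path, group_spec: dict) -> CountMatrix:
    """Read a delimited genes x samples count table and attach group labels.

    group_spec maps sample id to group (1/2 or the strings normal/disease).
    Gene order is preserved.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate gene IDs: {dup}")
    missing = [s for s in group_spec if s not in df.columns]
    if missing:
        raise ValueError(f"samples in group spec missing from table header: {missing}")
    df = df[list(group_spec)]
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr) | (arr < 0))
    if len(bad):
        g, s = bad[0]
        raise ValueError(
            f"non-numeric or negative count at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}"
        )
    labels = {"normal": 1, "disease": 2, "1": 1, "2": 2, 1: 1, 2: 2}
    group = np.array([labels[group_spec[s]] for s in df.columns])
    return CountMatrix(arr, df.index.tolist(), df.columns.tolist(), group)


def read_group_file(path) -> dict:
    """Two-column TSV (sample_id, group in {normal, disease})."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "group"],
                     dtype=str, comment="#")
    return dict(zip(df["sample_id"], df["group"]))


def write_counts(cm: CountMatrix, path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def filter_low_counts(cm: CountMatrix, threshold: int = 10):
    """Drop genes whose total count across all samples is <= threshold.

    Returns (filtered CountMatrix, list of discarded gene ids).
    """
    totals = cm.counts.sum(axis=1)
    keep = totals > threshold
    if not np.any(keep):
        raise ValueError("low-count filter removed every gene")
    discarded = [g for g, k in zip(cm.gene_ids, keep) if not k]
    out = CountMatrix(
        cm.counts[keep], [g for g, k in zip(cm.gene_ids, keep) if k],
        list(cm.sample_ids), cm.group.copy(),
    )
    return out, discarded


def _tmm_factor_pair(obs, ref, lib_obs, lib_ref,
                     logratio_trim=0.3, sum_trim=0.05):
    """TMM factor of one sample against the reference (log2 scale -> 2**f)."""
    keep = (obs > 0) & (ref > 0)
    o = obs[keep] / lib_obs
    r = ref[keep] / lib_ref
    if o.size == 0:
        return 1.0
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # inverse asymptotic variance of M (binomial delta method)
    w = (lib_obs - obs[keep]) / (lib_obs * obs[keep]) \
        + (lib_ref - ref[keep]) / (lib_ref * ref[keep])
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = len(M)
    loM = np.floor(n * logratio_trim) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * sum_trim) + 1
    hiA = n + 1 - loA
    rM = pd.Series(M).rank().to_numpy()
    rA = pd.Series(A).rank().to_numpy()
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not np.any(keep2):
        return 1.0
    f = np.nansum(M[keep2] / w[keep2]) / np.nansum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_normalize(cm: CountMatrix, logratio_trim: float = 0.3,
                  sum_trim: float = 0.05):
    """TMM scaling factors and the normalized matrix.

    The reference sample is the one whose upper-quartile of library-size-scaled
    counts is closest to the mean upper-quartile. Factors are centered to
    geometric mean 1, and normalized counts are
    counts / (library_size * factor) * mean library size, keeping values on a
    count-like scale.
    """
    lib = cm.counts.sum(axis=0)
    zero = np.nonzero(lib == 0)[0]
    if len(zero):
        raise ValueError(f"sample {cm.sample_ids[zero[0]]!r} has all-zero counts")
    uq = np.array([np.quantile(cm.counts[:, j] / lib[j], 0.75)
                   for j in range(cm.n_samples)])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_factor_pair(cm.counts[:, j], cm.counts[:, ref_idx],
                         lib[j], lib[ref_idx], logratio_trim, sum_trim)
        for j in range(cm.n_samples)
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    norm = cm.counts / (lib * factors) * lib.mean()
    nf = NormFactors(list(cm.sample_ids), lib, factors,
                     reference_sample=cm.sample_ids[ref_idx])
    out = CountMatrix(norm, list(cm.gene_ids), list(cm.sample_ids), cm.group.copy())
    return nf, out
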