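"""Count I/O, the low-count filter, and TMM normalization."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from desyn import countio
from desyn.countio import CountMatrix


def _write_tsv(path, df):
    df.to_csv(path, sep="\t", index_label="gene_id")


class TestReadCounts:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame([[1, 2], [3, 4], [5, 0]], index=["a", "b", "c"],
                          columns=["s1", "s2"])
        p = tmp_path / "c.tsv"
        _write_tsv(p, df)
        cm = countio.read_counts(p, {"s1": "normal", "s2": "disease"})
        assert cm.gene_ids == ["a", "b", "c"]
        assert np.array_equal(cm.counts, df.to_numpy(dtype=float))
        assert list(cm.group) == [1, 2]

    def test_negative_entry_names_cell(self, tmp_path):
        df = pd.DataFrame([[1, 2], [3, -4]], index=["a", "b"], columns=["s1", "s2"])
        p = tmp_path / "c.tsv"
        _write_tsv(p, df)
        with pytest.raises(ValueError, match=r"'b'.*'s2'"):
            countio.read_counts(p, {"s1": "normal", "s2": "disease"})

    def test_duplicate_gene_id(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\ts1\ts2\ndup\t1\t2\ndup\t3\t4\n")
        with pytest.raises(ValueError, match="dup"):
            countio.read_counts(p, {"s1": "normal", "s2": "disease"})

    def test_missing_sample(self, tmp_path):
        df = pd.DataFrame([[1, 2]], index=["a"], columns=["s1", "s2"])
        p = tmp_path / "c.tsv"
        _write_tsv(p, df)
        with pytest.raises(ValueError, match="s9"):
            countio.read_counts(p, {"s1": "normal", "s9": "disease"})


class TestFilterLowCounts:
    def _cm(self, sums):
        counts = np.array([[s, 0, 0, 0] for s in sums], dtype=float)
        return CountMatrix(counts, [f"g{i}" for i in range(len(sums))],
                           list("abcd"), np.array([1, 1, 2, 2]))

    def test_boundary_is_discarded(self):
        # total of exactly the threshold is discarded ("no greater than")
        out, dropped = countio.filter_low_counts(self._cm([10, 11, 0]), 10)
        assert out.gene_ids == ["g1"]
        assert dropped == ["g0", "g2"]

    def test_negative_threshold_keeps_all(self):
        out, dropped = countio.filter_low_counts(self._cm([10, 11, 0]), -1)
        assert out.n_genes == 3 and dropped == []

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="every gene"):
            countio.filter_low_counts(self._cm([0, 0, 0]), 10)

    def test_idempotent(self, rng):
        counts = rng.poisson(5, size=(50, 4)).astype(float)
        cm = CountMatrix(counts, [f"g{i}" for i in range(50)], list("abcd"),
                         np.array([1, 1, 2, 2]))
        once, _ = countio.filter_low_counts(cm, 15)
        twice, dropped2 = countio.filter_low_counts(once, 15)
        assert twice.gene_ids == once.gene_ids and dropped2 == []


def _literal_tmm_oracle(counts, ref_idx):
    """Direct transcription of the trimmed-mean-of-M-values definition:
    per sample vs reference, drop zero genes, trim M by 30% and A by 5% per
    tail, weight the surviving M by inverse asymptotic variance, exponentiate,
    center to geometric mean one.
    """
    lib = counts.sum(axis=0)
    factors = []
    for j in range(counts.shape[1]):
        obs, ref = counts[:, j], counts[:, ref_idx]
        keep = (obs > 0) & (ref > 0)
        o, r = obs[keep] / lib[j], ref[keep] / lib[ref_idx]
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        w = (lib[j] - obs[keep]) / (lib[j] * obs[keep]) + \
            (lib[ref_idx] - ref[keep]) / (lib[ref_idx] * ref[keep])
        if np.max(np.abs(M)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        loM, hiM = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
        loA, hiA = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
        rM = pd.Series(M).rank().to_numpy()
        rA = pd.Series(A).rank().to_numpy()
        k = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        factors.append(2.0 ** (np.sum(M[k] / w[k]) / np.sum(1.0 / w[k])))
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_columns_are_identity(self):
        col = np.array([10.0, 100, 3, 55, 7, 300])
        counts = np.tile(col[:, None], (1, 4))
        cm = CountMatrix(counts, [f"g{i}" for i in range(6)], list("abcd"),
                         np.array([1, 1, 2, 2]))
        nf, norm = countio.tmm_normalize(cm)
        assert np.allclose(nf.factor, 1.0)
        assert np.allclose(norm.counts, counts, atol=1e-9)

    def test_doubled_column_equalized(self):
        # column 2 = 2 x column 1: every M-value against the reference is the
        # same constant, so the trimmed weighted mean is that constant, the
        # centered factors are 1, and library scaling equalizes the columns
        col = np.array([12.0, 40, 100, 7, 250, 33])
        counts = np.column_stack([col, 2 * col, col, 2 * col])
        cm = CountMatrix(counts, [f"g{i}" for i in range(6)], list("abcd"),
                         np.array([1, 1, 2, 2]))
        nf, norm = countio.tmm_normalize(cm)
        # hand-check: M = log2((c/L1)/(c/L2)) identical for all genes
        assert np.allclose(nf.factor, 1.0, atol=1e-9)
        for j in range(1, 4):
            assert np.allclose(norm.counts[:, j], norm.counts[:, 0], atol=1e-9)

    def test_matches_literal_oracle(self, rng):
        counts = rng.poisson(
            10 ** rng.normal(1.5, 0.6, size=20)[:, None]
            * rng.uniform(0.7, 1.5, size=4)[None, :]).astype(float)
        counts[counts == 0] = 1.0
        cm = CountMatrix(counts, [f"g{i}" for i in range(20)], list("abcd"),
                         np.array([1, 1, 2, 2]))
        nf, _ = countio.tmm_normalize(cm)
        ref_idx = cm.sample_ids.index(nf.reference_sample)
        assert np.allclose(nf.factor, _literal_tmm_oracle(counts, ref_idx),
                           atol=1e-6)

    def test_matches_edger(self, rng, tmp_path):
        """Independent cross-check against edgeR's calcNormFactors."""
        counts = np.abs(rng.poisson(
            10 ** rng.normal(2, 0.7, size=150)[:, None]
            * rng.uniform(0.6, 1.8, size=5)[None, :])).astype(float)
        csv = tmp_path / "m.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(edgeR));'
             f'x<-as.matrix(read.csv("{csv}"));'
             f'cat(calcNormFactors(x, method="TMM"), sep="\\n")'],
            capture_output=True, text=True)
        if r.returncode != 0:
            pytest.skip(f"Rscript/edgeR unavailable: {r.stderr[:200]}")
        expected = np.array([float(x) for x in r.stdout.split()])
        cm = CountMatrix(counts, [f"g{i}" for i in range(150)],
                         list("abcde"), np.array([1, 1, 1, 2, 2]))
        nf, _ = countio.tmm_normalize(cm)
        assert np.allclose(nf.factor, expected, atol=1e-6)

    def test_all_zero_sample_errors(self):
        counts = np.array([[1.0, 0], [2, 0]])
        cm = CountMatrix(counts, ["g0", "g1"], ["a", "b"], np.array([1, 2]))
        with pytest.raises(ValueError, match="'b'"):
            countio.tmm_normalize(cm)

    def test_libsize_factor_product_order_invariant(self, rng):
        counts = rng.poisson(50, size=(30, 4)).astype(float) + 1
        cm = CountMatrix(counts, [f"g{i}" for i in range(30)], list("abcd"),
                         np.array([1, 1, 2, 2]))
        nf, _ = countio.tmm_normalize(cm)
        perm = [2, 0, 3, 1]
        cm2 = CountMatrix(counts[:, perm], cm.gene_ids,
                          [cm.sample_ids[j] for j in perm],
                          cm.group[perm])
        nf2, _ = countio.tmm_normalize(cm2)
        assert np.isclose(np.prod(nf.library_size * nf.factor),
                          np.prod(nf2.library_size * nf2.factor), rtol=1e-9)


@given(st.lists(st.integers(min_value=0, max_value=500),
                min_size=4, max_size=40))
@settings(max_examples=50, deadline=None)
def test_filter_partition_property(sums):
    """Kept + discarded genes partition the input, for any totals."""
    counts = np.array([[s, 0, 0, 0] for s in sums], dtype=float)
    cm = CountMatrix(counts, [f"g{i}" for i in range(len(sums))],
                     list("abcd"), np.array([1, 1, 2, 2]))
    try:
        kept, dropped = countio.filter_low_counts(cm, 10)
    except ValueError:
        assert all(s <= 10 for s in sums)
        return
    assert sorted(kept.gene_ids + dropped) == sorted(cm.gene_ids)
    assert all(counts[cm.gene_ids.index(g)].sum() > 10 for g in kept.gene_ids)
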