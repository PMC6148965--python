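"""End-to-end DESyn run: filter -> TMM -> chi-square screen -> shrinkage ->
permutation null -> q-values -> DE list -> replicate classification.

Also houses the deterministic fixture generator used by the test suite.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import countio, ebayes, nbmodel, permfdr, repcalls
from .countio import CountMatrix

log = logging.getLogger("desyn")


@dataclass
class RunConfig:
    null_cutoff: float = 0.1
    fdr: float = 0.05
    fwer: float = 0.05
    max_permutations: int = permfdr.DEFAULT_MAX_PERMS
    seed: int = 0
    filter_threshold: int = 10
    skip_tmm: bool = False
    global_bonferroni: bool = False
    classify: bool = True

    def __post_init__(self):
        if not (0.0 <= self.null_cutoff <= 1.0):
            raise ValueError("null_cutoff must lie in [0, 1]")
        for name in ("fdr", "fwer"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.max_permutations < 1:
            raise ValueError("max_permutations must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class RunResult:
    results: pd.DataFrame  # gene_id, lr, p_chi2, lr_eb, p_perm, q_value, flag
    de_genes: list
    calls: repcalls.ReplicateCallMatrix | None
    manifest: dict
    norm_factors: countio.NormFactors | None


def run_desyn(cm: CountMatrix, config: RunConfig | None = None) -> RunResult:
    """Run the full method on a raw count matrix."""
    config = config or RunConfig()
    manifest = {"seed": config.seed, "config": asdict(config),
                "genes_in": cm.n_genes, "n1": cm.n1, "n2": cm.n2}

    cm_f, discarded = countio.filter_low_counts(cm, config.filter_threshold)
    manifest["genes_filtered_out"] = len(discarded)
    manifest["genes_tested"] = cm_f.n_genes
    log.info("filter: %d genes in, %d discarded", cm.n_genes, len(discarded))

    nf = None
    if config.skip_tmm:
        norm = cm_f
    else:
        nf, norm = countio.tmm_normalize(cm_f)
        manifest["tmm_factors"] = dict(zip(nf.sample_ids, nf.factor.tolist()))
        log.info("tmm: reference sample %s", nf.reference_sample)

    # NB likelihoods are evaluated on integers; round once here
    counts = np.round(norm.counts)
    Y1 = counts[:, norm.group == 1]
    Y2 = counts[:, norm.group == 2]

    lr, p_chi2, fits = nbmodel.lrt_batch(Y1, Y2)
    stats = permfdr.eb_statistics(Y1, Y2, fits["pooled"])
    lr_eb = stats["lr_eb"]
    manifest["hyperpriors"] = {
        ctx: {"phi0": hp.phi0, "tau20": hp.tau20, "n_genes_used": hp.n_genes_used}
        for ctx, hp in stats["hyperpriors"].items()
    }
    log.info("screen: %d genes, %d with NA fits",
             len(lr), int(np.sum(~stats["ok"])))

    null_like = permfdr.select_null_like(np.nan_to_num(p_chi2, nan=-1.0),
                                         config.null_cutoff)
    obs_g1 = tuple(np.nonzero(norm.group == 1)[0])
    perms = permfdr.enumerate_permutations(
        norm.n1, norm.n2, config.max_permutations, config.seed, obs_g1)
    null = permfdr.build_null(counts, null_like, perms, config.null_cutoff)
    manifest["M"] = null.M
    manifest["n_null_like"] = null.n_null_like
    log.info("null: %d permutations x %d null-like genes",
             null.M, null.n_null_like)

    p_perm = permfdr.empirical_pvalues(lr_eb, null)
    q = permfdr.storey_qvalues(p_perm)

    flag = np.where(stats["ok"], "ok", "fit_failed")
    results = pd.DataFrame({
        "gene_id": norm.gene_ids,
        "lr": lr,
        "p_chi2": p_chi2,
        "lr_eb": lr_eb,
        "p_perm": p_perm,
        "q_value": q,
        "flag": flag,
    })
    de_mask = np.nan_to_num(q, nan=1.0) <= config.fdr
    de_genes = [g for g, d in zip(norm.gene_ids, de_mask) if d]
    manifest["n_de"] = len(de_genes)

    calls = None
    if config.classify and de_genes:
        g1fit = stats["fits"]["group1"]
        phiB1 = stats["phiB"]["group1"]
        gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
        fits_g1 = {}
        for g in de_genes:
            i = gene_pos[g]
            mu = g1fit["mu"][i]
            if mu <= 0:
                mu = 0.5  # all-zero normal group: half-count floor
            fits_g1[g] = (mu, phiB1[i])
        fwer = config.fwer
        n2 = norm.n2
        if config.global_bonferroni:
            fwer = config.fwer / max(1, len(de_genes))
        disease = counts[np.array([gene_pos[g] for g in de_genes])][:, norm.group == 2]
        rep_ids = [s for s, grp in zip(norm.sample_ids, norm.group) if grp == 2]
        calls = repcalls.classify_replicates(de_genes, fits_g1, disease,
                                             rep_ids, fwer)
    return RunResult(results, de_genes, calls, manifest, nf)


def desyn_qvalues(cm: CountMatrix, config: RunConfig | None = None) -> np.ndarray:
    """Caller adapter for the simulation studies: CountMatrix -> q-values."""
    config = config or RunConfig(skip_tmm=True, classify=False,
                                 filter_threshold=-1)
    return run_desyn(cm, config).results["q_value"].to_numpy()


def mean_only_qvalues(cm: CountMatrix) -> np.ndarray:
    """Baseline caller: mean-only NB LRT (common dispersion) + Storey."""
    counts = np.round(cm.counts)
    Y1 = counts[:, cm.group == 1]
    Y2 = counts[:, cm.group == 2]
    _, p = nbmodel.mean_only_lrt_batch(Y1, Y2)
    return permfdr.storey_qvalues(p)


def make_fixture(kind: str, n_genes: int = 500, seed: int = 0,
                 n_per_group: int = 4):
    """Deterministic small datasets for tests: (CountMatrix, truth DataFrame).

    kinds: "null" (all genes EE), "planted" (strong mean shifts in all
    disease replicates for a few genes), "fig1-like" (a few genes whose
    shift, roughly 16-fold, hits only a subset of disease replicates).
    """
    kinds = {"null": 0, "planted": 1, "fig1-like": 2}
    if kind not in kinds:
        raise ValueError(f"unknown fixture kind {kind!r}")
    # distinct stream per kind so different kinds never share draws
    rng = np.random.default_rng([seed, kinds[kind]])
    mu = np.maximum(10.0 ** rng.normal(2.0, 0.5, size=n_genes), 1.0)
    phi = rng.gamma(2.0, 0.075, size=n_genes)
    n = 2 * n_per_group
    r = 1.0 / np.maximum(phi, 1e-12)
    counts = rng.negative_binomial(
        r[:, None], (r / (r + mu))[:, None], size=(n_genes, n)).astype(float)

    truth = pd.DataFrame({
        "gene_id": [f"gene_{i + 1}" for i in range(n_genes)],
        "is_de": 0,
        "aberrant_reps": "",
    })
    n_plant = min(4, n_genes)
    if kind in ("planted", "fig1-like"):
        for i in range(n_plant):
            if kind == "planted":
                reps = list(range(n_per_group))
            else:
                n_hit = 1 + int(rng.integers(0, n_per_group))
                reps = sorted(rng.choice(n_per_group, size=n_hit,
                                         replace=False).tolist())
            shifted = mu[i] * 16.0
            rr = max(r[i], 1e-12)
            for j in reps:
                counts[i, n_per_group + j] = rng.negative_binomial(
                    rr, rr / (rr + shifted))
            truth.loc[i, "is_de"] = 1
            truth.loc[i, "aberrant_reps"] = ",".join(str(j + 1) for j in reps)

    cm = CountMatrix(
        counts,
        truth["gene_id"].tolist(),
        [f"normal_{j + 1}" for j in range(n_per_group)]
        + [f"disease_{j + 1}" for j in range(n_per_group)],
        np.array([1] * n_per_group + [2] * n_per_group),
    )
    return cm, truth
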