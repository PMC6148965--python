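"""Simulation studies for power/FDR benchmarking of syndrome-style DE tests.

Counts for both groups are drawn gene-wise from NB(mu, phi) with parameters
sampled from a pool (either an empirical per-gene (mu, phi) table or a
documented synthetic stand-in). DE genes in the disease group follow one of
three scenarios:

  1. dispersion shift in every disease replicate:
     phi_g2 = phi_g1 + X_phi * delta_phi, delta_phi ~ Beta(2, 2);
  2. the same dispersion shift but only in the last k_g replicates,
     k_g ~ U{1, 2, 3, 4};
  3. joint shift: dispersion as in scenario 1 (smaller size X_phi) plus a
     mean shift mu_g2 = mu_g1 + X_mu * delta_mu * sigma_g1 with
     delta_mu ~ Beta(2, 4) and sigma_g1 the NB standard deviation
     sqrt(mu_g1 + phi_g1 * mu_g1^2).

Studies 1-3 use scenarios 1-3 exclusively (default 4000 EE + 1000 DE genes,
scaled proportionally for smaller gene counts); study 4 mixes all three
(3950 EE + 350 of each scenario at full scale). Study sizes: X_phi = 0.4 in
studies 1-2, X_phi = 0.3 and X_mu = 2 in studies 3-4's scenario-3 genes.

Simulated counts are generated with equal library sizes and treated as
already normalized; callers are evaluated by TPr at fixed nominal FDR,
realized FDR, ROC and AUC against the truth ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .countio import CountMatrix

DEFAULT_DE_FRACTION = 0.2  # 1000 of 5000 at full scale
STUDY4_SCENARIO_FRACTION = 0.07  # 350 of 5000, per scenario


@dataclass
class ScenarioConfig:
    scenario: int
    X_phi: float = 0.4
    phi_beta: tuple = (2.0, 2.0)  # delta_phi ~ Beta(2, 2)
    X_mu: float = 0.0
    mu_beta: tuple = (2.0, 4.0)  # delta_mu ~ Beta(2, 4)
    k_choices: tuple = (1, 2, 3, 4)  # scenario 2 affected-replicate count

    @classmethod
    def for_study(cls, study: int) -> "ScenarioConfig":
        if study in (1, 2):
            return cls(scenario=study, X_phi=0.4)
        if study == 3:
            return cls(scenario=3, X_phi=0.3, X_mu=2.0)
        raise ValueError("scenario config is per-study only for studies 1-3")


@dataclass
class ParameterPool:
    mu: np.ndarray
    phi: np.ndarray
    provenance: str = "synthetic"

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        if np.any(self.mu <= 0):
            raise ValueError("pool means must be positive")
        if np.any(self.phi < 0):
            raise ValueError("pool dispersions must be non-negative")

    def sample(self, n: int, rng: np.random.Generator):
        replace = n > len(self.mu)
        idx = rng.choice(len(self.mu), size=n, replace=replace)
        return self.mu[idx], self.phi[idx]


def build_parameter_pool(source="synthetic", n: int = 5000,
                         seed: int = 0) -> ParameterPool:
    """(mu, phi) pool, from an empirical table or the synthetic stand-in.

    source may be "synthetic", a path to a TSV/CSV with columns
    (gene_id, mu, phi), or a DataFrame with columns mu and phi. The synthetic
    stand-in draws log10 mu ~ N(2, 0.5^2) truncated to mu >= 1 and
    phi ~ Gamma(shape 2, mean 0.15).
    """
    if isinstance(source, str) and source != "synthetic":
        sep = "," if source.endswith(".csv") else "\t"
        source = pd.read_csv(source, sep=sep)
    if isinstance(source, pd.DataFrame):
        if np.any(source["mu"].to_numpy() <= 0):
            raise ValueError("empirical pool contains non-positive means")
        return ParameterPool(source["mu"].to_numpy(),
                             source["phi"].to_numpy(), "empirical-file")
    rng = np.random.default_rng(seed)
    log10mu = rng.normal(2.0, 0.5, size=n)
    mu = np.maximum(10.0 ** log10mu, 1.0)
    phi = rng.gamma(shape=2.0, scale=0.15 / 2.0, size=n)
    return ParameterPool(mu, phi, "synthetic")


@dataclass
class SimTruth:
    is_de: np.ndarray
    scenario: np.ndarray  # 0 for EE genes
    mu_g1: np.ndarray
    phi_g1: np.ndarray
    mu_g2: np.ndarray  # (G, n_per_group) per-replicate disease means
    phi_g2: np.ndarray  # (G, n_per_group) per-replicate disease dispersions
    delta_phi: np.ndarray
    delta_mu: np.ndarray
    k_g: np.ndarray  # 0 where not applicable

    def to_frame(self, gene_ids) -> pd.DataFrame:
        df = pd.DataFrame({
            "gene_id": gene_ids,
            "is_de": self.is_de.astype(int),
            "scenario": self.scenario,
            "mu_g1": self.mu_g1,
            "phi_g1": self.phi_g1,
            "delta_phi": self.delta_phi,
            "delta_mu": self.delta_mu,
            "k_g": self.k_g,
        })
        for j in range(self.mu_g2.shape[1]):
            df[f"mu_g2_rep{j + 1}"] = self.mu_g2[:, j]
            df[f"phi_g2_rep{j + 1}"] = self.phi_g2[:, j]
        return df


def _draw_nb(rng, mu, phi):
    """NB(mu, phi) variates; phi = 0 genes are Poisson."""
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(mu.shape)
    pois = phi <= 0
    if np.any(pois):
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if np.any(nb):
        r = 1.0 / phi[nb]
        out[nb] = rng.negative_binomial(r, r / (r + mu[nb]))
    return out


def simulate_study(study: int, n_genes: int = 5000, n_per_group: int = 4,
                   pool: ParameterPool | None = None, seed: int = 0,
                   de_fraction: float = DEFAULT_DE_FRACTION):
    """One simulated dataset: (CountMatrix, SimTruth).

    Studies 1-3 plant round(de_fraction * n_genes) DE genes of the study's
    scenario; study 4 plants three equal scenario blocks of
    round(0.07 * n_genes) genes each (3950 EE + 350 + 350 + 350 at the full
    5000-gene scale). DE genes occupy the tail of the gene order; the truth
    ledger records every draw.
    """
    if study not in (1, 2, 3, 4):
        raise ValueError(f"unknown simulation study {study!r}")
    if n_per_group < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    if pool is None:
        pool = build_parameter_pool(seed=seed)

    if study == 4:
        n_per_scen = int(round(STUDY4_SCENARIO_FRACTION / DEFAULT_DE_FRACTION
                               * de_fraction * n_genes))
        scen_of_de = np.repeat([1, 2, 3], n_per_scen)
    else:
        n_de = int(round(de_fraction * n_genes))
        scen_of_de = np.full(n_de, study)
    n_de = len(scen_of_de)
    n_ee = n_genes - n_de

    mu1, phi1 = pool.sample(n_genes, rng)
    scenario = np.zeros(n_genes, dtype=int)
    scenario[n_ee:] = scen_of_de
    is_de = scenario > 0

    mu2 = np.tile(mu1[:, None], (1, n_per_group))
    phi2 = np.tile(phi1[:, None], (1, n_per_group))
    delta_phi = np.zeros(n_genes)
    delta_mu = np.zeros(n_genes)
    k_g = np.zeros(n_genes, dtype=int)

    for scen in (1, 2, 3):
        idx = np.nonzero(scenario == scen)[0]
        if len(idx) == 0:
            continue
        cfg = ScenarioConfig.for_study(scen)
        d_phi = rng.beta(*cfg.phi_beta, size=len(idx))
        delta_phi[idx] = d_phi
        shift = cfg.X_phi * d_phi
        if scen == 1 or scen == 3:
            phi2[idx] += shift[:, None]
        else:  # scenario 2: only the last k_g replicates shift
            k = rng.choice(cfg.k_choices, size=len(idx))
            k = np.minimum(k, n_per_group)
            k_g[idx] = k
            for j in range(n_per_group):
                hit = j >= n_per_group - k
                phi2[idx[hit], j] += shift[hit]
        if scen == 3:
            d_mu = rng.beta(*cfg.mu_beta, size=len(idx))
            delta_mu[idx] = d_mu
            sigma1 = np.sqrt(mu1[idx] + phi1[idx] * mu1[idx] ** 2)
            mu2[idx] += (cfg.X_mu * d_mu * sigma1)[:, None]

    Y1 = np.column_stack([_draw_nb(rng, mu1, phi1) for _ in range(n_per_group)])
    Y2 = np.column_stack([_draw_nb(rng, mu2[:, j], phi2[:, j])
                          for j in range(n_per_group)])
    counts = np.concatenate([Y1, Y2], axis=1)
    gene_ids = [f"gene_{i + 1}" for i in range(n_genes)]
    sample_ids = ([f"normal_{j + 1}" for j in range(n_per_group)]
                  + [f"disease_{j + 1}" for j in range(n_per_group)])
    group = np.array([1] * n_per_group + [2] * n_per_group)
    cm = CountMatrix(counts, gene_ids, sample_ids, group)
    truth = SimTruth(is_de, scenario, mu1, phi1, mu2, phi2,
                     delta_phi, delta_mu, k_g)
    return cm, truth


@dataclass
class EvalResult:
    table: pd.DataFrame  # per nominal FDR level: n_declared, tpr, actual_fdr
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def evaluate(scores, truth, nominal_fdr_grid=(0.01, 0.05, 0.10)) -> EvalResult:
    """Score a caller's per-gene q-values (or p-values) against the truth.

    Lower score = more significant. Actual FDR with an empty declared set is
    0 by convention. The ROC sweeps the score threshold (ties by trapezoid).
    """
    scores = np.asarray(scores, dtype=float)
    is_de = truth.is_de if isinstance(truth, SimTruth) else np.asarray(truth)
    is_de = is_de.astype(bool)
    if len(scores) != len(is_de):
        raise ValueError("scores and truth have different lengths")
    n_true = int(is_de.sum())
    rows = []
    for level in nominal_fdr_grid:
        declared = scores <= level
        tp = int(np.sum(declared & is_de))
        fp = int(np.sum(declared & ~is_de))
        rows.append({
            "nominal_fdr": level,
            "n_declared": int(declared.sum()),
            "tpr": tp / n_true if n_true else np.nan,
            "actual_fdr": fp / max(1, int(declared.sum())),
        })
    fin = np.isfinite(scores)
    # NaN scores (untested genes) rank last
    s = np.where(fin, scores, np.inf)
    if is_de.all() or (~is_de).all():
        fpr = tpr = np.array([0.0, 1.0])
        a = np.nan
    else:
        fpr, tpr, _ = roc_curve(is_de, -s)
        a = float(_trapezoid_auc(fpr, tpr))
    return EvalResult(pd.DataFrame(rows), fpr, tpr, a)


def run_study_replicates(study: int, n_per_group: int, caller,
                         n_reps: int = 50, n_genes: int = 5000,
                         pool: ParameterPool | None = None,
                         base_seed: int = 0, nominal_fdr: float = 0.05,
                         de_fraction: float = DEFAULT_DE_FRACTION) -> pd.DataFrame:
    """Repeat a study; per repetition: TP/total positives at the nominal FDR,
    realized FDR, and AUC, with across-repetition means and SDs appended.

    caller maps a CountMatrix to per-gene scores on the q-value scale.
    Repetition seeds are base_seed + repetition index.
    """
    rows = []
    for rep in range(n_reps):
        seed = base_seed + rep
        cm, truth = simulate_study(study, n_genes, n_per_group, pool, seed,
                                   de_fraction)
        try:
            q = np.asarray(caller(cm), dtype=float)
        except Exception as e:
            raise RuntimeError(f"caller failed on repetition {rep}: {e}") from e
        ev = evaluate(q, truth, nominal_fdr_grid=(nominal_fdr,))
        r = ev.table.iloc[0]
        tp = int(round(r["tpr"] * truth.is_de.sum()))
        rows.append({"rep": rep, "seed": seed, "true_positives": tp,
                     "total_positives": int(r["n_declared"]),
                     "tpr": float(r["tpr"]),
                     "actual_fdr": float(r["actual_fdr"]),
                     "auc": ev.auc})
    df = pd.DataFrame(rows)
    summary = df[["true_positives", "total_positives", "tpr", "actual_fdr",
                  "auc"]].agg(["mean", "std"])
    df.attrs["summary"] = summary
    return df
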