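"""Empirical-Bayes shrinkage of per-gene NB dispersions.

Model: phi_hat_g | phi_g ~ N(phi_g, tau2_g) and phi_g ~ N(phi0, tau20), one
hyperprior per pooling context (pooled, group1, group2), each estimated from
all genes. The posterior mean is the precision-weighted average

    phiB_g = (phi_hat_g / tau2_g + phi0 / tau20) / (1 / tau2_g + 1 / tau20),

floored at zero because the NB dispersion cannot be negative. Hyperpriors are
estimated by method of moments under the two-level normal model:
phi0 = mean(phi_hat), tau20 = max(0, var(phi_hat) - mean(tau2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_GENES = 10


@dataclass
class HyperPrior:
    context: str
    phi0: float
    tau20: float
    n_genes_used: int


def estimate_hyperprior(phi_hats, tau2s, context: str = "pooled") -> HyperPrior:
    """Method-of-moments hyperprior from per-gene MLEs and their variances.

    Non-finite entries (failed fits) are excluded and counted out.
    """
    phi_hats = np.asarray(phi_hats, dtype=float)
    tau2s = np.asarray(tau2s, dtype=float)
    if phi_hats.shape != tau2s.shape:
        raise ValueError("phi_hats and tau2s must have equal length")
    usable = np.isfinite(phi_hats) & np.isfinite(tau2s) & (tau2s > 0)
    phi_hats = phi_hats[usable]
    tau2s = tau2s[usable]
    if len(phi_hats) < MIN_GENES:
        raise ValueError(
            f"only {len(phi_hats)} usable genes; need at least {MIN_GENES} "
            "for a reliable hyperprior"
        )
    phi0 = float(np.mean(phi_hats))
    tau20 = float(max(0.0, np.var(phi_hats, ddof=1) - np.mean(tau2s)))
    return HyperPrior(context, max(phi0, 0.0), tau20, int(len(phi_hats)))


def shrink_dispersion(phi_hat_g: float, tau2_g: float, hp: HyperPrior) -> float:
    """Posterior-mean dispersion, floored at zero."""
    if tau2_g <= 0:
        raise ValueError("tau2_g must be positive")
    if hp.tau20 == 0.0:
        return hp.phi0
    num = phi_hat_g / tau2_g + hp.phi0 / hp.tau20
    den = 1.0 / tau2_g + 1.0 / hp.tau20
    return max(0.0, num / den)


def shrink_dispersion_batch(phi_hats, tau2s, hp: HyperPrior) -> np.ndarray:
    phi_hats = np.asarray(phi_hats, dtype=float)
    tau2s = np.asarray(tau2s, dtype=float)
    if np.any(tau2s <= 0):
        raise ValueError("tau2s must be positive")
    if hp.tau20 == 0.0:
        return np.full(len(phi_hats), hp.phi0)
    out = (phi_hats / tau2s + hp.phi0 / hp.tau20) / (1.0 / tau2s + 1.0 / hp.tau20)
    return np.maximum(out, 0.0)
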