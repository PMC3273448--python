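"""The Besag-York-Mollié (BYM) convolution model for one outcome.

``o_i ~ Poisson(e_i * rho_i)`` with ``log rho_i = alpha + u_i + v_i``:
``u`` is an intrinsic-CAR (spatially structured) field, ``v`` an
exchangeable (unstructured) field, and ``alpha`` a flat intercept.
Precisions get diffuse ``Gamma(0.5, 0.0005)`` hyperpriors by default.

The share of between-area variability attributable to spatial correlation is
summarized per posterior draw as ``s_u^2 / (s_u^2 + sigma_v^2)``, where
``s_u^2 = sum_i (u_i - ubar)^2 / (n - 1)`` is the *marginal* (empirical)
variance of the spatial field — not the conditional variance ``1/tau_u`` —
and ``sigma_v^2 = 1/tau_v``.

Sampling uses the hierarchically centered parameterization: the total
log-relative-risk field ``b = u + v`` carries the Poisson likelihood and is
updated by vectorized single-site Metropolis, while ``u`` given ``b`` has a
Gaussian full conditional (ICAR prior combined with ``b - u ~ N(0,
1/tau_v)``) and is drawn exactly by Gibbs in graph-coloring blocks.  With
counts as informative as hospital admissions this mixes far better than
updating ``u`` and ``v`` against the likelihood directly.  The flat
direction ``(u + c, b + c, alpha - c)`` left by the improper ICAR prior is
removed by re-centering ``u`` (per connected component) after every sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .areal_data import AdjacencyStructure, ArealCounts
from .mcmc import (BlockRW, MCMCConfig, PosteriorSamples, convergence_report,
                   dic, icar_effective_rank, icar_quadratic_form,
                   metropolis_block, poisson_deviance)
from .priors import PrecisionPrior, update_precision

__all__ = ["BYMResult", "fit_bym", "spatial_fraction", "exceedance_probability"]


@dataclass
class BYMResult:
    samples: PosteriorSamples
    adjacency: AdjacencyStructure
    counts: ArealCounts
    dic: float
    p_d: float
    convergence: dict

    @property
    def converged(self) -> bool:
        return self.convergence["converged"]

    def spatial_fraction_summary(self, level: float = 0.95):
        med = self.samples.median("spatial_fraction")
        lo, hi = self.samples.interval("spatial_fraction", level)
        return {"median": med, "ci_low": float(lo), "ci_high": float(hi)}

    def exceedance(self, threshold: float = 1.0) -> np.ndarray:
        return exceedance_probability(np.exp(self.samples.stacked("log_rr")), threshold)

    def area_table(self, level: float = 0.95) -> pd.DataFrame:
        rr = np.exp(self.samples.stacked("log_rr"))
        a = (1 - level) / 2 * 100
        lo, hi = np.percentile(rr, [a, 100 - a], axis=0)
        prob = exceedance_probability(rr)
        return pd.DataFrame({
            "area_id": self.counts.area_ids,
            "rr_median": np.median(rr, axis=0),
            "rr_ci_low": lo, "rr_ci_high": hi,
            "pr_rr_gt_1": prob,
            "flagged": prob > 0.95,
        })


def spatial_fraction(u_draws: np.ndarray, sigma_v2_draws: np.ndarray):
    """Per-draw spatial fraction and its posterior summary.

    ``u_draws``: (..., n_areas) ICAR field draws; ``sigma_v2_draws``: matching
    unstructured variances.  Returns ``(fraction_draws, summary_dict)``.
    """
    u = np.asarray(u_draws, dtype=float)
    if u.shape[-1] < 2:
        raise ValueError("need at least two areas")
    s_u2 = u.var(axis=-1, ddof=1)
    frac = s_u2 / (s_u2 + np.asarray(sigma_v2_draws, dtype=float))
    flat = frac.ravel()
    summary = {"median": float(np.median(flat)),
               "ci_low": float(np.percentile(flat, 2.5)),
               "ci_high": float(np.percentile(flat, 97.5))}
    return frac, summary


def exceedance_probability(rr_draws: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Share of posterior draws with relative risk above ``threshold``, per area."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rr = np.asarray(rr_draws, dtype=float)
    return (rr > threshold).mean(axis=0)


def fit_bym(counts: ArealCounts, adjacency: AdjacencyStructure,
            config: MCMCConfig | None = None,
            precision_prior: str | PrecisionPrior = "gamma(0.5,0.0005)") -> BYMResult:
    """Fit the BYM model by Metropolis-within-Gibbs (centered parameterization)."""
    config = config or MCMCConfig()
    if counts.expected is None:
        counts = counts.with_expected()
    if counts.area_ids != adjacency.area_ids:
        raise ValueError("counts are not aligned with the adjacency structure")
    prior = PrecisionPrior.parse(precision_prior)

    n = adjacency.n_areas
    o = counts.observed.astype(float)
    e = np.asarray(counts.expected, dtype=float)
    sum_o = o.sum()
    deg = adjacency.degrees.astype(float)
    d_prior = np.where(deg == 0, 1.0, deg)  # exchangeable fallback for isolates
    W = adjacency.adjacency_matrix
    colors = adjacency.coloring()
    all_idx = np.arange(n)
    n_eff = icar_effective_rank(adjacency)
    labels = adjacency.component_labels if adjacency.n_components > 1 else None

    keep = config.n_kept
    store = {k: np.empty((config.n_chains, keep) + shp) for k, shp in {
        "alpha": (), "u": (n,), "v": (n,), "tau_u": (), "tau_v": (),
        "sigma_u2_marginal": (), "sigma_v2": (), "spatial_fraction": (),
        "log_rr": (n,)}.items()}
    dev = np.empty((config.n_chains, keep))
    acc_rates = {}

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    for ch in range(config.n_chains):
        rng = np.random.default_rng(seeds[ch])
        alpha = float(np.log(max(sum_o, 1.0) / e.sum()))
        b = np.log(np.maximum(o, 0.5) / e) - alpha  # total field u + v
        u = np.zeros(n)
        tau_u, tau_v = 10.0, 10.0
        rw_b = BlockRW(n, config.proposal_sd)
        rw_tau = BlockRW(1, 0.5)

        def db(idx, new, old):
            like = o[idx] * (new - old) - e[idx] * np.exp(alpha) * (
                np.exp(new) - np.exp(old))
            return like - 0.5 * tau_v * ((new - u[idx]) ** 2 - (old - u[idx]) ** 2)

        total = config.burn_in + config.n_iter
        k = 0
        for it in range(total):
            in_burn = it < config.burn_in
            if not in_burn:
                rw_b.frozen = rw_tau.frozen = True
            # intercept: exp(alpha) | rest ~ Gamma(sum o, sum e*exp(b))
            S = float(np.sum(e * np.exp(b)))
            alpha = float(np.log(rng.gamma(sum_o, 1.0 / S))) if sum_o > 0 else alpha
            # total log-risk field: Poisson likelihood + N(u, 1/tau_v) prior
            acc = metropolis_block(rng, all_idx, b, db, rw_b)
            if not in_burn:
                rw_b.record(acc)
            # ICAR field | b: Gaussian full conditional, exact Gibbs by colors
            for idx in colors:
                s = (W @ u)[idx]
                prec = tau_u * d_prior[idx] + tau_v
                mean = (tau_u * s + tau_v * b[idx]) / prec
                u[idx] = mean + rng.standard_normal(idx.size) / np.sqrt(prec)
            # remove the flat direction (u+c, b+c, alpha-c)
            if labels is None:
                c = u.mean()
                u -= c
                b -= c
                alpha += c
            else:
                for cc in range(adjacency.n_components):
                    m = labels == cc
                    c = u[m].mean()
                    u[m] -= c
                    b[m] -= c
                alpha += 0.0  # per-component levels absorbed into b's likelihood fit
            # precisions
            tau_u = update_precision(rng, tau_u, icar_quadratic_form(u, adjacency),
                                     n_eff, prior, rw_tau)
            v = b - u
            tau_v = update_precision(rng, tau_v, float(v @ v), n, prior, rw_tau)
            if not in_burn and (it - config.burn_in) % config.thin == config.thin - 1:
                log_rr = alpha + b
                s_u2 = float(u.var(ddof=1))
                sv2 = 1.0 / tau_v
                store["alpha"][ch, k] = alpha
                store["u"][ch, k] = u
                store["v"][ch, k] = v
                store["tau_u"][ch, k] = tau_u
                store["tau_v"][ch, k] = tau_v
                store["sigma_u2_marginal"][ch, k] = s_u2
                store["sigma_v2"][ch, k] = sv2
                store["spatial_fraction"][ch, k] = s_u2 / (s_u2 + sv2)
                store["log_rr"][ch, k] = log_rr
                dev[ch, k] = poisson_deviance(o, e * np.exp(log_rr))
                k += 1
        acc_rates[f"chain{ch}_b"] = rw_b.acceptance_rate

    samples = PosteriorSamples(store, dev, acc_rates, config)
    # deviance at the posterior means of the parameters
    mu_hat = e * np.exp(samples.mean("alpha") + samples.mean("u") + samples.mean("v"))
    dic_val, p_d = dic(dev, poisson_deviance(o, mu_hat))
    conv = convergence_report(
        samples, names=["alpha", "tau_u", "tau_v", "spatial_fraction"])
    if not conv["converged"]:
        warnings.warn(
            f"BYM chains may not have converged (R-hat > {conv['threshold']} "
            f"for {conv['flagged']}); consider a longer schedule")
    return BYMResult(samples, adjacency, counts, dic_val, p_d, conv)
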