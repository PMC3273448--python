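"""Shared MCMC machinery for Poisson log-linear random-effect models.

The samplers in :mod:`arealvar.bym` and :mod:`arealvar.scm` are
Metropolis-within-Gibbs: precision parameters get conjugate gamma Gibbs
updates, intercepts get exact Gibbs draws (flat prior, Poisson likelihood
with a shared log-offset is gamma-conjugate on the exponentiated
intercept), the total log-risk field carrying the likelihood is updated by
vectorized random-walk Metropolis, and the structured fields are drawn
from their Gaussian full conditionals.  Updates touching an intrinsic-CAR
(ICAR) field proceed in vectorized blocks given by a proper graph
coloring, which keeps block members conditionally independent because no
two areas in a block are neighbors; exchangeable components are
conditionally independent everywhere and use a single vectorized block.

Proposal scales adapt by Robbins-Monro during burn-in only (target
acceptance 0.3-0.5) and are frozen afterwards, so the kept draws come from
a fixed-kernel chain.

The ICAR prior is improper: its density is defined only up to shifts within
each connected component of the adjacency graph.  Identifiability is
restored by re-centering each field to mean zero after every sweep, with the
absorbed constant folded into the model intercept; the effective rank used
in precision updates is ``n - (number of connected components)`` (isolated
areas, which fall back to an exchangeable conditional, count as full-rank).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .areal_data import AdjacencyStructure

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "icar_quadratic_form",
    "icar_log_density",
    "icar_full_conditional",
    "gibbs_update_precision",
    "mh_update_site",
    "center_sum_to_zero",
    "rhat",
    "convergence_report",
    "poisson_deviance",
    "dic",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Chain schedule.  Defaults are a desk-scale reduced schedule.

    ``long_schedule`` gives the long schedule typical of WinBUGS-era
    disease-mapping analyses (50,000 burn-in, 100,000 sampling iterations
    keeping every 10th).
    """

    n_iter: int = 2000
    burn_in: int = 2000
    thin: int = 4
    n_chains: int = 2
    seed: int = 0
    proposal_sd: float = 0.1
    adapt: bool = True

    def __post_init__(self):
        if self.n_iter <= 0 or self.burn_in < 0 or self.thin < 1 or self.n_chains < 1:
            raise ValueError("invalid MCMC schedule")

    @classmethod
    def long_schedule(cls, seed: int = 0, n_chains: int = 2) -> "MCMCConfig":
        return cls(n_iter=100_000, burn_in=50_000, thin=10, n_chains=n_chains, seed=seed)

    @property
    def n_kept(self) -> int:
        return self.n_iter // self.thin

    def with_seed(self, seed: int) -> "MCMCConfig":
        return replace(self, seed=seed)


class PosteriorSamples:
    """Post-burn-in, thinned draws for a named set of parameters.

    Scalar parameters are stored as ``(chains, draws)`` arrays, vector
    parameters as ``(chains, draws, dim)``.
    """

    def __init__(self, params: dict[str, np.ndarray], deviance: np.ndarray,
                 acceptance: dict[str, float], config: MCMCConfig):
        shapes = {v.shape[:2] for v in params.values()}
        if len(shapes) > 1:
            raise ValueError("all parameters must share the chain/draw shape")
        self.params = params
        self.deviance = np.asarray(deviance, dtype=float)
        if not np.all(np.isfinite(self.deviance)):
            raise ValueError("non-finite deviance draws")
        self.acceptance = acceptance
        self.config = config

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    def __contains__(self, name: str) -> bool:
        return name in self.params

    def stacked(self, name: str) -> np.ndarray:
        """Draws pooled across chains: (chains*draws,) or (chains*draws, dim)."""
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def median(self, name: str) -> np.ndarray | float:
        m = np.median(self.stacked(name), axis=0)
        return float(m) if np.ndim(m) == 0 else m

    def interval(self, name: str, level: float = 0.95):
        a = (1 - level) / 2 * 100
        q = np.percentile(self.stacked(name), [a, 100 - a], axis=0)
        return q[0], q[1]

    def mean(self, name: str) -> np.ndarray | float:
        m = self.stacked(name).mean(axis=0)
        return float(m) if np.ndim(m) == 0 else m

    def summary(self, names=None, level: float = 0.95) -> pd.DataFrame:
        names = list(self.params) if names is None else list(names)
        rows = []
        for nm in names:
            s = self.stacked(nm)
            if s.ndim == 1:
                s = s[:, None]
            med = np.median(s, axis=0)
            lo, hi = np.percentile(s, [(1 - level) / 2 * 100, (1 + level) / 2 * 100], axis=0)
            for k in range(s.shape[1]):
                label = nm if s.shape[1] == 1 else f"{nm}[{k}]"
                rows.append({"parameter": label, "median": med[k],
                             "ci_low": lo[k], "ci_high": hi[k]})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table."""
        rows = []
        for nm, a in self.params.items():
            c, d = a.shape[:2]
            if a.ndim == 2:
                a = a[:, :, None]
            for k in range(a.shape[2]):
                label = nm if a.shape[2] == 1 and self.params[nm].ndim == 2 else f"{nm}[{k}]"
                for ch in range(c):
                    rows.append(pd.DataFrame({
                        "chain": ch, "iteration": np.arange(d),
                        "parameter": label, "value": a[ch, :, k]}))
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# ICAR primitives


def icar_quadratic_form(u, adjacency: AdjacencyStructure) -> float:
    """``sum over neighbor pairs of (u_i - u_j)^2`` plus ``u_i^2`` for isolated areas.

    Isolated areas take an exchangeable fallback so their contribution is a
    plain sum of squares under the same precision.
    """
    u = np.asarray(u, dtype=float)
    if u.size != adjacency.n_areas:
        raise ValueError("field length does not match adjacency")
    e = adjacency.edge_index
    q = float(np.sum((u[e[:, 0]] - u[e[:, 1]]) ** 2)) if e.size else 0.0
    iso = adjacency.degrees == 0
    if iso.any():
        q += float(np.sum(u[iso] ** 2))
    return q


def icar_effective_rank(adjacency: AdjacencyStructure) -> int:
    """Rank of the ICAR precision: n - #components, counting isolated areas
    (exchangeable fallback) as full rank."""
    return adjacency.n_areas - adjacency.n_components + adjacency.n_isolated


def icar_log_density(u, adjacency: AdjacencyStructure, tau: float) -> float:
    """Unnormalized ICAR log-density ``(n_eff/2) log tau - (tau/2) Q(u)``.

    Defined up to a constant not depending on ``u`` or ``tau``.
    """
    n_eff = icar_effective_rank(adjacency)
    return 0.5 * n_eff * math.log(tau) - 0.5 * tau * icar_quadratic_form(u, adjacency)


def icar_full_conditional(u, i: int, adjacency: AdjacencyStructure, tau: float):
    """Conditional mean and precision of ``u_i`` given its neighbors.

    ``mean = average of neighbors``, ``precision = tau * degree``.  Isolated
    areas fall back to the exchangeable conditional N(0, 1/tau).
    """
    u = np.asarray(u, dtype=float)
    if u.size != adjacency.n_areas:
        raise ValueError("field length does not match adjacency")
    d = int(adjacency.degrees[i])
    if d == 0:
        return 0.0, float(tau)
    W = adjacency.adjacency_matrix
    s = float(W[i].dot(u).item() if hasattr(W[i].dot(u), "item") else W[i].dot(u))
    return s / d, float(tau * d)


def center_sum_to_zero(field, adjacency: AdjacencyStructure):
    """Subtract the mean within each connected component.

    Returns ``(centered_field, constants)`` where ``constants`` is the
    per-component mean, aligned to component labels, so that callers can fold
    the absorbed level into an intercept.
    """
    x = np.asarray(field, dtype=float).copy()
    labels = adjacency.component_labels
    n_comp = adjacency.n_components
    constants = np.zeros(n_comp)
    for k in range(n_comp):
        m = labels == k
        constants[k] = x[m].mean()
        x[m] -= constants[k]
    return x, constants


# ---------------------------------------------------------------------------
# elementary updates


def gibbs_update_precision(rng, quadratic: float, n_eff: float,
                           prior_shape: float = 0.5, prior_rate: float = 0.0005) -> float:
    """Conjugate gamma draw for a precision parameter.

    Posterior is ``Gamma(prior_shape + n_eff/2, prior_rate + quadratic/2)``
    (shape/rate).  For an ICAR field ``quadratic`` is the pairwise
    difference form and ``n_eff`` its effective rank; for exchangeable
    components it is the plain sum of squares with ``n_eff = n``.
    """
    if prior_shape <= 0 or prior_rate <= 0:
        raise ValueError("prior shape and rate must be positive")
    if not np.isfinite(quadratic):
        raise ValueError("non-finite quadratic form")
    shape = prior_shape + 0.5 * n_eff
    rate = prior_rate + 0.5 * quadratic
    return float(rng.gamma(shape, 1.0 / rate))


_nan_warned = [False]


def mh_update_site(current: float, log_target, proposal_sd: float, rng):
    """One symmetric random-walk Metropolis step for a scalar.

    Returns ``(value, accepted)``.  A NaN at the proposal is treated as a
    rejection (warned once).
    """
    lp0 = log_target(current)
    if not np.isfinite(lp0):
        raise ValueError("log_target not finite at current value")
    prop = current + proposal_sd * rng.standard_normal()
    lp1 = log_target(prop)
    if np.isnan(lp1):
        if not _nan_warned[0]:
            warnings.warn("log_target returned NaN at a proposal; treated as rejection")
            _nan_warned[0] = True
        return current, False
    if math.log(rng.random()) < lp1 - lp0:
        return prop, True
    return current, False


# ---------------------------------------------------------------------------
# vectorized building blocks used by the model samplers


class BlockRW:
    """Per-site random-walk proposal scales with Robbins-Monro adaptation."""

    TARGET = 0.4  # middle of the 0.3-0.5 acceptance band

    def __init__(self, size: int, sd: float = 0.1):
        self.log_sd = np.full(size, math.log(sd))
        self.t = 0
        self.frozen = False
        self.n_acc = 0.0
        self.n_prop = 0.0

    @property
    def sd(self) -> np.ndarray:
        return np.exp(self.log_sd)

    def adapt(self, accepted: np.ndarray, idx=None) -> None:
        if self.frozen:
            return
        self.t += 1
        gamma = min(0.25, 2.0 / self.t ** 0.6)
        delta = gamma * (accepted.astype(float) - self.TARGET)
        if idx is None:
            self.log_sd += delta
        else:
            self.log_sd[idx] += delta

    def record(self, accepted: np.ndarray) -> None:
        self.n_acc += float(np.sum(accepted))
        self.n_prop += accepted.size

    @property
    def acceptance_rate(self) -> float:
        return self.n_acc / self.n_prop if self.n_prop else float("nan")


def metropolis_block(rng, idx, current, delta_log_target, scales: BlockRW):
    """Vectorized Metropolis update of the sites in ``idx``.

    ``delta_log_target(idx, new, old)`` returns the per-site change in the
    unnormalized log posterior when site ``i`` moves from ``old`` to ``new``
    with everything else fixed; sites in ``idx`` must be conditionally
    independent (non-adjacent) for this to be a valid joint update.
    Mutates ``current`` in place and returns the per-site acceptance mask.
    """
    old = current[idx]
    sd = scales.sd[idx] if scales.log_sd.size == current.size else scales.sd
    new = old + sd * rng.standard_normal(idx.size)
    dlp = delta_log_target(idx, new, old)
    acc = np.log(rng.random(idx.size)) < dlp
    current[idx] = np.where(acc, new, old)
    scales.adapt(acc, idx if scales.log_sd.size == current.size else None)
    return acc


# ---------------------------------------------------------------------------
# diagnostics and model comparison


def rhat(samples: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    ``samples`` has shape (chains, draws); each chain is split in half, so at
    least two chains and ten kept draws per chain are required.
    """
    a = np.asarray(samples, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected a (chains, draws) array")
    c, d = a.shape
    if c < 2:
        raise ValueError("rhat needs at least two chains (set n_chains >= 2)")
    if d < 10:
        raise ValueError("rhat needs at least 10 kept draws per chain")
    half = d // 2
    splits = np.concatenate([a[:, :half], a[:, half: 2 * half]], axis=0)
    m, n = splits.shape
    chain_means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_hat = (n - 1) / n * W + B / n
    return float(math.sqrt(var_hat / W))


def convergence_report(samples: PosteriorSamples, threshold: float = 1.1,
                       names=None) -> dict:
    """Per-parameter max split-R-hat with flags above ``threshold``."""
    names = list(samples.params) if names is None else list(names)
    out, flagged = {}, []
    for nm in names:
        a = samples[nm]
        if a.ndim == 2:
            a = a[:, :, None]
        vals = [rhat(a[:, :, k]) for k in range(a.shape[2])]
        out[nm] = float(np.max(vals))
        if out[nm] > threshold:
            flagged.append(nm)
    return {"rhat": out, "flagged": flagged, "converged": not flagged,
            "threshold": threshold}


def poisson_deviance(observed, mu) -> float:
    """``-2 sum log PoissonPMF(o; mu)`` (saturated term not subtracted)."""
    o = np.asarray(observed, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return float(-2.0 * np.sum(o * np.log(mu) - mu - gammaln(o + 1.0)))


def dic(deviance_draws, deviance_at_posterior_mean: float):
    """Deviance information criterion and effective number of parameters.

    ``pD = mean(D) - D(posterior mean of parameters)``;
    ``DIC = mean(D) + pD``.  A negative ``pD`` (possible under strong
    posterior skewness) is returned with a warning.
    """
    d = np.asarray(deviance_draws, dtype=float).ravel()
    if not (np.all(np.isfinite(d)) and np.isfinite(deviance_at_posterior_mean)):
        raise ValueError("non-finite deviance input")
    dbar = float(d.mean())
    pd_ = dbar - float(deviance_at_posterior_mean)
    if -1e-8 * max(1.0, abs(dbar)) < pd_ < 0:
        pd_ = 0.0  # floating cancellation of identical draws
    if pd_ < 0:
        warnings.warn("negative pD: posterior mean fits worse than average draw")
    return dbar + pd_, pd_
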