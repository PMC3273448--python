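"""Hyperprior specifications for precision parameters and the SCM scaling.

The default precision hyperprior is the diffuse conjugate
``tau ~ Gamma(0.5, 0.0005)`` (equivalently an inverse-gamma on the
variance).  The sensitivity alternatives span the families commonly probed
in disease mapping: a tighter gamma on the variance scale, a wide uniform on
the standard deviation, and a half-normal on the standard deviation.  Gamma
variants are conjugate and updated by Gibbs; the sd-scale priors are updated
by adaptive random-walk Metropolis on log(tau).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .mcmc import BlockRW, gibbs_update_precision

__all__ = ["PrecisionPrior", "DeltaPrior", "update_precision"]


@dataclass(frozen=True)
class PrecisionPrior:
    kind: str            # "gamma" | "uniform_sd" | "halfnormal_sd"
    a: float = 0.5       # gamma shape | uniform upper bound | half-normal precision
    b: float = 0.0005    # gamma rate  | unused

    @classmethod
    def parse(cls, spec: "str | PrecisionPrior") -> "PrecisionPrior":
        """Parse specs like ``gamma(0.5,0.0005)``, ``uniform_sd(0,100)``,
        ``halfnormal_sd(0.01)``."""
        if isinstance(spec, cls):
            return spec
        s = spec.strip().lower().replace(" ", "")
        m = re.fullmatch(r"(\w+)\(([^)]*)\)", s)
        name, args = (m.group(1), m.group(2).split(",")) if m else (s, [])
        nums = [float(x) for x in args if x]
        if name in {"gamma", "inverse_gamma", "invgamma"}:
            a, b = (nums + [0.5, 0.0005])[:2]
            return cls("gamma", a, b)
        if name == "uniform_sd":
            upper = nums[-1] if nums else 100.0
            return cls("uniform_sd", upper)
        if name == "halfnormal_sd":
            prec = nums[0] if nums else 0.01
            return cls("halfnormal_sd", prec)
        raise ValueError(f"unknown precision prior {spec!r}")

    def log_density_log_tau(self, w: float, n_eff: float, quadratic: float) -> float:
        """Unnormalized log posterior of ``w = log(tau)`` given a Gaussian
        component with quadratic form ``quadratic`` and rank ``n_eff``."""
        tau = math.exp(w)
        ll = 0.5 * n_eff * w - 0.5 * tau * quadratic
        if self.kind == "gamma":
            return ll + self.a * w - self.b * tau
        sigma = math.exp(-0.5 * w)
        if self.kind == "uniform_sd":
            if sigma >= self.a:
                return -math.inf
            return ll - 0.5 * w  # d(sigma)/d(w) Jacobian, flat density in sigma
        if self.kind == "halfnormal_sd":
            return ll - 0.5 * self.a * sigma * sigma - 0.5 * w
        raise AssertionError(self.kind)


def update_precision(rng, tau: float, quadratic: float, n_eff: float,
                     prior: PrecisionPrior, rw: BlockRW | None = None) -> float:
    """One update of a precision parameter under ``prior``.

    Conjugate Gibbs for gamma priors; otherwise one adaptive random-walk
    Metropolis step on log(tau) using the scalar scale state ``rw``.
    """
    if prior.kind == "gamma":
        return gibbs_update_precision(rng, quadratic, n_eff, prior.a, prior.b)
    if rw is None:
        raise ValueError("non-conjugate precision prior needs a proposal-scale state")
    w = math.log(tau)
    lp0 = prior.log_density_log_tau(w, n_eff, quadratic)
    w1 = w + float(rw.sd[0]) * rng.standard_normal()
    lp1 = prior.log_density_log_tau(w1, n_eff, quadratic)
    acc = math.log(rng.random()) < lp1 - lp0
    rw.adapt(np.array([acc]))
    rw.record(np.array([acc]))
    return math.exp(w1) if acc else tau


@dataclass(frozen=True)
class DeltaPrior:
    """Prior for the SCM scaling parameter delta, specified on log(delta).

    ``lognormal``: log(delta) ~ Normal(0, precision ``a``), default
    precision 0.2 (variance 5).  ``uniform``: delta ~ Uniform(a, b) with
    hard rejection at the bounds.
    """

    kind: str = "lognormal"
    a: float = 0.2
    b: float = 2.0

    @classmethod
    def parse(cls, spec: "str | DeltaPrior") -> "DeltaPrior":
        if isinstance(spec, cls):
            return spec
        s = spec.strip().lower().replace(" ", "")
        m = re.fullmatch(r"(\w+)\(([^)]*)\)", s)
        name, args = (m.group(1), m.group(2).split(",")) if m else (s, [])
        nums = [float(x) for x in args if x]
        if name == "lognormal":
            prec = nums[-1] if nums else 0.2
            return cls("lognormal", prec)
        if name == "uniform":
            lo, hi = (nums + [0.5, 2.0])[:2]
            return cls("uniform", lo, hi)
        raise ValueError(f"unknown delta prior {spec!r}")

    def log_density_log_delta(self, t: float) -> float:
        if self.kind == "lognormal":
            return -0.5 * self.a * t * t
        lo, hi = math.log(self.a), math.log(self.b)
        if not (lo < t < hi):
            return -math.inf
        return t  # uniform density in delta; Jacobian of t = log(delta)
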