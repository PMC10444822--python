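"""Reaction-term families for the activator-inhibitor model, behind a registry.

The default family is the activator-depleted-substrate (Schnakenberg) system

    f(u, v) = gamma * (a - u + u^2 v)        # activator u
    h(u, v) = gamma * (b - u^2 v)            # substrate v

with the positive homogeneous steady state u* = a + b, v* = b / (a + b)^2.
``gamma`` sets the reaction timescale relative to diffusion; ``a`` and ``b``
are base production rates of activator and substrate.  A Gierer-Meinhardt
family is registered as an alternate.  Kinetic constants may be scalars or
per-grid-point arrays, which is how exogenous spatial gradients are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize


@dataclass(frozen=True)
class Kinetics:
    """One reaction family bound to concrete constants.

    ``f``/``h`` evaluate the activator/inhibitor (or substrate) reaction
    terms; ``jacobian`` returns (f_u, f_v, h_u, h_v) at a state, used for the
    linear stability analysis and the explicit-step stability guard.
    """

    name: str
    constants: dict
    f: Callable
    h: Callable
    jacobian: Callable
    steady_state: Callable

    def with_constants(self, **overrides) -> "Kinetics":
        merged = {**self.constants, **overrides}
        return get_kinetics(self.name, **merged)


def _schnakenberg(a=0.1, b=0.9, gamma=1.0) -> Kinetics:
    c = {"a": a, "b": b, "gamma": gamma}

    def f(u, v, c=c):
        return c["gamma"] * (c["a"] - u + u * u * v)

    def h(u, v, c=c):
        return c["gamma"] * (c["b"] - u * u * v)

    def jacobian(u, v, c=c):
        g = c["gamma"]
        fu = g * (2.0 * u * v - 1.0)
        fv = g * u * u
        hu = -g * 2.0 * u * v
        hv = -g * u * u
        return fu, fv, hu, hv

    def steady_state(c=c):
        u = c["a"] + c["b"]
        if np.any(np.asarray(u) <= 0):
            raise ValueError("Schnakenberg steady state requires a + b > 0")
        return u, c["b"] / u ** 2

    return Kinetics("schnakenberg", c, f, h, jacobian, steady_state)


def _gierer_meinhardt(rho=1.0, mu_u=1.0, mu_v=1.2, basal=0.05, gamma=1.0) -> Kinetics:
    """Gierer-Meinhardt activator-inhibitor: autocatalysis saturated by v."""
    c = {"rho": rho, "mu_u": mu_u, "mu_v": mu_v, "basal": basal, "gamma": gamma}

    def f(u, v, c=c):
        return c["gamma"] * (c["basal"] + c["rho"] * u * u / v - c["mu_u"] * u)

    def h(u, v, c=c):
        return c["gamma"] * (c["rho"] * u * u - c["mu_v"] * v)

    def jacobian(u, v, c=c):
        g = c["gamma"]
        fu = g * (2.0 * c["rho"] * u / v - c["mu_u"])
        fv = -g * c["rho"] * u * u / (v * v)
        hu = g * 2.0 * c["rho"] * u
        hv = -g * c["mu_v"]
        return fu, fv, hu, hv

    def steady_state(c=c):
        # solve f = h = 0 numerically from a positive initial guess
        def resid(z):
            u, v = np.exp(z)  # keep positivity
            return [float(f(u, v)), float(h(u, v))]

        sol = optimize.root(resid, x0=[0.0, 0.0], method="hybr")
        if not sol.success:
            raise ValueError(
                f"no positive homogeneous steady state found "
                f"(residual {np.max(np.abs(sol.fun)):.3e})")
        u, v = np.exp(sol.x)
        return float(u), float(v)

    return Kinetics("gierer_meinhardt", c, f, h, jacobian, steady_state)


KINETICS_REGISTRY: dict[str, Callable[..., Kinetics]] = {
    "schnakenberg": _schnakenberg,
    "gierer_meinhardt": _gierer_meinhardt,
}


def get_kinetics(name: str, **constants) -> Kinetics:
    """Instantiate a registered kinetics family with the given constants."""
    try:
        factory = KINETICS_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown kinetics {name!r}; registered: {sorted(KINETICS_REGISTRY)}"
        ) from None
    return factory(**constants)
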