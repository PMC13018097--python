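"""Non-spatial models: equilibria, linear stability and the Hopf scan.

The full model tracks (u, i, v); the reduced model eliminates the virus
through the quasi-steady relation v = (alpha*q/q_v)*i, which collapses
infection into the single rate beta_tilde.  The reduced system never
oscillates; the full one loses stability of its interior equilibrium
through a Hopf bifurcation as the burst size alpha grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import ModelParams, beta_tilde

__all__ = ["Equilibrium", "BifurcationDiagram", "rhs", "jacobian",
           "equilibria", "stability", "simulate_ode", "limit_cycle_amplitude",
           "find_hopf", "hopf_scan"]

_MARGINAL_TOL = 1.0e-10


@dataclass
class Equilibrium:
    """An equilibrium point with its Jacobian spectrum."""

    state: tuple[float, ...]
    eigenvalues: np.ndarray | None = None
    classification: str | None = None
    physical: bool = True

    @property
    def u(self) -> float:
        return self.state[0]

    @property
    def i(self) -> float:
        return self.state[1]


def rhs(t: float, y: np.ndarray, params: ModelParams,
        model: str = "full") -> np.ndarray:
    """Right-hand side of the full (u,i,v) or reduced (u,i) system."""
    K, p, q = params.K, params.p, params.q
    if model == "full":
        u, i, v = y
        infect = params.beta * u * v / K
        return np.array([
            p * u * (1.0 - (u + i) / K) - infect,
            infect - q * i,
            params.alpha * q * i - params.q_v * v,
        ])
    if model == "reduced":
        u, i = y
        bt = beta_tilde(params)
        infect = bt * u * i / K
        return np.array([
            p * u * (1.0 - (u + i) / K) - infect,
            infect - q * i,
        ])
    raise ValueError(f"unknown model {model!r}")


def jacobian(y: np.ndarray, params: ModelParams,
             model: str = "full") -> np.ndarray:
    K, p, q = params.K, params.p, params.q
    if model == "full":
        u, i, v = y
        b = params.beta
        return np.array([
            [p * (1 - (2 * u + i) / K) - b * v / K, -p * u / K, -b * u / K],
            [b * v / K, -q, b * u / K],
            [0.0, params.alpha * q, -params.q_v],
        ])
    if model == "reduced":
        u, i = y
        bt = beta_tilde(params)
        return np.array([
            [p * (1 - (2 * u + i) / K) - bt * i / K, -(p + bt) * u / K],
            [bt * i / K, bt * u / K - q],
        ])
    raise ValueError(f"unknown model {model!r}")


def equilibria(params: ModelParams, model: str = "full") -> list[Equilibrium]:
    """The three equilibria: extinction, infection-free, interior.

    Interior point: u* = q*K/bt, i* = p*K*(bt - q)/(bt*(bt + p)), and for
    the full model v* = (alpha*q/q_v)*i*.  It is flagged non-physical when
    bt < q (i* < 0).
    """
    K = params.K
    bt = beta_tilde(params)
    pts: list[tuple[float, ...]] = []
    if model == "full":
        pts.append((0.0, 0.0, 0.0))
        pts.append((K, 0.0, 0.0))
    else:
        pts.append((0.0, 0.0))
        pts.append((K, 0.0))
    if bt > 0:
        u_star = params.q * K / bt
        i_star = params.p * K * (bt - params.q) / (bt * (bt + params.p))
        if model == "full":
            v_star = params.alpha * params.q / params.q_v * i_star
            interior = (u_star, i_star, v_star)
        else:
            interior = (u_star, i_star)
        pts.append(interior)
    eqs = []
    for k, pt in enumerate(pts):
        eq = Equilibrium(state=pt, physical=all(c >= 0 for c in pt))
        stability(eq, params, model)
        eqs.append(eq)
    return eqs


def stability(eq: Equilibrium, params: ModelParams,
              model: str = "full") -> str:
    """Classify by the sign of the largest real part of the Jacobian."""
    J = jacobian(np.asarray(eq.state, dtype=float), params, model)
    eig = np.linalg.eigvals(J)
    eq.eigenvalues = eig
    top = float(np.max(eig.real))
    if abs(top) < _MARGINAL_TOL:
        eq.classification = "marginal"
    elif top < 0:
        eq.classification = "stable"
    else:
        eq.classification = "unstable"
    return eq.classification


def simulate_ode(params: ModelParams, y0, horizon: float,
                 model: str = "full", rtol: float = 1.0e-9,
                 t_eval: np.ndarray | None = None):
    """Stiff-safe adaptive integration (LSODA) of either system."""
    y0 = np.asarray(y0, dtype=float)
    scale = np.full(y0.shape, params.K)
    if model == "full" and params.q_v > 0:
        scale[2] = max(params.K, params.alpha * params.q * params.K / params.q_v)
    sol = solve_ivp(rhs, (0.0, horizon), y0, args=(params, model),
                    method="LSODA", rtol=rtol, atol=rtol * scale,
                    t_eval=t_eval, dense_output=t_eval is None)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol


def _interior(params: ModelParams, model: str) -> Equilibrium:
    return equilibria(params, model)[-1]


def limit_cycle_amplitude(params: ModelParams, model: str = "full",
                          transient: float = 1.0e4,
                          n_cycles: float = 20.0) -> tuple[float, float]:
    """(min, max) of u on the attractor after discarding the transient.

    The measurement window and sampling rate are scaled from the linear
    oscillation period at the interior equilibrium.
    """
    eq = _interior(params, model)
    imag = np.abs(np.asarray(eq.eigenvalues).imag)
    omega = float(imag.max())
    period = 2 * np.pi / omega if omega > 0 else 500.0
    y0 = np.asarray(eq.state, dtype=float) * 1.01 + 1.0e-6
    sol = simulate_ode(params, y0, transient, model=model)
    y1 = sol.y[:, -1]
    window = n_cycles * period
    t_eval = np.linspace(0.0, window, max(int(n_cycles * 200), 2000))
    sol2 = solve_ivp(rhs, (0.0, window), y1, args=(params, model),
                     method="LSODA", rtol=1.0e-9,
                     atol=1.0e-9 * max(params.K, 1.0), t_eval=t_eval)
    u = sol2.y[0]
    return float(u.min()), float(u.max())


def _critical_real_part(alpha: float, params: ModelParams, model: str) -> float:
    eq = _interior(params.replace(alpha=float(alpha)), model)
    return float(np.max(np.asarray(eq.eigenvalues).real))


def find_hopf(params: ModelParams, alpha_lo: float, alpha_hi: float,
              model: str = "full", tol: float = 1.0e-8) -> float:
    """Bracket the Hopf point by the sign change of the critical eigenvalue
    pair's real part and refine until |Re lambda| < tol."""
    f = lambda a: _critical_real_part(a, params, model)
    f_lo, f_hi = f(alpha_lo), f(alpha_hi)
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no stability change in alpha: Re = {f_lo:.3g} at {alpha_lo}, "
            f"{f_hi:.3g} at {alpha_hi}"
        )
    a = brentq(f, alpha_lo, alpha_hi, xtol=1e-6, rtol=8.9e-16)
    # xtol in alpha does not guarantee |Re| < tol; tighten by bisection if needed
    while abs(f(a)) > tol:  # pragma: no cover - brentq is usually enough
        lo, hi = a * (1 - 1e-12), a * (1 + 1e-12)
        if f(lo) * f(a) <= 0:
            a = 0.5 * (lo + a)
        else:
            a = 0.5 * (a + hi)
    return float(a)


@dataclass
class BifurcationDiagram:
    """One-parameter scan in the burst size alpha."""

    alpha: np.ndarray
    u_eq: np.ndarray
    stable: np.ndarray
    u_min_cycle: np.ndarray
    u_max_cycle: np.ndarray
    hopf_alpha: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alpha,
            "u_eq": self.u_eq,
            "stable": self.stable,
            "u_min_cycle": self.u_min_cycle,
            "u_max_cycle": self.u_max_cycle,
        })


def hopf_scan(params: ModelParams, alpha_values, horizon: float = 2.0e4,
              transient: float = 1.0e4, model: str = "full") -> BifurcationDiagram:
    """Scan the interior equilibrium in alpha; where unstable, integrate past
    the transient and record the min/max of u over the final cycles."""
    alpha_values = np.sort(np.asarray(alpha_values, dtype=float))
    u_eq = np.empty_like(alpha_values)
    stable = np.zeros(alpha_values.shape, dtype=bool)
    u_min = np.full_like(alpha_values, np.nan)
    u_max = np.full_like(alpha_values, np.nan)
    for k, a in enumerate(alpha_values):
        pk = params.replace(alpha=float(a))
        eq = _interior(pk, model)
        u_eq[k] = eq.u
        stable[k] = eq.classification == "stable"
        if not stable[k] and eq.physical:
            n_cycles = max(5.0, (horizon - transient) / 500.0)
            u_min[k], u_max[k] = limit_cycle_amplitude(
                pk, model=model, transient=transient, n_cycles=n_cycles)
    hopf_alpha = None
    flips = np.nonzero(stable[:-1] != stable[1:])[0]
    if flips.size:
        j = flips[0]
        try:
            hopf_alpha = find_hopf(params, alpha_values[j], alpha_values[j + 1],
                                   model=model)
        except ValueError:  # pragma: no cover
            hopf_alpha = None
    return BifurcationDiagram(
        alpha=alpha_values, u_eq=u_eq, stable=stable,
        u_min_cycle=u_min, u_max_cycle=u_max, hopf_alpha=hopf_alpha,
        meta={"model": model, "params": params.to_dict()},
    )
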