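"""Travelling-wave speeds: linear-spreading theory and empirical tracking.

For the two-species reduction the infection invades a uniform uninfected
background u_b at the pulled-front speed 2*sqrt(D_U*(bt*u_b/K - q)).  For
the explicit-virus system the (i, v) subsystem linearised about
(u_b, 0, 0) has, for spatial decay rate lambda, the growth matrix

    M(lambda) = [[D_U*lambda^2 - q,       beta*u_b/K      ],
                 [alpha*q,                D_v*lambda^2 - q_v]]

and the minimal speed is c* = min_{lambda>0} mu_max(lambda)/lambda with
mu_max the largest (real) eigenvalue.  Untreated fronts travel at
2*sqrt(D_U*p) (linear diffusion) or sqrt(D_P*p/2) (pressure-driven,
degenerate diffusion); no closed-form speed is attempted for the
cross-diffusion systems with infection — only empirical front tracking
applies there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import ModelParams, Trajectory, beta_tilde

__all__ = ["WaveResult", "FrontTrack", "speed_two_species",
           "speed_three_species", "front_density", "untreated_front_speed",
           "track_front", "growth_matrix_eigenvalue"]

_LAMBDA_BRACKET = (1.0e-2, 1.0e3)  # 1/mm


@dataclass(frozen=True)
class WaveResult:
    """A front speed (mm/h) with the minimising decay rate where defined."""

    speed: float
    decay_rate: float | None
    method: str
    invades: bool = True


def speed_two_species(params: ModelParams,
                      background_u: float | None = None) -> WaveResult:
    """Linear spreading speed of the infection in the reduced model."""
    if background_u is None:
        background_u = params.K
    bt = beta_tilde(params)
    growth = bt * background_u / params.K - params.q
    if growth < 0:
        return WaveResult(speed=0.0, decay_rate=None,
                          method="two-species", invades=False)
    c = 2.0 * np.sqrt(params.D_U * growth)
    lam = np.sqrt(growth / params.D_U) if growth > 0 else None
    return WaveResult(speed=float(c), decay_rate=lam, method="two-species")


def growth_matrix_eigenvalue(lam: float, params: ModelParams,
                             background_u: float) -> float:
    """Largest eigenvalue of M(lambda) for the linearised (i, v) subsystem."""
    a = params.D_U * lam * lam - params.q
    d = params.D_v * lam * lam - params.q_v
    bc = (params.beta * background_u / params.K) * params.alpha * params.q
    return 0.5 * (a + d) + np.sqrt(0.25 * (a - d) ** 2 + bc)


def speed_three_species(params: ModelParams,
                        background_u: float | None = None) -> WaveResult:
    """Minimal spreading speed for the explicit-virus system.

    Bracketed golden-section minimisation of mu_max(lambda)/lambda on a
    log-lambda interval.  Returns a no-invasion marker when the uniform
    mode has no positive growth (bt*u_b/K <= q).
    """
    if background_u is None:
        background_u = params.K
    mu0 = growth_matrix_eigenvalue(0.0, params, background_u)
    if mu0 <= 0:
        return WaveResult(speed=0.0, decay_rate=None,
                          method="three-species", invades=False)

    def c_of_logs(s: float) -> float:
        lam = np.exp(s)
        return growth_matrix_eigenvalue(lam, params, background_u) / lam

    res = minimize_scalar(c_of_logs,
                          bounds=(np.log(_LAMBDA_BRACKET[0]),
                                  np.log(_LAMBDA_BRACKET[1])),
                          method="bounded",
                          options={"xatol": 1.0e-12})
    lam_star = float(np.exp(res.x))
    return WaveResult(speed=float(res.fun), decay_rate=lam_star,
                      method="three-species")


def untreated_front_speed(params: ModelParams) -> float:
    """Invasion speed of the uninfected tumour under the movement rule."""
    if params.movement == "undirected":
        return float(2.0 * np.sqrt(params.D_U * params.p))
    return float(np.sqrt(params.D_P * params.p / 2.0))


def front_density(params: ModelParams, model: str = "U2") -> float:
    """Uninfected density at the front behind which the infection keeps up
    with the untreated tumour front.

    U2: closed form (q + p)*K/bt, the background at which the two-species
    infection speed equals 2*sqrt(D_U*p).  U3: the analogous root of
    speed_three_species(., u_b) = 2*sqrt(D_U*p), found by bracketed
    root-finding on (q*K/bt, K).
    """
    model = model.upper()
    bt = beta_tilde(params)
    if bt == 0:
        raise ValueError("front density undefined for beta_tilde = 0")
    if model == "U2":
        return float((params.q + params.p) * params.K / bt)
    if model != "U3":
        raise ValueError("model must be 'U2' or 'U3'")
    target = 2.0 * np.sqrt(params.D_U * params.p)

    def gap(ub: float) -> float:
        return speed_three_species(params, background_u=ub).speed - target

    lo = params.q * params.K / bt * (1.0 + 1.0e-9)
    hi = params.K
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo * g_hi > 0:
        raise ValueError(
            f"front density not bracketed in ({lo:.4g}, {hi:.4g}): "
            f"gap({lo:.4g}) = {g_lo:.3g}, gap({hi:.4g}) = {g_hi:.3g}"
        )
    return float(brentq(gap, lo, hi, xtol=1e-10 * params.K))


@dataclass
class FrontTrack:
    """Front positions over time with a least-squares speed estimate."""

    times: np.ndarray
    positions: np.ndarray

    def fit_speed(self, t_min: float | None = None,
                  t_max: float | None = None) -> float:
        t, x = self.times, self.positions
        mask = np.isfinite(x)
        if t_min is not None:
            mask &= t >= t_min
        if t_max is not None:
            mask &= t <= t_max
        if mask.sum() < 2:
            raise ValueError("fewer than two detected front positions in window")
        slope = np.polyfit(t[mask], x[mask], 1)[0]
        return float(slope)


def track_front(traj: Trajectory, species: str = "u",
                level: float | None = None) -> FrontTrack:
    """Outermost position where the species density reaches ``level``.

    ``level`` defaults to 0.05*K.  Positions are NaN at times with no site
    above the level; 2D lattice states are read along their central row.
    """
    if len(traj.states) < 3:
        raise ValueError("trajectory must contain at least 3 recorded states")
    if level is None:
        K = traj.meta.get("params", {}).get("K", 1.0)
        level = 0.05 * K
    positions = []
    for st in traj.states:
        x, arr = st.section(species)
        above = np.abs(arr) >= level
        if not above.any():
            positions.append(np.nan)
        else:
            positions.append(float(np.max(np.abs(x[above]))))
    return FrontTrack(times=np.asarray(traj.times),
                      positions=np.asarray(positions))
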