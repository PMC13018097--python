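"""Stochastic hybrid lattice simulator.

Integer cell counts per site undergo probabilistic lysis, infection,
division/death and movement; the viral concentration follows an explicit
balance equation forced by the (stochastic) number of lysed cells.  One
step applies, in order and with every probability evaluated on the
time-n state:

1. lysis            L_j ~ Binomial(I_j, tau*q), virions released at x_j
2. infection        each uninfected cell converts w.p. tau*beta*v_j/K
3. division/death   remaining uninfected cells divide w.p. tau*G(rho_j)_+
                    or die w.p. tau*G(rho_j)_-, G(rho) = p*(1 - rho/K)
4. movement         multinomial hop to a neighbour (theta/2d each side for
                    undirected movement, theta*(rho_j - rho_nb)_+/(2dK)
                    for pressure-driven movement) or stay
5. virus            v <- v + tau*D_v*lap(v) + alpha*L/delta^d - tau*q_v*v

Boundaries are reflecting for cells and virus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    InitialCondition,
    Lattice,
    ModelParams,
    StabilityError,
    Trajectory,
    make_initial_state,
    theta_from_diffusion,
)

__all__ = ["LatticeState", "EnsembleResult", "step", "simulate", "ensemble",
           "movement_probabilities"]


@dataclass
class LatticeState:
    """Hybrid state: integer counts U, I and real viral concentration v."""

    U: np.ndarray
    I: np.ndarray
    v: np.ndarray
    t: float
    delta: float
    dimension: int

    @property
    def measure(self) -> float:
        return self.delta ** self.dimension

    @property
    def u(self) -> np.ndarray:
        """Uninfected cell density U/delta^d."""
        return self.U / self.measure

    @property
    def i(self) -> np.ndarray:
        return self.I / self.measure

    @property
    def rho(self) -> np.ndarray:
        """Local pressure = total cell density."""
        return (self.U + self.I) / self.measure

    @property
    def axis(self) -> np.ndarray:
        n = (self.U.shape[0] - 1) // 2
        return np.arange(-n, n + 1) * self.delta

    def section(self, species: str = "u") -> tuple[np.ndarray, np.ndarray]:
        """(x, density) along the full axis (1D) or the central row (2D)."""
        arr = {"u": self.u, "i": self.i, "v": self.v,
               "total": self.rho}[species]
        if self.dimension == 2:
            arr = arr[(arr.shape[0] - 1) // 2]
        return self.axis, arr

    def copy(self) -> "LatticeState":
        return LatticeState(self.U.copy(), self.I.copy(), self.v.copy(),
                            self.t, self.delta, self.dimension)


def movement_probabilities(rho: np.ndarray, theta: float, params: ModelParams
                           ) -> list[np.ndarray]:
    """Per-site probabilities of hopping to each neighbour (stay excluded).

    Order: (left, right) in 1D; (row-1, row+1, col-1, col+1) in 2D.  Faces
    pointing out of the lattice carry probability zero (reflecting walls);
    for the pressure rule no probability is positive towards a site of
    equal or higher pressure.
    """
    d = params.dimension
    denom = 2 * d
    if params.movement == "undirected":
        probs = []
        for axis in range(d):
            for shift in (-1, 1):
                F = np.full_like(rho, theta / denom, dtype=float)
                idx = [slice(None)] * d
                idx[axis] = 0 if shift == -1 else -1
                F[tuple(idx)] = 0.0
                probs.append(F)
        return probs
    # pressure-driven: edge padding makes the out-of-domain difference zero
    padded = np.pad(rho, 1, mode="edge")
    probs = []
    core = tuple(slice(1, -1) for _ in range(d))
    for axis in range(d):
        for shift in (-1, 1):
            nb = np.roll(padded, -shift, axis=axis)[core]
            F = theta * np.clip(rho - nb, 0.0, None) / (denom * params.K)
            probs.append(F)
    return probs


def _apply_moves(X: np.ndarray, probs: list[np.ndarray],
                 rng: np.random.Generator) -> np.ndarray:
    """Multinomial redistribution of the counts in X along ``probs``.

    Sampling is restricted to occupied sites; on the sparse lattices of the
    2D experiments this dominates the step cost otherwise.
    """
    k = len(probs)
    flat = X.ravel()
    occ = np.flatnonzero(flat)
    if occ.size == 0:
        return X.copy()
    pvals = np.empty((occ.size, k + 1))
    for ci, F in enumerate(probs):
        pvals[:, ci] = F.ravel()[occ]
    pvals[:, k] = 1.0 - pvals[:, :k].sum(axis=1)
    counts = rng.multinomial(flat[occ], pvals)
    new = np.zeros_like(X)
    new.ravel()[occ] = counts[:, k]
    d = X.ndim
    moved = np.zeros_like(X)
    ci = 0
    for axis in range(d):
        for shift in (-1, 1):
            moved.ravel()[:] = 0
            moved.ravel()[occ] = counts[:, ci]
            dst = [slice(None)] * d
            src = [slice(None)] * d
            if shift == -1:
                dst[axis], src[axis] = slice(None, -1), slice(1, None)
            else:
                dst[axis], src[axis] = slice(1, None), slice(None, -1)
            new[tuple(dst)] += moved[tuple(src)]
            ci += 1
    return new


def _laplacian(v: np.ndarray, delta: float) -> np.ndarray:
    """Discrete Laplacian with reflecting (zero-flux) boundaries."""
    out = np.zeros_like(v)

    def sl(axis, s):
        idx = [slice(None)] * v.ndim
        idx[axis] = s
        return tuple(idx)

    for axis in range(v.ndim):
        if v.shape[axis] == 1:
            continue  # a single site has no flux anywhere
        out[sl(axis, slice(1, -1))] += (v[sl(axis, slice(2, None))]
                                        + v[sl(axis, slice(None, -2))]
                                        - 2 * v[sl(axis, slice(1, -1))])
        # reflecting walls: the outside ghost equals the edge value
        out[sl(axis, 0)] += v[sl(axis, 1)] - v[sl(axis, 0)]
        out[sl(axis, -1)] += v[sl(axis, -2)] - v[sl(axis, -1)]
    return out / delta ** 2


def _bounding_slices(tot: np.ndarray) -> tuple[slice, ...] | None:
    """Slices covering all occupied sites plus a one-site halo."""
    if tot.ndim == 1:
        occ = np.flatnonzero(tot)
        if occ.size == 0:
            return None
        return (slice(max(occ[0] - 1, 0), min(occ[-1] + 2, tot.shape[0])),)
    rows = np.flatnonzero(tot.any(axis=1))
    if rows.size == 0:
        return None
    cols = np.flatnonzero(tot.any(axis=0))
    return (slice(max(rows[0] - 1, 0), min(rows[-1] + 2, tot.shape[0])),
            slice(max(cols[0] - 1, 0), min(cols[-1] + 2, tot.shape[1])))


def _check_prob(p: np.ndarray | float, label: str) -> None:
    pmax = float(np.max(p))
    if pmax > 1.0 or np.min(p) < 0.0:
        raise StabilityError(f"{label} probability leaves [0, 1] (max {pmax:.3g})")


def step(state: LatticeState, params: ModelParams,
         rng: np.random.Generator) -> LatticeState:
    """One synchronous update of the hybrid lattice model."""
    tau = params.tau
    meas = state.measure
    U, I, v = state.U, state.I, state.v

    # all cell events happen inside the occupied bounding box (plus a
    # one-site halo for movement); the virus is updated on the full lattice
    bbox = _bounding_slices(U + I)
    L = np.zeros_like(U)
    U_new = np.zeros_like(U)
    I_new = np.zeros_like(I)
    _check_prob(tau * params.q, "lysis")
    if bbox is not None:
        Ub, Ib, vb = U[bbox], I[bbox], v[bbox]
        rho_b = (Ub + Ib) / meas
        occ = np.flatnonzero((Ub + Ib).ravel())
        U_f, I_f = Ub.ravel()[occ], Ib.ravel()[occ]

        # 1. lysis of infected cells; virions released at the time-n site
        L_f = rng.binomial(I_f, tau * params.q)
        Lb = np.zeros_like(Ib)
        Lb.ravel()[occ] = L_f
        L[bbox] = Lb

        # 2. infection of uninfected cells by local free virions
        p_inf = tau * params.beta * vb.ravel()[occ] / params.K
        _check_prob(p_inf, "infection")
        C_f = rng.binomial(U_f, p_inf)

        # 3. density-regulated division/death of remaining uninfected cells
        G = params.p * (1.0 - rho_b.ravel()[occ] / params.K)
        p_div = tau * np.clip(G, 0.0, None)
        p_die = -tau * np.clip(G, None, 0.0)
        _check_prob(p_div + p_die, "division/death")
        U_f2 = U_f - C_f
        U_f2 = U_f2 + rng.binomial(U_f2, p_div) - rng.binomial(U_f2, p_die)
        Ub_new = np.zeros_like(Ub)
        Ib_new = np.zeros_like(Ib)
        Ub_new.ravel()[occ] = U_f2
        Ib_new.ravel()[occ] = I_f - L_f + C_f

        # 4. movement of all cells, probabilities from the time-n pressure;
        # halo sites are empty, so treating the box edge as a wall is exact
        # unless it coincides with the true (reflecting) domain wall
        theta = theta_from_diffusion(params)
        if theta > 0:
            probs = movement_probabilities(rho_b, theta, params)
            Ub_new = _apply_moves(Ub_new, probs, rng)
            Ib_new = _apply_moves(Ib_new, probs, rng)
        U_new[bbox] = Ub_new
        I_new[bbox] = Ib_new

    # 5. explicit viral balance forced by the sampled lysis counts
    v_new = (v + tau * params.D_v * _laplacian(v, params.delta)
             + params.alpha * L / meas - tau * params.q_v * v)

    return LatticeState(U=U_new, I=I_new, v=v_new, t=state.t + tau,
                        delta=state.delta, dimension=state.dimension)


def _boundary_occupied(state: LatticeState) -> bool:
    tot = state.U + state.I
    if state.dimension == 1:
        return bool(tot[0] > 0 or tot[-1] > 0)
    return bool(tot[0].any() or tot[-1].any()
                or tot[:, 0].any() or tot[:, -1].any())


def simulate(params: ModelParams, ic: InitialCondition | None = None,
             horizon: float = 100.0, seed: int = 1, record_every: int = 100,
             half_width: float | None = None,
             initial_state: LatticeState | None = None) -> Trajectory:
    """Run the hybrid simulator for ``horizon`` hours.

    Reproducible given (params, ic, seed).  Records the state every
    ``record_every`` steps; scalar totals and extinction times go into
    ``Trajectory.totals`` / ``Trajectory.meta``.  A warning is emitted if
    cells ever reach the outermost lattice sites.
    """
    if ic is None:
        ic = InitialCondition.from_params(params)
    if initial_state is None:
        if half_width is None:
            half_width = ic.max_radius + 3.0
        lattice = Lattice(delta=params.delta, half_width=half_width,
                          dimension=params.dimension)
        state = make_initial_state(ic, lattice, params, target="abm")
    else:
        state = initial_state.copy()

    nsteps = int(round(horizon / params.tau))
    rng = np.random.default_rng(seed)

    times = [state.t]
    states = [state.copy()]
    tot_U = [int(state.U.sum())]
    tot_I = [int(state.I.sum())]
    tot_v = [float(state.v.sum() * state.measure)]
    ext_time_u = np.inf
    first_zero_i = np.inf if state.I.sum() > 0 else state.t
    last_zero_i = state.t if state.I.sum() == 0 else np.inf
    boundary_hit = False

    for n in range(1, nsteps + 1):
        state = step(state, params, rng)
        su, si = int(state.U.sum()), int(state.I.sum())
        if su == 0 and not np.isfinite(ext_time_u):
            ext_time_u = state.t
        if si == 0:
            if not np.isfinite(first_zero_i):
                first_zero_i = state.t
            last_zero_i = state.t
        if not boundary_hit and _boundary_occupied(state):
            boundary_hit = True
            warnings.warn("cells reached the lattice boundary buffer; "
                          "enlarge half_width", stacklevel=2)
        if n % record_every == 0 or n == nsteps:
            times.append(state.t)
            states.append(state.copy())
            tot_U.append(su)
            tot_I.append(si)
            tot_v.append(float(state.v.sum() * state.measure))

    return Trajectory(
        times=np.asarray(times),
        states=states,
        totals={
            "total_U": np.asarray(tot_U),
            "total_I": np.asarray(tot_I),
            "total_v": np.asarray(tot_v),
        },
        meta={
            "kind": "abm",
            "seed": seed,
            "params": params.to_dict(),
            "ext_time_u": ext_time_u,
            "first_zero_i": first_zero_i,
            "last_zero_i": last_zero_i,
            "boundary_hit": boundary_hit,
        },
    )


@dataclass
class EnsembleResult:
    """Per-replicate extinction times and totals across seeded runs."""

    times: np.ndarray          # shared recording grid (h)
    total_U: np.ndarray        # (M, T) uninfected counts
    total_I: np.ndarray        # (M, T) infected counts
    ext_time_u: np.ndarray     # (M,) first time sum(U) = 0, inf if never
    first_zero_i: np.ndarray   # (M,) first time sum(I) = 0
    last_zero_i: np.ndarray    # (M,) last recorded time sum(I) = 0
    final_U: np.ndarray
    final_I: np.ndarray
    seeds: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.seeds)

    def final_cells_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "replicate": np.arange(self.M),
            "seed": self.seeds,
            "final_cells": self.final_U + self.final_I,
        })


def ensemble(params: ModelParams, ic: InitialCondition | None = None,
             horizon: float = 100.0, M: int = 5, base_seed: int = 1,
             record_every: int = 100, half_width: float | None = None,
             keep_states: bool = False) -> EnsembleResult:
    """Run ``M`` independent replicates with seeds base_seed..base_seed+M-1."""
    if M < 1:
        raise ValueError("M must be >= 1")
    seeds = np.arange(base_seed, base_seed + M)
    rows_U, rows_I = [], []
    ext_u, fz_i, lz_i, fin_U, fin_I = [], [], [], [], []
    times = None
    for s in seeds:
        traj = simulate(params, ic=ic, horizon=horizon, seed=int(s),
                        record_every=record_every, half_width=half_width)
        if times is None:
            times = traj.times
        rows_U.append(traj.totals["total_U"])
        rows_I.append(traj.totals["total_I"])
        ext_u.append(traj.meta["ext_time_u"])
        fz_i.append(traj.meta["first_zero_i"])
        lz_i.append(traj.meta["last_zero_i"])
        fin_U.append(traj.totals["total_U"][-1])
        fin_I.append(traj.totals["total_I"][-1])
    return EnsembleResult(
        times=times,
        total_U=np.asarray(rows_U),
        total_I=np.asarray(rows_I),
        ext_time_u=np.asarray(ext_u, dtype=float),
        first_zero_i=np.asarray(fz_i, dtype=float),
        last_zero_i=np.asarray(lz_i, dtype=float),
        final_U=np.asarray(fin_U),
        final_I=np.asarray(fin_I),
        seeds=seeds,
        meta={"params": params.to_dict(), "horizon": horizon},
    )
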