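"""Parameters, derived quantities, grids and initial conditions.

Everything downstream (lattice simulator, PDE solvers, ODE analysis,
wave-speed theory) reads its rates and scales from :class:`ModelParams`.
The module also owns the flat key/value configuration dialect used by the
command line interface.
"""

from __future__ import annotations

import configparser
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "StabilityError",
    "ModelParams",
    "Plateau",
    "InitialCondition",
    "Lattice",
    "Trajectory",
    "beta_tilde",
    "theta_from_diffusion",
    "matched_pressure_diffusion",
    "make_initial_state",
    "validate",
    "load_config",
    "RunSetup",
    "preset_path",
    "K_DEFAULTS",
    "V0_DEFAULTS",
]


class ConfigError(ValueError):
    """Malformed parameter set or configuration file."""


class StabilityError(ValueError):
    """A discretisation violates a probability bound or a CFL condition."""


#: Carrying capacity per spatial dimension (cells/mm, cells/mm^2).
K_DEFAULTS = {1: 1.0e3, 2: 1.0e4}
#: Initial viral plateau height per spatial dimension.
V0_DEFAULTS = {1: 2.67e4, 2: (2.67e3) ** 2}

MOVEMENT_RULES = ("undirected", "pressure")

_RATE_FIELDS = ("p", "q", "q_v", "alpha", "beta", "D_U", "D_P", "D_v")
_POSITIVE_FIELDS = ("K", "tau", "delta")
_NONNEG_FIELDS = ("R_u", "R_v", "R_i", "V_0")


@dataclass(frozen=True)
class ModelParams:
    """All biological/viral rates and scales plus lattice discretisation.

    Units: rates in 1/h, diffusivities in mm^2/h, lengths in mm, densities
    in cells per mm (1D) or per mm^2 (2D).  ``alpha`` is the viral burst
    size (virions released per lysed cell) and ``beta`` the infection rate;
    the infection probability per cell and step is ``tau*beta*v/K``.
    """

    p: float = 1.87e-2
    q: float = 4.17e-2
    q_v: float = 1.67e-1
    alpha: float = 580.0
    beta: float = 7.00e-4
    D_U: float = 1.88e-4
    D_P: float = 1.50e-3
    D_v: float = 1.00e-2
    K: float = 1.0e3
    R_u: float = 2.6
    R_v: float = 0.5
    R_i: float = 0.0
    V_0: float = 2.67e4
    tau: float = 0.02
    delta: float = 0.1
    movement: str = "undirected"
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.movement not in MOVEMENT_RULES:
            raise ConfigError(
                f"movement must be one of {MOVEMENT_RULES}, got {self.movement!r}"
            )
        if self.dimension not in (1, 2):
            raise ConfigError(f"dimension must be 1 or 2, got {self.dimension!r}")
        for name in _RATE_FIELDS + _NONNEG_FIELDS:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")

    @classmethod
    def reference(cls, dimension: int = 1, movement: str = "undirected",
                  **overrides: Any) -> "ModelParams":
        """Reference parameter set with the dimension-matched K and V_0."""
        kw: dict[str, Any] = dict(
            dimension=dimension,
            movement=movement,
            K=K_DEFAULTS[dimension],
            V_0=V0_DEFAULTS[dimension],
        )
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    @property
    def cell_diffusivity(self) -> float:
        """Diffusivity selected by the movement rule (D_U or D_P)."""
        return self.D_U if self.movement == "undirected" else self.D_P

    @property
    def site_measure(self) -> float:
        """delta (1D) or delta^2 (2D): converts site counts to densities."""
        return self.delta ** self.dimension

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def beta_tilde(params: ModelParams) -> float:
    """Effective cell-to-cell infection rate beta*alpha*q/q_v (1/h).

    Obtained by eliminating the virus under the quasi-steady assumption
    v ~= (alpha*q/q_v) * i.  Invariant under joint rescaling of
    (alpha, q_v) by the same factor.
    """
    if params.q_v == 0:
        raise ZeroDivisionError("q_v = 0: quasi-steady infection rate undefined")
    return params.beta * params.alpha * params.q / params.q_v


def theta_from_diffusion(params: ModelParams, diffusivity: float | None = None) -> float:
    """Per-step movement probability theta matching the target diffusivity.

    theta = 2*tau*D/delta^2 in 1D and 4*tau*D/delta^2 in 2D, with D chosen
    by the movement rule unless ``diffusivity`` is given explicitly.
    """
    D = params.cell_diffusivity if diffusivity is None else diffusivity
    theta = 2 * params.dimension * params.tau * D / params.delta ** 2
    if theta > 1.0:
        raise StabilityError(
            f"theta = {theta:.3g} > 1: lattice too coarse for D = {D:.3g}"
        )
    return theta


def matched_pressure_diffusion(D_U: float, p: float | None = None) -> float:
    """D_P that equalises the two untreated front speeds.

    Solves 2*sqrt(D_U*p) = sqrt(D_P*p/2), i.e. D_P = 8*D_U; the growth
    rate p cancels and is accepted only for signature clarity.
    """
    if D_U < 0:
        raise ValueError("D_U must be non-negative")
    return 8.0 * D_U


@dataclass(frozen=True)
class Plateau:
    """Piecewise-constant radial profile: ``height`` on \\|x\\| <= radius."""

    height: float
    radius: float

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ConfigError("plateau height must be non-negative")
        if self.radius < 0:
            raise ConfigError("plateau radius must be non-negative")

    def profile(self, r: np.ndarray) -> np.ndarray:
        # half-open tolerance so a node sitting exactly on the radius is inside
        return np.where(np.abs(r) <= self.radius * (1 + 1e-12) + 1e-15,
                        float(self.height), 0.0)


@dataclass(frozen=True)
class InitialCondition:
    """Initial plateaux for uninfected cells, infected cells and virus."""

    u0: Plateau
    i0: Plateau
    v0: Plateau

    @classmethod
    def from_params(cls, params: ModelParams) -> "InitialCondition":
        return cls(
            u0=Plateau(0.9 * params.K, params.R_u),
            i0=Plateau(0.0, params.R_i),
            v0=Plateau(params.V_0, params.R_v),
        )

    def quasi_steady_equivalent(self, params: "ModelParams") -> "InitialCondition":
        """Map the viral plateau onto infected cells for the two-species
        reductions.

        Models without an explicit virus cannot be seeded by free virions;
        the quasi-steady relation v = (alpha*q/q_v)*i converts the initial
        viral load into the equivalent infected-cell plateau
        i0 = q_v*v0/(alpha*q) on the same support.
        """
        if params.alpha * params.q == 0:
            return InitialCondition(u0=self.u0, i0=self.i0,
                                    v0=Plateau(0.0, 0.0))
        i_height = self.i0.height + self.v0.height * params.q_v / (
            params.alpha * params.q)
        radius = max(self.i0.radius, self.v0.radius) if i_height > 0 else 0.0
        return InitialCondition(u0=self.u0,
                                i0=Plateau(i_height, radius),
                                v0=Plateau(0.0, 0.0))

    @property
    def max_radius(self) -> float:
        """Largest finite plateau radius (an infinite radius means the
        plateau fills whatever domain it is realised on)."""
        radii = [p.radius for p in (self.u0, self.i0, self.v0)
                 if np.isfinite(p.radius)]
        return max(radii, default=0.0)


@dataclass(frozen=True)
class Lattice:
    """Uniform lattice for the agent-based simulator.

    Sites are at j*delta for j in [-n, n] along each axis, with
    n = round(half_width/delta); 2D uses the tensor grid.
    """

    delta: float
    half_width: float
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.half_width <= 0:
            raise ConfigError("delta and half_width must be positive")

    @property
    def n_side(self) -> int:
        return 2 * int(round(self.half_width / self.delta)) + 1

    @property
    def axis(self) -> np.ndarray:
        n = int(round(self.half_width / self.delta))
        return np.arange(-n, n + 1) * self.delta

    def radii(self) -> np.ndarray:
        ax = self.axis
        if self.dimension == 1:
            return np.abs(ax)
        return np.hypot(ax[:, None], ax[None, :])

    @property
    def measure(self) -> float:
        return self.delta ** self.dimension


@dataclass
class Trajectory:
    """Time-stamped states plus scalar summaries of one run.

    ``totals`` holds physical totals: cell/virion numbers for the lattice
    model, integrals of the densities (with the radial measure where
    applicable) for the PDE solvers.
    """

    times: np.ndarray
    states: list
    totals: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def index_at(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def state_at(self, t: float):
        return self.states[self.index_at(t)]

    def summary_frame(self) -> pd.DataFrame:
        data = {"t": self.times}
        data.update(self.totals)
        return pd.DataFrame(data)


def make_initial_state(ic: InitialCondition, grid, params: ModelParams,
                       target: str = "abm"):
    """Realise an :class:`InitialCondition` on a grid.

    ``target='abm'`` builds a :class:`virowave.abm.LatticeState` with integer
    counts ``round(height * delta^d)`` per site inside each plateau;
    ``target='pde'`` samples the densities at the nodes of a
    :class:`virowave.pde.GridSpec`.
    """
    for plat, name in ((ic.u0, "u0"), (ic.i0, "i0")):
        if plat.height > params.K * (1 + 1e-12):
            raise ConfigError(f"{name} plateau height {plat.height} exceeds K")

    if target == "abm":
        from .abm import LatticeState

        if grid.half_width < ic.max_radius:
            raise ConfigError("lattice does not span the initial plateaux")
        r = grid.radii()
        meas = grid.measure
        U = np.rint(ic.u0.profile(r) * meas).astype(np.int64)
        I = np.rint(ic.i0.profile(r) * meas).astype(np.int64)
        v = ic.v0.profile(r).astype(float)
        return LatticeState(U=U, I=I, v=v, t=0.0,
                            delta=grid.delta, dimension=grid.dimension)
    if target == "pde":
        from .pde import FieldState

        x = grid.x
        if grid.L < ic.max_radius:
            raise ConfigError("grid does not span the initial plateaux")
        r = np.abs(x)
        return FieldState(
            u=ic.u0.profile(r).astype(float),
            i=ic.i0.profile(r).astype(float),
            v=ic.v0.profile(r).astype(float),
            t=0.0,
            x=x,
            radial=grid.radial,
        )
    raise ValueError(f"unknown target {target!r}")


def validate(params: ModelParams, grid=None) -> list[str]:
    """Return the list of violated probability/stability constraints.

    Empty for the reference parameters at tau=0.02 h, delta=0.1 mm.  The
    reachable viral bound used for the infection probability is
    max(V_0, alpha*q*K/q_v) (initial plateau vs quasi-steady level at
    carrying capacity).
    """
    report: list[str] = []
    tau, delta = params.tau, params.delta
    # net growth magnitude is bounded by p for densities up to 2K
    if tau * 2 * params.p > 1:
        report.append(f"tau*|G| = {tau * 2 * params.p:.3g} > 1 (division/death)")
    if tau * params.q > 1:
        report.append(f"tau*q = {tau * params.q:.3g} > 1 (lysis probability)")
    if tau * params.q_v > 1:
        report.append(f"tau*q_v = {tau * params.q_v:.3g} > 1 (viral decay)")
    v_bound = params.V_0
    if params.q_v > 0:
        v_bound = max(v_bound, params.alpha * params.q * params.K / params.q_v)
    if tau * params.beta * v_bound / params.K > 1:
        report.append(
            f"tau*beta*v/K = {tau * params.beta * v_bound / params.K:.3g} > 1 "
            "for reachable v (infection probability)"
        )
    if tau * params.D_v / delta ** 2 > 0.5:
        report.append(
            f"tau*D_v/delta^2 = {tau * params.D_v / delta ** 2:.3g} > 1/2 "
            "(explicit viral scheme unstable)"
        )
    try:
        theta_from_diffusion(params)
    except StabilityError as exc:
        report.append(str(exc))
    if params.K != K_DEFAULTS[params.dimension]:
        report.append(
            f"warning: K = {params.K:.3g} differs from the reference value "
            f"{K_DEFAULTS[params.dimension]:.3g} for dimension {params.dimension}"
        )
    if grid is not None:
        dx = getattr(grid, "dx", None)
        dt = getattr(grid, "dt", None)
        if dx is not None and dt is not None:
            Dmax = max(params.D_U, params.D_v)
            if dt * Dmax / dx ** 2 > 0.5:
                report.append(
                    f"dt*D/dx^2 = {dt * Dmax / dx ** 2:.3g} > 1/2 (PDE CFL)"
                )
    return report


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------

_MODEL_KEYS = {"p", "q", "q_v", "alpha", "beta", "D_U", "D_P", "D_v", "K",
               "movement", "dimension"}
_NUMERICS_KEYS = {"tau", "delta", "dx", "dt", "L", "radial"}
_INITIAL_KEYS = {"R_u", "R_v", "R_i", "V_0", "u0_height", "i0_height"}
_RUN_KEYS = {"horizon", "record_every", "seed", "replicates", "model",
             "half_width", "alpha_values", "q_v_values", "D_v_values"}
_SECTIONS = {
    "model": _MODEL_KEYS,
    "numerics": _NUMERICS_KEYS,
    "initial": _INITIAL_KEYS,
    "run": _RUN_KEYS,
}
_STRING_KEYS = {"movement", "model"}
_INT_KEYS = {"dimension", "record_every", "seed", "replicates"}
_BOOL_KEYS = {"radial"}
_LIST_KEYS = {"alpha_values", "q_v_values", "D_v_values"}


@dataclass
class RunSetup:
    """Resolved content of a configuration file."""

    params: ModelParams
    numerics: dict[str, Any]
    run: dict[str, Any]

    @property
    def initial_condition(self) -> InitialCondition:
        ic = InitialCondition.from_params(self.params)
        heights = self.run.get("_heights", {})
        if heights:
            u0 = Plateau(heights.get("u0_height", ic.u0.height), ic.u0.radius)
            i0 = Plateau(heights.get("i0_height", ic.i0.height), ic.i0.radius)
            ic = InitialCondition(u0=u0, i0=i0, v0=ic.v0)
        return ic


def _coerce(section: str, key: str, raw: str):
    if key in _STRING_KEYS:
        return raw.strip()
    if key in _BOOL_KEYS:
        val = raw.strip().lower()
        if val in ("true", "yes", "1"):
            return True
        if val in ("false", "no", "0"):
            return False
        raise ConfigError(f"[{section}] {key}: cannot parse boolean from {raw!r}")
    if key in _LIST_KEYS:
        try:
            return [float(tok) for tok in raw.replace(",", " ").split()]
        except ValueError as exc:
            raise ConfigError(f"[{section}] {key}: {exc}") from exc
    try:
        val = float(raw)
    except ValueError as exc:
        raise ConfigError(f"[{section}] {key}: cannot parse number from {raw!r}") from exc
    if key in _INT_KEYS:
        return int(round(val))
    return val


def load_config(path: str | Path) -> RunSetup:
    """Parse a configuration file into a :class:`RunSetup`.

    Unknown sections or keys are rejected with the offending name in the
    message.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keep key case (D_U vs d_u)
    cp.read(path)

    values: dict[str, dict[str, Any]] = {s: {} for s in _SECTIONS}
    for section in cp.sections():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section [{section}] in {path.name}")
        for key, raw in cp.items(section):
            if key not in _SECTIONS[section]:
                raise ConfigError(
                    f"unknown key {key!r} in section [{section}] of {path.name}"
                )
            values[section][key] = _coerce(section, key, raw)

    param_kw: dict[str, Any] = {}
    param_kw.update(values["model"])
    for key in ("tau", "delta"):
        if key in values["numerics"]:
            param_kw[key] = values["numerics"][key]
    for key in ("R_u", "R_v", "R_i", "V_0"):
        if key in values["initial"]:
            param_kw[key] = values["initial"][key]
    params = ModelParams(**param_kw)

    numerics = {k: v for k, v in values["numerics"].items()
                if k in ("dx", "dt", "L", "radial")}
    run = dict(values["run"])
    heights = {k: v for k, v in values["initial"].items()
               if k in ("u0_height", "i0_height")}
    if heights:
        run["_heights"] = heights
    return RunSetup(params=params, numerics=numerics, run=run)


def preset_path(name: str) -> Path:
    """Path of a bundled configuration file (e.g. ``table1``)."""
    here = Path(__file__).parent / "presets" / f"{name}.cfg"
    if not here.exists():
        available = sorted(p.stem for p in (Path(__file__).parent / "presets").glob("*.cfg"))
        raise ConfigError(f"unknown preset {name!r}; available: {available}")
    return here
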