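"""Forward simulation of the discretized anisotropic wave equation.

The continuum Euler-Lagrange equation of the anisotropic wave Lagrangian,

    phidotdot = phi_xx + phi**(2*beta) * phi_yy + beta * phi**(2*beta-1) * phi_y**2,

is discretized on a regular 2D grid with the standard stencils

    phi_y  -> (phi(x, y+1) - phi(x, y-1)) / 2
    phi_xx -> phi(x+1, y) - 2*phi(x, y) + phi(x-1, y)
    phi_yy -> phi(x, y+1) - 2*phi(x, y) + phi(x, y-1)

and split into two first-order equations by introducing theta = phidot:

    dphi/dt   = theta
    dtheta/dt = phi_xx + phi**(2*beta) * phi_yy
                + beta * phi**(2*beta-1) * phi_y**2.

At beta = 0 this is exactly the 5-point discrete wave equation. The
observer assumes the field strength phi(x, y) itself is measured at every
node, with additive i.i.d. Gaussian noise.

Grid axes: the first array axis is x (the direction with the plain
Laplacian coupling), the second is y (the direction carrying the
anisotropic phi**(2*beta) coupling). Node flattening is row-major, i.e.
y varies fastest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from anisofield.exceptions import DomainError, IntegrationError

__all__ = [
    "BoundarySpec",
    "FieldState",
    "SimulationConfig",
    "Trajectory",
    "discrete_derivatives",
    "eom_rhs",
    "integrate",
    "observe",
    "phase_embed",
    "node_columns",
]

_BOUNDARY_MODES = ("mirror", "periodic", "fixed")


@dataclass(frozen=True)
class BoundarySpec:
    """Edge handling for the spatial stencils.

    ``mirror`` (default) is zero-flux: the ghost value one step outside the
    grid mirrors the value one step inside, so a uniform field stays a
    fixed point. ``periodic`` wraps; ``fixed`` pads with a constant value.
    """

    mode: str = "mirror"
    fixed_values: float | None = None

    def __post_init__(self):
        if self.mode not in _BOUNDARY_MODES:
            raise ValueError(f"boundary mode must be one of {_BOUNDARY_MODES}")
        if self.mode == "fixed" and self.fixed_values is None:
            raise ValueError("fixed boundary requires fixed_values")
        if self.mode != "fixed" and self.fixed_values is not None:
            raise ValueError("fixed_values only valid with mode='fixed'")


@dataclass
class FieldState:
    """Field amplitude ``phi`` and its rate of change ``theta`` on a grid."""

    phi: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.phi.shape != self.theta.shape:
            raise ValueError(
                f"phi and theta shapes differ: {self.phi.shape} vs {self.theta.shape}"
            )
        if self.phi.ndim != 2 or min(self.phi.shape) < 1:
            raise ValueError(f"expected a 2D grid of size >= 1x1, got {self.phi.shape}")
        if not (np.isfinite(self.phi).all() and np.isfinite(self.theta).all()):
            raise ValueError("field state contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.phi.shape

    def copy(self) -> "FieldState":
        return FieldState(self.phi.copy(), self.theta.copy())


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a forward simulation.

    ``beta`` may be None for configs used purely as inversion scaffolding
    (the inversion estimates it).
    """

    beta: float | None = None
    dt: float = 0.05
    n_steps: int = 200
    integrator: str = "rk4"
    boundary: BoundarySpec = field(default_factory=BoundarySpec)
    obs_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not self.n_steps >= 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.integrator not in ("rk4", "euler"):
            raise ValueError(f"integrator must be 'rk4' or 'euler', got {self.integrator!r}")
        if self.obs_noise_sd < 0:
            raise ValueError(f"obs_noise_sd must be >= 0, got {self.obs_noise_sd}")

    def with_beta(self, beta: float) -> "SimulationConfig":
        return replace(self, beta=beta)

    def to_dict(self) -> dict:
        d = {
            "beta": self.beta,
            "dt": self.dt,
            "n_steps": self.n_steps,
            "integrator": self.integrator,
            "boundary": {"mode": self.boundary.mode},
            "obs_noise_sd": self.obs_noise_sd,
            "seed": self.seed,
        }
        if self.boundary.fixed_values is not None:
            d["boundary"]["fixed_values"] = self.boundary.fixed_values
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        bnd = d.pop("boundary", None)
        boundary = BoundarySpec(**bnd) if bnd else BoundarySpec()
        return cls(boundary=boundary, **d)


@dataclass
class Trajectory:
    """Simulated field history: uniformly spaced times and state grids."""

    times: np.ndarray
    phis: np.ndarray  # (n_times, H, W)
    thetas: np.ndarray  # (n_times, H, W)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.phis = np.asarray(self.phis, dtype=float)
        self.thetas = np.asarray(self.thetas, dtype=float)
        if self.times.ndim != 1 or len(self.times) != self.phis.shape[0]:
            raise ValueError("times must align with states")
        if self.phis.shape != self.thetas.shape:
            raise ValueError("phi and theta histories must share a shape")
        diffs = np.diff(self.times)
        if len(diffs) and (np.any(diffs <= 0) or not np.allclose(diffs, diffs[0])):
            raise ValueError("times must be strictly increasing with uniform spacing")

    def __len__(self) -> int:
        return len(self.times)

    def state(self, i: int) -> FieldState:
        return FieldState(self.phis[i], self.thetas[i])

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.phis.shape[1:]


def _pad(phi: np.ndarray, boundary: BoundarySpec) -> np.ndarray:
    """Pad the trailing two (spatial) axes by one ghost cell per side."""
    nd = phi.ndim
    width = [(0, 0)] * (nd - 2) + [(1, 1), (1, 1)]
    if boundary.mode == "periodic":
        return np.pad(phi, width, mode="wrap")
    if boundary.mode == "fixed":
        return np.pad(phi, width, mode="constant", constant_values=boundary.fixed_values)
    # mirror (zero-flux): ghost mirrors the value one step inside; for a
    # size-1 axis the only sensible zero-flux ghost is the edge itself.
    out = phi
    for ax_off, ax in enumerate((nd - 2, nd - 1)):
        w = [(0, 0)] * nd
        w[ax] = (1, 1)
        mode = "reflect" if out.shape[ax] > 1 else "edge"
        out = np.pad(out, w, mode=mode)
    return out


def discrete_derivatives(
    phi: np.ndarray, x: int, y: int, boundary: BoundarySpec | None = None
):
    """Discrete stencils at one node: ``(phi_y, phi_xx, phi_yy)``.

    ``phi_y`` is the centred first difference along y, ``phi_xx`` and
    ``phi_yy`` the second differences along x and y; out-of-grid
    neighbours are resolved by the boundary mode.
    """
    boundary = boundary or BoundarySpec()
    phi = np.asarray(phi, dtype=float)
    if phi.ndim != 2:
        raise ValueError("phi must be a 2D grid")
    h, w = phi.shape
    if not (0 <= x < h and 0 <= y < w):
        raise IndexError(f"node ({x}, {y}) outside grid of shape {phi.shape}")
    p = _pad(phi, boundary)
    i, j = x + 1, y + 1
    phi_y = 0.5 * (p[i, j + 1] - p[i, j - 1])
    phi_xx = p[i + 1, j] - 2.0 * p[i, j] + p[i - 1, j]
    phi_yy = p[i, j + 1] - 2.0 * p[i, j] + p[i, j - 1]
    return float(phi_y), float(phi_xx), float(phi_yy)


def _beta_is_integerlike(beta) -> bool:
    """True when 2*beta and 2*beta - 1 are both integers, i.e. beta integral."""
    b = np.asarray(beta)
    return bool(np.all(np.equal(np.mod(b, 1.0), 0.0)))


def _pow(phi: np.ndarray, expnt) -> np.ndarray:
    """Elementwise power without domain checks (non-finite values flow through)."""
    e = np.asarray(expnt, dtype=float)
    if e.ndim == 0 and float(e).is_integer():
        with np.errstate(divide="ignore", over="ignore"):
            return phi ** int(e)
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        return np.power(phi, e)


def _rhs(phi: np.ndarray, theta: np.ndarray, beta, boundary: BoundarySpec):
    """Equations of motion on (possibly batched) grids; no domain checks.

    ``phi``/``theta`` have shape ``(..., H, W)``; ``beta`` broadcasts
    against them (a scalar, a per-batch array of shape ``(..., 1, 1)``, or
    a per-node grid).
    """
    p = _pad(phi, boundary)
    core = (slice(None),) * (phi.ndim - 2)
    lap_x = p[core + (slice(2, None), slice(1, -1))] - 2.0 * phi + p[core + (slice(None, -2), slice(1, -1))]
    lap_y = p[core + (slice(1, -1), slice(2, None))] - 2.0 * phi + p[core + (slice(1, -1), slice(None, -2))]
    grad_y = 0.5 * (p[core + (slice(1, -1), slice(2, None))] - p[core + (slice(1, -1), slice(None, -2))])
    with np.errstate(invalid="ignore", over="ignore"):
        dtheta = lap_x + _pow(phi, 2.0 * np.asarray(beta)) * lap_y \
            + np.asarray(beta) * _pow(phi, 2.0 * np.asarray(beta) - 1.0) * grad_y**2
    return theta, dtheta


def eom_rhs(state: FieldState, beta: float, boundary: BoundarySpec | None = None):
    """Time derivatives ``(dphi, dtheta)`` of the discretized equations of motion.

    Raises :class:`DomainError` when ``beta`` is non-integer and any
    ``phi <= 0`` (fractional powers of a non-positive field are undefined).
    """
    boundary = boundary or BoundarySpec()
    if not _beta_is_integerlike(beta) and np.any(state.phi <= 0):
        raise DomainError(
            f"non-integer beta={beta} requires phi > 0 everywhere "
            f"(min phi = {state.phi.min()})"
        )
    dphi, dtheta = _rhs(state.phi, state.theta, beta, boundary)
    return dphi.copy(), dtheta


def _step(phi, theta, beta, dt, boundary, integrator):
    if integrator == "euler":
        dphi, dtheta = _rhs(phi, theta, beta, boundary)
        return phi + dt * dphi, theta + dt * dtheta
    k1p, k1t = _rhs(phi, theta, beta, boundary)
    k2p, k2t = _rhs(phi + 0.5 * dt * k1p, theta + 0.5 * dt * k1t, beta, boundary)
    k3p, k3t = _rhs(phi + 0.5 * dt * k2p, theta + 0.5 * dt * k2t, beta, boundary)
    k4p, k4t = _rhs(phi + dt * k3p, theta + dt * k3t, beta, boundary)
    phi = phi + (dt / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
    theta = theta + (dt / 6.0) * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
    return phi, theta


def _integrate_arrays(
    phi0: np.ndarray,
    theta0: np.ndarray,
    beta,
    dt: float,
    n_steps: int,
    integrator: str = "rk4",
    boundary: BoundarySpec | None = None,
    check: bool = True,
    freeze_mask: np.ndarray | None = None,
):
    """Fixed-step integration on (possibly batched) grids.

    Returns ``(phis, thetas)`` of shape ``(n_steps + 1, ..., H, W)``. With
    ``check=True`` raises :class:`IntegrationError` at the first step that
    produces a non-finite value; with ``check=False`` non-finite values
    propagate (batched inversions treat them as failed trials).
    ``freeze_mask`` (H, W booleans), when given, freezes nodes outside the
    mask at their initial values.
    """
    boundary = boundary or BoundarySpec()
    phi = np.array(phi0, dtype=float)
    theta = np.array(theta0, dtype=float)
    phis = np.empty((n_steps + 1,) + phi.shape)
    thetas = np.empty_like(phis)
    phis[0], thetas[0] = phi, theta
    hold = None
    if freeze_mask is not None:
        hold = ~np.asarray(freeze_mask, dtype=bool)
    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        for k in range(n_steps):
            new_phi, new_theta = _step(phi, theta, beta, dt, boundary, integrator)
            if hold is not None:
                new_phi = np.where(hold, phi, new_phi)
                new_theta = np.where(hold, theta, new_theta)
            phi, theta = new_phi, new_theta
            if check and not (np.isfinite(phi).all() and np.isfinite(theta).all()):
                raise IntegrationError(
                    f"non-finite field values at step {k + 1} "
                    f"(t = {(k + 1) * dt:g}); integration aborted",
                    step=k + 1,
                )
            phis[k + 1], thetas[k + 1] = phi, theta
    return phis, thetas


def integrate(initial: FieldState, config: SimulationConfig) -> Trajectory:
    """Integrate the equations of motion from an initial state.

    Deterministic given the config; observation noise is applied
    separately by :func:`observe`.
    """
    if config.beta is None:
        raise ValueError("config.beta must be set for forward simulation")
    phis, thetas = _integrate_arrays(
        initial.phi,
        initial.theta,
        config.beta,
        config.dt,
        config.n_steps,
        integrator=config.integrator,
        boundary=config.boundary,
        check=True,
    )
    times = np.arange(config.n_steps + 1) * config.dt
    return Trajectory(times=times, phis=phis, thetas=thetas)


def node_columns(shape: tuple[int, int]) -> list[str]:
    """Column labels ``node_x_y`` in row-major order (y fastest)."""
    h, w = shape
    return [f"node_{x}_{y}" for x in range(h) for y in range(w)]


def observe(traj: Trajectory, obs_noise_sd: float, seed) -> pd.DataFrame:
    """Noisy observations of the field: wide DataFrame (time + node columns).

    Grids are flattened row-major (y fastest) and i.i.d. Gaussian noise of
    standard deviation ``obs_noise_sd`` is added; reproducible for a given
    seed.
    """
    if obs_noise_sd < 0:
        raise ValueError("obs_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    flat = traj.phis.reshape(len(traj), -1)
    noisy = flat + rng.normal(0.0, obs_noise_sd, size=flat.shape) if obs_noise_sd > 0 else flat.copy()
    df = pd.DataFrame(noisy, columns=node_columns(traj.grid_shape))
    df.insert(0, "time", traj.times)
    return df


def phase_embed(series, times) -> np.ndarray:
    """Planar phase-portrait embedding: ``(s_i * cos(t_i), s_i * sin(t_i))``.

    Returns an ``(n, 2)`` array; used for the rotating-frame visualisation
    of node timeseries.
    """
    s = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if s.shape != t.shape:
        raise ValueError("series and times must have equal lengths")
    return np.column_stack([s * np.cos(t), s * np.sin(t)])
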