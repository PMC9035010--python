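"""Variational-Laplace estimation of the anisotropy exponent.

The generative model for an observed multichannel timeseries ``y`` (time x
nodes) is the deterministic forward integration of the discretized
anisotropic wave equation from unknown initial conditions, observed through
additive i.i.d. Gaussian noise:

    y(t, node) = g(beta, phi0, theta0)(t, node) + e,   e ~ N(0, exp(-lambda_obs))

The unknowns are the anisotropy exponent ``beta``, the initial field and
rate grids ``phi0, theta0``, and the observation-noise log-precision
``lambda_obs`` (a log-precision on state fluctuations is carried as a
hyperparameter with a Gaussian prior; because the forward sweep is
deterministic the data do not update it and its posterior equals its
prior). All posteriors are Gaussian (Laplace approximation) and the model
score is the variational free energy

    F = <log p(y | params)>_q  -  KL[q(params), p(params)]

which trades accuracy against complexity. The optimisation follows a
D/E/M pattern:

* D step: generalized-coordinate embedding of each node series (the series
  and its first ``order - 1`` temporal derivatives from local polynomial
  fits) seeds the initial-condition estimates;
* E step: damped Gauss-Newton updates of (beta, phi0, theta0) maximising F
  with numerical (central-difference) Jacobians;
* M step: Newton updates of the observation log-precision.

Because F is strongly non-convex in ``beta`` (the exponent enters through
``phi ** (2*beta)``), the scalar ``beta`` is first profiled: candidate
values spanning the prior support are each fitted with ``beta`` clamped
(warm-starting the states from the neighbouring candidate), and the joint
Gauss-Newton refinement starts from the best profile point. The recorded
free-energy trace of the final run is non-decreasing by construction
(candidate steps that would lower F are rejected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from anisofield.exceptions import IntegrationError, UnidentifiableDataError
from anisofield.simulator import (
    FieldState,
    SimulationConfig,
    _integrate_arrays,
    observe,
)

__all__ = [
    "PriorSpec",
    "GeneralisedSeries",
    "PosteriorReport",
    "InversionOptions",
    "generalized_embed",
    "free_energy",
    "invert",
    "predict_response",
    "coerce_timeseries",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors over the inversion unknowns.

    ``beta_var == 0`` denotes a fixed (reduced) anisotropy exponent: the
    inversion clamps ``beta`` at ``beta_mean`` instead of estimating it.
    ``init_state_mean`` is an optional ``(2, H, W)`` array of prior means
    for (phi0, theta0); when None the priors are centred on the
    generalized-coordinate embedding of the first samples.
    """

    beta_mean: float = 0.0
    beta_var: float = 1.0
    init_state_mean: np.ndarray | None = None
    init_state_var: float = 1.0
    logprec_obs_mean: float = 0.0
    logprec_obs_var: float = 16.0
    logprec_state_mean: float = 0.0
    logprec_state_var: float = 16.0

    def __post_init__(self):
        for name in ("beta_var", "init_state_var", "logprec_obs_var", "logprec_state_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_reduced_beta(self, beta_mean: float = 0.0) -> "PriorSpec":
        """The reduced prior fixing beta (zero prior variance)."""
        return replace(self, beta_mean=beta_mean, beta_var=0.0)


@dataclass
class GeneralisedSeries:
    """A timeseries in generalized coordinates of motion.

    ``coeffs`` has shape ``(n_samples, order)``: column ``k`` holds the
    estimate of the k-th temporal derivative (column 0 is the smoothed
    series itself). ``smoothness`` is the assumed autocorrelation width of
    the fluctuations, in time units; it sets the local-fit window.
    """

    order: int
    coeffs: np.ndarray
    smoothness: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != self.order:
            raise ValueError("coeffs must be (n_samples, order)")


def generalized_embed(
    series, order: int = 4, smoothness: float = 0.1, dt: float = 1.0
) -> GeneralisedSeries:
    """Embed a timeseries in generalized coordinates via local polynomial fits.

    A Savitzky-Golay filter of polynomial order ``order`` over a sliding
    window of width ~``4 * smoothness`` estimates the series and its first
    ``order - 1`` derivatives at every sample. ``dt`` is the sampling
    interval; ``smoothness`` is in the same time units.
    """
    s = np.asarray(series, dtype=float).ravel()
    if len(s) <= order:
        raise ValueError(
            f"series of length {len(s)} too short for embedding order {order}"
        )
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    window = int(round(4.0 * smoothness / dt)) | 1  # odd
    window = max(window, (order + 1) | 1)
    max_win = len(s) if len(s) % 2 else len(s) - 1
    window = min(window, max_win)
    if window <= order:
        raise ValueError("series too short for the requested smoothness window")
    cols = [
        savgol_filter(s, window, polyorder=order, deriv=k, delta=dt, mode="interp")
        for k in range(order)
    ]
    return GeneralisedSeries(order=order, coeffs=np.column_stack(cols), smoothness=smoothness)


@dataclass
class PosteriorReport:
    """Laplace-approximate posterior and free energy from an inversion.

    ``param_mean``/``param_cov`` cover the jointly estimated parameters in
    the order given by ``param_names`` (``beta`` first when free, then
    ``phi0_x_y`` and ``theta0_x_y`` row-major). ``beta_index`` is None when
    beta was clamped (reduced model). ``prior_mean``/``prior_var`` are the
    matching per-parameter prior moments.
    """

    beta_mean: float
    beta_var: float
    logprec_posteriors: dict
    init_state_posterior: dict
    free_energy: float
    f_trace: list
    converged: bool
    param_mean: np.ndarray
    param_cov: np.ndarray
    param_names: list
    beta_index: int | None
    prior_mean: np.ndarray
    prior_var: np.ndarray
    priors: PriorSpec
    grid_shape: tuple

    def to_dict(self) -> dict:
        return {
            "beta_mean": self.beta_mean,
            "beta_var": self.beta_var,
            "logprec_posteriors": {
                k: {"mean": m, "var": v} for k, (m, v) in self.logprec_posteriors.items()
            },
            "init_state_posterior": {
                k: np.asarray(v).tolist() for k, v in self.init_state_posterior.items()
            },
            "free_energy": self.free_energy,
            "f_trace": list(self.f_trace),
            "converged": self.converged,
            "param_names": list(self.param_names),
            "param_mean": np.asarray(self.param_mean).tolist(),
            "param_cov": np.asarray(self.param_cov).tolist(),
            "beta_index": self.beta_index,
            "prior_mean": np.asarray(self.prior_mean).tolist(),
            "prior_var": np.asarray(self.prior_var).tolist(),
            "grid_shape": list(self.grid_shape),
        }


@dataclass(frozen=True)
class InversionOptions:
    """Convergence and differencing settings for :func:`invert`."""

    max_iter: int = 64
    f_tol: float = 1e-2  # nats; convergence when the F gain drops below this
    rel_step: float = 1e-4  # relative central-difference step
    max_inner: int = 8  # Levenberg retries per E step
    embed_order: int = 4
    smoothness: float | None = None  # defaults to 2 * dt
    profile_points: int = 17  # beta candidates scanned across the prior support
    profile_span: float = 4.0  # scan half-width in prior standard deviations
    profile_iters: int = 10  # Gauss-Newton iterations per profile candidate


def coerce_timeseries(observed, shape=None):
    """Normalize observed data to ``(times, Y, (H, W))``.

    Accepts a wide DataFrame (``time`` column plus ``node_x_y`` columns) or
    a ``(times, values)`` pair with an explicit grid shape.
    """
    if isinstance(observed, pd.DataFrame):
        if "time" not in observed.columns:
            raise ValueError("observed DataFrame needs a 'time' column")
        node_cols = [c for c in observed.columns if c.startswith("node_")]
        if not node_cols:
            raise ValueError("observed DataFrame has no node_x_y columns")
        coords = []
        for c in node_cols:
            parts = c.split("_")
            coords.append((int(parts[1]), int(parts[2])))
        h = max(x for x, _ in coords) + 1
        w = max(y for _, y in coords) + 1
        if sorted(coords) != [(x, y) for x in range(h) for y in range(w)]:
            raise ValueError("node columns do not form a complete grid")
        order = np.argsort([x * w + y for x, y in coords])
        times = observed["time"].to_numpy(dtype=float)
        Y = observed[node_cols].to_numpy(dtype=float)[:, order]
        return times, Y, (h, w)
    times, Y = observed
    times = np.asarray(times, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if shape is None:
        side = int(round(np.sqrt(Y.shape[1])))
        if side * side != Y.shape[1]:
            raise ValueError("grid shape required for non-square node counts")
        shape = (side, side)
    return times, Y, tuple(shape)


def _gaussian_kl(mean_q, cov_q, mean_p, prec_p, logdet_cov_p):
    """KL( N(mean_q, cov_q) || N(mean_p, cov_p) ) for a diagonal prior."""
    d = len(mean_q)
    diff = mean_q - mean_p
    sign, logdet_q = np.linalg.slogdet(cov_q)
    if sign <= 0:
        raise np.linalg.LinAlgError("posterior covariance not positive definite")
    tr = float(np.sum(prec_p * np.diag(cov_q)))
    quad = float(diff @ (prec_p * diff))
    return 0.5 * (tr + quad - d + logdet_cov_p - logdet_q)


def _scalar_kl(mq, vq, mp, vp):
    if vp == 0:
        return 0.0 if (vq == 0 and mq == mp) else np.inf
    vq = max(vq, 0.0)
    if vq == 0:
        return np.inf
    return 0.5 * (vq / vp + (mq - mp) ** 2 / vp - 1.0 + np.log(vp / vq))


def free_energy(observed, predicted, q, priors: PriorSpec, jac=None) -> float:
    """Variational free energy of a fitted model.

    ``F = <log p(y|params)>_q - KL[q, p]`` under Gaussian posteriors ``q``:
    the expected log-likelihood of the residuals at the posterior-mean
    observation precision (including the curvature correction
    ``tr(cov_q J' J)`` when a Jacobian is supplied), minus the KL
    divergences of the parameter and log-precision posteriors from their
    priors.

    ``q`` must provide ``param_mean``, ``param_cov``, ``prior_mean``,
    ``prior_var`` (arrays over the jointly estimated parameters) and
    ``logprec_posteriors`` with an ``obs`` entry (optionally ``state``) --
    a :class:`PosteriorReport` qualifies, as does any object with those
    attributes.
    """
    y = np.asarray(observed, dtype=float)
    g = np.asarray(predicted, dtype=float)
    if y.shape != g.shape:
        raise ValueError("observed and predicted shapes differ")
    if not (np.isfinite(y).all() and np.isfinite(g).all()):
        raise ValueError("non-finite observed or predicted values")
    r = (y - g).ravel()
    n_obs = r.size
    lp = dict(q.logprec_posteriors)
    m_lam, v_lam = lp["obs"]
    gauss_sq = float(r @ r)
    if jac is not None:
        J = np.asarray(jac, dtype=float).reshape(n_obs, -1)
        gauss_sq += float(np.sum((J @ np.asarray(q.param_cov)) * J))
    accuracy = -0.5 * np.exp(m_lam) * gauss_sq + 0.5 * n_obs * m_lam - 0.5 * n_obs * _LOG2PI
    prior_var = np.asarray(q.prior_var, dtype=float)
    prec_p = 1.0 / prior_var
    logdet_p = float(np.sum(np.log(prior_var)))
    kl_params = _gaussian_kl(
        np.asarray(q.param_mean, dtype=float),
        np.asarray(q.param_cov, dtype=float),
        np.asarray(q.prior_mean, dtype=float),
        prec_p,
        logdet_p,
    )
    kl_lam = _scalar_kl(m_lam, v_lam, priors.logprec_obs_mean, priors.logprec_obs_var)
    ms, vs = lp.get("state", (priors.logprec_state_mean, priors.logprec_state_var))
    kl_state = _scalar_kl(ms, vs, priors.logprec_state_mean, priors.logprec_state_var)
    F = accuracy - kl_params - kl_lam - kl_state
    if not np.isfinite(F):
        raise ValueError("free energy is non-finite")
    return float(F)


@dataclass
class _Q:
    """Minimal posterior container accepted by :func:`free_energy`."""

    param_mean: np.ndarray
    param_cov: np.ndarray
    prior_mean: np.ndarray
    prior_var: np.ndarray
    logprec_posteriors: dict


def predict_response(
    beta: float, init: FieldState, model: SimulationConfig
) -> pd.DataFrame:
    """Deterministic forward sweep: integrate then observe noiselessly.

    This is the generative mean used inside :func:`invert`.
    """
    from anisofield.simulator import integrate

    traj = integrate(init, model.with_beta(beta))
    return observe(traj, 0.0, 0)


def _predict_batch(params, shape, clamp_beta, beta_fixed, dt, n_steps, integrator, boundary):
    """Forward-model observations for a batch of parameter vectors.

    ``params`` is ``(B, p)``; returns ``(B, T, N)``. Non-finite values flow
    through so failed trials can be rejected by the caller.
    """
    params = np.atleast_2d(np.asarray(params, dtype=float))
    B = params.shape[0]
    h, w = shape
    hw = h * w
    off = 0 if clamp_beta else 1
    beta = np.full(B, beta_fixed) if clamp_beta else params[:, 0]
    phi0 = params[:, off : off + hw].reshape(B, h, w)
    theta0 = params[:, off + hw :].reshape(B, h, w)
    phis, _ = _integrate_arrays(
        phi0,
        theta0,
        beta[:, None, None],
        dt,
        n_steps,
        integrator=integrator,
        boundary=boundary,
        check=False,
    )
    # phis: (T, B, H, W) -> (B, T, N)
    return np.moveaxis(phis.reshape(n_steps + 1, B, hw), 0, 1)


def _optimize_logprec(gauss_sq, n_obs, mu0, v0, m_start):
    """Newton ascent of F in the observation log-precision (concave in it)."""
    m = float(m_start)
    for _ in range(100):
        grad = 0.5 * n_obs - 0.5 * np.exp(m) * gauss_sq - (m - mu0) / v0
        hess = -0.5 * np.exp(m) * gauss_sq - 1.0 / v0
        step = np.clip(-grad / hess, -4.0, 4.0)
        m += step
        if abs(step) < 1e-12:
            break
    v = 1.0 / (0.5 * np.exp(m) * gauss_sq + 1.0 / v0)
    return float(m), float(v)


class _VLProblem:
    """One Gauss-Newton variational-Laplace fit at fixed model structure."""

    def __init__(self, Y, forward, m0, s0, priors, opts):
        self.Y = Y
        self.forward = forward
        self.m0 = np.asarray(m0, dtype=float)
        self.s0 = np.asarray(s0, dtype=float)
        self.prec0 = 1.0 / self.s0
        self.priors = priors
        self.opts = opts
        self.p = len(self.m0)

    def jacobian(self, m):
        p = self.p
        h = self.opts.rel_step * np.maximum(np.abs(m), 1.0)
        pert = np.repeat(m[None], 2 * p, axis=0)
        idx = np.arange(p)
        pert[2 * idx, idx] += h
        pert[2 * idx + 1, idx] -= h
        G = self.forward(pert)  # (2p, T, N)
        J = (G[2 * idx] - G[2 * idx + 1]) / (2.0 * h[:, None, None])
        return np.moveaxis(J, 0, -1).reshape(self.Y.size, p)

    def evaluate(self, m, g, J, m_lam, v_lam):
        """Consistent (F, cov, q) at an iterate; None when undefined."""
        if not np.isfinite(J).all():
            return None
        pi = np.exp(m_lam)
        H = pi * (J.T @ J) + np.diag(self.prec0)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        q = _Q(m, cov, self.m0, self.s0,
               {"obs": (m_lam, v_lam),
                "state": (self.priors.logprec_state_mean, self.priors.logprec_state_var)})
        try:
            F = free_energy(self.Y, g, q, self.priors, jac=J)
        except (ValueError, np.linalg.LinAlgError):
            return None
        return F, cov, q

    def run(self, m_start=None, m_lam_start=None, max_iter=None, f_tol=None):
        """Damped Gauss-Newton ascent of F; returns the best iterate found.

        The returned ``f_trace`` is non-decreasing: E/M updates whose
        consistent re-evaluation would lower F are rejected.
        """
        opts = self.opts
        max_iter = max_iter if max_iter is not None else opts.max_iter
        f_tol = f_tol if f_tol is not None else opts.f_tol
        m = np.array(self.m0 if m_start is None else m_start, dtype=float)
        g = self.forward(m[None])[0]
        if not np.isfinite(g).all():
            m = self.m0.copy()
            g = self.forward(m[None])[0]
        if not np.isfinite(g).all():
            return None
        r = (self.Y - g).ravel()
        if m_lam_start is None:
            m_lam, v_lam = _optimize_logprec(
                float(r @ r), r.size, self.priors.logprec_obs_mean,
                self.priors.logprec_obs_var, self.priors.logprec_obs_mean,
            )
        else:
            m_lam, v_lam = _optimize_logprec(
                float(r @ r), r.size, self.priors.logprec_obs_mean,
                self.priors.logprec_obs_var, m_lam_start,
            )
        J = self.jacobian(m)
        res = self.evaluate(m, g, J, m_lam, v_lam)
        if res is None and m_start is not None:
            # a warm start outside the model's domain (e.g. negative phi0
            # against a fractional beta) falls back to the prior mean
            m = self.m0.copy()
            g = self.forward(m[None])[0]
            if not np.isfinite(g).all():
                return None
            r = (self.Y - g).ravel()
            m_lam, v_lam = _optimize_logprec(
                float(r @ r), r.size, self.priors.logprec_obs_mean,
                self.priors.logprec_obs_var, self.priors.logprec_obs_mean,
            )
            J = self.jacobian(m)
            res = self.evaluate(m, g, J, m_lam, v_lam)
        if res is None:
            return None
        F, cov, q = res
        f_trace = [F]
        converged = False
        damping = 1e-6
        for it in range(1, max_iter + 1):
            state_prev = (m, g, J, cov, q, m_lam, v_lam)
            # E step: damped Gauss-Newton on the parameters.
            pi = np.exp(m_lam)
            r = (self.Y - g).ravel()
            grad = pi * (J.T @ r) - self.prec0 * (m - self.m0)
            Hmat = pi * (J.T @ J) + np.diag(self.prec0)
            obj = -0.5 * pi * float(r @ r) - 0.5 * float(
                (m - self.m0) @ (self.prec0 * (m - self.m0))
            )
            accepted = False
            for _ in range(opts.max_inner):
                try:
                    step = np.linalg.solve(
                        Hmat + damping * np.diag(np.diag(Hmat)), grad
                    )
                except np.linalg.LinAlgError:
                    damping *= 10.0
                    continue
                m_try = m + step
                g_try = self.forward(m_try[None])[0]
                if np.isfinite(g_try).all():
                    r_try = (self.Y - g_try).ravel()
                    with np.errstate(over="ignore"):
                        obj_try = -0.5 * pi * float(r_try @ r_try) - 0.5 * float(
                            (m_try - self.m0) @ (self.prec0 * (m_try - self.m0))
                        )
                    if np.isfinite(obj_try) and obj_try > obj:
                        accepted = True
                        damping = max(damping / 10.0, 1e-9)
                        m, g = m_try, g_try
                        break
                damping *= 10.0
            if accepted:
                J_new = self.jacobian(m)
                if np.isfinite(J_new).all():
                    J = J_new
            # M step: observation log-precision given the new residuals.
            pi = np.exp(m_lam)
            try:
                cov_cur = np.linalg.inv(pi * (J.T @ J) + np.diag(self.prec0))
            except np.linalg.LinAlgError:
                m, g, J, cov, q, m_lam, v_lam = state_prev
                break
            r = (self.Y - g).ravel()
            gauss_sq = float(r @ r) + float(np.sum((J @ cov_cur) * J))
            m_lam_new, v_lam_new = _optimize_logprec(
                gauss_sq, r.size, self.priors.logprec_obs_mean,
                self.priors.logprec_obs_var, m_lam,
            )
            res = self.evaluate(m, g, J, m_lam_new, v_lam_new)
            if res is None:
                m, g, J, cov, q, m_lam, v_lam = state_prev
                break
            F_new, cov_new, q_new = res
            if F_new < f_trace[-1] - 1e-9:
                m, g, J, cov, q, m_lam, v_lam = state_prev
                converged = True
                break
            m_lam, v_lam = m_lam_new, v_lam_new
            cov, q = cov_new, q_new
            gain = F_new - f_trace[-1]
            f_trace.append(F_new)
            logger.debug("GN iter %d: F = %.4f (dF = %.3g)", it, F_new, gain)
            if not accepted or gain < f_tol:
                converged = True
                break
        return {
            "m": m, "g": g, "J": J, "cov": cov,
            "m_lam": m_lam, "v_lam": v_lam,
            "F": float(f_trace[-1]), "f_trace": [float(v) for v in f_trace],
            "converged": converged,
        }


def invert(
    observed,
    model: SimulationConfig,
    priors: PriorSpec | None = None,
    opts: InversionOptions | None = None,
    shape=None,
) -> PosteriorReport:
    """Estimate a Gaussian posterior over the anisotropy exponent.

    Parameters
    ----------
    observed : DataFrame or (times, values)
        Wide timeseries; see :func:`coerce_timeseries`. Sampling must be
        uniform -- the forward integrator steps at the sampling interval.
    model : SimulationConfig
        Integrator/boundary settings; any ``beta`` it carries is ignored
        (beta is what the inversion estimates, or clamps when the prior
        variance over beta is zero).
    priors : PriorSpec, optional
    opts : InversionOptions, optional
    shape : tuple, optional
        Grid shape when ``observed`` is a bare array pair.

    Returns
    -------
    PosteriorReport
        Posterior moments, free energy and its (non-decreasing) trace.
    """
    priors = priors or PriorSpec()
    opts = opts or InversionOptions()
    times, Y, shape = coerce_timeseries(observed, shape)
    if not np.isfinite(Y).all():
        raise ValueError("observed data contain non-finite values")
    T, N = Y.shape
    h, w = shape
    if N != h * w:
        raise ValueError(f"{N} node columns inconsistent with grid {shape}")
    if min(h, w) < 2:
        raise ValueError("the grid must span at least 2 nodes in each direction")
    if T < 3:
        raise ValueError("need at least 3 time samples")
    if float(np.ptp(Y)) < 1e-10:
        raise UnidentifiableDataError(
            "constant observations carry no information about beta"
        )
    dts = np.diff(times)
    if np.any(dts <= 0) or not np.allclose(dts, dts[0]):
        raise ValueError("observation times must be uniform and increasing")
    dt = float(dts[0])
    n_steps = T - 1
    smooth = opts.smoothness if opts.smoothness is not None else 2.0 * dt

    # --- D step: generalized-coordinate embedding seeds the initial state.
    phi0_seed = np.empty(N)
    theta0_seed = np.empty(N)
    for j in range(N):
        emb = generalized_embed(Y[:, j], order=opts.embed_order, smoothness=smooth, dt=dt)
        phi0_seed[j] = emb.coeffs[0, 0]
        theta0_seed[j] = emb.coeffs[0, 1]
    # the model's fractional powers require phi > 0: keep the seed inside
    # the domain even when noise drives the first samples negative
    phi0_seed = np.maximum(phi0_seed, 1e-2)

    clamp = priors.beta_var == 0.0
    if priors.init_state_mean is not None:
        ism = np.asarray(priors.init_state_mean, dtype=float)
        if ism.shape != (2, h, w):
            raise ValueError("init_state_mean must have shape (2, H, W)")
        init_mean = np.concatenate([ism[0].ravel(), ism[1].ravel()])
    else:
        init_mean = np.concatenate([phi0_seed, theta0_seed])
        # very noisy data can make the derivative seeds wild enough that the
        # forward model diverges at the prior mean; fall back to zero rates
        probe = _predict_batch(
            init_mean[None], shape, True, priors.beta_mean, dt, n_steps,
            model.integrator, model.boundary,
        )
        if not np.isfinite(probe).all():
            init_mean = np.concatenate([Y[0], np.zeros(N)])

    state_names = [f"phi0_{x}_{y}" for x in range(h) for y in range(w)] + [
        f"theta0_{x}_{y}" for x in range(h) for y in range(w)
    ]
    beta_fixed = priors.beta_mean

    def make_forward(clamped, beta_val):
        def forward(params_batch):
            return _predict_batch(
                params_batch, shape, clamped, beta_val, dt, n_steps,
                model.integrator, model.boundary,
            )
        return forward

    if clamp:
        m0 = init_mean.copy()
        s0 = np.full(2 * N, priors.init_state_var, dtype=float)
        problem = _VLProblem(Y, make_forward(True, beta_fixed), m0, s0, priors, opts)
        result = problem.run()
        if result is None:
            raise IntegrationError(
                "forward model diverges at the prior mean; adjust priors", step=None
            )
        names = state_names
        beta_index = None
    else:
        m0 = np.concatenate([[priors.beta_mean], init_mean])
        s0 = np.concatenate([[priors.beta_var], np.full(2 * N, priors.init_state_var)])
        names = ["beta"] + state_names
        beta_index = 0
        # --- beta profile: clamp beta at candidates across the prior
        # support, warm-starting states from the nearest fitted candidate.
        sd0 = float(np.sqrt(priors.beta_var))
        cand = priors.beta_mean + sd0 * np.linspace(
            -opts.profile_span, opts.profile_span, opts.profile_points
        )
        order = np.argsort(np.abs(cand - priors.beta_mean), kind="stable")
        prof_F = np.full(len(cand), -np.inf)
        prof_state = [None] * len(cand)
        warm: dict[int, tuple] = {}
        for ci in order:
            beta_c = float(cand[ci])
            done = [k for k in warm if prof_state[k] is not None]
            if done:
                nearest = min(done, key=lambda k: abs(cand[k] - beta_c))
                m_start, lam_start = prof_state[nearest]
            else:
                m_start, lam_start = init_mean, None
            prob_c = _VLProblem(
                Y, make_forward(True, beta_c), init_mean,
                np.full(2 * N, priors.init_state_var, dtype=float), priors, opts,
            )
            res_c = prob_c.run(
                m_start=m_start, m_lam_start=lam_start,
                max_iter=opts.profile_iters, f_tol=opts.f_tol,
            )
            if res_c is not None:
                prof_F[ci] = res_c["F"]
                prof_state[ci] = (res_c["m"], res_c["m_lam"])
                warm[ci] = True
        if np.isfinite(prof_F).any():
            best = int(np.argmax(prof_F))
            m_start = np.concatenate([[cand[best]], prof_state[best][0]])
            lam_start = prof_state[best][1]
        else:
            m_start, lam_start = m0, None
        problem = _VLProblem(Y, make_forward(False, beta_fixed), m0, s0, priors, opts)
        result = problem.run(m_start=m_start, m_lam_start=lam_start)
        if result is None:
            raise IntegrationError(
                "forward model diverges at the prior mean; adjust priors", step=None
            )

    m, cov = result["m"], result["cov"]
    var = np.diag(cov)
    off = 0 if clamp else 1
    hw = h * w
    report = PosteriorReport(
        beta_mean=beta_fixed if clamp else float(m[0]),
        beta_var=0.0 if clamp else float(var[0]),
        logprec_posteriors={
            "obs": (result["m_lam"], result["v_lam"]),
            "state": (priors.logprec_state_mean, priors.logprec_state_var),
        },
        init_state_posterior={
            "phi0_mean": m[off : off + hw].reshape(h, w),
            "theta0_mean": m[off + hw :].reshape(h, w),
            "phi0_var": var[off : off + hw].reshape(h, w),
            "theta0_var": var[off + hw :].reshape(h, w),
        },
        free_energy=result["F"],
        f_trace=result["f_trace"],
        converged=result["converged"],
        param_mean=m,
        param_cov=cov,
        param_names=names,
        beta_index=beta_index,
        prior_mean=m0,
        prior_var=s0,
        priors=priors,
        grid_shape=shape,
    )
    return report
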