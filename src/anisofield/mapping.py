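"""Pixelwise anisotropy maps from imaging movies.

Each pixel on a stride lattice inside the mask is inverted independently:
the pixel's own timeseries is the observation, and the measured timeseries
of its four in-mask neighbours enter the discretized equations of motion as
known, time-varying boundary data. The per-pixel unknowns are the local
anisotropy exponent ``beta``, the pixel's initial field value and rate, and
the observation log-precision; the estimator is the same damped
Gauss-Newton variational-Laplace scheme as the grid inversion, vectorised
across pixels.

Maps are combined in the order: average posteriors across trials, then
across subjects, then smooth -- the per-map arithmetic mean of posterior
means with mixture-moment variances (a precision-weighted combination is
available behind a flag). Smoothing is a truncated 2D Gaussian moving
average (window ``(2*semiwidth + 1)**2``, sigma = semiwidth / 2) with
mask-aware renormalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from anisofield.inversion import InversionOptions, PriorSpec, generalized_embed

__all__ = [
    "Movie",
    "BetaMap",
    "pixelwise_beta_map",
    "pixelwise_beta_maps",
    "average_posterior_maps",
    "smooth_map",
    "zscore_mean_timecourse",
]

logger = logging.getLogger(__name__)


@dataclass
class Movie:
    """An imaging movie: frames x height x width, with a validity mask."""

    data: np.ndarray
    mask: np.ndarray | None = None
    dt: float = 1.0
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be frames x height x width")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match frames "
                f"{self.data.shape[1:]}"
            )
        if not self.dt > 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class BetaMap:
    """Per-pixel posterior over the anisotropy exponent.

    Non-evaluated pixels carry NaN in ``mean``/``var`` and False in
    ``evaluated``.
    """

    mean: np.ndarray
    var: np.ndarray
    evaluated: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        self.evaluated = np.asarray(self.evaluated, dtype=bool)
        if not (self.mean.shape == self.var.shape == self.evaluated.shape):
            raise ValueError("mean, var and evaluated must share a shape")
        if np.any(self.var[self.evaluated] < 0):
            raise ValueError("posterior variances must be >= 0 where evaluated")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mean.shape

    def copy(self) -> "BetaMap":
        return BetaMap(self.mean.copy(), self.var.copy(), self.evaluated.copy())


def _pixel_forward(beta, phi0, theta0, nb, dt):
    """Batched single-node integration with observed neighbour boundaries.

    ``beta, phi0, theta0`` are (B,) arrays; ``nb`` is (T, 4, B) with the
    east/west (x+-1) and north/south (y+-1) neighbour traces. Neighbour
    values at RK4 half-steps are linear interpolations between frames.
    Returns predictions (T, B); non-finite values flow through.
    """
    T = nb.shape[0]
    out = np.empty((T, len(phi0)))
    phi, th = phi0.astype(float).copy(), theta0.astype(float).copy()
    out[0] = phi
    b2 = 2.0 * beta
    b21 = b2 - 1.0

    def accel(p, e, w, n, s):
        with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
            return (
                (e - 2.0 * p + w)
                + np.power(p, b2) * (n - 2.0 * p + s)
                + beta * np.power(p, b21) * (0.5 * (n - s)) ** 2
            )

    with np.errstate(invalid="ignore", over="ignore", divide="ignore"):
        for k in range(T - 1):
            n0, n1 = nb[k], nb[k + 1]
            nm = 0.5 * (n0 + n1)
            # RK4 for dphi = theta, dtheta = accel(phi, neighbours(t))
            k1p = th
            k1t = accel(phi, *n0)
            k2p = th + 0.5 * dt * k1t
            k2t = accel(phi + 0.5 * dt * k1p, *nm)
            k3p = th + 0.5 * dt * k2t
            k3t = accel(phi + 0.5 * dt * k2p, *nm)
            k4p = th + dt * k3t
            k4t = accel(phi + dt * k3p, *n1)
            phi = phi + (dt / 6.0) * (k1p + 2 * k2p + 2 * k3p + k4p)
            th = th + (dt / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
            out[k + 1] = phi
    return out


def _gn_fit(Y, nb, dt, m_start, m0, prec0, priors, opts, max_iter):
    """Damped Gauss-Newton fits for B independent single-node problems.

    ``Y`` (T, B), ``nb`` (T, 4, B); ``m_start``/``m0`` (B, 3) parameter
    vectors (beta, phi0, theta0); ``prec0`` (B, 3) per-pixel prior
    precisions (a huge beta precision pins beta, which is how the profile
    stage clamps it). Returns the accepted iterates plus per-pixel
    quantities needed for scoring and the Laplace covariance.
    """
    T, B = Y.shape
    eye3 = np.eye(3)

    def forward(params):  # (B, 3) -> (T, B)
        return _pixel_forward(params[:, 0], params[:, 1], params[:, 2], nb, dt)

    def optimize_lam(sse_eff):
        mu0, v0 = priors.logprec_obs_mean, priors.logprec_obs_var
        m = np.full(B, mu0)
        safe = np.where(np.isfinite(sse_eff) & (sse_eff > 0), sse_eff, float(T))
        for _ in range(60):
            grad = 0.5 * T - 0.5 * np.exp(m) * safe - (m - mu0) / v0
            hess = -0.5 * np.exp(m) * safe - 1.0 / v0
            m += np.clip(-grad / hess, -4.0, 4.0)
        v = 1.0 / (0.5 * np.exp(m) * safe + 1.0 / v0)
        return m, v

    def jacobian(m):
        hsteps = opts.rel_step * np.maximum(np.abs(m), 1.0)
        J = np.empty((B, T, 3))
        with np.errstate(invalid="ignore", over="ignore"):
            for j in range(3):
                plus, minus = m.copy(), m.copy()
                plus[:, j] += hsteps[:, j]
                minus[:, j] -= hsteps[:, j]
                J[:, :, j] = (forward(plus) - forward(minus)).T / (2.0 * hsteps[:, j, None])
        bad = ~np.isfinite(J).all(axis=(1, 2))
        J[bad] = 0.0  # inert rows: no Gauss-Newton step for failed pixels
        return J

    m = m_start.copy()
    g = forward(m)
    bad = ~np.isfinite(g).all(axis=0)
    if bad.any():
        m[bad] = m0[bad]
        g = forward(m)
    with np.errstate(invalid="ignore"):
        sse = np.einsum("tb,tb->b", Y - g, Y - g)
    m_lam, v_lam = optimize_lam(sse)
    damping = np.full(B, 1e-6)
    for _ in range(max_iter):
        J = jacobian(m)
        pi = np.exp(m_lam)
        r = np.where(np.isfinite(g), Y - g, 0.0)
        JtJ = np.einsum("btp,btq->bpq", J, J)
        Jtr = np.einsum("btp,tb->bp", J, r)
        grad = pi[:, None] * Jtr - prec0 * (m - m0)
        Hm = pi[:, None, None] * JtJ + prec0[:, :, None] * eye3[None]
        with np.errstate(invalid="ignore"):
            obj = -0.5 * pi * np.einsum("tb,tb->b", r, r) - 0.5 * np.einsum(
                "bp,bp->b", (m - m0) ** 2, prec0
            )
        improved = np.zeros(B, dtype=bool)
        m_new = m.copy()
        for _ in range(opts.max_inner):
            act = np.nonzero(~improved)[0]
            if len(act) == 0:
                break
            diag = np.einsum("bpp->bp", Hm[act])
            Hd = Hm[act] + (damping[act, None] * diag)[:, :, None] * eye3[None]
            try:
                step = np.linalg.solve(Hd, grad[act, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                damping[act] = np.minimum(damping[act] * 10.0, 1e12)
                continue
            trial = m[act] + step
            g_try = _pixel_forward(
                trial[:, 0], trial[:, 1], trial[:, 2], nb[:, :, act], dt
            )
            fin = np.isfinite(g_try).all(axis=0)
            with np.errstate(invalid="ignore"):
                r_try = np.where(np.isfinite(g_try), Y[:, act] - g_try, 0.0)
                obj_try = -0.5 * pi[act] * np.einsum("tb,tb->b", r_try, r_try) - 0.5 * np.einsum(
                    "bp,bp->b", (trial - m0[act]) ** 2, prec0[act]
                )
            accept = fin & (obj_try > obj[act])
            acc_idx = act[accept]
            m_new[acc_idx] = trial[accept]
            improved[acc_idx] = True
            damping[acc_idx] = np.maximum(damping[acc_idx] / 10.0, 1e-9)
            rej_idx = act[~accept]
            damping[rej_idx] = np.minimum(damping[rej_idx] * 10.0, 1e12)
        m = m_new
        g = forward(m)
        with np.errstate(invalid="ignore"):
            sse = np.einsum("tb,tb->b", np.where(np.isfinite(g), Y - g, 0.0),
                            np.where(np.isfinite(g), Y - g, 0.0))
        try:
            cov = np.linalg.inv(Hm)
            tr_corr = np.einsum("bpq,bpq->b", JtJ, cov)
        except np.linalg.LinAlgError:
            tr_corr = np.zeros(B)
        m_lam, v_lam = optimize_lam(sse + tr_corr)
        if not improved.any():
            break
    J = jacobian(m)
    JtJ = np.einsum("btp,btq->bpq", J, J)
    H = np.exp(m_lam)[:, None, None] * JtJ + prec0[:, :, None] * eye3[None]
    ok = np.isfinite(g).all(axis=0) & np.isfinite(J).any(axis=(1, 2))
    return {"m": m, "g": g, "sse": sse, "H": H, "m_lam": m_lam, "v_lam": v_lam, "ok": ok}


def _batched_pixel_invert(Y, nb, dt, priors, opts, chunk: int = 3000):
    """Variational-Laplace fits for B independent pixels at once.

    ``Y`` is (T, B) pixel observations, ``nb`` (T, 4, B) neighbour traces.
    A profile stage first fits (phi0, theta0, log-precision) with the
    anisotropy exponent pinned at candidates spanning its prior support
    (the landscape is strongly non-convex in beta), then the free
    three-parameter Gauss-Newton run starts from each pixel's best profile
    point. Returns (beta_mean, beta_var, ok) arrays of shape (B,).
    Batches larger than ``chunk`` pixels are processed in slices to bound
    the profile stage's memory use.
    """
    T, B = Y.shape
    if B > chunk:
        parts = [
            _batched_pixel_invert(Y[:, s], nb[:, :, s], dt, priors, opts, chunk)
            for s in (slice(k, k + chunk) for k in range(0, B, chunk))
        ]
        return tuple(np.concatenate(v) for v in zip(*parts))
    smooth = opts.smoothness if opts.smoothness is not None else 2.0 * dt
    phi0 = Y[0].copy()
    theta0 = np.empty(B)
    for j in range(B):
        emb = generalized_embed(Y[:, j], order=opts.embed_order, smoothness=smooth, dt=dt)
        phi0[j] = emb.coeffs[0, 0]
        theta0[j] = emb.coeffs[0, 1]
    m0 = np.stack([np.full(B, priors.beta_mean), phi0, theta0], axis=1)  # (B, 3)
    prec0 = np.broadcast_to(
        np.array([1.0 / priors.beta_var, 1.0 / priors.init_state_var,
                  1.0 / priors.init_state_var]),
        (B, 3),
    ).copy()

    # profile stage: beta pinned at candidates across the prior support
    sd0 = float(np.sqrt(priors.beta_var))
    cand = priors.beta_mean + sd0 * np.linspace(
        -opts.profile_span, opts.profile_span, opts.profile_points
    )
    K = len(cand)
    Y_rep = np.tile(Y, (1, K))
    nb_rep = np.tile(nb, (1, 1, K))
    m0_rep = np.tile(m0, (K, 1))
    m0_rep[:, 0] = np.repeat(cand, B)
    prec_rep = np.tile(prec0, (K, 1))
    prec_rep[:, 0] = 1e12  # pins beta during the profile
    fit = _gn_fit(Y_rep, nb_rep, dt, m0_rep.copy(), m0_rep, prec_rep, priors, opts,
                  max_iter=opts.profile_iters)
    # profile score: accuracy at the optimised precision plus the beta prior
    with np.errstate(invalid="ignore", over="ignore"):
        score = (
            -0.5 * np.exp(fit["m_lam"]) * fit["sse"]
            + 0.5 * T * fit["m_lam"]
            - 0.5 * (m0_rep[:, 0] - priors.beta_mean) ** 2 / priors.beta_var
        )
    score[~fit["ok"]] = -np.inf
    score = score.reshape(K, B)
    best = np.argmax(score, axis=0)
    m_prof = fit["m"].reshape(K, B, 3)[best, np.arange(B)]
    m_start = np.where(np.isfinite(score[best, np.arange(B)])[:, None], m_prof, m0)

    # free run from the best profile point
    fit = _gn_fit(Y, nb, dt, m_start, m0, prec0, priors, opts, max_iter=opts.max_iter)
    beta_mean = fit["m"][:, 0]
    beta_var = np.full(B, np.nan)
    ok = fit["ok"]
    if ok.any():
        try:
            cov_ok = np.linalg.inv(fit["H"][ok])
            beta_var[ok] = cov_ok[:, 0, 0]
        except np.linalg.LinAlgError:
            for idx in np.nonzero(ok)[0]:
                try:
                    beta_var[idx] = np.linalg.inv(fit["H"][idx])[0, 0]
                except np.linalg.LinAlgError:
                    pass
    ok = ok & np.isfinite(beta_var) & (beta_var > 0)
    return beta_mean, beta_var, ok


def _stride_lattice(mask: np.ndarray, stride: int):
    """Indices of stride-lattice pixels whose 4 neighbours are in the mask."""
    h, w = mask.shape
    xs, ys = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    lattice = (xs % stride == 0) & (ys % stride == 0) & mask
    interior = np.zeros_like(mask)
    interior[1:-1, 1:-1] = (
        mask[2:, 1:-1] & mask[:-2, 1:-1] & mask[1:-1, 2:] & mask[1:-1, :-2]
    )
    return np.nonzero(lattice & interior)


def pixelwise_beta_map(
    movie: Movie,
    stride: int = 2,
    priors: PriorSpec | None = None,
    opts: InversionOptions | None = None,
    prescale: float = 1.0,
) -> BetaMap:
    """Per-pixel anisotropy posteriors on a stride lattice inside the mask.

    Every ``stride``-th pixel (in both directions) whose four immediate
    neighbours are in the mask is inverted with the neighbours' measured
    timeseries as known boundary data. Pixels whose inversion fails are
    marked missing (logged), never fatal. ``prescale`` multiplies the raw
    movie values before inversion (for data whose units need bringing to
    the model's amplitude scale).
    """
    return pixelwise_beta_maps(
        [movie], stride=stride, priors=priors, opts=opts, prescale=prescale
    )[0]


def pixelwise_beta_maps(
    movies,
    stride: int = 2,
    priors: PriorSpec | None = None,
    opts: InversionOptions | None = None,
    prescale: float = 1.0,
) -> list[BetaMap]:
    """:func:`pixelwise_beta_map` for several movies in one batched solve.

    All movies must share the frame shape, mask, frame count and frame
    interval (e.g. the trials of one recording session); their pixels are
    stacked into a single batch, which amortises the integrator overhead.
    """
    movies = list(movies)
    if not movies:
        raise ValueError("need at least one movie")
    first = movies[0]
    if first.n_frames < 3:
        raise ValueError("movie needs at least 3 frames")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    priors = priors or PriorSpec()
    # fewer profile candidates/iterations than the grid inversion: each
    # pixel problem has only 3 parameters and the free run refines locally
    opts = opts or InversionOptions(profile_points=9, profile_iters=6, max_iter=32)
    if priors.beta_var <= 0:
        raise ValueError("pixelwise inversion needs a positive beta prior variance")
    for mv in movies[1:]:
        if (
            mv.frame_shape != first.frame_shape
            or mv.n_frames != first.n_frames
            or not np.array_equal(mv.mask, first.mask)
            or mv.dt != first.dt
        ):
            raise ValueError("movies must share shape, mask, frame count and dt")
    mask = first.mask
    h, w = first.frame_shape
    if not mask.any():
        raise ValueError("empty mask: no pixels to evaluate")
    ii, jj = _stride_lattice(mask, stride)
    npix = len(ii)
    if npix == 0:
        return [
            BetaMap(np.full((h, w), np.nan), np.full((h, w), np.nan),
                    np.zeros((h, w), dtype=bool))
            for _ in movies
        ]
    Ys, nbs = [], []
    for mv in movies:
        data = mv.data * prescale
        Ys.append(data[:, ii, jj])
        nbs.append(
            np.stack(
                [
                    data[:, ii + 1, jj],  # east (x+1)
                    data[:, ii - 1, jj],  # west (x-1)
                    data[:, ii, jj + 1],  # north (y+1)
                    data[:, ii, jj - 1],  # south (y-1)
                ],
                axis=1,
            )
        )
    Y = np.concatenate(Ys, axis=1)  # (T, n_movies * npix)
    nb = np.concatenate(nbs, axis=2)
    b_mean, b_var, ok = _batched_pixel_invert(Y, nb, first.dt, priors, opts)
    out = []
    for k, mv in enumerate(movies):
        sl = slice(k * npix, (k + 1) * npix)
        mk, vk, okk = b_mean[sl], b_var[sl], ok[sl]
        n_fail = int((~okk).sum())
        if n_fail:
            coords = list(zip(ii[~okk].tolist(), jj[~okk].tolist()))
            logger.warning(
                "pixelwise inversion failed at %d/%d pixels of movie %s: %s",
                n_fail, npix, mv.labels or k, coords[:20],
            )
        mean = np.full((h, w), np.nan)
        var = np.full((h, w), np.nan)
        evaluated = np.zeros((h, w), dtype=bool)
        mean[ii[okk], jj[okk]] = mk[okk]
        var[ii[okk], jj[okk]] = vk[okk]
        evaluated[ii[okk], jj[okk]] = True
        out.append(BetaMap(mean, var, evaluated))
    return out


def average_posterior_maps(maps, method: str = "moment") -> BetaMap:
    """Combine per-pixel posteriors across maps (trials, then subjects).

    ``moment`` (default): arithmetic mean of posterior means; variance is
    the mean of variances plus the between-map variance of means (the
    moments of the equal-weight mixture). ``precision``: precision-weighted
    mean with the combined precision's variance. A pixel contributes where
    evaluated; the output is evaluated on the union.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("need at least one map")
    shape = maps[0].shape
    for mp in maps:
        if mp.shape != shape:
            raise ValueError("all maps must share a shape")
    if method not in ("moment", "precision"):
        raise ValueError("method must be 'moment' or 'precision'")
    means = np.stack([mp.mean for mp in maps])
    vars_ = np.stack([mp.var for mp in maps])
    valid = np.stack([mp.evaluated for mp in maps])
    count = valid.sum(axis=0)
    union = count > 0
    mean = np.full(shape, np.nan)
    var = np.full(shape, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "moment":
            m = np.where(valid, means, 0.0).sum(axis=0) / np.where(union, count, 1)
            within = np.where(valid, vars_, 0.0).sum(axis=0) / np.where(union, count, 1)
            between = np.where(valid, (means - m) ** 2, 0.0).sum(axis=0) / np.where(
                union, count, 1
            )
            mean[union] = m[union]
            var[union] = (within + between)[union]
        else:
            wgt = np.where(valid, 1.0 / vars_, 0.0)
            total = wgt.sum(axis=0)
            mean[union] = (np.where(valid, wgt * means, 0.0).sum(axis=0) / total)[union]
            var[union] = (1.0 / total)[union]
    return BetaMap(mean, var, union)


def smooth_map(beta_map: BetaMap, semiwidth: int = 7) -> BetaMap:
    """Mask-aware truncated-Gaussian smoothing of the posterior means.

    The kernel is a 2D Gaussian with sigma = semiwidth / 2 truncated to a
    ``(2*semiwidth + 1)**2`` window and normalised to unit sum; weights
    falling on missing pixels are redistributed over the present ones.
    The evaluated grid is unchanged and no values are written outside it.
    """
    if semiwidth < 0:
        raise ValueError("semiwidth must be >= 0")
    out = beta_map.copy()
    if semiwidth == 0:
        return out
    sigma = semiwidth / 2.0
    ax = np.arange(-semiwidth, semiwidth + 1)
    gx = np.exp(-(ax**2) / (2.0 * sigma**2))
    kernel = np.outer(gx, gx)
    kernel /= kernel.sum()
    valid = beta_map.evaluated & np.isfinite(beta_map.mean)
    filled = np.where(valid, beta_map.mean, 0.0)
    num = ndimage.convolve(filled, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    out.mean = np.where(valid, sm, np.nan)
    return out


def zscore_mean_timecourse(movie: Movie) -> np.ndarray:
    """Per-frame spatial mean of temporally z-scored in-mask pixels.

    Each pixel's trace is centred and divided by its temporal standard
    deviation; pixels with zero variance are excluded with a warning. The
    returned series has (numerically) zero temporal mean.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to z-score over time")
    X = movie.data[:, movie.mask]  # (T, M)
    if X.shape[1] == 0:
        raise ValueError("empty mask: no pixels to average")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    good = sd > 0
    if not good.all():
        warnings.warn(
            f"excluding {int((~good).sum())} zero-variance pixels from the "
            "mean timecourse",
            RuntimeWarning,
            stacklevel=2,
        )
    if not good.any():
        raise ValueError("all in-mask pixels have zero temporal variance")
    z = (X[:, good] - mu[good]) / sd[good]
    return z.mean(axis=1)
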