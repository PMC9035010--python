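"""Scalable Lagrangian field densities and scale transformations.

A scale transformation maps a field configuration ``phi(r)`` on space-time
``r = (t, x, y, z)`` to ``phi_s(r) = lam * phi(lam**(-alpha) * r)`` with a
direction-specific exponent ``alpha_nu`` per axis. An action
``S[phi] = integral of L(phi, d phi)`` is *scalable* (possesses mechanical
similarity) when ``S[phi_s] = lam**n * S[phi]`` for every field
configuration, not just solutions of the equations of motion.

Expanding an analytic Lagrangian density as a power series in the field and
its first derivatives,

    L = sum C * phi**a * phidot**b_t * phi_x**b_x * phi_y**b_y * phi_z**b_z,

the action is scalable if and only if every monomial with a non-zero
coefficient satisfies

    a + sum_nu (1 - alpha_nu) * b_nu == n - sum_nu alpha_nu,

which fixes the field exponent ``a`` as a function of the derivative
exponents ``b_nu``. The anisotropic wave model used throughout this package
is the three-term special case (in two spatial dimensions, with
``alpha_t == alpha_x`` and ``n == alpha_y + 2``)

    L = phidot**2 - phi_x**2 - phi**(2*beta) * phi_y**2,

where ``beta = alpha_y - alpha_x`` quantifies the degree of anisotropy and
``beta == 0`` recovers the ordinary (isotropic) wave Lagrangian.

Everything here treats the exponent vector as four-dimensional
``(t, x, y, z)``; two-dimensional models simply carry ``alpha_z = 0`` and
``b_z = 0``, which leaves all sums unchanged.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass

import numpy as np

from anisofield.exceptions import DomainError

__all__ = [
    "ScalingExponents",
    "MonomialTerm",
    "LagrangianSpec",
    "Domain",
    "is_scalable_term",
    "forced_phi_exponent",
    "anisotropic_wave_spec",
    "lagrangian_density",
    "scaled_field",
    "numeric_action",
]

_N_AXES = 4  # (t, x, y, z)


@dataclass(frozen=True)
class ScalingExponents:
    """Direction-specific scaling exponents of a scale transformation.

    Parameters
    ----------
    alpha_t, alpha_x, alpha_y, alpha_z : float
        Exponents of the space-time axes; the transformation sends axis
        ``nu`` to ``lam**alpha_nu * nu``. ``alpha_z`` defaults to 0 for
        two-dimensional models.
    n : float
        Scaling degree of the action: ``S[phi_s] = lam**n * S[phi]``.
    lam : float
        Scale factor; must be strictly positive.
    """

    alpha_t: float
    alpha_x: float
    alpha_y: float
    alpha_z: float = 0.0
    n: float = 0.0
    lam: float = 1.0

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError(f"scale factor lam must be positive, got {self.lam}")

    @property
    def beta(self) -> float:
        """Anisotropy exponent ``beta = alpha_y - alpha_x`` (read-only)."""
        return self.alpha_y - self.alpha_x

    @property
    def alphas(self) -> tuple[float, float, float, float]:
        return (self.alpha_t, self.alpha_x, self.alpha_y, self.alpha_z)

    @classmethod
    def for_anisotropic_wave(
        cls, beta: float, alpha_x: float = 1.0, lam: float = 1.0
    ) -> "ScalingExponents":
        """Exponents of the anisotropic wave construction.

        Sets ``alpha_t = alpha_x``, ``alpha_y = alpha_x + beta`` and the
        scaling degree ``n = alpha_y + 2``.
        """
        alpha_y = alpha_x + beta
        return cls(
            alpha_t=alpha_x,
            alpha_x=alpha_x,
            alpha_y=alpha_y,
            alpha_z=0.0,
            n=alpha_y + 2.0,
            lam=lam,
        )


def _as_b_vector(b) -> tuple[int, int, int, int]:
    """Normalize a derivative-exponent vector to 4 non-negative ints."""
    seq = tuple(b)
    if len(seq) > _N_AXES:
        raise ValueError(f"at most {_N_AXES} derivative exponents, got {len(seq)}")
    seq = seq + (0,) * (_N_AXES - len(seq))
    out = []
    for v in seq:
        if not isinstance(v, numbers.Integral) or v < 0:
            raise ValueError(f"derivative exponents must be integers >= 0, got {v!r}")
        out.append(int(v))
    return tuple(out)


@dataclass(frozen=True)
class MonomialTerm:
    """One monomial ``C * phi**a * phidot**b_t * phi_x**b_x * phi_y**b_y * phi_z**b_z``."""

    C: float
    a: float = 0.0
    b_t: int = 0
    b_x: int = 0
    b_y: int = 0
    b_z: int = 0

    def __post_init__(self):
        for name in ("b_t", "b_x", "b_y", "b_z"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValueError(f"{name} must be an integer >= 0, got {v!r}")
            object.__setattr__(self, name, int(v))
        if not np.isfinite(self.C):
            raise ValueError(f"coefficient C must be finite, got {self.C}")
        if not np.isfinite(self.a):
            raise ValueError(f"field exponent a must be finite, got {self.a}")

    @property
    def b(self) -> tuple[int, int, int, int]:
        return (self.b_t, self.b_x, self.b_y, self.b_z)


@dataclass(frozen=True)
class LagrangianSpec:
    """An ordered collection of monomial terms in first derivatives only.

    ``spatial_dims`` restricts which derivative axes terms may use: a term
    with ``b_y > 0`` needs at least 2 spatial dimensions, ``b_z > 0``
    exactly 3.
    """

    terms: tuple[MonomialTerm, ...]
    spatial_dims: int = 2

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        if self.spatial_dims not in (1, 2, 3):
            raise ValueError(f"spatial_dims must be 1, 2 or 3, got {self.spatial_dims}")
        for term in self.terms:
            if not isinstance(term, MonomialTerm):
                raise TypeError(f"terms must be MonomialTerm, got {type(term)!r}")
            if term.b_y > 0 and self.spatial_dims < 2:
                raise ValueError("term uses phi_y but spatial_dims < 2")
            if term.b_z > 0 and self.spatial_dims < 3:
                raise ValueError("term uses phi_z but spatial_dims < 3")

    def to_json(self) -> str:
        return json.dumps(
            {
                "spatial_dims": self.spatial_dims,
                "terms": [{"C": t.C, "a": t.a, "b": list(t.b)} for t in self.terms],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LagrangianSpec":
        obj = json.loads(text)
        terms = tuple(
            MonomialTerm(C=d["C"], a=d.get("a", 0.0), **dict(zip(("b_t", "b_x", "b_y", "b_z"), _as_b_vector(d.get("b", ())))))
            for d in obj["terms"]
        )
        return cls(terms=terms, spatial_dims=obj["spatial_dims"])


def _all_integral(*values) -> bool:
    return all(
        isinstance(v, numbers.Integral) or (isinstance(v, float) and v.is_integer())
        for v in values
    )


def is_scalable_term(
    term: MonomialTerm, exps: ScalingExponents, tol: float = 1e-12
) -> bool:
    """Check the scalability condition for one monomial.

    The term contributes to a scalable action under ``exps`` iff

        a + sum_nu (1 - alpha_nu) * b_nu == n - sum_nu alpha_nu.

    Comparison is exact when every exponent involved is an integer,
    otherwise within absolute tolerance ``tol``.
    """
    alphas = exps.alphas
    lhs = term.a + sum((1.0 - al) * bv for al, bv in zip(alphas, term.b))
    rhs = exps.n - sum(alphas)
    if _all_integral(term.a, exps.n, *alphas):
        return int(round(lhs)) == int(round(rhs))
    return abs(lhs - rhs) <= tol


def forced_phi_exponent(b, exps: ScalingExponents) -> float:
    """Field exponent forced on a monomial by the scalability condition.

    For fixed derivative exponents ``b = (b_t, b_x, b_y, b_z)`` the only
    scalable choice is

        a = n + sum_nu ((alpha_nu - 1) * b_nu - alpha_nu).
    """
    bvec = _as_b_vector(b)
    alphas = exps.alphas
    return exps.n + sum((al - 1.0) * bv - al for al, bv in zip(alphas, bvec))


def anisotropic_wave_spec(beta: float) -> LagrangianSpec:
    """Three-term anisotropic wave Lagrangian density.

    ``L = phidot**2 - phi_x**2 - phi**(2*beta) * phi_y**2``; the field
    exponent on the y-gradient term is ``a = 2*beta``, forced by the
    scalability condition under ``alpha_t = alpha_x``,
    ``alpha_y = alpha_x + beta``, ``n = alpha_y + 2``.
    """
    return LagrangianSpec(
        terms=(
            MonomialTerm(C=1.0, a=0.0, b_t=2),
            MonomialTerm(C=-1.0, a=0.0, b_x=2),
            MonomialTerm(C=-1.0, a=2.0 * beta, b_y=2),
        ),
        spatial_dims=2,
    )


def _phi_power(phi, a):
    """``phi ** a`` with the package's fractional-power convention.

    Integer ``a`` is evaluated for any ``phi`` (negative bases allowed);
    non-integer ``a`` requires ``phi > 0`` and raises :class:`DomainError`
    otherwise.
    """
    phi = np.asarray(phi, dtype=float)
    if _all_integral(a):
        ai = int(a)
        if ai == 0:
            return np.ones_like(phi)
        with np.errstate(divide="ignore"):
            return phi**ai
    if np.any(phi <= 0):
        raise DomainError(
            f"fractional field exponent {a} requires phi > 0 "
            f"(min phi = {phi.min()})"
        )
    return phi**a


def lagrangian_density(spec: LagrangianSpec, phi, dphi):
    """Evaluate the Lagrangian density at field value(s) and derivatives.

    Parameters
    ----------
    spec : LagrangianSpec
    phi : float or ndarray
        Field value(s).
    dphi : sequence of float or ndarray
        Derivatives ``(phidot, phi_x[, phi_y[, phi_z]])``; length must be
        ``spec.spatial_dims + 1``.
    """
    dphi = [np.asarray(d, dtype=float) for d in dphi]
    if len(dphi) != spec.spatial_dims + 1:
        raise ValueError(
            f"expected {spec.spatial_dims + 1} derivative components, got {len(dphi)}"
        )
    phi = np.asarray(phi, dtype=float)
    total = np.zeros(np.broadcast_shapes(phi.shape, *(d.shape for d in dphi)))
    for term in spec.terms:
        val = term.C * _phi_power(phi, term.a)
        for d, bv in zip(dphi, term.b):
            if bv:
                val = val * d**bv
        total = total + val
    if total.ndim == 0:
        return float(total)
    return total


def scaled_field(field_fn, exps: ScalingExponents):
    """Scale-transform a field configuration.

    Given ``phi(t, x, y[, z])`` returns
    ``phi_s(r) = lam * phi(lam**(-alpha) * r)`` with componentwise axis
    exponents.
    """
    alphas = exps.alphas
    lam = exps.lam

    def phi_s(*coords):
        if len(coords) > _N_AXES:
            raise ValueError("at most 4 coordinates (t, x, y, z)")
        rescaled = [np.asarray(c) / lam ** alphas[i] for i, c in enumerate(coords)]
        return lam * field_fn(*rescaled)

    return phi_s


@dataclass(frozen=True)
class Domain:
    """Axis-aligned space-time box with a regular evaluation grid.

    ``bounds`` are per-axis ``(lo, hi)`` pairs in the order
    ``(t, x[, y[, z]])``; ``num`` is the number of grid points per axis
    (scalar or per-axis).
    """

    bounds: tuple[tuple[float, float], ...]
    num: int | tuple[int, ...] = 64

    def __post_init__(self):
        object.__setattr__(self, "bounds", tuple(tuple(b) for b in self.bounds))
        nums = self.nums
        for n in nums:
            if n < 8:
                raise ValueError(f"need >= 8 grid points per axis, got {n}")
        for lo, hi in self.bounds:
            if not hi > lo:
                raise ValueError(f"empty axis bounds ({lo}, {hi})")

    @property
    def nums(self) -> tuple[int, ...]:
        if isinstance(self.num, numbers.Integral):
            return (int(self.num),) * len(self.bounds)
        return tuple(int(n) for n in self.num)

    def axes(self) -> list[np.ndarray]:
        return [
            np.linspace(lo, hi, n) for (lo, hi), n in zip(self.bounds, self.nums)
        ]

    def scaled(self, exps: ScalingExponents) -> "Domain":
        """The image of this box under the scale transformation of ``exps``."""
        alphas = exps.alphas
        new_bounds = tuple(
            (lo * exps.lam ** alphas[i], hi * exps.lam ** alphas[i])
            for i, (lo, hi) in enumerate(self.bounds)
        )
        return Domain(bounds=new_bounds, num=self.num)


def numeric_action(
    spec: LagrangianSpec, field_fn, domain: Domain, grad=None
) -> float:
    """Trapezoidal quadrature of the action over a space-time box.

    Parameters
    ----------
    spec : LagrangianSpec
    field_fn : callable
        ``phi(t, x[, y[, z]])`` accepting broadcastable arrays.
    domain : Domain
        Must have ``spec.spatial_dims + 1`` axes.
    grad : callable, optional
        Analytic gradient ``grad(t, x, ...) -> sequence of derivative
        arrays`` in axis order; when omitted, derivatives are estimated
        with second-order central differences on the grid.

    The result is deterministic for a fixed grid resolution.
    """
    if len(domain.bounds) != spec.spatial_dims + 1:
        raise ValueError(
            f"domain has {len(domain.bounds)} axes but spec needs "
            f"{spec.spatial_dims + 1}"
        )
    axes = domain.axes()
    mesh = np.meshgrid(*axes, indexing="ij")
    values = np.asarray(field_fn(*mesh), dtype=float)
    if grad is not None:
        derivs = [np.asarray(d, dtype=float) for d in grad(*mesh)]
    else:
        derivs = list(np.gradient(values, *axes))
    density = lagrangian_density(spec, values, derivs)
    density = np.broadcast_to(density, values.shape)
    out = density
    for ax in reversed(range(len(axes))):
        out = np.trapezoid(out, axes[ax], axis=ax)
    return float(out)
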