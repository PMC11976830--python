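"""Closed-form integrated Lennard-Jones 12-6 potentials for sphere–rod systems.

The sphere is a uniform continuum of LJ material points (density ``rho_s``),
the rod a material line (line density ``lambda_lin``).  Integrating the LJ
12-6 pair potential over the sphere gives the sphere–point potential
``U_SP(r)``; integrating that along the rod gives the sphere–rod potential
``W``.  The axial integral has three closed-form branches depending on how
the perpendicular distance ``h`` from the sphere center to the rod axis
compares with the sphere radius ``a``:

* ``h > a`` — the rod axis clears the sphere; the primitive ``G`` contains
  arctangent terms in ``y/sqrt(h^2 - a^2)``.
* ``h < a`` — the axis pierces the sphere (the rod itself must stay
  outside); the arctangents turn into a logarithm whose argument, combined
  across the two endpoints, is manifestly positive, keeping ``W`` real.
* ``h = a`` — the axis is tangent to the sphere; a separate, simpler
  primitive applies (the limit of the other two after an h-only singular
  term cancels between the endpoints).

Near tangency the individual terms of the primitives blow up like
``(h^2 - a^2)^{-8}`` while their combination stays finite, so double
precision loses most significant digits there; evaluation escalates to
arbitrary precision (mpmath) with the working precision adapted to the
estimated cancellation.

All quantities are in reduced LJ units (lengths in sigma, energies in
epsilon) unless other parameter values are supplied.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from enum import Enum

import mpmath

from .errors import BranchError, DomainError, OverlapError, PrecisionError
from .geometry import LJParams, LocalConfig, Rod, Sphere, min_distance_to_rod, validate_no_overlap

__all__ = [
    "Branch",
    "PotentialResult",
    "lj_pair",
    "sphere_point_potential",
    "G_primitive",
    "finite_rod_potential",
    "infinite_rod_potential",
    "point_rod_potential",
    "BRANCH_TOLERANCE",
]

#: half-width (in units of sigma) of the band |h - a| <= tau around tangency
#: inside which the dedicated tangent closed form is used
BRANCH_TOLERANCE = 1e-6


class Branch(Enum):
    H_GT_A = "h>a"
    TANGENT = "h=a"
    H_LT_A = "h<a"
    INFINITE_ROD = "infinite_rod"
    SPHERE_POINT = "sphere_point"
    POINT_ROD = "point_rod"


@dataclass(frozen=True)
class PotentialResult:
    """Integrated potential value plus branch/diagnostic metadata."""

    W: float
    branch: Branch
    precision_mode: str  # "standard" | "extended"
    h: float
    delta: float  # h - a

    def __float__(self) -> float:
        return self.W


# ---------------------------------------------------------------------------
# point and sphere-point potentials

def lj_pair(r: float, p: LJParams) -> float:
    """LJ 12-6 potential 4 eps [(sigma/r)^12 - (sigma/r)^6] between two points."""
    if not r > 0:
        raise DomainError(f"pair distance must be positive, got {r}")
    x6 = (p.sigma / r) ** 6
    return 4.0 * p.epsilon * (x6 * x6 - x6)


def sphere_point_potential(r: float, s: Sphere, p: LJParams) -> float:
    """Integrated potential between a continuum LJ sphere and a point at
    center-to-center distance ``r > a``."""
    a = s.a
    if not r > a:
        raise OverlapError(
            f"point at r={r} overlaps sphere of radius {a}", min_distance=r, radius=a
        )
    sig6 = p.sigma ** 6
    u = r * r - a * a
    poly = 5 * a ** 6 + 45 * a ** 4 * r * r + 63 * a ** 2 * r ** 4 + 15 * r ** 6
    pref = 2.0 * s.rho_s * a ** 3 * sig6 * p.A_cs / 9.0
    return pref * (poly * sig6 / (15.0 * u ** 9) - 1.0 / u ** 3)


def _usp_bracket(y, h, a, sig6, ns):
    """U_SP(sqrt(y^2+h^2)) divided by the sphere-rod prefactor
    2 rho_s a^3 sigma^6 A_cs / 9 — i.e. d/dy of the reduced primitives."""
    r2 = y * y + h * h
    u = r2 - a * a
    poly = 5 * a ** 6 + 45 * a ** 4 * r2 + 63 * a ** 2 * r2 * r2 + 15 * r2 ** 3
    return poly * sig6 / (15 * u ** 9) - 1 / u ** 3


# ---------------------------------------------------------------------------
# reduced primitives of the axial integral (prefactor 2 lam rho_s a^3 sig^6 A/9
# divided out).  `ns` is the math backend: math, cmath, or mpmath.

def _g_reduced(y, h, a, sig6, ns):
    """Primitive for h > a, including the arctangent terms."""
    u = h * h - a * a
    D = u + y * y
    S = 16 * a ** 6 + 216 * a ** 4 * h ** 2 + 378 * a ** 2 * h ** 4 + 105 * h ** 6
    su = ns.sqrt(u)
    at = ns.atan(y / su)
    rep = (
        8 * a ** 6 * y / (15 * u * D ** 8)
        - 4 * y * (4 * a ** 6 - 9 * a ** 4 * h ** 2) / (35 * u ** 2 * D ** 7)
        + y * (11 * a ** 6 - 9 * a ** 4 * h ** 2 + 63 * a ** 2 * h ** 4) / (105 * u ** 3 * D ** 6)
        + y * S * (
            1 / (1050 * u ** 4 * D ** 5)
            + 3 / (2800 * u ** 5 * D ** 4)
            + 1 / (800 * u ** 6 * D ** 3)
            + 1 / (640 * u ** 7 * D ** 2)
            + 3 / (1280 * u ** 8 * D)
        )
        + 3 * S / (1280 * u ** 8 * su) * at
    )
    att = y / (4 * u * D ** 2) + 3 * y / (8 * u ** 2 * D) + 3 / (8 * u ** 2 * su) * at
    return sig6 * rep - att


def _q_reduced(y, h, a, sig6, ns):
    """Primitive for h < a without the end-to-end logarithmic term."""
    u = h * h - a * a  # negative
    D = u + y * y      # positive for a rod outside the sphere
    S = 16 * a ** 6 + 216 * a ** 4 * h ** 2 + 378 * a ** 2 * h ** 4 + 105 * h ** 6
    rep = (
        8 * a ** 6 * y / (15 * u * D ** 8)
        - 4 * y * (4 * a ** 6 - 9 * a ** 4 * h ** 2) / (35 * u ** 2 * D ** 7)
        + y * (11 * a ** 6 - 9 * a ** 4 * h ** 2 + 63 * a ** 2 * h ** 4) / (105 * u ** 3 * D ** 6)
        + y * S * (
            1 / (1050 * u ** 4 * D ** 5)
            + 3 / (2800 * u ** 5 * D ** 4)
            + 1 / (800 * u ** 6 * D ** 3)
            + 1 / (640 * u ** 7 * D ** 2)
            + 3 / (1280 * u ** 8 * D)
        )
    )
    att = y / (4 * u * D ** 2) + 3 * y / (8 * u ** 2 * D)
    return sig6 * rep - att


def _p_reduced(y0, yL, h, a, sig6, ns):
    """End-to-end logarithmic term for h < a.

    The per-endpoint logarithms have negative arguments; only their
    combination is real.  In endpoint coordinates the combined argument
    factorizes as ((s-yL)(s+y0)) / ((s+yL)(s-y0)) with s = sqrt(a^2-h^2),
    which is positive whenever the rod stays outside the sphere.
    """
    b = a * a - h * h  # positive
    S = 16 * a ** 6 + 216 * a ** 4 * h ** 2 + 378 * a ** 2 * h ** 4 + 105 * h ** 6
    sb = ns.sqrt(b)
    arg = ((sb - yL) * (sb + y0)) / ((sb + yL) * (sb - y0))
    coef = 3 * sig6 * S / (2560 * b ** 8 * sb) - 3 / (16 * b ** 2 * sb)
    return coef * ns.log(arg)


def _tangent_reduced(y, a, sig6):
    """Primitive for the tangent case h = a (rod axis grazing the sphere)."""
    return 1 / (5 * y ** 5) - (sig6 / 15) * (
        128 * a ** 6 / (17 * y ** 17)
        + 72 * a ** 4 / (5 * y ** 15)
        + 108 * a ** 2 / (13 * y ** 13)
        + 15 / (11 * y ** 11)
    )


def _bracket(y0, yL, h, a, sig6, ns, branch: Branch):
    """Reduced potential W / (2 lam rho_s a^3 sig^6 A_cs / 9) for one branch."""
    if branch is Branch.H_GT_A:
        return _g_reduced(yL, h, a, sig6, ns) - _g_reduced(y0, h, a, sig6, ns)
    if branch is Branch.H_LT_A:
        return (
            _q_reduced(yL, h, a, sig6, ns)
            - _q_reduced(y0, h, a, sig6, ns)
            + _p_reduced(y0, yL, h, a, sig6, ns)
        )
    if branch is Branch.TANGENT:
        return _tangent_reduced(yL, a, sig6) - _tangent_reduced(y0, a, sig6)
    raise BranchError(f"no reduced bracket for branch {branch}")


def G_primitive(y: float, h: float, s: Sphere, p: LJParams) -> float:
    """The h > a primitive of the axial integral (prefactor divided out).

    Its y-derivative is the sphere–point integrand; it is odd in y and
    vanishes at y = 0.  Raises if called on the wrong branch.
    """
    if not h > s.a:
        raise BranchError(f"G primitive requires h > a, got h={h}, a={s.a}")
    return _g_reduced(y, h, s.a, p.sigma ** 6, math)


# ---------------------------------------------------------------------------
# precision management

def _cancellation_scale(a: float, sigma: float) -> float:
    return (a + sigma) ** 2


def needs_extended(h: float, a: float, sigma: float) -> bool:
    """Whether |h^2-a^2| is small enough that the (h^2-a^2)^{-8} terms of the
    primitives cancel beyond double precision."""
    u = abs(h * h - a * a)
    return u < 0.05 * _cancellation_scale(a, sigma)


def _dps_for(h: float, a: float, sigma: float) -> int:
    """Working decimal digits for the extended path: ~8.5 digits are lost per
    decade of |h^2-a^2| below the (a+sigma)^2 scale, plus headroom."""
    u = abs(h * h - a * a)
    if u == 0.0:
        return 200
    loss = 9.0 * max(0.0, math.log10(_cancellation_scale(a, sigma) / u))
    return min(300, 30 + int(loss))


def _prefactor(lambda_lin: float, s: Sphere, p: LJParams) -> float:
    return 2.0 * lambda_lin * s.rho_s * s.a ** 3 * p.sigma ** 6 * p.A_cs / 9.0


def _select_branch(h: float, a: float, sigma: float, y0: float, yL: float) -> Branch:
    d = h - a
    if abs(d) <= BRANCH_TOLERANCE * sigma and y0 * yL > 0.0:
        return Branch.TANGENT
    if d >= 0.0:
        return Branch.H_GT_A
    return Branch.H_LT_A


def _eval_bracket(y0, yL, h, a, sigma, branch, force_extended=False):
    """Evaluate the reduced bracket, escalating precision when needed.

    Returns (value, precision_mode).
    """
    sig6 = sigma ** 6
    extended = force_extended or (branch is not Branch.TANGENT and needs_extended(h, a, sigma))
    if not extended:
        try:
            val = _bracket(y0, yL, h, a, sig6, math, branch)
        except (OverflowError, ZeroDivisionError):
            val = math.nan
        if math.isfinite(val):
            return val, "standard"
        extended = True
    with mpmath.workdps(_dps_for(h, a, sigma)):
        mpf = mpmath.mpf
        val_mp = _bracket(mpf(y0), mpf(yL), mpf(h), mpf(a), mpf(sigma) ** 6, mpmath, branch)
        val = float(val_mp)
    if not math.isfinite(val):
        raise PrecisionError(
            f"bracket non-finite even in extended precision (h={h}, a={a}, y0={y0}, yL={yL})"
        )
    return val, "extended"


# ---------------------------------------------------------------------------
# public potentials

def finite_rod_potential(
    c: LocalConfig, s: Sphere, r: Rod, p: LJParams, force_extended: bool = False
) -> PotentialResult:
    """Integrated sphere–rod potential for a finite rod (closed form).

    Dispatches between the h > a, tangent, and h < a branches.  A rod
    declared infinite routes to :func:`infinite_rod_potential` using the
    perpendicular distance only.  ``force_extended`` evaluates in arbitrary
    precision unconditionally (useful when differencing the result
    numerically, where double-precision noise would be amplified).
    """
    if r.is_infinite:
        return infinite_rod_potential(c.h, s, r.lambda_lin, p)
    if not math.isclose(c.L, r.L, rel_tol=1e-9, abs_tol=0.0):
        raise ValueError(f"configuration rod length {c.L} disagrees with rod.L {r.L}")
    if not validate_no_overlap(c, s):
        raise OverlapError(
            "rod penetrates (or touches) the sphere",
            min_distance=min_distance_to_rod(c),
            radius=s.a,
        )
    h, a, sigma = c.h, s.a, p.sigma
    y0, yL = c.y0, c.yL
    branch = _select_branch(h, a, sigma, y0, yL)
    if branch is Branch.TANGENT:
        # evaluate the tangent primitive exactly at h = a
        val, mode = _eval_bracket(y0, yL, a, a, sigma, branch)
    else:
        val, mode = _eval_bracket(y0, yL, h, a, sigma, branch, force_extended=force_extended)
    W = _prefactor(r.lambda_lin, s, p) * val
    return PotentialResult(W=W, branch=branch, precision_mode=mode, h=h, delta=h - a)


def _infinite_rod_logterms(h: float, s: Sphere, lambda_lin: float, p: LJParams):
    """Log-space pieces of the infinite-rod potential, scaled by t = h/a to
    keep every intermediate in floating range for arbitrarily large spheres."""
    a, sigma = s.a, p.sigma
    t = h / a
    v = t * t - 1.0
    s6 = 16 + 216 * t ** 2 + 378 * t ** 4 + 105 * t ** 6
    lpref = (
        math.log(math.pi * lambda_lin * s.rho_s * p.A_cs / 3.0)
        + 3 * math.log(a)
        + 6 * math.log(sigma)
    )
    l1 = 6 * math.log(sigma) + math.log(s6) - math.log(640.0) - 11 * math.log(a) - 8.5 * math.log(v)
    l2 = -math.log(4.0) - 5 * math.log(a) - 2.5 * math.log(v)
    return lpref, l1, l2, t, v, s6


def infinite_rod_potential(h: float, s: Sphere, lambda_lin: float, p: LJParams) -> PotentialResult:
    """Integrated potential between a sphere and an infinite thin rod.

    Depends only on the center-to-axis distance ``h > a``.  Evaluated in log
    space so that the (h^2-a^2)^{17/2}-type intermediates cannot overflow
    even for very large spheres.
    """
    if not h > s.a:
        raise OverlapError(
            f"infinite rod requires h > a, got h={h}, a={s.a}", min_distance=h, radius=s.a
        )
    lpref, l1, l2, *_ = _infinite_rod_logterms(h, s, lambda_lin, p)
    W = math.exp(lpref + l2) * math.expm1(l1 - l2)
    return PotentialResult(
        W=W, branch=Branch.INFINITE_ROD, precision_mode="standard", h=h, delta=h - s.a
    )


def infinite_rod_dWdh(h: float, s: Sphere, lambda_lin: float, p: LJParams) -> float:
    """Closed-form dW/dh of the infinite-rod potential (log-space, signed sum)."""
    if not h > s.a:
        raise OverlapError(f"infinite rod requires h > a, got h={h}, a={s.a}")
    a, sigma = s.a, p.sigma
    lpref, _l1, _l2, t, v, s6 = _infinite_rod_logterms(h, s, lambda_lin, p)
    s6p = 432 * t + 1512 * t ** 3 + 630 * t ** 5  # d(s6)/dt
    lA = 6 * math.log(sigma) + math.log(s6p) - math.log(640.0) - 12 * math.log(a) - 8.5 * math.log(v)
    lB = (
        math.log(17.0 * t * s6)
        + 6 * math.log(sigma)
        - math.log(640.0)
        - 12 * math.log(a)
        - 9.5 * math.log(v)
    )
    lC = math.log(5.0 * t / 4.0) - 6 * math.log(a) - 3.5 * math.log(v)
    m = max(lA, lB, lC)
    total = math.exp(lA - m) - math.exp(lB - m) + math.exp(lC - m)
    if total == 0.0:
        return 0.0
    return math.copysign(math.exp(lpref + m + math.log(abs(total))), total)


def infinite_rod_attractive_force(h: float, s: Sphere, lambda_lin: float, p: LJParams) -> float:
    """Magnitude of the attractive (vdW) force component on the sphere from
    an infinite rod: 5 pi lam rho_s a^3 sig^6 A_cs h / (12 (h^2-a^2)^{7/2})."""
    if not h > s.a:
        raise OverlapError(f"infinite rod requires h > a, got h={h}, a={s.a}")
    u = h * h - s.a * s.a
    pref = 5.0 * math.pi * lambda_lin * s.rho_s * s.a ** 3 * p.sigma ** 6 * p.A_cs / 12.0
    return pref * h / u ** 3.5


def point_rod_potential(h: float, lambda_lin: float, p: LJParams) -> float:
    """Integrated LJ potential between a point particle and an infinite rod
    at perpendicular distance ``h``: (lam sig^6 A_cs / 16 h^5)((21/32) sig^6/h^6 - 1)."""
    if not h > 0:
        raise DomainError(f"point-rod distance must be positive, got {h}")
    sig6 = p.sigma ** 6
    return lambda_lin * sig6 * p.A_cs / (16.0 * h ** 5) * ((21.0 / 32.0) * sig6 / h ** 6 - 1.0)
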