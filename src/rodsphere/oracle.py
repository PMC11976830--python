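"""Independent numerical reference for the closed forms.

Everything here goes back to the defining integrals: adaptive quadrature of
the sphere–point potential along the rod (with the interval split at the
point of closest approach, where the integrand peaks), vector quadrature of
the segment force density for torques, and a two-dimensional quadrature of
the bare LJ pair potential over the sphere volume as an independent check
of the sphere–point closed form itself.  These routines are deliberately
slow and are used only by the test-suite and the ``verify`` CLI command.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath
import numpy as np
from scipy.integrate import quad

from .errors import OracleError, OverlapError
from .geometry import LJParams, LocalConfig, Rod, Sphere, min_distance_to_rod, validate_no_overlap
from .potentials import lj_pair, sphere_point_potential

__all__ = [
    "QuadratureSpec",
    "quadrature_potential",
    "quadrature_torque",
    "sphere_volume_quadrature",
]


@dataclass(frozen=True)
class QuadratureSpec:
    """Tolerances for the reference quadratures."""

    rel_tol: float = 1e-12
    abs_tol: float = 1e-300
    max_subdivisions: int = 400
    truncation_length: float = 1e4  # half-length, in sigma, for pseudo-infinite rods
    extended: bool = False  # force the arbitrary-precision integrator


DEFAULT_SPEC = QuadratureSpec()


def _split_points(y0: float, yL: float):
    return [0.0] if y0 < 0.0 < yL else None


def _quad_checked(f, lo, hi, q: QuadratureSpec, points=None):
    import warnings
    from scipy.integrate import IntegrationWarning

    with warnings.catch_warnings():
        # near-zero integrals trip the relative-tolerance roundoff warning;
        # the absolute error estimate below is what actually matters
        warnings.simplefilter("ignore", IntegrationWarning)
        val, err = quad(
            f, lo, hi, epsabs=q.abs_tol, epsrel=q.rel_tol, limit=q.max_subdivisions, points=points
        )
    if not math.isfinite(val):
        raise OracleError(f"quadrature returned non-finite value on [{lo}, {hi}]")
    if abs(err) > 100 * max(q.rel_tol * abs(val), 1e-12):
        raise OracleError(f"quadrature error estimate {err} too large for value {val}")
    return val


def quadrature_potential(
    c: LocalConfig, s: Sphere, r: Rod, p: LJParams, q: QuadratureSpec = DEFAULT_SPEC
) -> float:
    """Adaptive quadrature of lam * U_SP(sqrt(y^2+h^2)) along the rod."""
    if not r.is_infinite and not validate_no_overlap(c, s):
        raise OverlapError(
            "rod penetrates the sphere", min_distance=min_distance_to_rod(c), radius=s.a
        )
    h = c.h
    lam = r.lambda_lin
    if r.is_infinite:
        if not h > s.a:
            raise OverlapError(f"infinite rod requires h > a, got h={h}")
        T = q.truncation_length * p.sigma
        y0, yL = -T, T
    else:
        y0, yL = c.y0, c.yL
    if q.extended or abs(h - s.a) < 0.01 * p.sigma:
        # near tangency: integrate in arbitrary precision so the reference is
        # at least as accurate as the extended-precision analytic path
        with mpmath.workdps(40):
            hh = mpmath.mpf(h)

            def f_mp(y):
                return sphere_point_potential(float(mpmath.hypot(y, hh)), s, p)

            pts = [y0, 0.0, yL] if y0 < 0.0 < yL else [y0, yL]
            val = float(lam * mpmath.quad(f_mp, pts))
        if not math.isfinite(val):
            raise OracleError("extended-precision quadrature returned non-finite value")
        return val

    def f(y):
        return sphere_point_potential(math.hypot(y, h), s, p)

    return lam * _quad_checked(f, y0, yL, q, points=_split_points(y0, yL))


def quadrature_torque(
    c: LocalConfig,
    s: Sphere,
    r: Rod,
    p: LJParams,
    q: QuadratureSpec = DEFAULT_SPEC,
    reference_point: str = "rod_center",
) -> float:
    """Signed n_z torque on the rod from direct vector quadrature.

    Each rod segment at axial position x feels the central force
    f = -lam U_SP'(r) (s - c)/r from the sphere; the torque about the
    reference point is the integral of the lever-arm cross product.  In
    local in-plane coordinates the z-component reduces to
    lam * h * integral (x - x_ref) U_SP'(r)/r dx.
    """
    if r.is_infinite:
        raise OverlapError("torque quadrature requires a finite rod")
    if not validate_no_overlap(c, s):
        raise OverlapError(
            "rod penetrates the sphere", min_distance=min_distance_to_rod(c), radius=s.a
        )
    if reference_point == "rod_center":
        x_ref = c.L / 2.0
    elif reference_point == "rod_end_O":
        x_ref = 0.0
    else:
        raise ValueError(f"unknown reference point {reference_point!r}")
    h, x_c = c.h, c.x_c
    lam = r.lambda_lin

    a = s.a
    sig6 = p.sigma ** 6
    pref = 2.0 * s.rho_s * a ** 3 * sig6 * p.A_cs / 9.0

    def dusp(rr):
        # analytic r-derivative of the sphere-point potential
        u = rr * rr - a * a
        poly = 5 * a ** 6 + 45 * a ** 4 * rr ** 2 + 63 * a ** 2 * rr ** 4 + 15 * rr ** 6
        dpoly = 90 * a ** 4 * rr + 252 * a ** 2 * rr ** 3 + 90 * rr ** 5
        return pref * (
            dpoly * sig6 / (15.0 * u ** 9)
            - 18.0 * rr * poly * sig6 / (15.0 * u ** 10)
            + 6.0 * rr / u ** 4
        )

    def f(x):
        rr = math.hypot(x - x_c, h)
        return (x - x_ref) * dusp(rr) / rr

    pts = [x_c] if 0.0 < x_c < c.L else None
    return lam * h * _quad_checked(f, 0.0, c.L, q, points=pts)


def sphere_volume_quadrature(
    r_point: float, s: Sphere, p: LJParams, q: QuadratureSpec = DEFAULT_SPEC
) -> float:
    """2-D quadrature of the LJ pair potential over the sphere volume.

    Independent check of the sphere–point closed form: integrate over shell
    radius R and polar angle (via its cosine mu), with the point on the
    polar axis at distance r_point > a from the center.
    """
    if not r_point > s.a:
        raise OverlapError(f"point at r={r_point} overlaps sphere of radius {s.a}")

    def inner(R):
        def g(mu):
            d = math.sqrt(R * R + r_point * r_point - 2.0 * R * r_point * mu)
            return lj_pair(d, p)

        val, _ = quad(g, -1.0, 1.0, epsabs=q.abs_tol, epsrel=q.rel_tol, limit=q.max_subdivisions)
        return R * R * val

    outer, err = quad(
        inner, 0.0, s.a, epsabs=q.abs_tol, epsrel=q.rel_tol, limit=q.max_subdivisions
    )
    if not math.isfinite(outer):
        raise OracleError("sphere volume quadrature returned non-finite value")
    return 2.0 * math.pi * s.rho_s * outer
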