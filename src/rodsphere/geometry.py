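"""Bodies, parameters and sphere–rod configuration geometry.

A configuration is described in the rod's local polar frame: the x-axis runs
along the rod axis from end O toward end L, the sphere center sits at polar
coordinates (rho, theta) with 0 <= theta <= pi measured from the rod
direction.  Derived quantities:

* ``h = rho*sin(theta)`` — perpendicular distance from the sphere center to
  the rod axis (the quantity the potentials depend on most sensitively),
* ``x_c = rho*cos(theta)`` — axial coordinate of the projection of the
  center onto the rod axis,
* ``y0 = -x_c`` and ``yL = L - x_c`` — the rod endpoints in the axial
  coordinate shifted so the projection of the center is at the origin.

Global (Cartesian) configurations are reduced to this local frame plus an
orthonormal basis used to rotate forces and torques back out.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidGeometryError

__all__ = [
    "LJParams",
    "Sphere",
    "Rod",
    "LocalConfig",
    "GlobalConfig",
    "FrameBasis",
    "local_config_from_global",
    "min_distance_to_rod",
    "validate_no_overlap",
    "read_config_table",
]


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones 12-6 parameters in reduced units.

    ``A_cs = 24*pi*epsilon`` is the Hamaker-style constant that sets the
    strength of all integrated (continuum) interactions; it is always
    derived from ``epsilon``, never stored independently.
    """

    epsilon: float = 1.0
    sigma: float = 1.0

    def __post_init__(self):
        if not (self.epsilon > 0 and math.isfinite(self.epsilon)):
            raise ValueError(f"epsilon must be positive, got {self.epsilon}")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be positive, got {self.sigma}")

    @property
    def A_cs(self) -> float:
        return 24.0 * math.pi * self.epsilon


@dataclass(frozen=True)
class Sphere:
    """A continuum sphere of radius ``a`` filled with LJ material points
    at number density ``rho_s`` (per length^3)."""

    a: float
    rho_s: float = 1.0

    def __post_init__(self):
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError(f"sphere radius must be positive and finite, got {self.a}")
        if not (self.rho_s > 0 and math.isfinite(self.rho_s)):
            raise ValueError(f"rho_s must be positive, got {self.rho_s}")


@dataclass(frozen=True)
class Rod:
    """A thin material line of length ``L`` (``math.inf`` allowed) with LJ
    points at line density ``lambda_lin`` (per length)."""

    L: float
    lambda_lin: float = 1.0

    def __post_init__(self):
        if not (self.L >= 0):
            raise ValueError(f"rod length must be >= 0 (or inf), got {self.L}")
        if not (self.lambda_lin > 0 and math.isfinite(self.lambda_lin)):
            raise ValueError(f"lambda_lin must be positive, got {self.lambda_lin}")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.L)


@dataclass(frozen=True)
class LocalConfig:
    """Sphere center at polar coordinates (rho, theta) in the rod frame of a
    rod of length ``L`` whose O-end is the origin."""

    rho: float
    theta: float
    L: float

    def __post_init__(self):
        if not (self.rho >= 0 and math.isfinite(self.rho)):
            raise ValueError(f"rho must be >= 0 and finite, got {self.rho}")
        if not (0.0 <= self.theta <= math.pi):
            raise ValueError(f"theta must lie in [0, pi], got {self.theta}")
        if not (self.L >= 0):
            raise ValueError(f"L must be >= 0 (or inf), got {self.L}")

    @property
    def h(self) -> float:
        """Perpendicular distance from the sphere center to the rod axis."""
        return self.rho * math.sin(self.theta)

    @property
    def x_c(self) -> float:
        """Axial coordinate of the projection of the sphere center."""
        return self.rho * math.cos(self.theta)

    @property
    def y0(self) -> float:
        return -self.x_c

    @property
    def yL(self) -> float:
        return self.L - self.x_c

    def mirrored(self) -> "LocalConfig":
        """The same physical configuration described from the L-end
        (theta -> pi - theta with the origin moved to the other end)."""
        if math.isinf(self.L):
            raise InvalidGeometryError("cannot mirror an infinite rod about its far end")
        xc_m = self.L - self.x_c
        rho_m = math.hypot(xc_m, self.h)
        theta_m = math.atan2(self.h, xc_m)
        return LocalConfig(rho=rho_m, theta=theta_m, L=self.L)


@dataclass(frozen=True)
class GlobalConfig:
    """Cartesian description: sphere center and the two rod endpoints."""

    sphere_center: np.ndarray
    rod_end_O: np.ndarray
    rod_end_L: np.ndarray

    def __post_init__(self):
        for name in ("sphere_center", "rod_end_O", "rod_end_L"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,):
                raise InvalidGeometryError(f"{name} must be a 3-vector, got shape {v.shape}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class FrameBasis:
    """Orthonormal directions of the local frame expressed in global
    coordinates: ``n_x`` along the rod (O -> L), ``n_rho`` from O toward the
    sphere center, ``n_z = (n_x x n_rho)/sin(theta)`` (for sin(theta) > 0),
    and ``n_h`` the in-plane unit vector from the axis toward the center."""

    n_x: np.ndarray
    n_rho: np.ndarray
    n_z: np.ndarray
    n_h: np.ndarray = field(default=None)


def _deterministic_perpendicular(u: np.ndarray) -> np.ndarray:
    """A reproducible unit vector perpendicular to unit vector ``u``: start
    from the coordinate axis with the smallest |component| and orthogonalize."""
    k = int(np.argmin(np.abs(u)))
    e = np.zeros(3)
    e[k] = 1.0
    v = e - np.dot(e, u) * u
    return v / np.linalg.norm(v)


def local_config_from_global(g: GlobalConfig) -> tuple[LocalConfig, FrameBasis]:
    """Reduce a Cartesian configuration to the local polar frame.

    Returns the local configuration and the basis vectors needed to rotate
    local-frame forces/torques into global coordinates.  When the sphere
    center lies on the rod axis (sin(theta) = 0) the perpendicular
    directions are chosen deterministically.
    """
    axis = g.rod_end_L - g.rod_end_O
    L = float(np.linalg.norm(axis))
    if L <= 0.0:
        raise InvalidGeometryError("rod endpoints coincide; rod direction undefined")
    n_x = axis / L

    d = g.sphere_center - g.rod_end_O
    rho = float(np.linalg.norm(d))
    if rho > 0.0:
        n_rho = d / rho
        cos_t = float(np.clip(np.dot(n_x, n_rho), -1.0, 1.0))
        theta = math.acos(cos_t)
    else:
        # center exactly at end O: direction degenerate, theta conventionally 0
        n_rho = n_x.copy()
        theta = 0.0

    cross = np.cross(n_x, n_rho)
    sin_t = float(np.linalg.norm(cross))
    if sin_t > 1e-14:
        n_z = cross / sin_t
        n_h = np.cross(n_z, n_x)  # in-plane, perpendicular to rod, toward center
    else:
        n_h = _deterministic_perpendicular(n_x)
        n_z = np.cross(n_x, n_h)

    c = LocalConfig(rho=rho, theta=theta, L=L)
    return c, FrameBasis(n_x=n_x, n_rho=n_rho, n_z=n_z, n_h=n_h)


def min_distance_to_rod(c: LocalConfig) -> float:
    """Minimum distance from the sphere center to the rod segment."""
    if c.y0 <= 0.0 <= c.yL:
        return c.h
    y_near = min(abs(c.y0), abs(c.yL))
    return math.hypot(c.h, y_near)


def validate_no_overlap(c: LocalConfig, s: Sphere) -> bool:
    """True iff the whole rod lies strictly outside the sphere."""
    return min_distance_to_rod(c) > s.a


def read_config_table(path) -> pd.DataFrame:
    """Read a batch of configurations from CSV or JSON.

    Accepted column sets:

    * global: ``xs,ys,zs,xo,yo,zo,xl,yl,zl`` (sphere center, rod end O,
      rod end L), or
    * local: ``rho,theta,L``.

    Returns the table with an added ``kind`` attribute ('global' or 'local').
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path, comment="#")
    global_cols = ["xs", "ys", "zs", "xo", "yo", "zo", "xl", "yl", "zl"]
    local_cols = ["rho", "theta", "L"]
    if all(col in df.columns for col in global_cols):
        df.attrs["kind"] = "global"
    elif all(col in df.columns for col in local_cols):
        df.attrs["kind"] = "local"
    else:
        raise InvalidGeometryError(
            "configuration table must have columns "
            f"{global_cols} (global) or {local_cols} (local); got {list(df.columns)}"
        )
    return df


def global_config_from_row(row) -> GlobalConfig:
    """Build a GlobalConfig from one row of a global-kind table."""
    return GlobalConfig(
        sphere_center=np.array([row["xs"], row["ys"], row["zs"]], dtype=float),
        rod_end_O=np.array([row["xo"], row["yo"], row["zo"]], dtype=float),
        rod_end_L=np.array([row["xl"], row["yl"], row["zl"]], dtype=float),
    )
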