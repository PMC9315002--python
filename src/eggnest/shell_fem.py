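"""Axisymmetric thin-shell compression stiffness.

Axial compression of an egg between two rigid plates is, in the linear
small-displacement limit, an axisymmetric problem: the 3-D shell reduces to
its meridian. The meridian is discretised into straight conical-frustum
elements with Kirchhoff-Love (thin shell) kinematics — linear meridional
displacement, cubic-Hermite normal displacement — the classical
axisymmetric shell-of-revolution element. The rigid frictionless plates
enter as concentrated axial loads at the two poles (the contact patch
shrinks to a point as the displacement goes to zero), so the plate-to-plate
stiffness ``K = F / Delta`` sees the two pole dimples in series.

For a thin spherical shell the point-load stiffness has the Reissner
closed form ``K_single = 4 E t^2 / (R sqrt(3 (1 - nu^2)))`` per dimple,
which serves as the analytic oracle for the solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .profiles import EggProfile

__all__ = [
    "ShellMaterial",
    "EggSpecimen",
    "StiffnessResult",
    "solve_axial_stiffness",
    "reissner_sphere_stiffness",
    "GRAVITY",
    "EGG_DENSITY",
]

GRAVITY = 9.81            # m s^-2
EGG_DENSITY = 1031.0      # kg m^-3, whole-egg density used when mass is absent
DEFAULT_E = 30e9          # Pa, typical avian eggshell Young's modulus
DEFAULT_NU = 0.3


@dataclass(frozen=True)
class ShellMaterial:
    """Linear-elastic shell wall: Young's modulus (Pa), Poisson ratio,
    uniform thickness (m)."""

    youngs_modulus: float = DEFAULT_E
    poisson: float = DEFAULT_NU
    thickness: float = 0.0

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0 <= self.poisson < 0.5:
            raise ValueError("Poisson ratio must be in [0, 0.5)")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class EggSpecimen:
    """One species' egg: geometry, wall material and mass.

    ``weight`` is the egg weight in newtons, ``mass * g``.
    """

    profile: EggProfile
    material: ShellMaterial
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError("mass must be positive")

    @property
    def weight(self) -> float:
        return self.mass * GRAVITY


@dataclass(frozen=True)
class StiffnessResult:
    """Axial compression stiffness with mesh-convergence metadata."""

    stiffness: float          # K, N m^-1
    axis: str                 # "long" | "short"
    mesh_elements: int        # meridian elements at the finest refinement
    converged: bool
    relative_change: float    # |K_fine - K_coarse| / K_fine at last refinement


def reissner_sphere_stiffness(radius: float, thickness: float,
                              youngs_modulus: float, poisson: float) -> float:
    """Reissner point-load stiffness of a thin spherical shell (one dimple).

    ``K = 4 E t^2 / (R sqrt(3 (1 - nu^2)))``, newtons per metre.
    """
    return 4.0 * youngs_modulus * thickness ** 2 / (
        radius * math.sqrt(3.0 * (1.0 - poisson ** 2)))


def _mesh_meridian(profile: EggProfile, n_elements: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes along the meridian, cosine-graded in arc length toward both
    poles (the point-load boundary layer scales as sqrt(R t))."""
    s_dense = profile.arc_length()
    total = s_dense[-1]
    t = np.linspace(0.0, np.pi, n_elements + 1)
    s_nodes = total * (1.0 - np.cos(t)) / 2.0
    z = np.interp(s_nodes, s_dense, profile.z)
    r = np.interp(s_nodes, s_dense, profile.r)
    r[0] = r[-1] = 0.0
    return r, z

# 4-point Gauss rule on [0, 1]
_GX = (np.polynomial.legendre.leggauss(4)[0] + 1.0) / 2.0
_GW = np.polynomial.legendre.leggauss(4)[1] / 2.0


def _element_stiffness(r1, z1, r2, z2, C, D, nu):
    """6x6 stiffness of one conical frustum in global (u_r, u_z, theta) DOFs.

    Local DOFs are (u_tangential, w_normal, beta) at each node, with linear
    u, Hermite-cubic w; beta = -dw/ds is the meridian rotation. Strains:
    eps_s = u', eps_theta = u_r/r, kap_s = -w'', kap_theta = -w' t_r / r.
    """
    L = math.hypot(r2 - r1, z2 - z1)
    tr, tz = (r2 - r1) / L, (z2 - z1) / L
    nr, nz = tz, -tr
    k = np.zeros((6, 6))
    for xi, wgt in zip(_GX, _GW):
        r = r1 + xi * (r2 - r1)
        # shape functions: u = [1-xi, xi]; w Hermite in (w1, th1, w2, th2)
        # with nodal slope w' = -theta
        h = np.array([1 - 3 * xi**2 + 2 * xi**3,
                      -L * (xi - 2 * xi**2 + xi**3),
                      3 * xi**2 - 2 * xi**3,
                      -L * (xi**3 - xi**2)])
        dh = np.array([(-6 * xi + 6 * xi**2) / L,
                       -(1 - 4 * xi + 3 * xi**2),
                       (6 * xi - 6 * xi**2) / L,
                       -(3 * xi**2 - 2 * xi)])
        d2h = np.array([(-6 + 12 * xi) / L**2,
                        -(-4 + 6 * xi) / L,
                        (6 - 12 * xi) / L**2,
                        -(6 * xi - 2) / L])
        # strain-displacement rows over local DOFs [u1, w1, th1, u2, w2, th2]
        B = np.zeros((4, 6))
        B[0, 0], B[0, 3] = -1.0 / L, 1.0 / L                       # eps_s
        B[1, 0] = (1 - xi) * tr / r                                 # eps_theta
        B[1, 3] = xi * tr / r
        B[1, [1, 2, 4, 5]] = h * nr / r
        B[2, [1, 2, 4, 5]] = -d2h                                   # kappa_s
        B[3, [1, 2, 4, 5]] = -dh * tr / r                           # kappa_theta
        E = np.array([[C, nu * C, 0, 0],
                      [nu * C, C, 0, 0],
                      [0, 0, D, nu * D],
                      [0, 0, nu * D, D]])
        k += wgt * L * 2 * math.pi * r * (B.T @ E @ B)
    T = np.zeros((6, 6))
    for a in (0, 3):
        T[a, a], T[a, a + 1] = tr, tz
        T[a + 1, a], T[a + 1, a + 1] = nr, nz
        T[a + 2, a + 2] = 1.0
    return T.T @ k @ T


def _solve_once(profile: EggProfile, material: ShellMaterial,
                n_elements: int) -> float:
    """Plate-to-plate axial stiffness K (N/m) for one mesh."""
    r, z = _mesh_meridian(profile, n_elements)
    E, nu, t = material.youngs_modulus, material.poisson, material.thickness
    C = E * t / (1 - nu ** 2)
    D = E * t ** 3 / (12 * (1 - nu ** 2))
    n_nodes = n_elements + 1
    rows, cols, vals = [], [], []
    for e in range(n_elements):
        ke = _element_stiffness(r[e], z[e], r[e + 1], z[e + 1], C, D, nu)
        dofs = [3 * e, 3 * e + 1, 3 * e + 2, 3 * e + 3, 3 * e + 4, 3 * e + 5]
        for a in range(6):
            for b in range(6):
                rows.append(dofs[a])
                cols.append(dofs[b])
                vals.append(ke[a, b])
    K = coo_matrix((vals, (rows, cols)), shape=(3 * n_nodes, 3 * n_nodes)).tocsr()
    # BCs: poles on the axis -> u_r = 0, theta = 0; bottom pole u_z = 0
    fixed = [0, 2, 3 * n_elements, 3 * n_elements + 2, 1]
    free = np.setdiff1d(np.arange(3 * n_nodes), fixed)
    F = np.zeros(3 * n_nodes)
    F[3 * n_elements + 1] = -1.0   # unit compressive force at the top pole
    u = np.zeros(3 * n_nodes)
    u[free] = spsolve(K[np.ix_(free, free)].tocsc(), F[free])
    delta = abs(u[3 * n_elements + 1])
    return 1.0 / delta


def solve_axial_stiffness(specimen: EggSpecimen, mesh_elements: int = 200,
                          axis: str = "long", rtol: float = 5e-3,
                          max_refinements: int = 3) -> StiffnessResult:
    """Linear axial compression stiffness of an egg between rigid plates.

    Solves the axisymmetric thin-shell problem on meshes of
    ``mesh_elements``, ``2 * mesh_elements``, ... until the stiffness
    changes by less than ``rtol`` between refinements (at least one
    refinement is always performed). ``axis="long"`` compresses along the
    axis of revolution; ``axis="short"`` is not supported by the
    axisymmetric reduction and raises.
    """
    if axis != "long":
        raise NotImplementedError(
            "the axisymmetric solver compresses along the long axis only")
    if mesh_elements < 50:
        raise ValueError("mesh_elements must be >= 50")
    prof, mat = specimen.profile, specimen.material
    if mat.thickness / prof.breadth >= 0.1:
        warnings.warn("t/A >= 0.1: outside the thin-shell regime, "
                      "stiffness may be inaccurate", stacklevel=2)
    n = mesh_elements
    k_prev = _solve_once(prof, mat, n)
    rel = np.inf
    for _ in range(max_refinements):
        n *= 2
        k_new = _solve_once(prof, mat, n)
        rel = abs(k_new - k_prev) / abs(k_new)
        k_prev = k_new
        if rel < rtol:
            break
    return StiffnessResult(stiffness=float(k_prev), axis=axis,
                           mesh_elements=n, converged=bool(rel < rtol),
                           relative_change=float(rel))
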