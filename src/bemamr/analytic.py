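"""Closed-form reference solutions on spherical geometries.

These classical results serve as independent accuracy references for the BEM
solver: the uniform interior field of a conducting sphere in a uniform
applied field, the capacitance of a sphere, and the Legendre-series surface
potential of a current dipole inside a multilayer concentric sphere with an
insulating exterior.
"""

from __future__ import annotations

import numpy as np
from scipy.special import eval_legendre, lpmv

from .operator import EPS0

__all__ = [
    "uniform_field_interior_factor",
    "sphere_capacitance",
    "multilayer_sphere_dipole_potential",
]


def uniform_field_interior_factor(sigma_in: float, sigma_out: float) -> float:
    """Interior field of a homogeneous sphere (conductivity sigma_in) embedded
    in an unbounded medium sigma_out under a uniform applied field:
    E_in = 3 sigma_out / (sigma_in + 2 sigma_out) * E0, uniform."""
    return 3.0 * sigma_out / (sigma_in + 2.0 * sigma_out)


def sphere_capacitance(radius: float) -> float:
    """Capacitance of an isolated conducting sphere, 4 pi eps0 R (F)."""
    return 4.0 * np.pi * EPS0 * radius


def multilayer_sphere_dipole_potential(
    radii,
    sigmas,
    dipole_pos,
    dipole_moment,
    points,
    lmax: int = 80,
) -> np.ndarray:
    """Potential of a current dipole inside nested concentric spherical shells.

    Parameters
    ----------
    radii : increasing boundary radii r_1 < ... < r_L (m); air outside r_L.
    sigmas : conductivity of the medium inside each boundary (S/m); the
        dipole must sit in the innermost compartment.
    dipole_pos : (3,) dipole location (m), |pos| < r_1.
    dipole_moment : (3,) current dipole moment p = I * d (A*m), pointing from
        sink to source.
    points : (n, 3) observation points with r_{L-1} < |point| <= r_L (the
        outermost compartment, e.g. skin facet centroids).
    lmax : series truncation order.

    The potential in layer j is expanded per degree l as
    A_j r^l + B_j r^-(l+1) (times P_l or P_l^1 cos(phi)); coefficients follow
    from continuity of V and of sigma dV/dr at each boundary and a vanishing
    normal current at the outer (insulated) boundary.  The same radial system
    serves the radial (m=0) and tangential (m=1) moment components.
    """
    radii = np.asarray(radii, dtype=np.float64)
    sigmas = np.asarray(sigmas, dtype=np.float64)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    L = len(radii)
    pos = np.asarray(dipole_pos, dtype=np.float64)
    p = np.asarray(dipole_moment, dtype=np.float64)
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    b = np.linalg.norm(pos)
    if b >= radii[0]:
        raise ValueError("dipole must lie inside the innermost boundary")

    # axis frame: z along the dipole radius vector (or +z for a central dipole)
    if b > 1e-14:
        ez = pos / b
    else:
        ez = np.array([0.0, 0.0, 1.0])
    p_r = float(p @ ez)
    p_t_vec = p - p_r * ez
    p_t = float(np.linalg.norm(p_t_vec))
    if p_t > 1e-14 * max(np.linalg.norm(p), 1e-300):
        ex = p_t_vec / p_t
    else:
        ex = np.cross(ez, [0.0, 0.0, 1.0])
        if np.linalg.norm(ex) < 1e-8:
            ex = np.cross(ez, [0.0, 1.0, 0.0])
        ex /= np.linalg.norm(ex)
    ey = np.cross(ez, ex)

    r_obs = np.linalg.norm(pts, axis=1)
    cos_g = np.clip((pts @ ez) / np.maximum(r_obs, 1e-300), -1.0, 1.0)
    phi = np.arctan2(pts @ ey, pts @ ex)

    # normalize lengths by the outer radius for numerical range
    s = radii[-1]
    rr = radii / s
    bb = b / s
    ro = r_obs / s

    V = np.zeros(len(pts))
    for l in range(1, lmax + 1):
        # source coefficients of the primary (infinite-medium) expansion,
        # valid for r > b: V_src = beta * r^-(l+1) * angular
        beta_r = p_r * l * bb ** (l - 1) / (4.0 * np.pi * sigmas[0] * s**2)
        beta_t = p_t * bb ** (l - 1) / (4.0 * np.pi * sigmas[0] * s**2)

        n_unk = 2 * L - 1  # A_1, then (A_j, B_j) for j = 2..L
        Amat = np.zeros((n_unk, n_unk))
        rhs_unit = np.zeros(n_unk)  # per unit source coefficient beta

        def a_idx(j):  # A_j column
            return 0 if j == 1 else 1 + 2 * (j - 2) + 0

        def b_idx(j):  # B_j column (j >= 2)
            return 1 + 2 * (j - 2) + 1

        row = 0
        for j in range(1, L):  # interface between layer j and j+1 at rr[j-1]
            R = rr[j - 1]
            # potential continuity
            Amat[row, a_idx(j)] = R**l
            if j >= 2:
                Amat[row, b_idx(j)] = R ** -(l + 1)
            Amat[row, a_idx(j + 1)] -= R**l
            Amat[row, b_idx(j + 1)] -= R ** -(l + 1)
            if j == 1:
                rhs_unit[row] = -(R ** -(l + 1))  # from B_1 = beta
            row += 1
            # normal current continuity
            Amat[row, a_idx(j)] = sigmas[j - 1] * l * R ** (l - 1)
            if j >= 2:
                Amat[row, b_idx(j)] = -sigmas[j - 1] * (l + 1) * R ** -(l + 2)
            Amat[row, a_idx(j + 1)] -= sigmas[j] * l * R ** (l - 1)
            Amat[row, b_idx(j + 1)] -= -sigmas[j] * (l + 1) * R ** -(l + 2)
            if j == 1:
                rhs_unit[row] = sigmas[0] * (l + 1) * R ** -(l + 2)
            row += 1
        # insulated outer boundary at rr[-1] = 1
        if L == 1:
            Amat[row, a_idx(1)] = l
            rhs_unit[row] = (l + 1)
        else:
            Amat[row, a_idx(L)] = l
            Amat[row, b_idx(L)] = -(l + 1)
            rhs_unit[row] = 0.0

        x = np.linalg.solve(Amat, rhs_unit)
        A_L = x[a_idx(L)]
        if L == 1:
            # single sphere: layer 1 holds the source term directly
            rad = A_L * ro**l + ro ** -(l + 1)
        else:
            rad = A_L * ro**l + x[b_idx(L)] * ro ** -(l + 1)

        Pl = eval_legendre(l, cos_g)
        V += beta_r * rad * Pl
        if p_t != 0.0:
            # scipy's lpmv carries the Condon-Shortley phase; the classical
            # expansion uses the unsigned associated Legendre function
            Pl1 = -lpmv(1, l, cos_g)
            V += beta_t * rad * Pl1 * np.cos(phi)
    return V
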