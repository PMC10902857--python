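"""Analytic and semi-analytic integrals of the Laplace kernels over triangles.

The two kernels that appear in the charge formulation are the single-layer
kernel 1/|r - r'| and its (negative) gradient (r - r')/|r - r'|^3.  For a
constant (pulse) charge density both inner integrals over a triangle have
closed forms built from per-edge logarithms plus a solid-angle term; the
remaining outer integral is done with a symmetric Gauss rule, optionally on a
4:1-subdivided copy of the outer triangle when the pair is close or touching.

Conventions: triangles are (…, 3, 3) vertex arrays, counter-clockwise when
viewed from the side the unit normal points to.  All lengths in meters.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "tri_potential_field",
    "tri_solid_angle",
    "gauss7_points",
    "subdivided_quadrature",
    "double_integral_gradient",
    "double_integral_single_layer",
]

_TINY = 1e-300

# 7-point symmetric Gauss rule on the triangle, degree of exactness 5.
_G7_BARY = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [0.797426985353087, 0.101286507323456, 0.101286507323456],
        [0.101286507323456, 0.797426985353087, 0.101286507323456],
        [0.101286507323456, 0.101286507323456, 0.797426985353087],
        [0.059715871789770, 0.470142064105115, 0.470142064105115],
        [0.470142064105115, 0.059715871789770, 0.470142064105115],
        [0.470142064105115, 0.470142064105115, 0.059715871789770],
    ]
)
_G7_W = np.array(
    [
        0.225,
        0.125939180544827,
        0.125939180544827,
        0.125939180544827,
        0.132394152788506,
        0.132394152788506,
        0.132394152788506,
    ]
)


def tri_solid_angle(tris: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Signed solid angle of triangles seen from points (van Oosterom-Strackee).

    Negative when the point lies on the side the triangle normal points to.
    """
    r1 = tris[..., 0, :] - points
    r2 = tris[..., 1, :] - points
    r3 = tris[..., 2, :] - points
    n1 = np.linalg.norm(r1, axis=-1)
    n2 = np.linalg.norm(r2, axis=-1)
    n3 = np.linalg.norm(r3, axis=-1)
    num = np.einsum("...i,...i->...", r1, np.cross(r2, r3))
    den = (
        n1 * n2 * n3
        + np.einsum("...i,...i->...", r1, r2) * n3
        + np.einsum("...i,...i->...", r1, r3) * n2
        + np.einsum("...i,...i->...", r2, r3) * n1
    )
    return 2.0 * np.arctan2(num, den)


def tri_potential_field(tris: np.ndarray, points: np.ndarray):
    """Closed-form inner integrals over triangles at observation points.

    Parameters
    ----------
    tris : (..., 3, 3) triangle vertices.
    points : (..., 3) observation points (broadcast against ``tris``).

    Returns
    -------
    pot : (...,) values of ``int_T 1/|r - r'| dA'``.
    field : (..., 3) values of ``int_T (r - r')/|r - r'|^3 dA'``.

    Both are finite for points on the triangle itself (the potential is
    weakly singular; the field returns the one-sided limit from the normal
    side plus the in-plane principal value).
    """
    tris = np.asarray(tris, dtype=np.float64)
    points = np.asarray(points, dtype=np.float64)
    v0, v1, v2 = tris[..., 0, :], tris[..., 1, :], tris[..., 2, :]
    nvec = np.cross(v1 - v0, v2 - v0)
    nnorm = np.linalg.norm(nvec, axis=-1, keepdims=True)
    n = nvec / np.maximum(nnorm, _TINY)
    d = np.einsum("...i,...i->...", n, points - v0)
    rho = points - d[..., None] * n

    pot = np.zeros(d.shape)
    grad_edge = np.zeros(d.shape + (3,))
    absd = np.abs(d)
    for a, b in ((v0, v1), (v1, v2), (v2, v0)):
        e = b - a
        elen = np.linalg.norm(e, axis=-1, keepdims=True)
        s = e / np.maximum(elen, _TINY)
        m = np.cross(s, n)
        lm = np.einsum("...i,...i->...", s, a - rho)
        lp = np.einsum("...i,...i->...", s, b - rho)
        p0 = np.einsum("...i,...i->...", m, a - rho)
        rm = np.linalg.norm(points - a, axis=-1)
        rp = np.linalg.norm(points - b, axis=-1)
        r02 = p0 * p0 + d * d
        # R + l vanishes only when the point sits on the edge's extension;
        # the corresponding p0 -> finite, log -> large but P0*log finite in
        # the limit; clip for safety.
        f2 = np.log(np.maximum(rp + lp, _TINY) / np.maximum(rm + lm, _TINY))
        beta = np.arctan2(p0 * lp, r02 + absd * rp) - np.arctan2(
            p0 * lm, r02 + absd * rm
        )
        pot = pot + p0 * f2 - absd * beta
        grad_edge = grad_edge + m * f2[..., None]

    omega = tri_solid_angle(tris, points)
    field = grad_edge - n * omega[..., None]
    return pot, field


def gauss7_points(tris: np.ndarray):
    """7-point Gauss nodes and weights on triangles.

    Returns (points, weights): points (..., 7, 3); weights (..., 7) summing to
    the triangle area.
    """
    tris = np.asarray(tris, dtype=np.float64)
    pts = np.einsum("qk,...kj->...qj", _G7_BARY, tris)
    v0, v1, v2 = tris[..., 0, :], tris[..., 1, :], tris[..., 2, :]
    area = 0.5 * np.linalg.norm(np.cross(v1 - v0, v2 - v0), axis=-1)
    w = _G7_W * area[..., None]
    return pts, w


def _subdivide_tris(tris: np.ndarray) -> np.ndarray:
    """4:1 midpoint subdivision; (..., 3, 3) -> (..., 4, 3, 3)."""
    v0, v1, v2 = tris[..., 0, :], tris[..., 1, :], tris[..., 2, :]
    m01 = 0.5 * (v0 + v1)
    m12 = 0.5 * (v1 + v2)
    m20 = 0.5 * (v2 + v0)
    children = np.stack(
        [
            np.stack([v0, m01, m20], axis=-2),
            np.stack([m01, v1, m12], axis=-2),
            np.stack([m20, m12, v2], axis=-2),
            np.stack([m01, m12, m20], axis=-2),
        ],
        axis=-3,
    )
    return children


def subdivided_quadrature(tris: np.ndarray, level: int = 0):
    """Gauss rule on a 4^level midpoint subdivision of each triangle.

    ``tris`` is a flat (P, 3, 3) list.  Returns points (P, nq, 3) and weights
    (P, nq) with nq = 7 * 4^level; weights sum to the triangle area.
    """
    tris = np.asarray(tris, dtype=np.float64).reshape(-1, 3, 3)
    npair = tris.shape[0]
    for _ in range(level):
        tris = _subdivide_tris(tris).reshape(npair, -1, 3, 3)
        tris = tris.reshape(-1, 3, 3)
    pts, w = gauss7_points(tris)
    return pts.reshape(npair, -1, 3), w.reshape(npair, -1)


def double_integral_gradient(
    tris_m: np.ndarray,
    normals_m: np.ndarray,
    areas_m: np.ndarray,
    tris_n: np.ndarray,
    level: int = 1,
) -> np.ndarray:
    """Galerkin double integral of the normal-gradient kernel, conductivity
    contrast factored out.

    Computes ``(1/A_m) n_m . integral_{A_m} integral_{A_n} (1/4pi)
    (r - r')/|r - r'|^3 dr' dr`` for pair lists: outer Gauss rule on a
    4^level subdivision of facet m, analytic inner integral over facet n.
    The row contrast K_m and the leading minus sign of the system matrix are
    applied at assembly time, not here.
    """
    tris_m = np.asarray(tris_m, dtype=np.float64).reshape(-1, 3, 3)
    tris_n = np.asarray(tris_n, dtype=np.float64).reshape(-1, 3, 3)
    normals_m = np.asarray(normals_m, dtype=np.float64).reshape(-1, 3)
    areas_m = np.asarray(areas_m, dtype=np.float64).reshape(-1)
    out = np.empty(len(tris_m))
    chunk = max(1, 1_000_000 // (7 * 4**level))
    for lo in range(0, len(tris_m), chunk):
        hi = min(len(tris_m), lo + chunk)
        pts, w = subdivided_quadrature(tris_m[lo:hi], level)
        _, field = tri_potential_field(tris_n[lo:hi, None, :, :], pts)
        proj = np.einsum("pi,pqi->pq", normals_m[lo:hi], field)
        out[lo:hi] = np.einsum("pq,pq->p", w, proj) / (4.0 * np.pi * areas_m[lo:hi])
    return out


def double_integral_single_layer(
    tris_m: np.ndarray, tris_n: np.ndarray, level: int = 1
) -> np.ndarray:
    """Galerkin double integral of 1/|r - r'| over a facet pair (m = n allowed).

    Outer Gauss rule on a 4^level subdivision of facet m, analytic inner
    integral over facet n; the self term's weak singularity is integrable and
    handled by the analytic inner integral.
    """
    tris_m = np.asarray(tris_m, dtype=np.float64).reshape(-1, 3, 3)
    tris_n = np.asarray(tris_n, dtype=np.float64).reshape(-1, 3, 3)
    out = np.empty(len(tris_m))
    chunk = max(1, 1_000_000 // (7 * 4**level))
    for lo in range(0, len(tris_m), chunk):
        hi = min(len(tris_m), lo + chunk)
        pts, w = subdivided_quadrature(tris_m[lo:hi], level)
        pot, _ = tri_potential_field(tris_n[lo:hi, None, :, :], pts)
        out[lo:hi] = np.einsum("pq,pq->p", w, pot)
    return out
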