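"""Deterministic phantom generators: nested-sphere head surrogates, electrode
patches, midlayer ROIs, cortical dipole clusters and a generic figure-8 coil.

These stand in for subject-specific anatomical meshes so that every solver
component can be exercised without external data.  All generators are
deterministic; optional jitter is driven by an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import HeadModel, TriSurface, compute_geometry, signed_volume
from .metrics import ObservationSet

__all__ = [
    "ShellSpec",
    "CoilSpec",
    "DipoleCluster",
    "make_icosphere",
    "make_multishell",
    "pick_electrode_patch",
    "make_midlayer_roi",
    "make_dipole_cluster",
    "make_figure8_coil",
    "focal_ring_montage",
    "SEVEN_TISSUE_CONDUCTIVITIES",
    "FOURTEEN_TISSUE_CONDUCTIVITIES",
    "three_shell_specs",
]

#: Empirical cortical dipole-moment surface density (A*m per m^2 == nA*m/mm^2).
OKADA_MURAKAMI = 1e-3


@dataclass
class ShellSpec:
    """One spherical shell boundary: outer radius (m), tissue name and the
    conductivity just inside (S/m).  The conductivity outside a shell is the
    inside conductivity of the enclosing shell; the outermost sees air (0)."""

    radius: float
    name: str
    sigma_inside: float


@dataclass
class CoilSpec:
    """Elementary current segments of a coil winding.

    midpoints (n, 3) m; directions (n, 3) unit; lengths (n,) m; drive
    amplitude I0 (A) and frequency f (Hz) of the sinusoidal current.
    """

    midpoints: np.ndarray
    directions: np.ndarray
    lengths: np.ndarray
    I0: float = 5e3
    f: float = 3e3

    @property
    def peak_didt(self) -> float:
        """Peak dI/dt of the sinusoidal drive, 2*pi*f*I0 (A/s)."""
        return 2.0 * np.pi * self.f * self.I0


@dataclass
class DipoleCluster:
    """Finite-length current dipoles: current flows from the source endpoint
    (+I) to the sink endpoint (-I) along the segment."""

    sources: np.ndarray  # (n, 3) +I endpoints
    sinks: np.ndarray  # (n, 3) -I endpoints
    currents: np.ndarray  # (n,) A
    sigma_medium: float = 0.275

    @property
    def moments(self) -> np.ndarray:
        """Vector dipole moments I*(source - sink), A*m."""
        return self.currents[:, None] * (self.sources - self.sinks)

    def monopoles(self) -> tuple[np.ndarray, np.ndarray]:
        """Point current monopole expansion: (positions, signed currents)."""
        pos = np.concatenate([self.sources, self.sinks])
        cur = np.concatenate([self.currents, -self.currents])
        return pos, cur


# -- sphere meshes -----------------------------------------------------------

_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosphere(radius: float, n_subdivisions: int) -> TriSurface:
    """Icosphere with 20 * 4^n facets, all vertices projected to ``radius``,
    outward-oriented (positive signed volume)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    verts = _ICO_VERTS.copy()
    faces = _ICO_FACES.copy()
    for _ in range(n_subdivisions):
        cache: dict[tuple[int, int], int] = {}
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                vlist.append(0.5 * (verts[i] + verts[j]))
                cache[key] = len(vlist) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces, dtype=np.int64)
    verts = radius * verts / np.linalg.norm(verts, axis=1, keepdims=True)
    surf = TriSurface(verts, faces, name=f"icosphere{n_subdivisions}")
    if signed_volume(surf) < 0:
        surf.facets = surf.facets[:, ::-1].copy()
    return surf


def three_shell_specs(
    radii=(0.08, 0.09, 0.1),
    sigmas=(0.33, 0.0042, 0.33),
    names=("brain", "skull", "scalp"),
) -> list[ShellSpec]:
    """Default validation phantom: brain / skull / scalp shells."""
    return [ShellSpec(r, n, s) for r, n, s in zip(radii, names, sigmas)]


def make_multishell(shells: list[ShellSpec], n_subdivisions: int) -> HeadModel:
    """Nested concentric icosphere shells, ordered innermost first.

    Contrasts follow from adjacent conductivities: surface i separates
    sigma_in = shells[i].sigma_inside from sigma_out = shells[i+1].sigma_inside
    (air, 0, outside the outermost shell).
    """
    radii = [s.radius for s in shells]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("shell radii must be strictly increasing outward")
    if any(s.sigma_inside < 0 for s in shells):
        raise ValueError("conductivities must be >= 0")
    surfaces = [make_icosphere(s.radius, n_subdivisions) for s in shells]
    for surf, s in zip(surfaces, shells):
        surf.name = s.name
    sigma_in = [s.sigma_inside for s in shells]
    sigma_out = [s.sigma_inside for s in shells[1:]] + [0.0]
    return HeadModel(surfaces, sigma_in, sigma_out)


# -- tissue conductivity presets (S/m) --------------------------------------

SEVEN_TISSUE_CONDUCTIVITIES = {
    "Skin": 0.1989,
    "Bone": 0.0177,
    "Eyes": 1.2000,
    "Cerebrospinal fluid": 1.6540,
    "Gray matter": 0.2750,
    "White matter": 0.1260,
    "Ventricles": 1.6540,
}

FOURTEEN_TISSUE_CONDUCTIVITIES = {
    "Skin": 0.1700,
    "Fat": 0.0573,
    "Muscle": 0.3550,
    "Eyes": 1.2000,
    "Cortical bone": 0.0064,
    "Trabecular bone": 0.0290,
    "Ventricles": 1.6540,
    "Dura mater": 0.1000,
    "Arachnoid mater": 0.1250,
    "Cerebrospinal fluid": 1.6540,
    "Pia mater": 0.1500,
    "Gray matter": 0.2750,
    "White matter": 0.1260,
}


# -- electrodes, ROIs, dipoles, coil ----------------------------------------

def _project_to_surface(surface: TriSurface, point: np.ndarray) -> np.ndarray:
    """Nearest facet centroid: a mesh-resolution projection onto the surface."""
    geo = compute_geometry(surface)
    i = int(np.argmin(np.linalg.norm(geo.centroids - point, axis=1)))
    return geo.centroids[i]


def pick_electrode_patch(
    surface: TriSurface, center: np.ndarray, radius: float
) -> np.ndarray:
    """Local facet indices whose centroid lies within ``radius`` of the
    projection of ``center`` onto the surface."""
    if radius <= 0:
        raise ValueError("electrode radius must be positive")
    center = np.asarray(center, dtype=np.float64)
    geo = compute_geometry(surface)
    anchor = _project_to_surface(surface, center)
    sel = np.flatnonzero(np.linalg.norm(geo.centroids - anchor, axis=1) <= radius)
    if sel.size == 0:
        raise ValueError(
            "empty electrode patch: mesh resolution too coarse for radius "
            f"{radius:g} m"
        )
    return sel


def focal_ring_montage(
    surface: TriSurface,
    center: np.ndarray,
    electrode_radius: float = 5e-3,
    separation: float = 30e-3,
) -> dict[str, np.ndarray]:
    """Five-electrode focal ring: one central patch plus four return patches
    at the given center-to-center separation, as local facet index sets."""
    center = np.asarray(center, dtype=np.float64)
    anchor = _project_to_surface(surface, center)
    rhat = anchor / np.linalg.norm(anchor)
    # local tangent frame
    t1 = np.cross(rhat, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-8:
        t1 = np.cross(rhat, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(rhat, t1)
    montage = {"center": pick_electrode_patch(surface, anchor, electrode_radius)}
    for k, ang in enumerate(np.arange(4) * np.pi / 2):
        offset = separation * (np.cos(ang) * t1 + np.sin(ang) * t2)
        montage[f"return{k}"] = pick_electrode_patch(
            surface, anchor + offset, electrode_radius
        )
    return montage


def _vertex_normals_areas(surface: TriSurface) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted vertex normals and one-third vertex area shares."""
    geo = compute_geometry(surface)
    vn = np.zeros_like(surface.vertices)
    va = np.zeros(len(surface.vertices))
    for k in range(3):
        np.add.at(vn, surface.facets[:, k], geo.normals * geo.areas[:, None])
        np.add.at(va, surface.facets[:, k], geo.areas / 3.0)
    norm = np.linalg.norm(vn, axis=1, keepdims=True)
    vn = vn / np.maximum(norm, 1e-300)
    return vn, va


def _midlayer_points(inner: TriSurface, outer: TriSurface):
    """Pair each outer vertex with its closest inner vertex; return midpoints,
    outward normals, gaps and vertex area shares of the outer surface."""
    tree = cKDTree(inner.vertices)
    d, idx = tree.query(outer.vertices)
    mid = 0.5 * (outer.vertices + inner.vertices[idx])
    vn, va = _vertex_normals_areas(outer)
    return mid, vn, d, va


def make_midlayer_roi(
    inner: TriSurface, outer: TriSurface, target: np.ndarray, radius: float
) -> ObservationSet:
    """Observation points halfway between two surfaces within ``radius`` of the
    target, with density comparable to the outer surface's nodal density."""
    target = np.asarray(target, dtype=np.float64)
    mid, _, _, va = _midlayer_points(inner, outer)
    keep = np.linalg.norm(mid - target, axis=1) <= radius
    if not np.any(keep):
        raise ValueError("no midlayer support within the requested radius")
    return ObservationSet(mid[keep], kind="midlayer-E", areas=va[keep])


def make_dipole_cluster(
    inner: TriSurface,
    outer: TriSurface,
    target: np.ndarray,
    cluster_radius: float = 2.3e-3,
    okada_murakami: float = OKADA_MURAKAMI,
    sigma_medium: float = 0.275,
    length_fraction: float = 0.5,
) -> DipoleCluster:
    """Finite-length current dipoles on the midlayer within ``cluster_radius``
    of the target, oriented along the local outer-surface normal.

    Each dipole represents the outer-surface vertex area share of its support
    point and carries moment = okada_murakami * represented area (A*m), i.e.
    the empirical cortical moment surface density.  Segment length is
    ``length_fraction`` of the local surface gap.
    """
    if cluster_radius <= 0:
        raise ValueError("cluster_radius must be positive")
    target = np.asarray(target, dtype=np.float64)
    mid, vn, gap, va = _midlayer_points(inner, outer)
    keep = np.linalg.norm(mid - target, axis=1) <= cluster_radius
    if not np.any(keep):
        raise ValueError("no midlayer support within cluster_radius of target")
    mid, vn, gap, va = mid[keep], vn[keep], gap[keep], va[keep]
    length = np.maximum(length_fraction * gap, 1e-6)
    moment = okada_murakami * va
    currents = moment / length
    half = 0.5 * length[:, None] * vn
    return DipoleCluster(mid + half, mid - half, currents, sigma_medium)


def make_figure8_coil(
    loop_radius: float,
    turns: int,
    segments_per_loop: int,
    standoff: float,
    target: np.ndarray,
    surface: TriSurface,
    I0: float = 5e3,
    f: float = 3e3,
) -> CoilSpec:
    """Generic figure-8 coil: two coplanar counter-wound circular loops
    tangent at the centerline, placed with the centerline along the local
    surface normal through the projection of ``target`` and the coil plane at
    ``standoff`` above the surface."""
    if segments_per_loop < 8:
        raise ValueError("segments_per_loop must be >= 8")
    target = np.asarray(target, dtype=np.float64)
    vn, _ = _vertex_normals_areas(surface)
    iv = int(np.argmin(np.linalg.norm(surface.vertices - target, axis=1)))
    anchor = surface.vertices[iv]
    n = vn[iv]
    t1 = np.cross(n, [0.0, 0.0, 1.0])
    if np.linalg.norm(t1) < 1e-8:
        t1 = np.cross(n, [0.0, 1.0, 0.0])
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    center = anchor + (standoff + 1e-6) * n

    mids, dirs, lens = [], [], []
    phi = np.linspace(0.0, 2.0 * np.pi, segments_per_loop + 1)
    for sign in (+1.0, -1.0):
        c0 = center + sign * loop_radius * t1
        # counter-wound: the two loops circulate oppositely
        pts = c0 + loop_radius * (
            np.cos(sign * phi)[:, None] * t1 + np.sin(sign * phi)[:, None] * t2
        )
        seg = np.diff(pts, axis=0)
        lens.append(np.linalg.norm(seg, axis=1))
        dirs.append(seg / np.linalg.norm(seg, axis=1, keepdims=True))
        mids.append(0.5 * (pts[:-1] + pts[1:]))
    mids = np.tile(np.concatenate(mids), (turns, 1))
    dirs = np.tile(np.concatenate(dirs), (turns, 1))
    lens = np.tile(np.concatenate(lens), turns)
    return CoilSpec(mids, dirs, lens, I0=I0, f=f)
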