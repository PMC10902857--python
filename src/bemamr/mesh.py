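"""Triangulated boundary surfaces, geometry caches and barycentric refinement.

A head model is an ordered collection of closed triangulated boundaries, each
separating an inner tissue (conductivity ``sigma_in``) from an outer one
(``sigma_out``).  Facets are oriented counter-clockwise seen from outside, so
normals point outward and the signed volume of a closed surface is positive.

The pulse (facet-constant) charge basis requires no mesh conformity, so
barycentric 4:1 subdivision never attempts connectivity repair and child
vertices are not merged with neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "TriSurface",
    "GeometryCache",
    "RefinementHistory",
    "HeadModel",
    "compute_geometry",
    "signed_volume",
    "barycentric_subdivide",
    "find_near_pairs",
]

#: Facets with area below this fraction of the surface mean are rejected.
DEGENERATE_REL_AREA = 1e-12


@dataclass
class TriSurface:
    """One triangulated boundary.

    vertices : (nv, 3) float64 coordinates in meters.
    facets : (nf, 3) int64 vertex triples, CCW viewed from outside.
    """

    vertices: np.ndarray
    facets: np.ndarray
    name: str = ""
    surface_id: int = 0

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64)
        if self.facets.size and (
            self.facets.min() < 0 or self.facets.max() >= len(self.vertices)
        ):
            raise ValueError(f"surface {self.name!r}: facet index out of range")

    @property
    def n_facets(self) -> int:
        return len(self.facets)

    def facet_triangles(self, ids=None) -> np.ndarray:
        """Vertex coordinates per facet, shape (nf, 3, 3)."""
        f = self.facets if ids is None else self.facets[ids]
        return self.vertices[f]


@dataclass
class GeometryCache:
    """Per-facet geometry derived from a TriSurface.

    areas (m^2), normals (unit), centroids (m), circumradii (m) and the mean
    edge length (m) over the whole surface.
    """

    areas: np.ndarray
    normals: np.ndarray
    centroids: np.ndarray
    circumradii: np.ndarray
    mean_edge_length: float


@dataclass
class RefinementHistory:
    """Parent map and refinement level for one generation of one surface.

    ``parent[i]`` is the facet's index in the previous generation (itself if
    unrefined); ``level[i]`` counts ancestral subdivisions.
    """

    parent: np.ndarray
    level: np.ndarray


def compute_geometry(surface: TriSurface) -> GeometryCache:
    """Build areas, unit normals, centroids, circumradii and mean edge length.

    Raises ValueError naming the first degenerate (zero-area) facet.
    """
    tri = surface.facet_triangles()
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    cross = np.cross(v1 - v0, v2 - v0)
    cnorm = np.linalg.norm(cross, axis=1)
    areas = 0.5 * cnorm
    if areas.size:
        bad = np.flatnonzero(areas <= DEGENERATE_REL_AREA * max(areas.mean(), 1e-30))
        if bad.size:
            raise ValueError(
                f"surface {surface.name!r}: degenerate facet {int(bad[0])} "
                f"(area {areas[bad[0]]:.3e} m^2)"
            )
    normals = cross / cnorm[:, None]
    centroids = (v0 + v1 + v2) / 3.0
    a = np.linalg.norm(v1 - v2, axis=1)
    b = np.linalg.norm(v2 - v0, axis=1)
    c = np.linalg.norm(v0 - v1, axis=1)
    circumradii = a * b * c / (2.0 * cnorm)
    mean_edge = float(np.mean(np.concatenate([a, b, c]))) if areas.size else 0.0
    return GeometryCache(areas, normals, centroids, circumradii, mean_edge)


def signed_volume(surface: TriSurface) -> float:
    """Signed volume of a closed oriented surface (positive = outward normals)."""
    tri = surface.facet_triangles()
    return float(
        np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    )


def barycentric_subdivide(
    surface: TriSurface, facet_ids: Iterable[int]
) -> tuple[TriSurface, RefinementHistory]:
    """4:1 midpoint subdivision of the selected facets.

    Each selected facet is replaced (in place, preserving its slot order) by
    four coplanar similar children; three new facets are appended per
    selection.  Unselected facets are untouched.  New midpoint vertices are
    appended without deduplication across neighbours: the pulse basis needs no
    conforming mesh and no connectivity repair is attempted.
    """
    ids = np.unique(np.asarray(list(facet_ids), dtype=np.int64))
    if ids.size and (ids.min() < 0 or ids.max() >= surface.n_facets):
        raise ValueError(
            f"surface {surface.name!r}: refinement id out of range "
            f"(max valid {surface.n_facets - 1})"
        )
    nf = surface.n_facets
    if ids.size == 0:
        hist = RefinementHistory(np.arange(nf), np.zeros(nf, dtype=np.int64))
        return TriSurface(
            surface.vertices.copy(), surface.facets.copy(), surface.name,
            surface.surface_id,
        ), hist

    old_f = surface.facets
    sel = old_f[ids]
    verts = surface.vertices
    nv = len(verts)
    v0, v1, v2 = sel[:, 0], sel[:, 1], sel[:, 2]
    m01 = 0.5 * (verts[v0] + verts[v1])
    m12 = 0.5 * (verts[v1] + verts[v2])
    m20 = 0.5 * (verts[v2] + verts[v0])
    new_verts = np.concatenate([verts, m01, m12, m20])
    k = ids.size
    i01 = nv + np.arange(k)
    i12 = nv + k + np.arange(k)
    i20 = nv + 2 * k + np.arange(k)

    new_facets = old_f.copy()
    # child 0 replaces the parent slot; children 1..3 are appended
    new_facets[ids] = np.stack([v0, i01, i20], axis=1)
    appended = np.concatenate(
        [
            np.stack([i01, v1, i12], axis=1),
            np.stack([i20, i12, v2], axis=1),
            np.stack([i01, i12, i20], axis=1),
        ]
    )
    new_facets = np.concatenate([new_facets, appended])

    parent = np.concatenate([np.arange(nf), ids, ids, ids])
    level = np.zeros(nf + 3 * k, dtype=np.int64)
    level[ids] = 1
    level[nf:] = 1
    hist = RefinementHistory(parent, level)
    return TriSurface(new_verts, new_facets, surface.name, surface.surface_id), hist


class HeadModel:
    """Ordered surfaces with conductivities, contrasts and electrode labels.

    Facets of all surfaces are concatenated into flat per-facet arrays (areas,
    normals, centroids, circumradii, contrast K) used by the operator and the
    solver.  ``revision`` increments on every mesh change so that stale
    near-field blocks can be rejected.
    """

    def __init__(
        self,
        surfaces: Sequence[TriSurface],
        sigma_in: Sequence[float],
        sigma_out: Sequence[float],
        electrodes: dict[str, np.ndarray] | None = None,
    ):
        if len(surfaces) != len(sigma_in) or len(surfaces) != len(sigma_out):
            raise ValueError("one (sigma_in, sigma_out) pair per surface required")
        self.surfaces = list(surfaces)
        for i, s in enumerate(self.surfaces):
            s.surface_id = i
        self.sigma_in = np.asarray(sigma_in, dtype=np.float64)
        self.sigma_out = np.asarray(sigma_out, dtype=np.float64)
        # electrode name -> global facet index array
        self.electrodes: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=np.int64) for k, v in (electrodes or {}).items()
        }
        # per-surface cumulative refinement level of current facets
        self.levels: list[np.ndarray] = [
            np.zeros(s.n_facets, dtype=np.int64) for s in self.surfaces
        ]
        # per-surface list of RefinementHistory generations (for replay)
        self.history: list[list[RefinementHistory]] = [[] for _ in self.surfaces]
        self.excluded_surfaces: set[int] = set()
        self.revision = 0
        self.rebuild()

    # -- flat caches ---------------------------------------------------------

    def rebuild(self) -> None:
        caches = [compute_geometry(s) for s in self.surfaces]
        self.caches = caches
        self.offsets = np.concatenate(
            [[0], np.cumsum([s.n_facets for s in self.surfaces])]
        ).astype(np.int64)
        self.areas = np.concatenate([c.areas for c in caches])
        self.normals = np.concatenate([c.normals for c in caches])
        self.centroids = np.concatenate([c.centroids for c in caches])
        self.circumradii = np.concatenate([c.circumradii for c in caches])
        self.facet_surface = np.concatenate(
            [np.full(s.n_facets, i, dtype=np.int64) for i, s in enumerate(self.surfaces)]
        )
        denom = self.sigma_in + self.sigma_out
        ks = np.where(denom != 0.0, (self.sigma_in - self.sigma_out) / np.where(denom == 0, 1, denom), 0.0)
        self.K = ks[self.facet_surface]
        self.revision += 1

    @property
    def n_facets(self) -> int:
        return int(self.offsets[-1])

    @property
    def electrode_indices(self) -> np.ndarray:
        """Sorted global facet indices of all electrode facets."""
        if not self.electrodes:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(list(self.electrodes.values())))

    @property
    def electrode_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_facets, dtype=bool)
        mask[self.electrode_indices] = True
        return mask

    def surface_slice(self, sid: int) -> slice:
        return slice(int(self.offsets[sid]), int(self.offsets[sid + 1]))

    def global_to_local(self, gids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split global facet ids into (surface id, local facet id)."""
        gids = np.asarray(gids, dtype=np.int64)
        sid = np.searchsorted(self.offsets, gids, side="right") - 1
        return sid, gids - self.offsets[sid]

    def facet_triangles(self, gids=None) -> np.ndarray:
        tris = [s.facet_triangles() for s in self.surfaces]
        allt = np.concatenate(tris) if tris else np.empty((0, 3, 3))
        return allt if gids is None else allt[np.asarray(gids, dtype=np.int64)]

    @property
    def levels_flat(self) -> np.ndarray:
        return np.concatenate(self.levels)

    # -- refinement ----------------------------------------------------------

    def subdivide(self, selection: dict[int, np.ndarray]) -> dict[int, RefinementHistory]:
        """Subdivide per-surface local facet selections in place.

        Returns the per-surface RefinementHistory of this generation.  Global
        facet numbering changes; electrode indices are remapped through the
        parent maps (a refined electrode facet's children stay electrodes).
        """
        histories: dict[int, RefinementHistory] = {}
        new_index_maps: dict[int, np.ndarray] = {}
        for sid, local_ids in selection.items():
            surf = self.surfaces[sid]
            new_surf, hist = barycentric_subdivide(surf, local_ids)
            lvl = self.levels[sid][hist.parent] + hist.level
            self.surfaces[sid] = new_surf
            self.levels[sid] = lvl
            hist_abs = RefinementHistory(hist.parent, lvl)
            self.history[sid].append(hist_abs)
            histories[sid] = hist_abs
            new_index_maps[sid] = hist.parent

        old_offsets = self.offsets.copy()
        self.rebuild()
        # remap electrodes: any new facet whose parent was an electrode facet
        if self.electrodes:
            for name, gids in self.electrodes.items():
                sid_arr = np.searchsorted(old_offsets, gids, side="right") - 1
                new_gids = []
                for sid in np.unique(sid_arr):
                    loc = gids[sid_arr == sid] - old_offsets[sid]
                    if sid in histories:
                        parent = histories[sid].parent
                        sel = np.isin(parent, loc)
                        loc = np.flatnonzero(sel)
                    new_gids.append(loc + self.offsets[sid])
                self.electrodes[name] = np.concatenate(new_gids)
        return histories


def find_near_pairs(model: HeadModel, threshold_multiplier: float = 3.0) -> np.ndarray:
    """All unordered facet pairs closer than the multiplier times the pair's
    mean circumradius (centroid distance), across and within surfaces.

    The diagonal (m, m) is excluded; it is handled analytically (1/2 on the
    second-kind rows, the weakly singular self integral on electrode rows).
    Returns an (npairs, 2) int array of global facet ids with pair[0] < pair[1].
    """
    rad = model.circumradii
    if model.n_facets < 2:
        return np.empty((0, 2), dtype=np.int64)
    rmax = float(rad.max())
    tree = cKDTree(model.centroids)
    cand = tree.query_pairs(r=threshold_multiplier * rmax, output_type="ndarray")
    if cand.size == 0:
        return cand.reshape(0, 2).astype(np.int64)
    d = np.linalg.norm(
        model.centroids[cand[:, 0]] - model.centroids[cand[:, 1]], axis=1
    )
    keep = d <= threshold_multiplier * 0.5 * (rad[cand[:, 0]] + rad[cand[:, 1]])
    return np.ascontiguousarray(cand[keep], dtype=np.int64)
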