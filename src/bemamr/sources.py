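"""Excitations: TMS coil drive, TES voltage/current electrodes, EEG dipoles.

Each source class knows how to produce its primary electric field E^p (and
potential V^p where meaningful) and how to fill the right-hand side b of the
system R c = b:

* second-kind rows: ``b_m = (K_m / A_m) eps0 * integral_{A_m} n_m . E^p dr``
  (centroid or 7-point facet quadrature);
* first-kind electrode rows: ``b_m = integral_{A_m} V dr = V_m A_m`` for the
  enforced potential V_m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .integrals import gauss7_points
from .mesh import HeadModel
from .operator import EPS0, MU0, ChargeSolution, DirectBackend, NearFieldBlock
from .phantoms import CoilSpec, DipoleCluster

__all__ = [
    "UniformFieldSource",
    "TMSSource",
    "TESVoltageSource",
    "TESCurrentSource",
    "EEGSource",
    "tms_primary_E",
    "build_rhs",
    "ElectrodePreconditioner",
    "build_electrode_preconditioner",
    "injected_current",
    "rescale_to_current",
]


def tms_primary_E(coil: CoilSpec, didt: float, points: np.ndarray) -> np.ndarray:
    """Quasi-static primary field of a segmented coil, E^p = -dA/dt.

    ``E^p(r) = -(mu0 / 4 pi) dI/dt sum_j l_j d_j / |r - r_j|`` over the
    elementary current segments (midpoint r_j, unit direction d_j, length
    l_j).
    """
    if len(coil.midpoints) == 0:
        raise ValueError("coil has no current segments")
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    moments = coil.directions * coil.lengths[:, None]
    out = np.zeros_like(points)
    chunk = max(1, 2_000_000 // max(len(coil.midpoints), 1))
    for lo in range(0, len(points), chunk):
        hi = min(len(points), lo + chunk)
        d = np.linalg.norm(
            points[lo:hi, None, :] - coil.midpoints[None, :, :], axis=2
        )
        if np.any(d == 0.0):
            i, j = np.argwhere(d == 0.0)[0]
            raise ValueError(
                f"observation point {lo + i} coincides with coil segment {j}"
            )
        out[lo:hi] = np.einsum("ts,si->ti", 1.0 / d, moments)
    return -(MU0 / (4.0 * np.pi)) * didt * out


@dataclass
class UniformFieldSource:
    """Spatially uniform applied field (classical sphere-in-a-field setup)."""

    E0: np.ndarray

    def primary_E(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        return np.tile(np.asarray(self.E0, dtype=np.float64), (len(points), 1))


@dataclass
class TMSSource:
    """Coil excitation at the instant of peak (or given) current slew rate."""

    coil: CoilSpec
    didt: float | None = None  # A/s; defaults to the coil drive's peak

    @property
    def effective_didt(self) -> float:
        return self.coil.peak_didt if self.didt is None else self.didt

    def primary_E(self, points: np.ndarray) -> np.ndarray:
        return tms_primary_E(self.coil, self.effective_didt, points)


@dataclass
class TESVoltageSource:
    """Voltage electrodes: enforced potentials on labeled facet sets.

    ``potentials`` maps electrode label -> enforced potential (V).  The
    primary field is zero everywhere; the electrode facets obey the
    first-kind potential constraint instead.  ``target_current`` (A), when
    set, is the injected current the solution is later rescaled to on
    ``current_electrode``.
    """

    potentials: dict[str, float]
    target_current: float | None = None
    current_electrode: str = "center"

    def primary_E(self, points: np.ndarray) -> np.ndarray:
        return np.zeros((len(np.atleast_2d(points)), 3))


@dataclass
class TESCurrentSource:
    """Current electrodes injecting a uniform flux over each labeled patch.

    The primary field on an electrode facet is the injected current density
    divided by the interior conductivity, directed inward along the facet
    normal; zero on every other facet.
    """

    currents: dict[str, float]  # label -> injected current (A), positive = in


@dataclass
class EEGSource:
    """Cortical current dipole cluster, expanded to point current monopoles at
    the segment endpoints for primary-field evaluation via Coulomb's law."""

    cluster: DipoleCluster

    def primary_E(self, points: np.ndarray) -> np.ndarray:
        pos, cur = self.cluster.monopoles()
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        backend = DirectBackend()
        _, grad = backend.potential_and_gradient(pos, cur, points)
        return grad / self.cluster.sigma_medium

    def primary_V(self, points: np.ndarray) -> np.ndarray:
        pos, cur = self.cluster.monopoles()
        points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
        backend = DirectBackend()
        pot, _ = backend.potential_and_gradient(pos, cur, points)
        return pot / self.cluster.sigma_medium


SourceSpec = TMSSource | TESVoltageSource | TESCurrentSource | EEGSource


def _facet_mean_normal_Ep(model: HeadModel, primary_E, quadrature: str) -> np.ndarray:
    """Mean of n . E^p over each facet, by centroid or 7-point quadrature."""
    if quadrature == "centroid":
        Ep = primary_E(model.centroids)
        return np.einsum("mi,mi->m", model.normals, Ep)
    if quadrature != "7pt":
        raise ValueError("quadrature must be 'centroid' or '7pt'")
    tris = model.facet_triangles()
    pts, w = gauss7_points(tris)
    Ep = primary_E(pts.reshape(-1, 3)).reshape(pts.shape)
    proj = np.einsum("mi,mqi->mq", model.normals, Ep)
    return np.einsum("mq,mq->m", w, proj) / model.areas


def build_rhs(
    model: HeadModel, source: SourceSpec, quadrature: str | None = None
) -> np.ndarray:
    """Right-hand side vector b for the given excitation.

    Default facet quadrature is the centroid rule for TMS (the coil field is
    smooth on the scale of a facet) and the 7-point rule for EEG (the dipole
    field varies rapidly near the cluster).
    """
    M = model.n_facets
    el = model.electrode_indices

    if isinstance(source, TESVoltageSource):
        if not model.electrodes:
            raise ValueError("voltage source requires electrode labels on the model")
        b = np.zeros(M)
        emask = np.zeros(M, dtype=bool)
        emask[el] = True
        for name, volts in source.potentials.items():
            if name not in model.electrodes:
                raise ValueError(f"no electrode labeled {name!r} on the model")
            ids = model.electrodes[name]
            b[ids] = volts * model.areas[ids]
        return b

    if isinstance(source, TESCurrentSource):
        b = np.zeros(M)
        for name, amps in source.currents.items():
            if name not in model.electrodes:
                raise ValueError(f"no electrode labeled {name!r} on the model")
            ids = model.electrodes[name]
            area = model.areas[ids].sum()
            sigma_in = model.sigma_in[model.facet_surface[ids]]
            # uniform inward flux J = I / A_e; E^p = J / sigma_in, inward
            nEp = -amps / (area * sigma_in)
            b[ids] = model.K[ids] * EPS0 * nEp
        return b

    quadrature = quadrature or ("7pt" if isinstance(source, EEGSource) else "centroid")
    nEp = _facet_mean_normal_Ep(model, source.primary_E, quadrature)
    b = model.K * EPS0 * nEp
    if el.size:
        b[el] = 0.0
    return b


@dataclass
class ElectrodePreconditioner:
    """Dense inverse of the M_e x M_e electrode block of R.

    Applied as a left preconditioner that is the identity outside the
    electrode rows; it solves the first-kind electrode interactions directly
    and leaves GMRES to refine the rest of the model.
    """

    indices: np.ndarray
    block: np.ndarray
    inverse: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        y = np.array(x, dtype=np.float64, copy=True)
        y[self.indices] = self.inverse @ x[self.indices]
        return y


def build_electrode_preconditioner(
    model: HeadModel,
    nearfield: NearFieldBlock,
    guard_threshold: int = 3000,
) -> ElectrodePreconditioner:
    """Form and invert the electrode-electrode single-layer block.

    The block reproduces exactly what apply_R computes for electrode rows
    restricted to electrode columns (centroid terms plus near-field
    corrections), so an electrode-only problem is solved in one application.
    """
    el = model.electrode_indices
    if el.size == 0:
        raise ValueError("model has no electrode facets")
    if el.size > guard_threshold:
        raise ValueError(
            f"electrode block has {el.size} facets (> {guard_threshold}); "
            "coarsen the electrode discretization or raise the guard"
        )
    cen = model.centroids[el]
    d = np.linalg.norm(cen[:, None, :] - cen[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    areas = model.areas[el]
    S = areas[:, None] * areas[None, :] / (4.0 * np.pi * d)
    S = (S + nearfield.sl_corr[np.ix_(el, el)].toarray()) / EPS0
    inv = scipy.linalg.inv(S)
    return ElectrodePreconditioner(el, S, inv)


def _field_inside_at_facets(
    model: HeadModel,
    c: ChargeSolution,
    gids: np.ndarray,
    primary_E,
    backend: DirectBackend | None = None,
    near_multiplier: float = 3.0,
) -> np.ndarray:
    """Total E just inside the surface at facet centroids via the jump
    relation: n.E_in = n.(E^p + E^s_other) - c_m / (2 eps0), where E^s_other
    excludes the facet's own (principal-value) contribution, whose normal
    component vanishes on a planar facet."""
    backend = backend or DirectBackend()
    pts = model.centroids[gids]
    rad = model.circumradii
    # near facets of each evaluation point (excluding the facet itself)
    from scipy.spatial import cKDTree

    tree = cKDTree(model.centroids)
    rmax = float(rad.max())
    lists = tree.query_ball_point(pts, r=near_multiplier * rmax)
    prow, pcol = [], []
    for i, lst in enumerate(lists):
        arr = np.asarray(lst, dtype=np.int64)
        arr = arr[arr != gids[i]]
        if arr.size:
            dd = np.linalg.norm(pts[i] - model.centroids[arr], axis=1)
            arr = arr[dd <= near_multiplier * rad[arr]]
        prow.append(np.full(arr.shape, i))
        pcol.append(arr)
    prow = np.concatenate(prow)
    pcol = np.concatenate(pcol)

    q = c.c * model.areas
    excl = np.stack(
        [np.concatenate([prow, np.arange(len(gids))]), np.concatenate([pcol, gids])],
        axis=1,
    )
    _, grad = backend.potential_and_gradient(model.centroids, q, pts, exclude_pairs=excl)
    Es = grad / EPS0
    if len(prow):
        from .integrals import tri_potential_field

        tris = model.facet_triangles(pcol)
        _, gfield = tri_potential_field(tris, pts[prow])
        np.add.at(Es, prow, c.c[pcol, None] * gfield / (4.0 * np.pi * EPS0))
    E = Es + primary_E(pts)
    nE = np.einsum("mi,mi->m", model.normals[gids], E) - c.c[gids] / (2.0 * EPS0)
    return nE


def injected_current(
    model: HeadModel,
    c: ChargeSolution,
    source: SourceSpec,
    electrode: str,
    backend: DirectBackend | None = None,
) -> float:
    """Current injected through an electrode (A).

    ``I = sigma_skin * sum_j (-E_j . n_j) A_j`` over the electrode's facets,
    with E_j the total field just inside the skin surface.
    """
    if electrode not in model.electrodes:
        raise ValueError(f"no electrode labeled {electrode!r} on the model")
    gids = model.electrodes[electrode]
    areas = model.areas[gids]
    if areas.sum() == 0.0:
        raise ValueError(f"electrode {electrode!r} has zero area")
    primary = getattr(source, "primary_E", None)
    primary_E = primary if primary is not None else (lambda p: np.zeros((len(p), 3)))
    nE = _field_inside_at_facets(model, c, gids, primary_E, backend)
    sigma_skin = float(model.sigma_in[model.facet_surface[gids[0]]])
    return float(sigma_skin * np.sum(-nE * areas))


def rescale_to_current(
    c: ChargeSolution, I_measured: float, I_target: float
) -> ChargeSolution:
    """Linear rescale of a charge solution to hit a target injected current."""
    if I_measured == 0.0:
        raise ValueError("measured injected current is zero; cannot rescale")
    return ChargeSolution(c.c * (I_target / I_measured), c.model, c.revision)
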