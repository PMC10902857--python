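"""Matrix-free application of the BEM system operator and field recovery.

The system matrix R is never stored.  Its action on a charge-density vector c
is computed as a far-field sum over facet centroids (pluggable backend; the
shipped backend is exact chunked direct summation) plus a sparse near-field
correction that replaces centroid terms with Galerkin double integrals for
facet pairs closer than a few circumradii.

Row types:

* second-kind (standard) rows: ``(1/2) c_m - K_m * <n_m . E-sum>`` where K_m
  is the conductivity contrast of facet m's surface;
* first-kind (voltage electrode) rows: the single-layer potential integrated
  over the facet, including the weakly singular self term.

Fields and potentials are recovered at arbitrary observation points by
Coulomb superposition, with exact analytic facet integrals replacing the
centroid (point-charge) terms for observation points within a configurable
number of facet radii.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .integrals import (
    double_integral_gradient,
    double_integral_single_layer,
    tri_potential_field,
)
from .mesh import HeadModel, find_near_pairs

__all__ = [
    "EPS0",
    "MU0",
    "ChargeSolution",
    "DirectBackend",
    "NearFieldBlock",
    "build_nearfield",
    "update_nearfield",
    "apply_R",
    "assemble_dense",
    "evaluate_E",
    "evaluate_V",
]

#: Permittivity of free space (F/m).
EPS0 = 8.8541878128e-12
#: Permeability of free space (H/m).
MU0 = 4.0 * np.pi * 1e-7


@dataclass
class ChargeSolution:
    """Per-facet surface charge density c (C/m^2) tied to a model revision."""

    c: np.ndarray
    model: HeadModel
    revision: int = -1

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=np.float64).reshape(-1)
        if self.revision < 0:
            self.revision = self.model.revision
        if len(self.c) != self.model.n_facets:
            raise ValueError(
                f"charge vector length {len(self.c)} does not match model "
                f"facet count {self.model.n_facets}"
            )
        if not np.all(np.isfinite(self.c)):
            raise ValueError("charge vector contains non-finite entries")

    @property
    def Q(self) -> np.ndarray:
        """Total charge per facet, Q_m = c_m * A_m (C)."""
        return self.c * self.model.areas

    @property
    def total_charge(self) -> float:
        return float(self.Q.sum())


try:  # optional compiled kernel; the numpy path below is the reference
    import numba as _nb

    @_nb.njit(cache=True, fastmath=True)
    def _direct_sum_kernel(src, q, tgt):  # pragma: no cover - compiled
        nt = tgt.shape[0]
        pot = np.zeros(nt)
        grad = np.zeros((nt, 3))
        for t in range(nt):
            p = 0.0
            gx = 0.0
            gy = 0.0
            gz = 0.0
            for s in range(src.shape[0]):
                dx = tgt[t, 0] - src[s, 0]
                dy = tgt[t, 1] - src[s, 1]
                dz = tgt[t, 2] - src[s, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > 0.0:
                    inv = 1.0 / np.sqrt(r2)
                    w = q[s] * inv
                    p += w
                    w3 = w * inv * inv
                    gx += w3 * dx
                    gy += w3 * dy
                    gz += w3 * dz
            pot[t] = p
            grad[t, 0] = gx
            grad[t, 1] = gy
            grad[t, 2] = gz
        return pot, grad

except ImportError:  # pragma: no cover
    _direct_sum_kernel = None


class DirectBackend:
    """Exact direct-summation acceleration backend.

    Contract: given monopole charges at source points, return at each target
    ``pot = sum_s q_s / (4 pi |t - s|)`` and
    ``grad = sum_s q_s (t - s) / (4 pi |t - s|^3)``,
    with an optional list of (target, source) pairs to exclude; coincident
    source/target points contribute nothing.  Being a direct sum it is exact
    to rounding; an FMM-accelerated implementation may be substituted as long
    as it honors the same contract at its stated precision.
    """

    precision = 1e-15

    def __init__(self, max_chunk_elems: int = 4_000_000, use_compiled: bool = True):
        self.max_chunk_elems = max_chunk_elems
        self.use_compiled = use_compiled and _direct_sum_kernel is not None

    def potential_and_gradient(
        self,
        sources: np.ndarray,
        charges: np.ndarray,
        targets: np.ndarray,
        exclude_pairs: np.ndarray | None = None,
    ):
        sources = np.ascontiguousarray(sources, dtype=np.float64).reshape(-1, 3)
        charges = np.ascontiguousarray(charges, dtype=np.float64).reshape(-1)
        targets = np.ascontiguousarray(targets, dtype=np.float64).reshape(-1, 3)
        ns, nt = len(sources), len(targets)
        pot = np.zeros(nt)
        grad = np.zeros((nt, 3))
        if ns == 0 or nt == 0:
            return pot, grad
        inv4pi = 1.0 / (4.0 * np.pi)
        if self.use_compiled:
            pot, grad = _direct_sum_kernel(sources, charges, targets)
            pot = inv4pi * pot
            grad = inv4pi * grad
        else:
            chunk = max(1, self.max_chunk_elems // ns)
            for lo in range(0, nt, chunk):
                hi = min(nt, lo + chunk)
                diff = targets[lo:hi, None, :] - sources[None, :, :]
                r = np.linalg.norm(diff, axis=2)
                r = np.where(r == 0.0, np.inf, r)
                w = charges / r
                pot[lo:hi] = inv4pi * w.sum(axis=1)
                grad[lo:hi] = inv4pi * np.einsum("ts,tsi->ti", w / (r * r), diff)
        if exclude_pairs is not None and len(exclude_pairs):
            ep = np.asarray(exclude_pairs, dtype=np.int64).reshape(-1, 2)
            diff = targets[ep[:, 0]] - sources[ep[:, 1]]
            r = np.linalg.norm(diff, axis=1)
            live = r > 0.0  # zero-distance pairs were never accumulated
            if np.any(live):
                ep = ep[live]
                r = r[live]
                w = charges[ep[:, 1]] / r
                np.subtract.at(pot, ep[:, 0], inv4pi * w)
                np.subtract.at(
                    grad, ep[:, 0], inv4pi * (w / (r * r))[:, None] * diff[live]
                )
        return pot, grad


@dataclass
class NearFieldBlock:
    """Sparse corrections turning centroid interactions into exact Galerkin
    double integrals for near facet pairs.

    ``grad_corr[m, n]`` corrects the normal-gradient kernel row m for source
    n (pure geometry; the contrast K_m is applied at assembly).
    ``sl_corr[m, n]`` corrects the single-layer rows (electrode facets only)
    and carries the 1/(4 pi) but not the 1/eps0 factor; its diagonal holds the
    full weakly singular self integral.
    """

    pairs: np.ndarray
    grad_corr: sp.csr_matrix
    sl_corr: sp.csr_matrix
    multiplier: float
    quad_level: int
    touch_level: int
    revision: int


def _grad_entries(model: HeadModel, rows, cols, level: int) -> np.ndarray:
    """Exact-minus-centroid corrections of the normal-gradient kernel."""
    tris_n = model.facet_triangles(cols)
    exact = double_integral_gradient(
        model.facet_triangles(rows),
        model.normals[rows],
        model.areas[rows],
        tris_n,
        level=level,
    )
    dvec = model.centroids[rows] - model.centroids[cols]
    d = np.linalg.norm(dvec, axis=1)
    # coincident centroids contribute nothing to the far sum, so the whole
    # exact value is the correction there
    with np.errstate(divide="ignore", invalid="ignore"):
        cent = np.where(
            d > 0,
            model.areas[cols]
            / (4.0 * np.pi)
            * np.einsum("pi,pi->p", model.normals[rows], dvec)
            / np.maximum(d, 1e-300) ** 3,
            0.0,
        )
    return exact - cent


def _sl_entries(model: HeadModel, rows, cols, level: int) -> np.ndarray:
    """Exact-minus-centroid corrections of the single-layer kernel / (4 pi);
    for diagonal entries (rows == cols) the centroid term is zero and the full
    self integral is returned."""
    exact = double_integral_single_layer(
        model.facet_triangles(rows), model.facet_triangles(cols), level=level
    )
    dvec = model.centroids[rows] - model.centroids[cols]
    d = np.linalg.norm(dvec, axis=1)
    with np.errstate(divide="ignore"):
        cent = np.where(
            d > 0, model.areas[rows] * model.areas[cols] / np.maximum(d, 1e-300), 0.0
        )
    return (exact - cent) / (4.0 * np.pi)


def _split_touching(model: HeadModel, rows, cols) -> np.ndarray:
    """Mask of pairs considered touching/very close (distance below the sum of
    the two circumradii); these get a finer outer quadrature."""
    d = np.linalg.norm(model.centroids[rows] - model.centroids[cols], axis=1)
    return d < model.circumradii[rows] + model.circumradii[cols]


def _directed_grad_corr(model, rows, cols, level, touch_level):
    vals = np.empty(len(rows))
    touch = _split_touching(model, rows, cols)
    if np.any(~touch):
        vals[~touch] = _grad_entries(model, rows[~touch], cols[~touch], level)
    if np.any(touch):
        vals[touch] = _grad_entries(model, rows[touch], cols[touch], touch_level)
    return vals


def _directed_sl_corr(model, rows, cols, level, touch_level, self_level):
    vals = np.empty(len(rows))
    diag = rows == cols
    touch = _split_touching(model, rows, cols) & ~diag
    far = ~touch & ~diag
    if np.any(far):
        vals[far] = _sl_entries(model, rows[far], cols[far], level)
    if np.any(touch):
        vals[touch] = _sl_entries(model, rows[touch], cols[touch], touch_level)
    if np.any(diag):
        vals[diag] = _sl_entries(model, rows[diag], cols[diag], self_level)
    return vals


def build_nearfield(
    model: HeadModel,
    multiplier: float = 3.0,
    quad_level: int = 1,
    touch_level: int = 2,
    pairs: np.ndarray | None = None,
) -> NearFieldBlock:
    """Precompute near-field corrections for all facet pairs within
    ``multiplier`` mean pair circumradii (plus electrode self terms)."""
    if pairs is None:
        pairs = find_near_pairs(model, multiplier)
    M = model.n_facets
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    gvals = (
        _directed_grad_corr(model, rows, cols, quad_level, touch_level)
        if len(rows)
        else np.empty(0)
    )
    grad_corr = sp.csr_matrix((gvals, (rows, cols)), shape=(M, M))

    el = model.electrode_indices
    if el.size:
        emask = np.zeros(M, dtype=bool)
        emask[el] = True
        sel = emask[rows]
        srows = np.concatenate([rows[sel], el])
        scols = np.concatenate([cols[sel], el])
        svals = _directed_sl_corr(
            model, srows, scols, quad_level, touch_level, touch_level + 1
        )
        sl_corr = sp.csr_matrix((svals, (srows, scols)), shape=(M, M))
    else:
        sl_corr = sp.csr_matrix((M, M))
    return NearFieldBlock(
        pairs, grad_corr, sl_corr, multiplier, quad_level, touch_level, model.revision
    )


def update_nearfield(
    model: HeadModel,
    block: NearFieldBlock,
    old_to_new: np.ndarray,
    changed_new_ids: np.ndarray,
    full: bool = False,
) -> NearFieldBlock:
    """Refresh a near-field block after a mesh change.

    ``old_to_new`` maps old global facet ids to new ones (-1 for facets whose
    geometry changed, i.e. refined parents); ``changed_new_ids`` lists the new
    global ids of all changed/new facets.  Corrections between surviving
    unchanged facets are carried over; every pair touching a changed facet is
    rediscovered and recomputed.  ``full=True`` recomputes everything (oracle
    parity path).
    """
    if full:
        return build_nearfield(
            model, block.multiplier, block.quad_level, block.touch_level
        )
    old_to_new = np.asarray(old_to_new, dtype=np.int64)
    changed = np.asarray(changed_new_ids, dtype=np.int64)
    keep = (old_to_new[block.pairs[:, 0]] >= 0) & (old_to_new[block.pairs[:, 1]] >= 0)
    kept_pairs = old_to_new[block.pairs[keep]]

    # carry over surviving corrections
    op = block.pairs[keep]
    rows_old = np.concatenate([op[:, 0], op[:, 1]])
    cols_old = np.concatenate([op[:, 1], op[:, 0]])
    if len(rows_old):
        gvals = np.asarray(block.grad_corr[rows_old, cols_old], dtype=np.float64).reshape(-1)
    else:
        gvals = np.empty(0)
    rows_new = old_to_new[rows_old]
    cols_new = old_to_new[cols_old]

    # discover pairs involving changed facets
    M = model.n_facets
    rad = model.circumradii
    rmax = float(rad.max()) if M else 0.0
    tree = cKDTree(model.centroids)
    lists = tree.query_ball_point(
        model.centroids[changed], r=block.multiplier * rmax
    )
    prows, pcols = [], []
    changed_set = np.zeros(M, dtype=bool)
    changed_set[changed] = True
    for c, lst in zip(changed, lists):
        arr = np.asarray(lst, dtype=np.int64)
        arr = arr[arr != c]
        # avoid duplicating changed-changed pairs
        arr = arr[(~changed_set[arr]) | (arr > c)]
        prows.append(np.full(arr.shape, c))
        pcols.append(arr)
    if prows:
        prows = np.concatenate(prows)
        pcols = np.concatenate(pcols)
        d = np.linalg.norm(model.centroids[prows] - model.centroids[pcols], axis=1)
        ok = d <= block.multiplier * 0.5 * (rad[prows] + rad[pcols])
        prows, pcols = prows[ok], pcols[ok]
    else:
        prows = pcols = np.empty(0, dtype=np.int64)

    new_pairs = np.stack([prows, pcols], axis=1)
    nrows = np.concatenate([prows, pcols])
    ncols = np.concatenate([pcols, prows])
    ngvals = (
        _directed_grad_corr(model, nrows, ncols, block.quad_level, block.touch_level)
        if len(nrows)
        else np.empty(0)
    )
    all_rows = np.concatenate([rows_new, nrows])
    all_cols = np.concatenate([cols_new, ncols])
    all_gvals = np.concatenate([gvals, ngvals])
    grad_corr = sp.csr_matrix((all_gvals, (all_rows, all_cols)), shape=(M, M))

    pairs = np.concatenate([kept_pairs, new_pairs]) if len(new_pairs) else kept_pairs

    # electrode single-layer rows are few; rebuild them from the merged pairs
    el = model.electrode_indices
    if el.size:
        emask = np.zeros(M, dtype=bool)
        emask[el] = True
        drows = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dcols = np.concatenate([pairs[:, 1], pairs[:, 0]])
        sel = emask[drows]
        srows = np.concatenate([drows[sel], el])
        scols = np.concatenate([dcols[sel], el])
        svals = _directed_sl_corr(
            model, srows, scols, block.quad_level, block.touch_level,
            block.touch_level + 1,
        )
        sl_corr = sp.csr_matrix((svals, (srows, scols)), shape=(M, M))
    else:
        sl_corr = sp.csr_matrix((M, M))
    return NearFieldBlock(
        pairs, grad_corr, sl_corr, block.multiplier, block.quad_level,
        block.touch_level, model.revision,
    )


def _check_revision(model: HeadModel, block: NearFieldBlock) -> None:
    if block.revision != model.revision:
        raise ValueError(
            "stale near-field block: model revision "
            f"{model.revision} != block revision {block.revision}"
        )


def _deflation_mask(model: HeadModel) -> np.ndarray | None:
    """Rows receiving the zero-total-charge deflation term.

    When the outermost boundary faces a non-conducting exterior, its contrast
    is K = 1 and a uniform charge density on it is a null mode of the
    second-kind operator (it produces no interior field).  The physical
    solution of an inductive or charge-neutral excitation carries zero total
    charge, so a rank-one term proportional to the total charge can be added
    to those rows without changing the true solution while removing the
    singular mode.  Electrode (first-kind) rows break the null mode and may
    legitimately hold net charge, so deflation is disabled whenever electrode
    rows are present.
    """
    if model.electrode_indices.size:
        return None
    mask = model.sigma_out[model.facet_surface] == 0.0
    return mask if np.any(mask) else None


def apply_R(
    model: HeadModel,
    c: np.ndarray | ChargeSolution,
    nearfield: NearFieldBlock,
    backend: DirectBackend | None = None,
    deflate: bool = True,
) -> np.ndarray:
    """Matrix-free product R @ c.

    Standard rows are ``(1/2) c_m - K_m (n_m . field sum)``; electrode rows
    are the facet-integrated single-layer potential.  The far field comes from
    the backend at facet centroids; near pairs are corrected to exact double
    integrals via the near-field block.  ``deflate`` adds the
    zero-total-charge rank-one term on insulated outer boundaries (see
    ``_deflation_mask``).
    """
    _check_revision(model, nearfield)
    backend = backend or DirectBackend()
    cv = c.c if isinstance(c, ChargeSolution) else np.asarray(c, dtype=np.float64)
    q = cv * model.areas
    # self terms drop out automatically: zero-distance contributions are
    # discarded by the backend
    pot, grad = backend.potential_and_gradient(model.centroids, q, model.centroids)
    nsum = np.einsum("mi,mi->m", model.normals, grad) + nearfield.grad_corr @ cv
    out = 0.5 * cv - model.K * nsum
    el = model.electrode_indices
    if el.size:
        row_el = (model.areas * pot + nearfield.sl_corr @ cv) / EPS0
        out[el] = row_el[el]
    if deflate:
        mask = _deflation_mask(model)
        if mask is not None:
            out[mask] += q.sum() / (2.0 * model.areas[mask].sum())
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite values in operator output")
    return out


def assemble_dense(
    model: HeadModel, nearfield: NearFieldBlock, deflate: bool = True
) -> np.ndarray:
    """Explicit dense system matrix following the same near/far rule as the
    matrix-free path.  Debug/oracle utility for small meshes."""
    _check_revision(model, nearfield)
    M = model.n_facets
    if M > 4000:
        raise ValueError("dense assembly is limited to small meshes (<= 4000 facets)")
    dvec = model.centroids[:, None, :] - model.centroids[None, :, :]
    d = np.linalg.norm(dvec, axis=2)
    np.fill_diagonal(d, np.inf)
    Dcent = (
        model.areas[None, :]
        / (4.0 * np.pi)
        * np.einsum("mi,mni->mn", model.normals, dvec)
        / d**3
    )
    G = Dcent + nearfield.grad_corr.toarray()
    R = -model.K[:, None] * G
    np.fill_diagonal(R, np.diagonal(R) + 0.5)
    el = model.electrode_indices
    if el.size:
        Scent = model.areas[:, None] * model.areas[None, :] / (4.0 * np.pi * d)
        S = (Scent + nearfield.sl_corr.toarray()) / EPS0
        R[el, :] = S[el, :]
    if deflate:
        mask = _deflation_mask(model)
        if mask is not None:
            R[mask, :] += model.areas[None, :] / (2.0 * model.areas[mask].sum())
    return R


def _near_observation_pairs(
    model: HeadModel, points: np.ndarray, near_multiplier: float
):
    """(point, facet) pairs with distance below near_multiplier facet radii."""
    rad = model.circumradii
    rmax = float(rad.max())
    tree = cKDTree(model.centroids)
    lists = tree.query_ball_point(points, r=near_multiplier * rmax)
    prow, pcol = [], []
    for i, lst in enumerate(lists):
        arr = np.asarray(lst, dtype=np.int64)
        if arr.size:
            dd = np.linalg.norm(points[i] - model.centroids[arr], axis=1)
            arr = arr[dd <= near_multiplier * rad[arr]]
        if arr.size:
            prow.append(np.full(arr.shape, i))
            pcol.append(arr)
    if prow:
        return np.concatenate(prow), np.concatenate(pcol)
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def evaluate_E(
    model: HeadModel,
    c: np.ndarray | ChargeSolution,
    points: np.ndarray,
    backend: DirectBackend | None = None,
    near_multiplier: float = 1.0,
) -> np.ndarray:
    """Secondary electric field of the surface charges at observation points
    (V/m).  The total field is E^p + E^s, assembled by the caller.

    Observation points within ``near_multiplier`` facet radii of a facet
    centroid have that facet's centroid term replaced by the exact analytic
    facet integral.  A point exactly on a facet centroid is rejected (the
    normal field component is discontinuous there).
    """
    backend = backend or DirectBackend()
    cv = c.c if isinstance(c, ChargeSolution) else np.asarray(c, dtype=np.float64)
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    prow, pcol = _near_observation_pairs(model, points, near_multiplier)
    if len(prow):
        dd = np.linalg.norm(points[prow] - model.centroids[pcol], axis=1)
        if np.any(dd == 0.0):
            i = int(prow[np.argmin(dd)])
            raise ValueError(
                f"observation point {i} at {points[i]} coincides with a facet "
                "centroid; the E-field is discontinuous on the surface"
            )
    q = cv * model.areas
    excl = np.stack([prow, pcol], axis=1) if len(prow) else None
    _, grad = backend.potential_and_gradient(
        model.centroids, q, points, exclude_pairs=excl
    )
    E = grad / EPS0
    if len(prow):
        tris = model.facet_triangles(pcol)
        _, gfield = tri_potential_field(tris, points[prow])
        contrib = cv[pcol, None] * gfield / (4.0 * np.pi * EPS0)
        np.add.at(E, prow, contrib)
    return E


def evaluate_V(
    model: HeadModel,
    c: np.ndarray | ChargeSolution,
    points: np.ndarray,
    backend: DirectBackend | None = None,
    near_multiplier: float = 1.0,
) -> np.ndarray:
    """Single-layer potential of the surface charges at observation points (V).

    The potential is continuous across the surface, so observation points on a
    facet (e.g. EEG readout at skin facet centroids) are allowed: near facets'
    contributions use the exact analytic facet integral, which is finite on
    the facet itself.
    """
    backend = backend or DirectBackend()
    cv = c.c if isinstance(c, ChargeSolution) else np.asarray(c, dtype=np.float64)
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    prow, pcol = _near_observation_pairs(model, points, near_multiplier)
    q = cv * model.areas
    excl = np.stack([prow, pcol], axis=1) if len(prow) else None
    pot, _ = backend.potential_and_gradient(
        model.centroids, q, points, exclude_pairs=excl
    )
    V = pot / EPS0
    if len(prow):
        tris = model.facet_triangles(pcol)
        p, _ = tri_potential_field(tris, points[prow])
        contrib = cv[pcol] * p / (4.0 * np.pi * EPS0)
        np.add.at(V, prow, contrib)
    return V
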