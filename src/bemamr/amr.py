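"""Adaptive h-refinement driven by total facet charge.

Each pass: (1) rank facets of every non-excluded surface by |Q_m| = |c_m A_m|
and take the top ceil(r * M_s) per surface; (2) subdivide them 4:1
barycentrically, children inheriting the parent's charge density verbatim
(total charge is conserved exactly: four children of a quarter of the area at
the same density); (3) update the near-field block incrementally; (4) re-solve
warm-started from the inherited charge vector; (5) evaluate the ROI quantity
and stop when its inter-pass relative error drops below the threshold.

Closed-form growth predictors: facet count M' = M (1 + 3 r)^k after k passes
at rate r; minimum reachable edge length l' = l / 2^k; total runtime
t = t0 * sum_{n=0..N} (1 + 3 r)^n when one pass costs t0 at the initial size.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from .mesh import HeadModel
from .metrics import ObservationSet, l21_error, v_2norm_error
from .operator import (
    ChargeSolution,
    DirectBackend,
    NearFieldBlock,
    build_nearfield,
    evaluate_E,
    evaluate_V,
    update_nearfield,
)
from .solver import SolverSettings, SolveStats, solve
from .sources import SourceSpec

__all__ = [
    "AMRSettings",
    "PassRecord",
    "select_facets",
    "refine_step",
    "preemptive_refine",
    "run_amr",
    "predict_growth",
    "predict_edge",
    "predict_time",
]


@dataclass
class AMRSettings:
    """Adaptive-refinement parameters.

    rate: fraction of each surface's facets refined per pass (ceil of
    rate * current facet count, at least 1).  metric: "E-L21" evaluates the
    total E-field at the ROI and compares passes in the L21 sense;
    "V-2norm" evaluates potentials and uses the Euclidean relative error.
    """

    rate: float = 0.01
    max_passes: int = 30
    convergence_threshold: float = 0.01
    excluded_surfaces: set[int] = field(default_factory=set)
    metric: str = "E-L21"
    full_nearfield_rebuild: bool = False

    def __post_init__(self):
        if not (0 < self.rate <= 1):
            raise ValueError("rate must lie in (0, 1]")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence threshold must be positive")


@dataclass
class PassRecord:
    """Bookkeeping for one AMR pass."""

    index: int
    n_facets: int
    selected_per_surface: dict[int, int]
    roi_error: float
    charge_error: float
    iterations: int
    residual: float
    converged: bool


def select_facets(
    model: HeadModel, c: ChargeSolution, settings: AMRSettings
) -> dict[int, np.ndarray]:
    """Per-surface local indices of the ceil(rate * M_s) facets with the
    largest |total charge|, ties broken by ascending facet index."""
    Q = np.abs(c.c * model.areas)
    selection: dict[int, np.ndarray] = {}
    for sid in range(len(model.surfaces)):
        if sid in model.excluded_surfaces or sid in settings.excluded_surfaces:
            continue
        sl = model.surface_slice(sid)
        qs = Q[sl]
        k = int(np.ceil(settings.rate * len(qs)))
        if k <= 0 or len(qs) == 0:
            continue
        # stable sort on (-|Q|, index): mergesort keeps ascending-index ties
        order = np.argsort(-qs, kind="stable")
        selection[sid] = np.sort(order[:k])
    return selection


def refine_step(
    model: HeadModel,
    c: ChargeSolution,
    selection: dict[int, np.ndarray],
    nearfield: NearFieldBlock | None = None,
    full_rebuild: bool = False,
) -> tuple[ChargeSolution, NearFieldBlock | None]:
    """Subdivide the selected facets in place and inherit charge densities.

    Children copy the parent's charge density verbatim (density is already
    per unit area, so total charge is conserved exactly).  Returns the
    inherited charge vector on the new mesh and the updated near-field block.
    """
    old_offsets = model.offsets.copy()
    old_n = model.n_facets
    histories = model.subdivide(selection)

    # old -> new global id map; refined parents are geometry-changed (-1)
    old_to_new = np.empty(old_n, dtype=np.int64)
    changed_new = []
    c_new_parts = []
    for sid in range(len(model.surfaces)):
        lo, hi = int(old_offsets[sid]), int(old_offsets[sid + 1])
        new_lo = int(model.offsets[sid])
        n_old_s = hi - lo
        if sid in histories:
            parent = histories[sid].parent  # new local -> old local
            sel = np.asarray(selection[sid], dtype=np.int64)
            local_map = np.arange(n_old_s, dtype=np.int64)
            local_map[sel] = -1
            keep = local_map >= 0
            old_to_new[lo:hi] = np.where(keep, np.arange(n_old_s) + new_lo, -1)
            nf_new = model.surfaces[sid].n_facets
            changed_local = np.concatenate(
                [sel, np.arange(n_old_s, nf_new, dtype=np.int64)]
            )
            changed_new.append(changed_local + new_lo)
            c_new_parts.append(c.c[lo:hi][parent])
        else:
            old_to_new[lo:hi] = np.arange(n_old_s) + new_lo
            c_new_parts.append(c.c[lo:hi])
    c_new = ChargeSolution(np.concatenate(c_new_parts), model)

    block = None
    if nearfield is not None:
        changed = (
            np.concatenate(changed_new) if changed_new else np.empty(0, dtype=np.int64)
        )
        block = update_nearfield(
            model, nearfield, old_to_new, changed, full=full_rebuild
        )
    return c_new, block


def preemptive_refine(
    model: HeadModel,
    surface_ids: list[int],
    center: np.ndarray,
    radius: float,
    iterations: int = 2,
    exclude_after: bool = True,
) -> None:
    """Repeated 4:1 subdivision of the designated surfaces' facets within a
    sphere, then (by default) exclusion of those surfaces from further
    adaptive or global refinement.  Used to pre-resolve voltage electrodes,
    whose unsupervised refinement would grow the dense preconditioner block
    16-fold per pass."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    center = np.asarray(center, dtype=np.float64)
    for _ in range(iterations):
        selection = {}
        for sid in surface_ids:
            sl = model.surface_slice(sid)
            cen = model.centroids[sl]
            loc = np.flatnonzero(np.linalg.norm(cen - center, axis=1) <= radius)
            if loc.size:
                selection[sid] = loc
        if not selection:
            break
        model.subdivide(selection)
    if exclude_after:
        model.excluded_surfaces.update(surface_ids)


def _eval_roi(model, c, source, roi: ObservationSet, settings, backend):
    if settings.metric == "E-L21":
        Es = evaluate_E(model, c, roi.points, backend)
        return Es + source.primary_E(roi.points)
    if settings.metric == "V-2norm":
        Vs = evaluate_V(model, c, roi.points, backend)
        Vp = source.primary_V(roi.points) if hasattr(source, "primary_V") else 0.0
        return Vs + Vp
    raise ValueError(f"unknown AMR metric {settings.metric!r}")


def _roi_error(settings, new, old) -> float:
    if settings.metric == "E-L21":
        return l21_error(new, old)
    return v_2norm_error(new, old)


def run_amr(
    model: HeadModel,
    source: SourceSpec,
    roi: ObservationSet,
    solver_settings: SolverSettings,
    amr_settings: AMRSettings,
    backend: DirectBackend | None = None,
    nearfield: NearFieldBlock | None = None,
) -> tuple[ChargeSolution, list[PassRecord]]:
    """Alternate Solve and Refine until the ROI quantity converges.

    Returns the final charge solution (the model is refined in place) and the
    full pass history.  A solver that hits its iteration cap is flagged in
    the PassRecord and the loop continues.
    """
    backend = backend or DirectBackend()
    if nearfield is None:
        nearfield = build_nearfield(model)
    c, stats = solve(
        model, source, solver_settings, nearfield, backend, initial=True
    )
    roi_prev = _eval_roi(model, c, source, roi, amr_settings, backend)
    records = [
        PassRecord(
            0, model.n_facets, {}, np.inf, np.inf, stats.iterations,
            stats.final_residual, stats.converged,
        )
    ]
    for k in range(1, amr_settings.max_passes + 1):
        selection = select_facets(model, c, amr_settings)
        if not selection:
            break
        c_inherit, nearfield = refine_step(
            model, c, selection, nearfield,
            full_rebuild=amr_settings.full_nearfield_rebuild,
        )
        c, stats = solve(
            model, source, solver_settings, nearfield, backend,
            warm_start=c_inherit,
        )
        roi_new = _eval_roi(model, c, source, roi, amr_settings, backend)
        err = _roi_error(amr_settings, roi_new, roi_prev)
        dc = c.c - c_inherit.c
        charge_err = float(
            np.linalg.norm(dc) / max(np.linalg.norm(c.c), 1e-300)
        )
        records.append(
            PassRecord(
                k, model.n_facets,
                {sid: len(ids) for sid, ids in selection.items()},
                err, charge_err, stats.iterations, stats.final_residual,
                stats.converged,
            )
        )
        logger.info(
            "amr pass=%d facets=%d roi_error=%.3e iterations=%d residual=%.2e",
            k, model.n_facets, err, stats.iterations, stats.final_residual,
        )
        roi_prev = roi_new
        if err < amr_settings.convergence_threshold:
            break
    return c, records


# -- closed-form growth, resolution and cost predictors ----------------------

def predict_growth(M: int, r: float, k: int) -> float:
    """Facet count after k adaptive passes at refinement rate r:
    M' = M (1 + 3 r)^k."""
    if M < 1 or k < 0:
        raise ValueError("require M >= 1 and k >= 0")
    return M * (1.0 + 3.0 * r) ** k


def predict_edge(l: float, k: int) -> float:
    """Edge length of a facet subdivided on every one of k passes: l / 2^k."""
    if k < 0:
        raise ValueError("require k >= 0")
    return l / 2.0**k


def predict_time(t0: float, r: float, N: int) -> float:
    """Estimated total runtime of N AMR passes when the initial solve-plus-
    refine costs t0 and each pass grows the model by (1 + 3 r):
    t = t0 * sum_{n=0..N} (1 + 3 r)^n."""
    if N < 0:
        raise ValueError("require N >= 0")
    return t0 * sum((1.0 + 3.0 * r) ** n for n in range(N + 1))


def write_pass_history(path, records: list[PassRecord]) -> None:
    """Serialize the AMR pass history as CSV (pass, facets, errors, solver
    iterations) for convergence plots."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["pass", "facets", "roi_error", "charge_error", "iterations",
             "residual", "converged"]
        )
        for r in records:
            w.writerow(
                [r.index, r.n_facets, f"{r.roi_error:.6e}",
                 f"{r.charge_error:.6e}", r.iterations,
                 f"{r.residual:.3e}", int(r.converged)]
            )
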