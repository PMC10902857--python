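"""GMRES solution of the matrix-free system R c = b with warm starts.

Full (non-restarted) GMRES up to a small iteration cap; the initial solve of
an AMR sequence is allowed more iterations than subsequent warm-started
solves so its convergence saturates comparably.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse.linalg as spla

logger = logging.getLogger(__name__)

from .mesh import HeadModel
from .operator import ChargeSolution, DirectBackend, NearFieldBlock, apply_R
from .sources import (
    ElectrodePreconditioner,
    SourceSpec,
    TESVoltageSource,
    build_electrode_preconditioner,
    build_rhs,
)

__all__ = ["SolverSettings", "SolveStats", "solve"]


@dataclass
class SolverSettings:
    """Iterative-solver settings.

    backend_precision is the requested accuracy of the acceleration backend
    (the direct backend is exact); gmres_tolerance the relative-residual
    target; the two caps bound the initial (cold) and general (warm-started)
    solves.
    """

    backend_precision: float = 1e-6
    gmres_tolerance: float = 1e-5
    max_iterations_initial: int = 100
    max_iterations_general: int = 50

    def __post_init__(self):
        if not (0 < self.backend_precision < 1 and 0 < self.gmres_tolerance < 1):
            raise ValueError("tolerances must lie in (0, 1)")
        if self.max_iterations_initial < 1 or self.max_iterations_general < 1:
            raise ValueError("iteration caps must be >= 1")


@dataclass
class SolveStats:
    iterations: int
    residuals: list[float] = field(default_factory=list)
    converged: bool = True
    final_residual: float = 0.0


def solve(
    model: HeadModel,
    source: SourceSpec,
    settings: SolverSettings,
    nearfield: NearFieldBlock,
    backend: DirectBackend | None = None,
    warm_start: ChargeSolution | None = None,
    preconditioner: ElectrodePreconditioner | None = None,
    initial: bool = False,
    rhs: np.ndarray | None = None,
) -> tuple[ChargeSolution, SolveStats]:
    """Solve R c = b for the surface charge density.

    ``warm_start`` must match the current facet count (i.e. be the inherited
    charge vector after refinement).  The electrode-block left preconditioner
    is built and applied automatically whenever the model has electrode
    facets and the source enforces potentials.
    """
    backend = backend or DirectBackend()
    b = build_rhs(model, source) if rhs is None else rhs
    M = model.n_facets
    if warm_start is not None and len(warm_start.c) != M:
        raise ValueError(
            f"warm start length {len(warm_start.c)} does not match facet count {M}"
        )

    if np.all(b == 0.0):
        return ChargeSolution(np.zeros(M), model), SolveStats(iterations=0)

    if (
        preconditioner is None
        and isinstance(source, TESVoltageSource)
        and model.electrode_indices.size
    ):
        preconditioner = build_electrode_preconditioner(model, nearfield)

    def matvec(x):
        return apply_R(model, x, nearfield, backend)

    A = spla.LinearOperator((M, M), matvec=matvec, dtype=np.float64)
    Mop = None
    if preconditioner is not None:
        Mop = spla.LinearOperator(
            (M, M), matvec=preconditioner.apply, dtype=np.float64
        )

    residuals: list[float] = []

    def cb(pr_norm):
        residuals.append(float(pr_norm))
        logger.debug("gmres iteration %d residual %.3e", len(residuals), pr_norm)

    cap = settings.max_iterations_initial if initial else settings.max_iterations_general
    x0 = warm_start.c if warm_start is not None else None
    x, info = spla.gmres(
        A,
        b,
        x0=x0,
        rtol=settings.gmres_tolerance,
        atol=0.0,
        restart=cap,
        maxiter=1,
        M=Mop,
        callback=cb,
        callback_type="pr_norm",
    )
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("solver produced non-finite charge values")
    res = apply_R(model, x, nearfield, backend) - b
    final = float(np.linalg.norm(res) / np.linalg.norm(b))
    stats = SolveStats(
        iterations=len(residuals),
        residuals=residuals,
        converged=(info == 0),
        final_residual=final,
    )
    return ChargeSolution(x, model), stats
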