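"""Error functionals for field and potential comparisons.

Four discrepancy measures are used to compare two solutions sampled at the
same observation points:

* ``l21_error`` — sum of per-point Euclidean E-field differences over the
  summed base magnitudes; measures relative change in overall field strength.
* ``rdm_E`` — half the L21 distance between the two fields after each is
  normalized by its aggregate (Frobenius) norm; scale-invariant, measures a
  joint change in the spatial distribution of field strength and direction.
* ``v_2norm_error`` — plain Euclidean relative error between potential
  vectors.
* ``v_rdm`` — area-weighted RMS difference of area-norm-normalized
  potentials; the scale-invariant potential analogue.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ObservationSet",
    "l21_error",
    "rdm_E",
    "v_2norm_error",
    "v_rdm",
    "write_error_report",
]


@dataclass
class ObservationSet:
    """Observation points with a kind tag and optional per-point area weights.

    kind is ``"midlayer-E"`` (vector E-field readout) or ``"skin-potential"``
    (scalar potential readout at facet centroids, weighted by facet area).
    """

    points: np.ndarray
    kind: str = "midlayer-E"
    areas: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.areas is not None:
            self.areas = np.asarray(self.areas, dtype=np.float64).reshape(-1)
            if len(self.areas) != len(self.points):
                raise ValueError("one area weight per observation point required")
            if np.any(self.areas <= 0):
                raise ValueError("area weights must be positive")

    def __len__(self) -> int:
        return len(self.points)


def _as_field(x) -> np.ndarray:
    out = np.asarray(x, dtype=np.float64)
    if out.ndim != 2 or out.shape[1] != 3:
        raise ValueError("expected an (n, 3) field array")
    return out


def l21_error(E_test, E_base) -> float:
    """L21 relative error: sum_n |dE_n| / sum_n |E_n^base|."""
    t, b = _as_field(E_test), _as_field(E_base)
    if t.shape != b.shape:
        raise ValueError("field arrays must have matching shapes")
    denom = np.linalg.norm(b, axis=1).sum()
    if denom == 0.0:
        raise ValueError("base field is identically zero")
    return float(np.linalg.norm(t - b, axis=1).sum() / denom)


def rdm_E(E_test, E_base, norm: str = "fro") -> float:
    """Relative difference measure of two E-field samplings.

    0.5 * L21-distance between the fields each normalized by its aggregate
    2-norm.  For a stacked (n, 3) field array the natural aggregate magnitude
    is the Frobenius norm (default); ``norm="spectral"`` uses the largest
    singular value instead.
    """
    t, b = _as_field(E_test), _as_field(E_base)
    if t.shape != b.shape:
        raise ValueError("field arrays must have matching shapes")
    nt = np.linalg.norm(t, "fro" if norm == "fro" else 2)
    nb = np.linalg.norm(b, "fro" if norm == "fro" else 2)
    if nt == 0.0 or nb == 0.0:
        raise ValueError("cannot normalize a zero field")
    diff = t / nt - b / nb
    return float(0.5 * np.linalg.norm(diff, axis=1).sum() / np.linalg.norm(b / nb, axis=1).sum())


def v_2norm_error(V_test, V_base) -> float:
    """Euclidean relative error |V_test - V_base| / |V_base|."""
    t = np.asarray(V_test, dtype=np.float64).reshape(-1)
    b = np.asarray(V_base, dtype=np.float64).reshape(-1)
    if t.shape != b.shape:
        raise ValueError("potential vectors must have matching lengths")
    denom = np.linalg.norm(b)
    if denom == 0.0:
        raise ValueError("base potential is identically zero")
    return float(np.linalg.norm(t - b) / denom)


def v_rdm(V_test, V_base, areas) -> float:
    """Area-weighted RDM of two potential samplings.

    Each potential vector is normalized by its area-weighted 2-norm
    V_norm = (sum_m A_m V_m^2)^(1/2); the result is the square root of the
    area-weighted sum of squared differences of the normalized vectors.
    """
    t = np.asarray(V_test, dtype=np.float64).reshape(-1)
    b = np.asarray(V_base, dtype=np.float64).reshape(-1)
    a = np.asarray(areas, dtype=np.float64).reshape(-1)
    if not (t.shape == b.shape == a.shape):
        raise ValueError("potentials and areas must have matching lengths")
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    nt = np.sqrt(np.sum(a * t * t))
    nb = np.sqrt(np.sum(a * b * b))
    if nt == 0.0 or nb == 0.0:
        raise ValueError("cannot normalize a zero potential")
    return float(np.sqrt(np.sum(a * (t / nt - b / nb) ** 2)))


def write_error_report(path, rows: dict[str, dict[str, float]]) -> None:
    """Write a pairwise error table as CSV.

    ``rows`` maps a comparison label (e.g. "STD/REF") to a mapping of metric
    name to value; columns are the union of metric names.
    """
    path = Path(path)
    cols = sorted({m for r in rows.values() for m in r})
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["comparison", *cols])
        for label, r in rows.items():
            w.writerow([label, *[f"{r[m]:.6e}" if m in r else "" for m in cols]])
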