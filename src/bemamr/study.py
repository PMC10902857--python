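"""End-to-end STD / AMR / REF study protocol on sphere phantoms.

For one model and one excitation, three solutions are computed:

* STD — the initial mesh solved as-is (no refinement);
* AMR — the adaptively refined mesh and its solution;
* REF — the AMR mesh after one additional global 4:1 subdivision pass
  (every non-excluded facet subdivided indiscriminately), solved
  warm-started; the "silver standard".

Pairwise errors STD/REF, STD/AMR and AMR/REF are reported with the
mode-appropriate metrics: L21 and RDM of the total E-field at a midlayer ROI
for TES and TMS; Euclidean relative error and area-weighted RDM of the skin
potential for EEG.  TES solutions are independently rescaled to the target
injected current before metric evaluation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .amr import (
    AMRSettings,
    preemptive_refine,
    refine_step,
    run_amr,
    select_facets,
    write_pass_history,
)
from .io import write_model_bundle
from .mesh import HeadModel
from .metrics import (
    ObservationSet,
    l21_error,
    rdm_E,
    v_2norm_error,
    v_rdm,
    write_error_report,
)
from .operator import ChargeSolution, DirectBackend, build_nearfield, evaluate_E, evaluate_V
from .phantoms import (
    ShellSpec,
    focal_ring_montage,
    make_dipole_cluster,
    make_figure8_coil,
    make_icosphere,
    make_midlayer_roi,
    make_multishell,
    three_shell_specs,
)
from .solver import SolverSettings, solve
from .sources import (
    EEGSource,
    TESVoltageSource,
    TMSSource,
    injected_current,
    rescale_to_current,
)

__all__ = ["StudyConfig", "run_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Plain-data study description (serialized verbatim into provenance).

    mode: "tes" | "tms" | "eeg".  The phantom block gives shell radii (m),
    per-shell interior conductivities (S/m) and the icosphere subdivision
    level.  The target is a point on/near the innermost surface that the
    source aims at (TES/TMS) or the dipole cluster centers on (EEG).
    """

    mode: str = "tes"
    phantom: dict = field(
        default_factory=lambda: {
            "radii": [0.08, 0.09, 0.1],
            "sigmas": [0.33, 0.0042, 0.33],
            "n_subdivisions": 3,
        }
    )
    target: list = field(default_factory=lambda: [0.0, 0.0, 0.08])
    roi_radius: float = 0.02
    source: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    amr: dict = field(default_factory=dict)
    out: str = "study_out"
    seed: int = 0


def _make_model(cfg: StudyConfig) -> HeadModel:
    ph = cfg.phantom
    shells = [
        ShellSpec(r, n, s)
        for r, s, n in zip(
            ph["radii"], ph["sigmas"],
            ph.get("names", [f"shell{i}" for i in range(len(ph["radii"]))]),
        )
    ]
    return make_multishell(shells, ph["n_subdivisions"])


def _default_roi(cfg: StudyConfig, model: HeadModel) -> ObservationSet:
    """Midlayer-style E-field ROI just inside the innermost surface."""
    r0 = cfg.phantom["radii"][0]
    inner_aux = make_icosphere(0.875 * r0, cfg.phantom["n_subdivisions"])
    return make_midlayer_roi(
        inner_aux, model.surfaces[0], np.asarray(cfg.target), cfg.roi_radius
    )


def _setup(cfg: StudyConfig):
    model = _make_model(cfg)
    target = np.asarray(cfg.target, dtype=np.float64)
    src_cfg = dict(cfg.source)
    amr_kwargs = dict(cfg.amr)
    if cfg.mode == "tes":
        scalp_sid = len(model.surfaces) - 1
        montage = focal_ring_montage(
            model.surfaces[scalp_sid],
            target * (cfg.phantom["radii"][-1] / np.linalg.norm(target)),
            electrode_radius=src_cfg.get("electrode_radius", 5e-3),
            separation=src_cfg.get("separation", 30e-3),
        )
        offset = int(model.offsets[scalp_sid])
        model.electrodes = {
            name: loc + offset for name, loc in montage.items()
        }
        # preemptive refinement of the electrode region, then skin exclusion
        ring_center = model.centroids[model.electrodes["center"]].mean(axis=0)
        radius = 1.2 * (
            src_cfg.get("separation", 30e-3) + src_cfg.get("electrode_radius", 5e-3)
        )
        preemptive_refine(
            model, [scalp_sid], ring_center, radius,
            iterations=src_cfg.get("preemptive_iterations", 2),
        )
        potentials = {"center": +1.0}
        potentials.update(
            {k: -1.0 for k in model.electrodes if k.startswith("return")}
        )
        source = TESVoltageSource(
            potentials=potentials,
            target_current=src_cfg.get("target_current", 1e-3),
            current_electrode="center",
        )
        roi = _default_roi(cfg, model)
        metric = "E-L21"
    elif cfg.mode == "tms":
        coil = make_figure8_coil(
            loop_radius=src_cfg.get("loop_radius", 0.027),
            turns=src_cfg.get("turns", 1),
            segments_per_loop=src_cfg.get("segments_per_loop", 120),
            standoff=src_cfg.get("standoff", 0.01),
            target=np.asarray(cfg.target),
            surface=model.surfaces[-1],
            I0=src_cfg.get("I0", 5e3),
            f=src_cfg.get("f", 3e3),
        )
        source = TMSSource(coil)
        roi = _default_roi(cfg, model)
        metric = "E-L21"
    elif cfg.mode == "eeg":
        r0 = cfg.phantom["radii"][0]
        inner_aux = make_icosphere(
            0.875 * r0, max(cfg.phantom["n_subdivisions"] - 1, 2)
        )
        cluster = make_dipole_cluster(
            inner_aux,
            model.surfaces[0],
            np.asarray(cfg.target),
            cluster_radius=src_cfg.get("cluster_radius", 2.3e-3),
            sigma_medium=cfg.phantom["sigmas"][0],
        )
        source = EEGSource(cluster)
        # fixed readout: skin facet centroids and areas of the initial mesh
        sl = model.surface_slice(len(model.surfaces) - 1)
        roi = ObservationSet(
            model.centroids[sl], kind="skin-potential", areas=model.areas[sl]
        )
        metric = "V-2norm"
    else:
        raise ValueError(f"unknown study mode {cfg.mode!r}")
    amr_kwargs.setdefault("metric", metric)
    return model, source, roi, AMRSettings(**amr_kwargs)


def _total_roi_quantity(model, c, source, roi, backend):
    if roi.kind == "midlayer-E":
        return evaluate_E(model, c, roi.points, backend) + source.primary_E(roi.points)
    V = evaluate_V(model, c, roi.points, backend)
    if hasattr(source, "primary_V"):
        V = V + source.primary_V(roi.points)
    return V


def _maybe_rescale(model, c, source, backend):
    if isinstance(source, TESVoltageSource) and source.target_current is not None:
        I = injected_current(model, c, source, source.current_electrode, backend)
        if I == 0.0:
            raise RuntimeError("measured injected current is zero; aborting rescale")
        return rescale_to_current(c, I, source.target_current), I
    return c, None


def run_study(config: StudyConfig) -> dict:
    """Run the STD/AMR/REF protocol and write the report bundle.

    Returns a dict with the pairwise error table, pass history and artifact
    paths.  Stage failures leave a partial-results manifest naming the failed
    stage.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    backend = DirectBackend()
    solver_settings = SolverSettings(**config.solver)
    provenance = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "package_version": __version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "initial_drive": "+1 V center / -1 V returns" if config.mode == "tes" else None,
    }
    result: dict = {"provenance": provenance}
    stage = "setup"
    try:
        model_std, source, roi, amr_settings = _setup(config)
        nearfield = build_nearfield(model_std)

        stage = "STD"
        logger.info("stage=STD facets=%d", model_std.n_facets)
        c_std, stats_std = solve(
            model_std, source, solver_settings, nearfield, backend, initial=True
        )
        c_std, I_std = _maybe_rescale(model_std, c_std, source, backend)
        q_std = _total_roi_quantity(model_std, c_std, source, roi, backend)

        stage = "AMR"
        model_amr, source_a, roi_a, amr_settings_a = _setup(config)
        c_amr, records = run_amr(
            model_amr, source_a, roi, solver_settings, amr_settings, backend
        )
        c_amr, I_amr = _maybe_rescale(model_amr, c_amr, source_a, backend)
        q_amr = _total_roi_quantity(model_amr, c_amr, source_a, roi, backend)

        stage = "REF"
        logger.info("stage=REF global 4:1 subdivision")
        selection = {
            sid: np.arange(model_amr.surfaces[sid].n_facets)
            for sid in range(len(model_amr.surfaces))
            if sid not in model_amr.excluded_surfaces
        }
        nf_amr = build_nearfield(model_amr)
        c_ref, nf_ref = refine_step(model_amr, c_amr, selection, nf_amr)
        c_ref, stats_ref = solve(
            model_amr, source_a, solver_settings, nf_ref, backend,
            warm_start=c_ref,
        )
        c_ref, I_ref = _maybe_rescale(model_amr, c_ref, source_a, backend)
        q_ref = _total_roi_quantity(model_amr, c_ref, source_a, roi, backend)

        stage = "metrics"
        rows: dict[str, dict[str, float]] = {}
        for label, (qt, qb) in {
            "STD/REF": (q_std, q_ref),
            "STD/AMR": (q_std, q_amr),
            "AMR/REF": (q_amr, q_ref),
        }.items():
            if roi.kind == "midlayer-E":
                rows[label] = {"L21": l21_error(qt, qb), "RDM": rdm_E(qt, qb)}
            else:
                rows[label] = {
                    "dV": v_2norm_error(qt, qb),
                    "dV_RDM": v_rdm(qt, qb, roi.areas),
                }

        stage = "artifacts"
        write_error_report(out / "errors.csv", rows)
        write_pass_history(out / "amr_passes.csv", records)
        write_model_bundle(model_amr, out / "model_amr")
        np.savez(
            out / "charges.npz", c_std=c_std.c, c_amr=c_amr.c, c_ref=c_ref.c
        )
        provenance["injected_currents_A"] = {
            "STD": I_std, "AMR": I_amr, "REF": I_ref,
        }
        result.update(
            {
                "errors": rows,
                "passes": records,
                "facets": {
                    "STD": len(c_std.c), "AMR": len(c_amr.c), "REF": len(c_ref.c),
                },
                "out": str(out),
            }
        )
        with (out / "provenance.json").open("w") as fh:
            json.dump(provenance, fh, indent=2, default=str)
    except Exception as exc:  # partial-results manifest with diagnostics
        with (out / "provenance.json").open("w") as fh:
            json.dump(
                {**provenance, "failed_stage": stage, "error": repr(exc)},
                fh, indent=2, default=str,
            )
        raise
    return result
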