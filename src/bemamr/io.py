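"""Mesh and model-bundle I/O.

Single surfaces round-trip through STL/PLY/OFF via trimesh.  A multi-surface
model bundle is a directory holding one mesh file per boundary plus a YAML
manifest listing file, name, conductivities and electrode facet sets, with an
explicit length unit (meters internally; mm accepted at I/O).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import trimesh
import yaml

from .mesh import HeadModel, TriSurface

__all__ = ["read_surface", "write_surface", "write_model_bundle", "read_model_bundle"]

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3}


def read_surface(path, name: str = "", unit: str = "m") -> TriSurface:
    """Load a triangulated surface from STL/PLY/OFF, unmodified (no merging,
    repair or reordering)."""
    scale = _UNIT_SCALE[unit]
    m = trimesh.load_mesh(str(path), process=False)
    return TriSurface(
        np.asarray(m.vertices, dtype=np.float64) * scale,
        np.asarray(m.faces, dtype=np.int64),
        name=name or Path(path).stem,
    )


def write_surface(surface: TriSurface, path, unit: str = "m") -> None:
    scale = _UNIT_SCALE[unit]
    m = trimesh.Trimesh(
        vertices=surface.vertices / scale, faces=surface.facets, process=False
    )
    m.export(str(path))


def write_model_bundle(model: HeadModel, directory, fmt: str = "ply") -> Path:
    """Write every surface plus a manifest.yaml describing the model."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(model.surfaces):
        fname = f"{i:02d}_{s.name or 'surface'}.{fmt}"
        write_surface(s, directory / fname)
        entries.append(
            {
                "file": fname,
                "name": s.name,
                "sigma_in": float(model.sigma_in[i]),
                "sigma_out": float(model.sigma_out[i]),
            }
        )
    electrodes = {
        name: [int(g) for g in gids] for name, gids in model.electrodes.items()
    }
    manifest = {"unit": "m", "surfaces": entries, "electrodes": electrodes}
    with (directory / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return directory


def read_model_bundle(directory) -> HeadModel:
    directory = Path(directory)
    with (directory / "manifest.yaml").open() as fh:
        manifest = yaml.safe_load(fh)
    unit = manifest.get("unit", "m")
    surfaces, s_in, s_out = [], [], []
    for e in manifest["surfaces"]:
        surfaces.append(read_surface(directory / e["file"], name=e["name"], unit=unit))
        s_in.append(e["sigma_in"])
        s_out.append(e["sigma_out"])
    electrodes = {
        name: np.asarray(gids, dtype=np.int64)
        for name, gids in manifest.get("electrodes", {}).items()
    }
    return HeadModel(surfaces, s_in, s_out, electrodes=electrodes)
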