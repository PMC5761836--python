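"""YAML run-configuration: stages, meshes, muscles, materials.

Layout::

    stages:
      - label: "6dpf"
        mesh: stage1.vtk            # msh / vtk / inp
        muscles: muscles_stage1.yaml
        contact_set: contact_neurocranium
        reduction_muscle: retractor_dorsalis
        biting_muscles: [levator_externus_4, levator_posterior]
        materials:
          - {name: bone, youngs_modulus: 3670.0, poisson_ratio: 0.3, regions: [1]}
          - {name: tooth, youngs_modulus: 70000.0, poisson_ratio: 0.3, regions: [2]}

Relative paths resolve against the config file's directory.  Omitted
materials fall back to the default bone/tooth table.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fem import ElasticMaterial, default_materials
from .meshio import read_mesh
from .muscles import load_muscle_config
from .pipeline import StageSpec

__all__ = ["load_run_config", "materials_from_entries"]


def materials_from_entries(entries) -> list[ElasticMaterial]:
    mats = []
    for e in entries:
        mats.append(
            ElasticMaterial(
                name=str(e["name"]),
                youngs_modulus=float(e["youngs_modulus"]),
                poisson_ratio=float(e["poisson_ratio"]),
                region_tags=tuple(int(t) for t in e.get("regions", ())),
            )
        )
    return mats


def load_run_config(path) -> list[StageSpec]:
    """Parse a run configuration into ordered :class:`StageSpec` objects."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = path.parent
    stages = []
    for entry in cfg["stages"]:
        mesh = read_mesh(base / entry["mesh"])
        muscles = load_muscle_config(str(base / entry["muscles"]))
        mats = (
            materials_from_entries(entry["materials"])
            if "materials" in entry
            else default_materials()
        )
        stages.append(
            StageSpec(
                stage_label=str(entry["label"]),
                mesh=mesh,
                muscles=muscles,
                contact_set=entry["contact_set"],
                materials=mats,
                reduction_muscle=entry["reduction_muscle"],
                biting_muscles=tuple(entry.get("biting_muscles", ())),
            )
        )
    return stages
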