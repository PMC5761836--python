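"""Muscle load modelling: attachment geometry, force vectors, orientation angles.

A muscle is described by where it attaches (an insertion node set on the
structural mesh and either an origin node set or an explicit origin point),
its physiological cross-sectional area (PCSA, mm^2), and a specific tension
(N/mm^2, default 2.5 — the literature value for pharyngeal jaw muscle).

The modelling chain is deliberately simple and mirrors how distributed
muscle loads are built for skull finite-element models:

1. the pull direction is the unit vector from the insertion centroid to the
   origin centroid (muscles pull the loaded structure toward their origin);
2. the magnitude is mean-pair PCSA x specific tension, applied per side;
3. the total force is divided equally among the insertion nodes, so a
   100 uN muscle spread over 200 nodes loads each node with 0.5 uN.

Orientation is reported as three anatomical angles (degrees):

* RCA — rotation about the rostro-caudal axis: 0 deg pure lateral, 90 deg
  pure dorsal;
* MLA — rotation about the medio-lateral axis: 0 deg rostral, 90 deg
  dorsal, 180 deg caudal;
* DVA — rotation about the dorso-ventral axis: +90 deg rostral, 0 deg
  lateral, -90 deg caudal.

RCA and DVA use the magnitude of the *outward* lateral component, so
mirrored left/right muscles of a symmetric structure report identical
triples and pair averaging is a plain component-wise mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .mesh import AnatomicalFrame, TetMesh

__all__ = [
    "MuscleDefinition",
    "MuscleLoad",
    "AngleTriple",
    "attachment_centroid",
    "muscle_direction",
    "muscle_force_magnitude",
    "distribute_nodal_forces",
    "orientation_angles",
    "pair_average_angles",
    "load_muscle_config",
    "dump_muscle_config",
]

DEFAULT_SPECIFIC_TENSION = 2.5  # N/mm^2


@dataclass(frozen=True)
class MuscleDefinition:
    """One muscle (one side of a pair, or a median muscle)."""

    name: str
    side: str  # "left" | "right" | "median"
    insertion_set: str
    pcsa: float  # mm^2
    origin_set: str | None = None
    origin_point: tuple[float, float, float] | None = None
    specific_tension: float = DEFAULT_SPECIFIC_TENSION

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "median"):
            raise ValueError(f"side must be left/right/median, got {self.side!r}")
        if not (self.pcsa > 0):
            raise ValueError(f"muscle {self.name!r}: pcsa must be > 0, got {self.pcsa}")
        if not (self.specific_tension > 0):
            raise ValueError(
                f"muscle {self.name!r}: specific_tension must be > 0"
            )
        if (self.origin_set is None) == (self.origin_point is None):
            raise ValueError(
                f"muscle {self.name!r}: exactly one of origin_set / origin_point required"
            )

    @property
    def label(self) -> str:
        return f"{self.name}_{self.side}"


@dataclass(frozen=True)
class MuscleLoad:
    """Distributed nodal force set produced by one muscle."""

    muscle: MuscleDefinition
    unit_direction: np.ndarray  # insertion -> origin
    total_force: float  # N
    insertion_nodes: np.ndarray
    nodal_forces: np.ndarray  # (n, 3) N, all rows equal

    def resultant(self) -> np.ndarray:
        return self.nodal_forces.sum(axis=0)

    def scaled(self, factor: float) -> "MuscleLoad":
        return replace(
            self,
            total_force=self.total_force * factor,
            nodal_forces=self.nodal_forces * factor,
        )


@dataclass(frozen=True)
class AngleTriple:
    """Muscle orientation angles in degrees (RCA, MLA, DVA)."""

    rca: float  # [0, 90]
    mla: float  # (-180, 180]
    dva: float  # [-90, 90]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rca, self.mla, self.dva)


def attachment_centroid(mesh: TetMesh, set_name: str) -> np.ndarray:
    """Unweighted arithmetic mean of the coordinates of a node set."""
    idx = mesh.node_set(set_name)
    if len(idx) == 0:
        raise ValueError(f"node set {set_name!r} is empty")
    return mesh.node_coords[idx].mean(axis=0)


def muscle_direction(mesh: TetMesh, muscle: MuscleDefinition) -> np.ndarray:
    """Unit pull direction: from insertion centroid toward origin centroid."""
    ins = attachment_centroid(mesh, muscle.insertion_set)
    if muscle.origin_point is not None:
        org = np.asarray(muscle.origin_point, dtype=float)
    else:
        org = attachment_centroid(mesh, muscle.origin_set)
    d = org - ins
    norm = float(np.linalg.norm(d))
    if norm < 1e-12:
        raise ValueError(
            f"muscle {muscle.label!r}: insertion and origin centroids coincide"
        )
    return d / norm


def muscle_force_magnitude(*muscles: MuscleDefinition) -> float:
    """Per-side force magnitude (N) of a muscle or a left/right pair.

    The PCSA is averaged over the pair before multiplying by the shared
    specific tension, so both sides of a pair carry the same magnitude.
    """
    if not 1 <= len(muscles) <= 2:
        raise ValueError("expected one muscle or a left/right pair")
    tensions = {m.specific_tension for m in muscles}
    if len(tensions) != 1:
        raise ValueError(
            f"pair {muscles[0].name!r}: mismatched specific_tension {sorted(tensions)}"
        )
    pcsa = float(np.mean([m.pcsa for m in muscles]))
    return pcsa * muscles[0].specific_tension


def distribute_nodal_forces(
    mesh: TetMesh,
    muscle: MuscleDefinition,
    *,
    pair: MuscleDefinition | None = None,
) -> MuscleLoad:
    """Spread a muscle's total force equally over its insertion nodes.

    ``pair`` is the contralateral muscle when the magnitude should use the
    pair-averaged PCSA.  Each insertion node receives (total / n) x the
    unit pull direction; the vector sum therefore reproduces the total
    exactly.
    """
    nodes = mesh.node_set(muscle.insertion_set)
    if len(nodes) == 0:
        raise ValueError(f"muscle {muscle.label!r}: empty insertion set")
    direction = muscle_direction(mesh, muscle)
    members = (muscle,) if pair is None else (muscle, pair)
    total = muscle_force_magnitude(*members)
    per_node = (total / len(nodes)) * direction
    forces = np.tile(per_node, (len(nodes), 1))
    return MuscleLoad(muscle, direction, total, nodes, forces)


def orientation_angles(
    direction: np.ndarray,
    frame: AnatomicalFrame,
    side: str,
) -> AngleTriple:
    """Three-axis anatomical orientation of a pull direction.

    With l, r, d the outward-lateral, rostral and dorsal components:

    * RCA = atan2(|d|, |l|)            — 0 lateral .. 90 dorsal
    * MLA = atan2(d, r)                — 0 rostral, 90 dorsal, 180 caudal
    * DVA = atan2(r, |l|)              — +90 rostral, 0 lateral, -90 caudal
    """
    d = np.asarray(direction, dtype=float)
    norm = float(np.linalg.norm(d))
    if norm < 1e-12:
        raise ValueError("zero-length direction vector")
    lat, ros, dor = frame.components(d / norm, side)
    rca = math.degrees(math.atan2(abs(dor), abs(lat)))
    mla = math.degrees(math.atan2(dor, ros))
    dva = math.degrees(math.atan2(ros, abs(lat)))
    return AngleTriple(rca, mla, dva)


def pair_average_angles(left: AngleTriple, right: AngleTriple) -> AngleTriple:
    """Component-wise mean of a left/right angle pair.

    Side mirroring is already folded into the outward-lateral convention of
    :func:`orientation_angles`, so no further reflection is needed here.
    """
    return AngleTriple(
        (left.rca + right.rca) / 2.0,
        (left.mla + right.mla) / 2.0,
        (left.dva + right.dva) / 2.0,
    )


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_muscle_config(path_or_data) -> list[MuscleDefinition]:
    """Load muscle definitions from a YAML/JSON file or a parsed list."""
    if isinstance(path_or_data, (str, bytes)) or hasattr(path_or_data, "read"):
        with open(path_or_data) as fh:
            data = yaml.safe_load(fh)
    elif hasattr(path_or_data, "__fspath__"):
        with open(path_or_data) as fh:
            data = yaml.safe_load(fh)
    else:
        data = path_or_data
    if isinstance(data, dict):
        data = data.get("muscles", data)
    muscles = []
    for entry in data:
        entry = dict(entry)
        if "origin_point" in entry and entry["origin_point"] is not None:
            entry["origin_point"] = tuple(float(v) for v in entry["origin_point"])
        muscles.append(MuscleDefinition(**entry))
    return muscles


def dump_muscle_config(muscles: list[MuscleDefinition], path) -> None:
    entries = []
    for m in muscles:
        e = {
            "name": m.name,
            "side": m.side,
            "insertion_set": m.insertion_set,
            "pcsa": float(m.pcsa),
            "specific_tension": float(m.specific_tension),
        }
        if m.origin_set is not None:
            e["origin_set"] = m.origin_set
        else:
            e["origin_point"] = [float(v) for v in m.origin_point]
        entries.append(e)
    with open(path, "w") as fh:
        yaml.safe_dump({"muscles": entries}, fh, sort_keys=False)


def group_pairs(muscles: list[MuscleDefinition]) -> dict[str, list[MuscleDefinition]]:
    """Group muscles by name (a pair shares its name across sides)."""
    groups: dict[str, list[MuscleDefinition]] = {}
    for m in muscles:
        groups.setdefault(m.name, []).append(m)
    for name, members in groups.items():
        sides = [m.side for m in members]
        if len(sides) != len(set(sides)):
            raise ValueError(f"muscle pair {name!r} has duplicate sides {sides}")
        if len(members) > 2:
            raise ValueError(f"muscle {name!r} has more than two sides")
    return groups


def build_loads(mesh: TetMesh, muscles: list[MuscleDefinition]) -> list[MuscleLoad]:
    """Distributed loads for every muscle, with pair-averaged magnitudes."""
    loads = []
    for name, members in group_pairs(muscles).items():
        pair = members[1] if len(members) == 2 else None
        for k, m in enumerate(members):
            other = members[1 - k] if pair is not None else None
            loads.append(distribute_nodal_forces(mesh, m, pair=other))
    return loads
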