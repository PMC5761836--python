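"""Two-step developmental FEA per specimen, and ontogenetic series reports.

For each developmental stage the analysis runs in two steps:

1. **Full contraction** — every muscle at full isometric force
   simultaneously.  This yields maximum bite force, the force transferred
   to the neurocranium through the fixed contact patch, and the von Mises
   stress field with its hotspot.
2. **Sliding removal** — part of the reaction at the contact is directed
   along the anterior-posterior (rostro-caudal) axis, i.e. the jaw would
   slide along the neurocranium rather than compress against it.  One
   muscle pair is rescaled so the net anterior-posterior reaction vanishes
   and the case simulates pure compression; the compressive force normal
   to the neurocranium is then evaluated from the adjusted load
   combination.

The rescaling exploits linearity: the anterior-posterior reaction is
affine in the pair's scale factor, so the zeroing scale follows in closed
form from two solves.  The literal reduction-factor formula
``X = (F_total - F_old) / F_old`` (on anterior-posterior force components)
is computed alongside and cross-checked; with the pair opposing the rest
of the musculature the two agree up to sign (scale = -X), and the result
is flagged infeasible whenever the literal X falls outside [0, 1].

Bite force and von Mises stress are assessed without reduction: biting
benefits from shearing and does not require static compression.

Percent changes between stages follow the ratio convention: a change
reported as 337% means the later value is 3.37x the earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mesh import (
    AnatomicalFrame,
    TetMesh,
    boundary_facets,
    elements_touching,
    surface_node_ring,
)
from .muscles import (
    AngleTriple,
    MuscleDefinition,
    MuscleLoad,
    build_loads,
    group_pairs,
    muscle_direction,
    orientation_angles,
    pair_average_angles,
)
from .fem import (
    ConstraintSet,
    ElasticMaterial,
    LoadCase,
    SolutionField,
    StressField,
    assemble_global,
    reaction_resultant,
    recover_stresses,
    solve_linear_static,
)

__all__ = [
    "StageSpec",
    "ReductionResult",
    "StageReport",
    "OntogenySeries",
    "run_full_contraction",
    "eq2_reduction_factor",
    "zero_ap_sliding",
    "neurocranium_normal_force",
    "bite_force",
    "run_stage",
    "compare_ontogeny",
]


@dataclass
class StageSpec:
    """Everything needed to analyse one developmental stage."""

    stage_label: str
    mesh: TetMesh
    muscles: list[MuscleDefinition]
    contact_set: str
    materials: list[ElasticMaterial]
    reduction_muscle: str
    biting_muscles: tuple[str, ...] = ()
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame)

    def __post_init__(self) -> None:
        if len(self.mesh.node_set(self.contact_set)) == 0:
            raise ValueError(f"contact set {self.contact_set!r} is empty")
        names = {m.name for m in self.muscles}
        if self.reduction_muscle not in names:
            raise ValueError(
                f"reduction muscle {self.reduction_muscle!r} not among {sorted(names)}"
            )
        missing = [b for b in self.biting_muscles if b not in names]
        if missing:
            raise ValueError(f"biting muscles {missing} not among {sorted(names)}")


class StageAnalysis:
    """Cached per-stage state: stiffness matrix, muscle loads, constraints."""

    def __init__(self, stage: StageSpec):
        self.stage = stage
        self.loads: list[MuscleLoad] = build_loads(stage.mesh, stage.muscles)
        self.constraints = ConstraintSet(stage.mesh.node_set(stage.contact_set))
        self._K = None

    @property
    def K(self):
        if self._K is None:
            self._K = assemble_global(self.stage.mesh, self.stage.materials)
        return self._K

    def loads_for(self, names) -> list[MuscleLoad]:
        names = set(names)
        return [ld for ld in self.loads if ld.muscle.name in names]

    def case(self, name: str, loads=None) -> LoadCase:
        return LoadCase.from_muscle_loads(name, self.loads if loads is None else loads)

    def solve(self, case: LoadCase) -> SolutionField:
        return solve_linear_static(self.K, case, self.constraints)


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of removing anterior-posterior sliding via one muscle pair.

    ``x_factor`` is the literal reduction factor
    (F_total_ap - F_old_ap) / F_old_ap on anterior-posterior components;
    ``scale`` is the closed-form multiplier applied to the pair so the net
    anterior-posterior reaction vanishes.  ``feasible`` records whether
    x_factor lies in [0, 1]; ``discrepancy`` is |scale + x_factor|, the
    cross-check between the two routes (zero up to solver tolerance).
    """

    x_factor: float
    scale: float
    f_total_ap: float
    f_old_ap: float
    residual_ap_after: float
    feasible: bool
    discrepancy: float = 0.0


@dataclass
class StageReport:
    """Forces, stresses and muscle angles for one stage."""

    stage_label: str
    # full contraction
    bite_force: float  # N
    neurocranium_force: np.ndarray  # N, force exerted on the neurocranium
    neurocranium_force_magnitude: float
    hotspot_element: int
    hotspot_von_mises: float  # MPa
    equilibrium_residual: float  # |sum loads + sum reactions| N
    # reduced (pure compression) condition
    reduction: ReductionResult
    neurocranium_normal_force: float  # N, local facet-normal projection
    neurocranium_dorsal_force: float  # N, global dorsal-axis projection
    # orientation
    angles: dict[str, AngleTriple]

    def to_dict(self) -> dict:
        return {
            "stage_label": self.stage_label,
            "forces": {
                "bite_force_N": self.bite_force,
                "neurocranium_force_N": [float(v) for v in self.neurocranium_force],
                "neurocranium_force_magnitude_N": self.neurocranium_force_magnitude,
                "neurocranium_normal_force_N": self.neurocranium_normal_force,
                "neurocranium_dorsal_force_N": self.neurocranium_dorsal_force,
                "equilibrium_residual_N": self.equilibrium_residual,
            },
            "x_factor": self.reduction.x_factor,
            "reduction": {
                "scale": self.reduction.scale,
                "f_total_ap_N": self.reduction.f_total_ap,
                "f_old_ap_N": self.reduction.f_old_ap,
                "residual_ap_after_N": self.reduction.residual_ap_after,
                "feasible": self.reduction.feasible,
                "discrepancy": self.reduction.discrepancy,
            },
            "hotspot": {
                "element": int(self.hotspot_element),
                "MPa": float(self.hotspot_von_mises),
            },
            "angles": {
                name: {"RCA": t.rca, "MLA": t.mla, "DVA": t.dva}
                for name, t in self.angles.items()
            },
        }


@dataclass
class OntogenySeries:
    """Ordered stage reports plus consecutive-stage percent changes."""

    stages: list[StageReport]
    percent_changes: list[dict]


# ---------------------------------------------------------------------------
# step operations
# ---------------------------------------------------------------------------

def muscle_pair_angles(stage: StageSpec) -> dict[str, AngleTriple]:
    """Pair-averaged orientation angles for every muscle of the stage."""
    out: dict[str, AngleTriple] = {}
    for name, members in group_pairs(stage.muscles).items():
        triples = [
            orientation_angles(
                muscle_direction(stage.mesh, m), stage.frame, m.side
            )
            for m in members
        ]
        out[name] = (
            triples[0] if len(triples) == 1 else pair_average_angles(*triples)
        )
    return out


def hotspot_von_mises(
    mesh: TetMesh,
    stress: StressField,
    exclude_node_sets: list[str],
    *,
    rings: int = 1,
) -> tuple[int, float]:
    """Max per-element von Mises outside load-application/contact zones.

    Elements within ``rings`` node-rings of the excluded sets are masked
    out — a reproducible replacement for manual, case-by-case outlier
    screening near applied loads and corners.
    """
    seed = np.concatenate([mesh.node_set(s) for s in exclude_node_sets])
    zone = surface_node_ring(mesh, seed, rings=rings)
    excluded = elements_touching(mesh, zone)
    mask = np.ones(mesh.n_elements, dtype=bool)
    mask[excluded] = False
    if not np.any(mask):
        raise ValueError("exclusion zone covers the whole mesh")
    vm = np.where(mask, stress.von_mises, -np.inf)
    e = int(np.argmax(vm))
    return e, float(vm[e])


def bite_force(stage: StageSpec, analysis: StageAnalysis | None = None) -> float:
    """Magnitude of the resultant of the unreduced biting-muscle loads.

    The biting muscles (by default the levator externus 4 + levator
    posterior sling) act on the lower jaw; their force is taken as fully
    transmitted, so the bite force is the vector sum of their distributed
    loads over both sides.  No reduction applies.
    """
    if not stage.biting_muscles:
        raise ValueError("stage has no biting muscles configured")
    analysis = analysis or StageAnalysis(stage)
    loads = analysis.loads_for(stage.biting_muscles)
    resultant = np.sum([ld.resultant() for ld in loads], axis=0)
    return float(np.linalg.norm(resultant))


def eq2_reduction_factor(f_total_ap: float, f_old_ap: float) -> ReductionResult:
    """Literal reduction factor X = (F_total - F_old) / F_old.

    Computed on the anterior-posterior force components of all muscles
    (F_total) and of the pair to be reduced (F_old); the result must lie
    in [0, 1] to be feasible and is flagged otherwise.
    """
    if f_old_ap == 0:
        raise ZeroDivisionError("F_old has no anterior-posterior component")
    x = (f_total_ap - f_old_ap) / f_old_ap
    return ReductionResult(
        x_factor=float(x),
        scale=float(-x),
        f_total_ap=float(f_total_ap),
        f_old_ap=float(f_old_ap),
        residual_ap_after=float("nan"),
        feasible=bool(0.0 <= x <= 1.0),
    )


def zero_ap_sliding(
    stage: StageSpec,
    pair: str | None = None,
    analysis: StageAnalysis | None = None,
) -> tuple[ReductionResult, LoadCase, SolutionField]:
    """Rescale one muscle pair so the net anterior-posterior reaction is zero.

    By linearity the anterior-posterior reaction component is affine in the
    pair's scale s, so two solves (all-but-pair, pair alone) give the
    zeroing scale s* = -AP_without_pair / AP_pair_per_unit in closed form.
    Returns the reduction bookkeeping (including the literal
    X = (F_total - F_old)/F_old cross-check), the adjusted load case, and
    its solution.
    """
    analysis = analysis or StageAnalysis(stage)
    pair = pair or stage.reduction_muscle
    ap = np.asarray(stage.frame.rostral_axis, dtype=float)

    pair_loads = analysis.loads_for([pair])
    if not pair_loads:
        raise ValueError(f"unknown reduction pair {pair!r}")
    rest_loads = [ld for ld in analysis.loads if ld.muscle.name != pair]

    case_pair = analysis.case("pair_unit", pair_loads)
    case_rest = analysis.case("rest", rest_loads)
    total_mag = sum(np.linalg.norm(ld.resultant()) for ld in analysis.loads)

    f_old_ap = float(case_pair.total() @ ap)
    f_total_ap = float((case_pair.total() + case_rest.total()) @ ap)
    if abs(f_old_ap) <= 1e-12 * max(total_mag, 1e-300):
        raise ValueError(
            f"pair {pair!r} contributes no anterior-posterior component"
        )

    contact = stage.mesh.node_set(stage.contact_set)
    sol_rest = analysis.solve(case_rest)
    sol_pair = analysis.solve(case_pair)
    r_rest = reaction_resultant(sol_rest, contact, ap)
    r_pair = reaction_resultant(sol_pair, contact, ap)
    if abs(r_pair) <= 1e-12 * max(total_mag, 1e-300):
        raise ValueError(
            f"pair {pair!r} produces no anterior-posterior reaction"
        )
    scale = -r_rest / r_pair

    reduced = LoadCase.combine(
        f"reduced_{stage.stage_label}", case_rest, case_pair.scaled(scale)
    )
    sol = analysis.solve(reduced)
    residual_ap = abs(reaction_resultant(sol, contact, ap))

    literal = eq2_reduction_factor(f_total_ap, f_old_ap)
    result = ReductionResult(
        x_factor=literal.x_factor,
        scale=float(scale),
        f_total_ap=f_total_ap,
        f_old_ap=f_old_ap,
        residual_ap_after=float(residual_ap),
        feasible=literal.feasible,
        discrepancy=float(abs(scale + literal.x_factor)),
    )
    return result, reduced, sol


def contact_patch_normal(mesh: TetMesh, contact_set: str) -> np.ndarray:
    """Area-weighted mean outward normal of the contact surface patch."""
    nodes = mesh.node_set(contact_set)
    member = np.zeros(mesh.n_nodes, dtype=bool)
    member[nodes] = True
    faces = boundary_facets(mesh)
    faces = faces[np.all(member[faces], axis=1)]
    if len(faces) == 0:
        raise ValueError(f"contact set {contact_set!r} spans no boundary facets")
    p = mesh.node_coords[faces]
    normals = 0.5 * np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    total = normals.sum(axis=0)
    norm = np.linalg.norm(total)
    if norm < 1e-15:
        raise ValueError("degenerate contact patch (zero net normal)")
    return total / norm


def neurocranium_normal_force(
    stage: StageSpec,
    solution: SolutionField,
) -> float:
    """Compressive force on the neurocranium, normal to the contact patch.

    The force the structure exerts on the neurocranium is the negated
    reaction resultant over the contact set, projected on the patch's
    outward mean facet normal.
    """
    contact = stage.mesh.node_set(stage.contact_set)
    normal = contact_patch_normal(stage.mesh, stage.contact_set)
    force_on_neuro = -reaction_resultant(solution, contact)
    return float(force_on_neuro @ normal)


def run_full_contraction(
    stage: StageSpec, analysis: StageAnalysis | None = None
) -> tuple[dict, SolutionField, StressField]:
    """Step 1: all muscles at full force, acting simultaneously."""
    analysis = analysis or StageAnalysis(stage)
    case = analysis.case(f"full_{stage.stage_label}")
    sol = analysis.solve(case)
    stress = recover_stresses(stage.mesh, stage.materials, sol)

    contact = stage.mesh.node_set(stage.contact_set)
    reaction = reaction_resultant(sol, contact)
    force_on_neuro = -np.asarray(reaction)
    exclude = [stage.contact_set] + [m.insertion_set for m in stage.muscles]
    elem, vm = hotspot_von_mises(stage.mesh, stress, exclude)
    residual = float(np.linalg.norm(case.total() + sol.reactions.sum(axis=0)))
    summary = {
        "neurocranium_reaction": np.asarray(reaction),
        "neurocranium_force": force_on_neuro,
        "hotspot_element": elem,
        "hotspot_von_mises": vm,
        "equilibrium_residual": residual,
    }
    return summary, sol, stress


def run_stage(stage: StageSpec) -> StageReport:
    """Complete two-step analysis of one stage."""
    analysis = StageAnalysis(stage)
    summary, _, _ = run_full_contraction(stage, analysis)
    reduction, _, sol_reduced = zero_ap_sliding(stage, analysis=analysis)
    normal_force = neurocranium_normal_force(stage, sol_reduced)
    dorsal = np.asarray(stage.frame.dorsal_axis, dtype=float)
    contact = stage.mesh.node_set(stage.contact_set)
    dorsal_force = float(-reaction_resultant(sol_reduced, contact) @ dorsal)
    bf = bite_force(stage, analysis) if stage.biting_muscles else float("nan")
    return StageReport(
        stage_label=stage.stage_label,
        bite_force=bf,
        neurocranium_force=summary["neurocranium_force"],
        neurocranium_force_magnitude=float(
            np.linalg.norm(summary["neurocranium_force"])
        ),
        hotspot_element=summary["hotspot_element"],
        hotspot_von_mises=summary["hotspot_von_mises"],
        equilibrium_residual=summary["equilibrium_residual"],
        reduction=reduction,
        neurocranium_normal_force=normal_force,
        neurocranium_dorsal_force=dorsal_force,
        angles=muscle_pair_angles(stage),
    )


# ---------------------------------------------------------------------------
# ontogenetic comparison
# ---------------------------------------------------------------------------

def _stage_order_key(label: str):
    """Leading number of a stage label (e.g. '11dpf' -> 11.0), if any."""
    num = ""
    for ch in label.strip():
        if ch.isdigit() or (ch == "." and "." not in num):
            num += ch
        else:
            break
    return float(num) if num else None


def compare_ontogeny(stages: list[StageReport]) -> OntogenySeries:
    """Consecutive-stage ratios (x100) and angle deltas for a series.

    Percent change is the later/earlier ratio times 100 — a bite force
    going from 0.1 N to 0.337 N is an increase of 337%.
    """
    if len(stages) < 2:
        raise ValueError("need at least two stages to compare")
    labels = [s.stage_label for s in stages]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate stage labels: {labels}")
    keys = [_stage_order_key(lb) for lb in labels]
    if all(k is not None for k in keys) and any(
        b <= a for a, b in zip(keys, keys[1:])
    ):
        raise ValueError(f"stage labels not in chronological order: {labels}")

    changes = []
    for early, late in zip(stages, stages[1:]):
        def pct(a, b):
            return float(100.0 * b / a) if a != 0 else float("nan")

        entry = {
            "from": early.stage_label,
            "to": late.stage_label,
            "bite_force_pct": pct(early.bite_force, late.bite_force),
            "neurocranium_force_pct": pct(
                early.neurocranium_force_magnitude,
                late.neurocranium_force_magnitude,
            ),
            "neurocranium_normal_force_pct": pct(
                early.neurocranium_normal_force, late.neurocranium_normal_force
            ),
            "max_von_mises_pct": pct(
                early.hotspot_von_mises, late.hotspot_von_mises
            ),
            "angle_deltas": {
                name: {
                    "RCA": late.angles[name].rca - t.rca,
                    "MLA": late.angles[name].mla - t.mla,
                    "DVA": late.angles[name].dva - t.dva,
                }
                for name, t in early.angles.items()
                if name in late.angles
            },
        }
        changes.append(entry)
    return OntogenySeries(list(stages), changes)
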