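"""Deterministic synthetic phantoms: validation bars, a paired-lobe jaw, growth series.

No scan data ships with the package, so every pipeline stage is exercised
on programmatically generated tetrahedral phantoms:

* :func:`make_bar` — a structured rectangular bar with ``fixed_end`` /
  ``load_end`` node sets, for closed-form elasticity checks (delta = FL/EA,
  sigma = F/A, patch tests, near/far-field load comparisons).
* :func:`make_jaw_phantom` — a bilaterally symmetric pair of lobes joined
  by a thinner midline bridge, emulating the paired upper pharyngeal jaw:
  tooth-cap elements carry the stiff tooth material, the dorsal surface of
  the bridge is the ``contact_neurocranium`` patch (the fixed
  basipharyngeal contact), and three bilateral muscle insertion patches
  with dorsally placed origin points stand in for the jaw musculature.
  The thin bridge is the engineered weak zone where von Mises stress
  concentrates under symmetric full contraction.
* :func:`make_growth_series` — an allometric series of scaled phantoms
  with PCSA growing in proportion to muscle cross-section.

All phantoms are built by structured Kuhn subdivision of axis-aligned
boxes (each grid cell splits into six tetrahedra sharing the main
diagonal), with the left half produced by exact reflection of the right
half across the midsagittal plane x = 0 — so bilateral symmetry holds at
the element level, not just the node level, and generation is
bit-reproducible.

Placeholder PCSAs are sized so per-muscle forces are O(0.01-0.1 N),
keeping phantom outputs in the magnitude range plausible for larval fish
jaws without claiming to reproduce any measured specimen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .mesh import TetMesh
from .muscles import MuscleDefinition

__all__ = [
    "PhantomSpec",
    "make_bar",
    "make_jaw_phantom",
    "make_growth_series",
]

# even permutations of (0,1,2) keep the Kuhn tet orientation; odd ones swap
_PERMS = list(itertools.permutations((0, 1, 2)))


def _perm_sign(p) -> int:
    s = 1
    p = list(p)
    for i in range(3):
        for j in range(i + 1, 3):
            if p[i] > p[j]:
                s = -s
    return s


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the jaw phantom and its growth series.

    ``resolution`` is the number of element layers through the bridge
    thickness (the finest feature); the grid spacing everywhere is
    ``bridge_size[2] / resolution``.  ``seed`` feeds any optional jitter
    and is recorded so generation is reproducible.
    """

    kind: str = "jaw"
    lobe_size: tuple[float, float, float] = (0.4, 0.6, 0.4)  # mm, per lobe
    bridge_size: tuple[float, float, float] = (0.2, 0.2, 0.15)  # mm, full width
    resolution: int = 3
    growth_factor: tuple[float, float, float] = (1.26, 1.26, 1.26)
    seed: int = 0
    label_plan: dict = field(
        default_factory=lambda: {
            "contact": "contact_neurocranium",
            "muscles": ("levator_externus_4", "levator_posterior", "retractor_dorsalis"),
        }
    )

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "jaw"):
            raise ValueError(f"kind must be 'bar' or 'jaw', got {self.kind!r}")
        if min(self.lobe_size) <= 0 or min(self.bridge_size) <= 0:
            raise ValueError("dimensions must be positive")
        if min(self.growth_factor) <= 0:
            raise ValueError("growth_factor components must be positive")
        if self.resolution < 2:
            raise ValueError(
                "resolution too coarse to realize the bridge "
                "(fewer than 2 elements across)"
            )


# ---------------------------------------------------------------------------
# structured meshing primitives
# ---------------------------------------------------------------------------

def _grid_mesh(active, origin, h):
    """Tetrahedralize the active cells of a structured grid.

    ``active`` is a boolean (nx, ny, nz) cell mask; each active cell is
    split into six Kuhn tetrahedra sharing the (0,0,0)-(1,1,1) diagonal,
    which is conforming across neighbouring cells.  Returns node
    coordinates, tets, and the per-tet cell index triple for labelling.
    """
    active = np.asarray(active, dtype=bool)
    nx, ny, nz = active.shape
    node_id = -np.ones((nx + 1, ny + 1, nz + 1), dtype=np.int64)
    cells = np.argwhere(active)
    # activate the 8 grid corners of every active cell, in lexicographic order
    for dx, dy, dz in itertools.product((0, 1), repeat=3):
        node_id[cells[:, 0] + dx, cells[:, 1] + dy, cells[:, 2] + dz] = 0
    used = np.argwhere(node_id == 0)
    node_id[used[:, 0], used[:, 1], used[:, 2]] = np.arange(len(used))
    coords = np.asarray(origin, dtype=float) + used * np.asarray(h, dtype=float)

    tets = []
    owner = []
    for cx, cy, cz in cells:
        corner = np.array([cx, cy, cz])

        def nid(offset):
            i, j, k = corner + offset
            return node_id[i, j, k]

        for p in _PERMS:
            e0 = np.zeros(3, dtype=int)
            e1 = e0.copy()
            e1[p[0]] = 1
            e2 = e1.copy()
            e2[p[1]] = 1
            conn = [nid(e0), nid(e1), nid(e2), nid(np.ones(3, dtype=int))]
            if _perm_sign(p) < 0:
                conn[1], conn[2] = conn[2], conn[1]
            tets.append(conn)
            owner.append((cx, cy, cz))
    return coords, np.array(tets, dtype=np.int64), np.array(owner, dtype=np.int64)


def _select_nodes(coords, lo, hi, tol):
    """Nodes inside an axis-aligned box, inclusive within tolerance."""
    lo = np.asarray(lo, dtype=float) - tol
    hi = np.asarray(hi, dtype=float) + tol
    mask = np.all((coords >= lo) & (coords <= hi), axis=1)
    return np.nonzero(mask)[0]


def _mirror_x(mesh: TetMesh, tol: float) -> tuple[TetMesh, np.ndarray]:
    """Append the reflection of a right-half mesh across x = 0.

    Midplane nodes (|x| <= tol) are shared, so the result is conforming
    and exactly mirror-symmetric element by element.  Returns the merged
    mesh and the node map right-index -> mirrored-index.
    """
    coords = mesh.node_coords
    n = len(coords)
    is_mid = np.abs(coords[:, 0]) <= tol
    mirror_map = np.empty(n, dtype=np.int64)
    new_nodes = []
    for i in range(n):
        if is_mid[i]:
            mirror_map[i] = i
        else:
            mirror_map[i] = n + len(new_nodes)
            new_nodes.append([-coords[i, 0], coords[i, 1], coords[i, 2]])
    all_coords = np.vstack([coords, np.array(new_nodes)])
    # reflected connectivity needs one swap to restore positive orientation
    mirrored_tets = mirror_map[mesh.tets][:, [0, 2, 1, 3]]
    all_tets = np.vstack([mesh.tets, mirrored_tets])
    all_regions = np.concatenate([mesh.element_region, mesh.element_region])
    merged = TetMesh(all_coords, all_tets, all_regions, {})
    return merged, mirror_map


# ---------------------------------------------------------------------------
# bar phantom
# ---------------------------------------------------------------------------

def make_bar(length: float, cross_section: float, resolution: int) -> TetMesh:
    """Structured bar along +x with square cross-section.

    ``resolution`` is the number of element layers across the cross-section
    edge; the axial direction uses the same spacing.  Node sets
    ``fixed_end`` (x = 0) and ``load_end`` (x = length) cover the two end
    faces.
    """
    if length <= 0 or cross_section <= 0:
        raise ValueError("length and cross_section must be positive")
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    side = float(np.sqrt(cross_section))
    h = side / resolution
    nx = max(1, round(length / h))
    active = np.ones((nx, resolution, resolution), dtype=bool)
    coords, tets, _ = _grid_mesh(active, (0.0, 0.0, 0.0), (length / nx, h, h))
    tol = 1e-9 * max(length, side)
    mesh = TetMesh(coords, tets)
    mesh.node_sets["fixed_end"] = _select_nodes(
        coords, (0, 0, 0), (0, side, side), tol
    )
    mesh.node_sets["load_end"] = _select_nodes(
        coords, (length, 0, 0), (length, side, side), tol
    )
    return mesh


# ---------------------------------------------------------------------------
# jaw phantom
# ---------------------------------------------------------------------------

def make_jaw_phantom(spec: PhantomSpec | None = None):
    """Paired-lobe jaw phantom and its muscle configuration.

    Returns ``(mesh, muscles)``.  Geometry (canonical frame: +x lateral
    right, +y rostral, +z dorsal):

    * two lobes spanning ``x in [+-(bw/2), +-(bw/2 + Lx)]``;
    * a midline bridge of cross-section ``bridge_size[1] x bridge_size[2]``
      whose dorsal surface is flush with the lobe tops and carries the
      ``contact_neurocranium`` node set;
    * tooth-cap elements (region 2) on the ventral face of each lobe;
    * three bilateral muscles with insertion patches on the lateral,
      caudal and dorso-caudal lobe surfaces and explicit dorsal origin
      points, giving a rostral-pulling adductor pair and a strongly
      caudal retractor pair (the default reduction pair).
    """
    spec = spec or PhantomSpec()
    if spec.kind != "jaw":
        raise ValueError("make_jaw_phantom requires a spec with kind='jaw'")
    Lx, Ly, Lz = spec.lobe_size
    Bx, By, Bz = spec.bridge_size
    if By >= Ly or Bz >= Lz:
        raise ValueError("bridge must be smaller than the lobe cross-section")
    h = Bz / spec.resolution

    def n_of(extent):
        return max(1, round(extent / h))

    bx = max(1, round((Bx / 2) / h))  # bridge half-width in cells
    lx, ny, nz = n_of(Lx), n_of(Ly), n_of(Lz)
    by, bz = max(1, round(By / h)), spec.resolution
    # y-centred bridge, dorsal surface flush with the lobe top
    y0 = (ny - by) // 2
    nx_half = bx + lx
    active = np.zeros((nx_half, ny, nz), dtype=bool)
    active[bx:, :, :] = True  # lobe
    active[:bx, y0 : y0 + by, nz - bz :] = True  # bridge half

    coords, tets, owner = _grid_mesh(active, (0.0, 0.0, 0.0), (h, h, h))
    # tooth caps: ventral lobe cells in a rostro-medial box (region 2)
    cx, cy, cz = owner.T
    tooth = (
        (cx >= bx)
        & (cx < bx + max(1, lx // 3))
        & (cy >= ny - max(1, ny // 3))
        & (cz < max(1, nz // 8) + 1)
    )
    regions = np.where(tooth, 2, 1).astype(np.int64)

    half = TetMesh(coords, tets, regions, {})
    mesh, mirror_map = _mirror_x(half, tol=1e-12)

    tol = 1e-9 * max(Lx + Bx, Ly, Lz)
    X1 = nx_half * h  # lateral extent of the half model
    Ytop, Ztop = ny * h, nz * h

    def both_sides(right_nodes):
        return np.union1d(right_nodes, mirror_map[right_nodes])

    sets: dict[str, np.ndarray] = {}
    # dorsal contact patch: top surface of the bridge (both sides of midline)
    contact_r = _select_nodes(
        half.node_coords, (0, y0 * h, Ztop), (bx * h, (y0 + by) * h, Ztop), tol
    )
    sets[spec.label_plan["contact"]] = both_sides(contact_r)

    le4, lp, rd = spec.label_plan["muscles"]
    patches = {
        # lateral face of the lobe, ventral half, rostral-leaning
        le4: ((X1, 0.25 * Ytop, 0.0), (X1, 0.65 * Ytop, 0.5 * Lz)),
        # caudal face of the lobe (caudal = -y, so the y = 0 face), ventral band
        lp: ((bx * h, 0.0, 0.0), (X1, 0.0, 0.6 * Lz)),
        # caudal strip of the lobe's dorsal surface
        rd: ((0.55 * X1, 0.0, Ztop), (X1, 0.35 * Ytop, Ztop)),
    }

    for name, (lo, hi) in patches.items():
        right = _select_nodes(half.node_coords, lo, hi, tol)
        if len(right) == 0:
            raise ValueError(f"insertion patch {name!r} selected no nodes")
        sets[f"insertion_{name}_right"] = right
        sets[f"insertion_{name}_left"] = mirror_map[right]
    mesh.node_sets = sets
    # re-run index checks / sorting through the constructor
    mesh = TetMesh(mesh.node_coords, mesh.tets, mesh.element_region, sets)

    # origin points: dorsal to the jaw (toward the neurocranium), chosen so
    # the adductor pair pulls slightly rostral and the retractor strongly
    # caudal -- the condition under which removing anterior-posterior
    # sliding is a genuine reduction of the retractor pair
    origins = {
        le4: (X1 + 0.5 * Lx, 0.75 * Ytop, Ztop + 1.5 * Lz),
        lp: (0.7 * X1, -0.25 * Ytop, Ztop + 1.25 * Lz),
        rd: (0.8 * X1, -1.2 * Ytop, Ztop + 0.5 * Lz),
    }
    pcsa = {le4: 0.020, lp: 0.016, rd: 0.012}  # mm^2 placeholders
    muscles = []
    for name in (le4, lp, rd):
        ox, oy, oz = origins[name]
        for side, sx in (("right", 1.0), ("left", -1.0)):
            muscles.append(
                MuscleDefinition(
                    name=name,
                    side=side,
                    insertion_set=f"insertion_{name}_{side}",
                    origin_point=(sx * ox, oy, oz),
                    pcsa=pcsa[name],
                )
            )
    return mesh, muscles


# ---------------------------------------------------------------------------
# growth series
# ---------------------------------------------------------------------------

def make_growth_series(
    spec: PhantomSpec | None = None,
    stages: int = 3,
    anisotropy: list[tuple[float, float, float]] | None = None,
):
    """Ontogenetic series of scaled jaw phantoms.

    Stage k applies the cumulative per-axis product of the stage scale
    factors (``spec.growth_factor`` for every step unless ``anisotropy``
    gives per-stage triples) to node coordinates and muscle origin points.
    PCSA scales with the muscle cross-section, taken transverse to the
    dominant dorso-ventral pull: factor fx * fy per step.
    """
    spec = spec or PhantomSpec()
    if stages < 2:
        raise ValueError("a growth series needs at least 2 stages")
    steps = anisotropy if anisotropy is not None else [spec.growth_factor] * (stages - 1)
    if len(steps) != stages - 1:
        raise ValueError(f"need {stages - 1} scale triples, got {len(steps)}")
    for f in steps:
        if min(f) <= 0:
            raise ValueError("scale factors must be positive")

    base_mesh, base_muscles = make_jaw_phantom(spec)
    series = [(base_mesh, base_muscles)]
    cum = np.ones(3)
    for f in steps:
        cum = cum * np.asarray(f, dtype=float)
        mesh_k = base_mesh.scaled(cum)
        area = cum[0] * cum[1]
        muscles_k = [
            replace(
                m,
                origin_point=tuple(np.asarray(m.origin_point) * cum),
                pcsa=m.pcsa * area,
            )
            for m in base_muscles
        ]
        series.append((mesh_k, muscles_k))
    return series
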