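"""Labeled tetrahedral meshes: data model, validation and geometric queries.

A :class:`TetMesh` is the geometric substrate for the whole package: node
coordinates in millimetres, 4-node tetrahedra (TET4), an integer region tag
per element (e.g. bone vs tooth material regions), and named node sets that
anchor boundary conditions and muscle attachments ("contact_neurocranium",
"insertion_levator_externus_4_left", ...).

Conventions
-----------
* Units are fixed package-wide: mm, N, MPa (so N/mm^2 == MPa).
* Node and element indices are 0-based; format readers translate 1-based
  dialects on ingest.
* A tetrahedron (n0, n1, n2, n3) is canonically ordered when its signed
  volume det([p1-p0, p2-p0, p3-p0]) / 6 is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "TetMesh",
    "AnatomicalFrame",
    "MeshViolation",
    "validate_mesh",
    "element_volumes",
    "region_node_set",
    "boundary_facets",
]

#: Tolerance below which two nodes count as duplicates (mm).
DUPLICATE_NODE_TOL = 1e-9


@dataclass
class TetMesh:
    """Tetrahedral mesh with element region tags and named node sets.

    Parameters
    ----------
    node_coords
        ``(n_nodes, 3)`` float array of positions in mm.
    tets
        ``(n_elements, 4)`` integer array of node indices.
    element_region
        ``(n_elements,)`` integer tag per element.  Defaults to all-1.
    node_sets
        Mapping from set name to sorted integer node-index arrays.
    """

    node_coords: np.ndarray
    tets: np.ndarray
    element_region: np.ndarray | None = None
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_coords = np.ascontiguousarray(self.node_coords, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise ValueError("node_coords must have shape (n_nodes, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must have shape (n_elements, 4)")
        if self.element_region is None:
            self.element_region = np.ones(len(self.tets), dtype=np.int64)
        else:
            self.element_region = np.asarray(self.element_region, dtype=np.int64)
            if self.element_region.shape != (len(self.tets),):
                raise ValueError("element_region must have one tag per element")
        self.node_sets = {
            name: np.unique(np.asarray(idx, dtype=np.int64))
            for name, idx in self.node_sets.items()
        }
        n = self.n_nodes
        if len(self.tets) and (self.tets.min() < 0 or self.tets.max() >= n):
            raise IndexError("tet connectivity references node out of range")
        for name, idx in self.node_sets.items():
            if len(idx) and (idx.min() < 0 or idx.max() >= n):
                raise IndexError(f"node set {name!r} references node out of range")

    # -- basic queries ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.tets.shape[0]

    def region_tags(self) -> np.ndarray:
        """Distinct element region tags, sorted."""
        return np.unique(self.element_region)

    def node_set(self, name: str) -> np.ndarray:
        if name not in self.node_sets:
            raise KeyError(
                f"unknown node set {name!r}; available: {sorted(self.node_sets)}"
            )
        return self.node_sets[name]

    def copy(self) -> "TetMesh":
        return TetMesh(
            self.node_coords.copy(),
            self.tets.copy(),
            self.element_region.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
        )

    def scaled(self, factors: Iterable[float]) -> "TetMesh":
        """Return a copy with per-axis scaled coordinates (growth model)."""
        f = np.asarray(tuple(factors), dtype=float)
        if f.shape != (3,) or np.any(f <= 0):
            raise ValueError("scale factors must be three positive numbers")
        out = self.copy()
        out.node_coords = out.node_coords * f
        return out


@dataclass(frozen=True)
class AnatomicalFrame:
    """Orthonormal anatomical axes used for muscle orientation angles.

    The canonical frame is +x = lateral-right, +y = rostral, +z = dorsal.
    Left-side structures use -x as their outward lateral direction, so
    mirroring a muscle across the midsagittal plane leaves its angle triple
    unchanged.
    """

    lateral_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    rostral_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    dorsal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        m = np.array([self.lateral_axis, self.rostral_axis, self.dorsal_axis])
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-12):
            raise ValueError("frame axes must be orthonormal")

    def components(self, direction: np.ndarray, side: str) -> tuple[float, float, float]:
        """Project ``direction`` onto (outward-lateral, rostral, dorsal) axes.

        ``side`` is "left", "right" or "median"; for left-side structures
        the outward lateral direction is the negated lateral axis.  Median
        structures use the right convention.
        """
        if side not in ("left", "right", "median"):
            raise ValueError(f"side must be left/right/median, got {side!r}")
        d = np.asarray(direction, dtype=float)
        lat = float(d @ np.asarray(self.lateral_axis))
        if side == "left":
            lat = -lat
        ros = float(d @ np.asarray(self.rostral_axis))
        dor = float(d @ np.asarray(self.dorsal_axis))
        return lat, ros, dor


@dataclass(frozen=True)
class MeshViolation:
    """One itemised validation finding."""

    kind: str  # "inverted_element" | "duplicate_nodes" | "open_surface" | ...
    indices: tuple[int, ...]
    detail: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind} {self.indices}: {self.detail}"


def element_volumes(mesh: TetMesh, *, signed: bool = False) -> np.ndarray:
    """Per-element tetrahedron volume in mm^3.

    Volume of element (n0..n3) is det([p1-p0, p2-p0, p3-p0]) / 6; the
    absolute value is returned unless ``signed`` is requested (validation
    uses the sign to detect inverted elements).
    """
    p = mesh.node_coords[mesh.tets]  # (m, 4, 3)
    e = p[:, 1:] - p[:, :1]  # (m, 3, 3) edge matrix
    vol = np.linalg.det(e) / 6.0
    return vol if signed else np.abs(vol)


def boundary_facets(mesh: TetMesh) -> np.ndarray:
    """Outward-oriented boundary triangles (facets owned by exactly one tet).

    Each TET4 contributes four triangular facets; interior facets appear in
    two elements with opposite orientation, boundary facets in exactly one.
    Returned triangles keep the owning tet's outward orientation.
    """
    t = mesh.tets
    # facet opposite node i, ordered so the normal points out of the tet
    faces = np.concatenate(
        [
            t[:, [1, 2, 3]],
            t[:, [0, 3, 2]],
            t[:, [0, 1, 3]],
            t[:, [0, 2, 1]],
        ]
    )
    key = np.sort(faces, axis=1)
    _, inverse, counts = np.unique(
        key, axis=0, return_inverse=True, return_counts=True
    )
    return faces[counts[inverse] == 1]


def facet_incidence_counts(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Unique (sorted) facets and how many tets own each; oracle-friendly."""
    t = mesh.tets
    faces = np.concatenate(
        [t[:, [1, 2, 3]], t[:, [0, 2, 3]], t[:, [0, 1, 3]], t[:, [0, 1, 2]]]
    )
    uniq, counts = np.unique(np.sort(faces, axis=1), axis=0, return_counts=True)
    return uniq, counts


def validate_mesh(mesh: TetMesh, *, watertight: bool = True) -> list[MeshViolation]:
    """Report (never repair) violations of the mesh invariants.

    Checks: inverted/degenerate elements under the canonical ordering,
    duplicate nodes within :data:`DUPLICATE_NODE_TOL`, facets owned by more
    than two tets, and — when ``watertight`` — an open boundary surface
    (every boundary edge must be shared by exactly two boundary facets).
    """
    report: list[MeshViolation] = []

    vol = element_volumes(mesh, signed=True)
    for e in np.nonzero(vol <= 0)[0]:
        report.append(
            MeshViolation(
                "inverted_element",
                (int(e),),
                f"signed volume {vol[e]:.3e} mm^3 is not positive",
            )
        )

    # duplicate nodes within tolerance: grid hashing to avoid O(n^2)
    coords = mesh.node_coords
    if len(coords) > 1:
        rounded = np.round(coords / max(DUPLICATE_NODE_TOL, 1e-300)).astype(np.int64)
        _, inv, counts = np.unique(rounded, axis=0, return_inverse=True, return_counts=True)
        for g in np.nonzero(counts > 1)[0]:
            members = np.nonzero(inv == g)[0]
            d = np.linalg.norm(coords[members] - coords[members[0]], axis=1)
            if np.all(d <= DUPLICATE_NODE_TOL * 10):
                report.append(
                    MeshViolation(
                        "duplicate_nodes",
                        tuple(int(m) for m in members),
                        "coincident nodes within tolerance",
                    )
                )

    uniq, counts = facet_incidence_counts(mesh)
    over = np.nonzero(counts > 2)[0]
    for f in over:
        report.append(
            MeshViolation(
                "non_manifold_facet",
                tuple(int(i) for i in uniq[f]),
                f"facet owned by {counts[f]} tets",
            )
        )

    if watertight:
        surf = uniq[counts == 1]
        if len(surf):
            edges = np.concatenate(
                [surf[:, [0, 1]], surf[:, [1, 2]], surf[:, [0, 2]]]
            )
            ekey, ecount = np.unique(np.sort(edges, axis=1), axis=0, return_counts=True)
            open_edges = ekey[ecount != 2]
            for edge in open_edges:
                report.append(
                    MeshViolation(
                        "open_surface",
                        tuple(int(i) for i in edge),
                        "boundary edge not shared by exactly two surface facets",
                    )
                )
    return report


def region_node_set(mesh: TetMesh, tag_or_name: int | str) -> np.ndarray:
    """Nodes of an element region tag (int) or a named node set (str).

    The returned index array is sorted, hence deterministic.
    """
    if isinstance(tag_or_name, str):
        return mesh.node_set(tag_or_name)
    tag = int(tag_or_name)
    sel = mesh.element_region == tag
    if not np.any(sel):
        raise KeyError(f"unknown region tag {tag}")
    return np.unique(mesh.tets[sel])


def surface_node_ring(mesh: TetMesh, seed_nodes: np.ndarray, rings: int = 1) -> np.ndarray:
    """Expand a node set by ``rings`` of element adjacency.

    Used to mask out elements near load application / contact patches when
    hunting for stress hotspots.
    """
    nodes = np.unique(np.asarray(seed_nodes, dtype=np.int64))
    for _ in range(rings):
        touching = np.any(np.isin(mesh.tets, nodes), axis=1)
        nodes = np.union1d(nodes, np.unique(mesh.tets[touching]))
    return nodes


def elements_touching(mesh: TetMesh, nodes: np.ndarray) -> np.ndarray:
    """Indices of elements with at least one node in ``nodes``."""
    return np.nonzero(np.any(np.isin(mesh.tets, np.asarray(nodes)), axis=1))[0]
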