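"""Linear-static finite-element solver for 4-node tetrahedra.

Solves the equilibrium system K d = P for an isotropic linear-elastic body
meshed with constant-strain tetrahedra (TET4), under nodal point loads and
fixed (or prescribed) nodal displacements.  Constraints are applied by
reduction — fixed degrees of freedom are eliminated from the system — which
makes the recovered reaction forces exact: at a fixed freedom the reaction
is (K d) - P.

TET4 elements are the simplest volume element and are known to be somewhat
over-stiff in bending; all quantities this package compares are computed
within the same discretisation, so relative comparisons across load cases
and growth stages are unaffected by that bias.

Units: mm, N, MPa throughout (E in MPa, forces in N, displacements in mm,
stresses in MPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh, element_volumes

__all__ = [
    "ElasticMaterial",
    "ConstraintSet",
    "LoadCase",
    "SolutionField",
    "StressField",
    "element_stiffness",
    "assemble_global",
    "solve_linear_static",
    "recover_stresses",
    "reaction_resultant",
]

#: Above this number of free degrees of freedom the solver switches from a
#: direct sparse factorisation to a preconditioned conjugate gradient.
DIRECT_SOLVER_DOF_LIMIT = 300_000

# Default material table: larval fish bone at the low end of the published
# 3.67-8.40 GPa range, enamel-capped teeth at 70 GPa, Poisson 0.3 for both.
DEFAULT_BONE = ("bone", 3670.0, 0.3)
DEFAULT_TOOTH = ("tooth", 70000.0, 0.3)


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material assigned to element region tags."""

    name: str
    youngs_modulus: float  # MPa
    poisson_ratio: float
    region_tags: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not (self.youngs_modulus > 0):
            raise ValueError(f"{self.name}: Young's modulus must be > 0")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError(f"{self.name}: Poisson ratio must be in [0, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """6x6 isotropic elasticity matrix in Voigt order (xx,yy,zz,xy,yz,zx)."""
        E, nu = self.youngs_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.arange(3), np.arange(3)] = lam + 2 * mu
        D[np.arange(3, 6), np.arange(3, 6)] = mu
        return D


def default_materials() -> list[ElasticMaterial]:
    """Bone on region 1, tooth on region 2."""
    return [
        ElasticMaterial(DEFAULT_BONE[0], DEFAULT_BONE[1], DEFAULT_BONE[2], (1,)),
        ElasticMaterial(DEFAULT_TOOTH[0], DEFAULT_TOOTH[1], DEFAULT_TOOTH[2], (2,)),
    ]


@dataclass
class ConstraintSet:
    """Fixed nodes (all three translations) with optional prescribed values.

    ``values`` defaults to zero displacement; a (n_fixed, 3) array drives
    non-homogeneous boundary conditions such as a patch-test displacement
    field.
    """

    fixed_nodes: np.ndarray
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fixed_nodes = np.unique(np.asarray(self.fixed_nodes, dtype=np.int64))
        if len(self.fixed_nodes) == 0:
            raise ValueError("ConstraintSet needs at least one fixed node")
        if self.values is not None:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (len(self.fixed_nodes), 3):
                raise ValueError("values must be (n_fixed, 3), ordered like fixed_nodes")


@dataclass
class LoadCase:
    """Nodal point loads, typically summed over contributing muscle loads."""

    name: str
    nodal_loads: dict[int, np.ndarray] = field(default_factory=dict)

    def add(self, nodes: np.ndarray, forces: np.ndarray) -> "LoadCase":
        for n, f in zip(np.asarray(nodes), np.asarray(forces, dtype=float)):
            key = int(n)
            if key in self.nodal_loads:
                self.nodal_loads[key] = self.nodal_loads[key] + f
            else:
                self.nodal_loads[key] = np.array(f, dtype=float)
        return self

    def add_muscle_load(self, load) -> "LoadCase":
        return self.add(load.insertion_nodes, load.nodal_forces)

    def vector(self, n_nodes: int) -> np.ndarray:
        """Assemble the global load vector P (3 * n_nodes)."""
        P = np.zeros(3 * n_nodes)
        for n, f in self.nodal_loads.items():
            P[3 * n : 3 * n + 3] += f
        return P

    def total(self) -> np.ndarray:
        if not self.nodal_loads:
            return np.zeros(3)
        return np.sum(list(self.nodal_loads.values()), axis=0)

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(
            self.name,
            {n: f * factor for n, f in self.nodal_loads.items()},
        )

    @staticmethod
    def combine(name: str, *cases: "LoadCase") -> "LoadCase":
        out = LoadCase(name)
        for case in cases:
            for n, f in case.nodal_loads.items():
                out.add(np.array([n]), np.array([f]))
        return out

    @staticmethod
    def from_muscle_loads(name: str, loads) -> "LoadCase":
        case = LoadCase(name)
        for ld in loads:
            case.add_muscle_load(ld)
        return case


@dataclass
class SolutionField:
    """Displacements everywhere plus reactions at the fixed nodes."""

    displacements: np.ndarray  # (n_nodes, 3) mm
    fixed_nodes: np.ndarray
    reactions: np.ndarray  # (n_fixed, 3) N, ordered like fixed_nodes
    residual: float  # relative residual of the reduced solve

    def reaction_at(self, nodes: np.ndarray) -> np.ndarray:
        """Reactions for a subset of fixed nodes (order of ``nodes``)."""
        pos = {int(n): k for k, n in enumerate(self.fixed_nodes)}
        try:
            rows = [pos[int(n)] for n in np.asarray(nodes)]
        except KeyError as err:
            raise ValueError(f"node {err} is not constrained") from None
        return self.reactions[rows]


@dataclass
class StressField:
    """Per-element constant stress state recovered from a solution."""

    tensors: np.ndarray  # (m, 3, 3) MPa, symmetric
    von_mises: np.ndarray  # (m,) MPa
    principal_values: np.ndarray  # (m, 3) MPa, sorted descending
    principal_directions: np.ndarray  # (m, 3, 3), columns are directions


# ---------------------------------------------------------------------------
# element level
# ---------------------------------------------------------------------------

def _shape_gradients(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Constant shape-function gradients and volume of one TET4.

    The four linear shape functions N_i satisfy N_i(x_j) = delta_ij; their
    (constant) gradients are rows 1..3 of the inverse of the 4x4 matrix
    [[1, x_i, y_i, z_i]].
    """
    C = np.hstack([np.ones((4, 1)), coords])
    detC = np.linalg.det(C)
    volume = detC / 6.0
    if volume <= 0:
        raise ValueError(f"inverted or degenerate element (volume {volume:.3e})")
    grads = np.linalg.inv(C)[1:4, :].T  # (4, 3): row i = grad N_i
    return grads, volume


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """6x12 strain-displacement matrix (Voigt order xx,yy,zz,xy,yz,zx)."""
    B = np.zeros((6, 12))
    for i in range(4):
        bx, by, bz = grads[i]
        c = 3 * i
        B[0, c] = bx
        B[1, c + 1] = by
        B[2, c + 2] = bz
        B[3, c] = by
        B[3, c + 1] = bx
        B[4, c + 1] = bz
        B[4, c + 2] = by
        B[5, c] = bz
        B[5, c + 2] = bx
    return B


def element_stiffness(coords: np.ndarray, material: ElasticMaterial) -> np.ndarray:
    """12x12 TET4 stiffness K_e = V * B^T D B (constant-strain element)."""
    grads, volume = _shape_gradients(np.asarray(coords, dtype=float))
    B = _b_matrix(grads)
    D = material.d_matrix()
    return volume * (B.T @ D @ B)


# ---------------------------------------------------------------------------
# global level
# ---------------------------------------------------------------------------

def _material_per_element(mesh: TetMesh, materials) -> list[ElasticMaterial]:
    table: dict[int, ElasticMaterial] = {}
    for mat in materials:
        for tag in mat.region_tags:
            if tag in table:
                raise ValueError(
                    f"region tag {tag} covered by both {table[tag].name!r} and {mat.name!r}"
                )
            table[int(tag)] = mat
    per_elem = []
    for tag in mesh.element_region:
        if int(tag) not in table:
            raise ValueError(f"no material assigned to region tag {int(tag)}")
        per_elem.append(table[int(tag)])
    return per_elem


def _batch_gradients(mesh: TetMesh, elems: np.ndarray):
    """Vectorised shape gradients: (k, 4, 3) grads and (k,) volumes."""
    p = mesh.node_coords[mesh.tets[elems]]  # (k, 4, 3)
    C = np.concatenate([np.ones((len(elems), 4, 1)), p], axis=2)
    vol = np.linalg.det(C) / 6.0
    bad = np.nonzero(vol <= 0)[0]
    if len(bad):
        raise ValueError(
            f"inverted or degenerate element(s) {elems[bad[:5]].tolist()}"
        )
    grads = np.linalg.inv(C)[:, 1:4, :].transpose(0, 2, 1)  # (k, 4, 3)
    return grads, vol


def _batch_b(grads: np.ndarray) -> np.ndarray:
    """Vectorised 6x12 strain-displacement matrices, (k, 6, 12)."""
    k = grads.shape[0]
    B = np.zeros((k, 6, 12))
    for i in range(4):
        bx, by, bz = grads[:, i, 0], grads[:, i, 1], grads[:, i, 2]
        c = 3 * i
        B[:, 0, c] = bx
        B[:, 1, c + 1] = by
        B[:, 2, c + 2] = bz
        B[:, 3, c] = by
        B[:, 3, c + 1] = bx
        B[:, 4, c + 1] = bz
        B[:, 4, c + 2] = by
        B[:, 5, c] = bz
        B[:, 5, c + 2] = bx
    return B


def assemble_global(mesh: TetMesh, materials) -> sp.csr_matrix:
    """Scatter-add element stiffness matrices into the 3N x 3N global K.

    Elements are processed in batches grouped by material, so each batch
    shares one elasticity matrix D and K_e = V B^T D B is one einsum.
    """
    per_elem = _material_per_element(mesh, materials)
    m = mesh.n_elements
    mat_id = np.array([id(mat) for mat in per_elem])
    rows = np.empty(144 * m, dtype=np.int64)
    cols = np.empty(144 * m, dtype=np.int64)
    vals = np.empty(144 * m)
    dofs = (3 * mesh.tets[:, :, None] + np.arange(3)).reshape(m, 12)
    for mid in np.unique(mat_id):
        elems = np.nonzero(mat_id == mid)[0]
        D = per_elem[elems[0]].d_matrix()
        grads, vol = _batch_gradients(mesh, elems)
        B = _batch_b(grads)
        Ke = np.einsum("kia,ij,kjb,k->kab", B, D, B, vol, optimize=True)
        d = dofs[elems]
        rr = np.repeat(d, 12, axis=1)  # (k, 144) row index pattern
        cc = np.tile(d, (1, 12))
        pos = (144 * elems[:, None] + np.arange(144)).ravel()
        rows[pos] = rr.ravel()
        cols[pos] = cc.ravel()
        vals[pos] = Ke.reshape(len(elems), 144).ravel()
    n3 = 3 * mesh.n_nodes
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n3, n3)).tocsr()
    return K


def solve_linear_static(
    K: sp.spmatrix,
    loads: LoadCase,
    constraints: ConstraintSet,
    *,
    rtol: float = 1e-10,
) -> SolutionField:
    """Solve K d = P with fixed/prescribed freedoms eliminated.

    Uses a direct sparse factorisation up to
    :data:`DIRECT_SOLVER_DOF_LIMIT` free freedoms and conjugate gradients
    with a Jacobi preconditioner beyond.  Raises if the reduced system is
    singular (insufficient constraints) or loads are non-finite.
    """
    n3 = K.shape[0]
    n_nodes = n3 // 3
    P = loads.vector(n_nodes)
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite nodal loads")

    fixed = constraints.fixed_nodes
    fixed_dofs = (3 * fixed[:, None] + np.arange(3)).ravel()
    free_mask = np.ones(n3, dtype=bool)
    free_mask[fixed_dofs] = False
    free_dofs = np.nonzero(free_mask)[0]

    u = np.zeros(n3)
    if constraints.values is not None:
        u[fixed_dofs] = constraints.values.ravel()

    K = K.tocsr()
    K_ff = K[free_dofs][:, free_dofs]
    rhs = P[free_dofs] - K[free_dofs][:, fixed_dofs] @ u[fixed_dofs]

    if len(free_dofs):
        if len(free_dofs) <= DIRECT_SOLVER_DOF_LIMIT:
            try:
                lu = spla.splu(K_ff.tocsc())
                u_f = lu.solve(rhs)
            except RuntimeError as err:
                raise np.linalg.LinAlgError(
                    f"singular reduced system (insufficient constraints?): {err}"
                ) from None
        else:
            diag = K_ff.diagonal()
            M = sp.diags(np.where(diag > 0, 1.0 / diag, 1.0))
            u_f, info = spla.cg(K_ff, rhs, M=M, rtol=rtol, maxiter=20_000)
            if info != 0:
                raise np.linalg.LinAlgError(f"CG failed to converge (info={info})")
        if not np.all(np.isfinite(u_f)):
            raise np.linalg.LinAlgError("singular reduced system (non-finite solution)")
        u[free_dofs] = u_f
        ref = np.linalg.norm(rhs)
        residual = float(np.linalg.norm(K_ff @ u_f - rhs) / (ref if ref > 0 else 1.0))
        if residual > 1e-8:
            raise np.linalg.LinAlgError(
                f"solver residual {residual:.2e} exceeds 1e-8"
            )
    else:
        residual = 0.0

    # exact reactions at fixed freedoms: (K u) - applied loads
    reactions = (K[fixed_dofs] @ u - P[fixed_dofs]).reshape(-1, 3)
    return SolutionField(
        displacements=u.reshape(-1, 3),
        fixed_nodes=fixed,
        reactions=reactions,
        residual=residual,
    )


def recover_stresses(mesh: TetMesh, materials, solution: SolutionField) -> StressField:
    """Per-element constant stress, von Mises and principal decomposition.

    Strain is the (constant) symmetric displacement gradient of each TET4;
    stress follows from the isotropic elasticity matrix; von Mises is the
    deviatoric invariant sqrt(3 J2); principal values/directions come from
    a symmetric eigensolve, sorted descending.
    """
    if solution.displacements.shape != (mesh.n_nodes, 3):
        raise ValueError("solution does not match mesh")
    per_elem = _material_per_element(mesh, materials)
    m = mesh.n_elements
    mat_id = np.array([id(mat) for mat in per_elem])
    tensors = np.empty((m, 3, 3))
    u = solution.displacements
    for mid in np.unique(mat_id):
        elems = np.nonzero(mat_id == mid)[0]
        D = per_elem[elems[0]].d_matrix()
        grads, _ = _batch_gradients(mesh, elems)
        B = _batch_b(grads)
        u_e = u[mesh.tets[elems]].reshape(len(elems), 12)
        voigt = np.einsum("ij,kja,ka->ki", D, B, u_e)  # (k, 6)
        sxx, syy, szz, sxy, syz, szx = voigt.T
        tensors[elems, 0, 0] = sxx
        tensors[elems, 1, 1] = syy
        tensors[elems, 2, 2] = szz
        tensors[elems, 0, 1] = tensors[elems, 1, 0] = sxy
        tensors[elems, 1, 2] = tensors[elems, 2, 1] = syz
        tensors[elems, 0, 2] = tensors[elems, 2, 0] = szx
    s = tensors
    vm = np.sqrt(
        0.5
        * (
            (s[:, 0, 0] - s[:, 1, 1]) ** 2
            + (s[:, 1, 1] - s[:, 2, 2]) ** 2
            + (s[:, 2, 2] - s[:, 0, 0]) ** 2
        )
        + 3.0 * (s[:, 0, 1] ** 2 + s[:, 1, 2] ** 2 + s[:, 0, 2] ** 2)
    )
    evals, evecs = np.linalg.eigh(tensors)  # ascending
    order = np.argsort(evals, axis=1)[:, ::-1]
    principal = np.take_along_axis(evals, order, axis=1)
    directions = np.stack(
        [np.take_along_axis(evecs[k], order[k][None, :], axis=1) for k in range(m)]
    )
    return StressField(tensors, vm, principal, directions)


def reaction_resultant(
    solution: SolutionField,
    subset: np.ndarray,
    direction: np.ndarray | None = None,
):
    """Vector sum of reactions over ``subset`` of the fixed nodes.

    With ``direction`` given (a unit vector), returns the signed scalar
    component along it instead.
    """
    total = solution.reaction_at(subset).sum(axis=0)
    if direction is None:
        return total
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return float(total @ d)


def area_consistent_load(
    mesh: TetMesh,
    set_name: str,
    total_force: np.ndarray,
    *,
    name: str | None = None,
) -> LoadCase:
    """Nodal loads equivalent to a uniform traction on a boundary patch.

    For linear (TET4) elements the consistent load of a uniform surface
    traction gives each node one third of the area of every adjacent
    boundary facet; the per-node weights are those area sums, normalised so
    the vector total equals ``total_force``.  This is the loading under
    which uniform-stress closed forms (e.g. the axial bar) are reproduced
    exactly, in contrast to the equal-split distribution used for muscle
    attachments.
    """
    from .mesh import boundary_facets

    nodes = mesh.node_set(set_name)
    member = np.zeros(mesh.n_nodes, dtype=bool)
    member[nodes] = True
    faces = boundary_facets(mesh)
    faces = faces[np.all(member[faces], axis=1)]
    if len(faces) == 0:
        raise ValueError(f"node set {set_name!r} contains no boundary facets")
    p = mesh.node_coords[faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )
    weights = np.zeros(mesh.n_nodes)
    np.add.at(weights, faces.ravel(), np.repeat(areas / 3.0, 3))
    w = weights[nodes]
    w = w / w.sum()
    forces = w[:, None] * np.asarray(total_force, dtype=float)
    return LoadCase(name or f"traction_{set_name}").add(nodes, forces)
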