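"""Element stiffness, assembly, linear-static solve and stress recovery."""

import numpy as np
import pytest

from devfea.fem import (
    ConstraintSet,
    ElasticMaterial,
    LoadCase,
    area_consistent_load,
    assemble_global,
    element_stiffness,
    reaction_resultant,
    recover_stresses,
    solve_linear_static,
)
from devfea.mesh import TetMesh, boundary_facets
from devfea.phantoms import make_bar

BONE = ElasticMaterial("bone", 3670.0, 0.3, (1,))
CANON = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def _sympy_stiffness_oracle(coords, E, nu):
    """Independent element stiffness via symbolic strain-energy integrals.

    Interpolates each unit nodal displacement with barycentric shape
    functions, forms the symmetric gradient symbolically, and integrates
    the elastic energy density over the tetrahedron — no B-matrix, no
    Voigt bookkeeping.
    """
    import sympy as sp

    x, y, z = sp.symbols("x y z")
    pts = [sp.Matrix(list(p)) for p in coords]
    # barycentric shape functions: solve N_i affine with N_i(x_j) = delta_ij
    A = sp.Matrix([[1, *p] for p in coords])
    shape = []
    for i in range(4):
        coeff = A.solve(sp.Matrix([1 if j == i else 0 for j in range(4)]))
        shape.append(coeff[0] + coeff[1] * x + coeff[2] * y + coeff[3] * z)
    lam = sp.Rational(1) * E * nu / ((1 + nu) * (1 - 2 * nu)) if nu else 0
    mu = sp.Rational(1) * E / (2 * (1 + nu))

    def strain(dof):
        node, comp = divmod(dof, 3)
        u = [0, 0, 0]
        u[comp] = shape[node]
        grad = sp.Matrix(
            [[sp.diff(u[a], v) for v in (x, y, z)] for a in range(3)]
        )
        return (grad + grad.T) / 2

    # integrate over the canonical region of this tet (affine map: constant
    # integrand, so energy = density * volume)
    vol = abs(sp.Matrix([[*(pts[i] - pts[0])] for i in range(1, 4)]).det()) / 6
    K = np.zeros((12, 12))
    eps = [strain(d) for d in range(12)]
    for a in range(12):
        for b in range(a, 12):
            dens = lam * eps[a].trace() * eps[b].trace() + 2 * mu * sum(
                eps[a][i, j] * eps[b][i, j] for i in range(3) for j in range(3)
            )
            K[a, b] = K[b, a] = float(sp.simplify(dens) * vol)
    return K


def test_element_stiffness_matches_energy_oracle():
    """K_e of the canonical simplex equals the symbolic energy integral."""
    K = element_stiffness(CANON, ElasticMaterial("unit", 1.0, 0.0, (1,)))
    K_oracle = _sympy_stiffness_oracle(CANON, 1, 0)
    assert np.abs(K - K_oracle).max() <= 1e-12


def test_element_stiffness_symmetry_and_rigid_modes():
    rng = np.random.default_rng(7)
    coords = CANON + rng.uniform(-0.2, 0.2, (4, 3))
    if np.linalg.det(np.hstack([np.ones((4, 1)), coords])) < 0:
        coords = coords[[1, 0, 2, 3]]
    K = element_stiffness(coords, BONE)
    assert np.abs(K - K.T).max() <= 1e-12 * np.abs(K).max()
    evals = np.linalg.eigvalsh(K)
    scale = evals.max()
    assert np.sum(np.abs(evals) <= 1e-10 * scale) == 6  # 6 rigid-body modes
    assert np.all(evals >= -1e-10 * scale)  # positive semi-definite
    # rigid translation stores no energy
    for comp in range(3):
        t = np.tile(np.eye(3)[comp], 4)
        assert np.abs(K @ t).max() <= 1e-10 * scale


def test_inverted_element_rejected():
    with pytest.raises(ValueError, match="inverted"):
        element_stiffness(CANON[[1, 0, 2, 3]], BONE)


def test_assembly_single_element_equals_element_matrix(single_tet):
    K = assemble_global(single_tet, [BONE]).toarray()
    Ke = element_stiffness(single_tet.node_coords, BONE)
    assert np.abs(K - Ke).max() <= 1e-12 * np.abs(Ke).max()


def test_assembly_disconnected_tets_block_diagonal():
    coords = np.vstack([CANON, CANON + 10.0])
    mesh = TetMesh(coords, np.array([[0, 1, 2, 3], [4, 5, 6, 7]]))
    K = assemble_global(mesh, [BONE]).toarray()
    assert np.abs(K[:12, 12:]).max() == 0.0
    assert np.abs(K[12:, :12]).max() == 0.0


def test_material_stiffness_ratio():
    """Identical geometry: tooth-material entries scale by E_tooth/E_bone."""
    tooth = ElasticMaterial("tooth", 70000.0, 0.3, (1,))
    Kb = element_stiffness(CANON, BONE)
    Kt = element_stiffness(CANON, tooth)
    assert np.allclose(Kt, (70000.0 / 3670.0) * Kb, rtol=1e-12)


def test_missing_and_overlapping_materials(single_tet):
    with pytest.raises(ValueError, match="no material"):
        assemble_global(single_tet, [ElasticMaterial("m", 1.0, 0.0, (2,))])
    with pytest.raises(ValueError, match="covered by both"):
        assemble_global(
            single_tet,
            [ElasticMaterial("a", 1.0, 0.0, (1,)), ElasticMaterial("b", 2.0, 0.0, (1,))],
        )


@pytest.fixture(scope="module")
def bar_case():
    """Uniaxial bar: L=10 mm, A=1 mm2, E=3670 MPa, nu=0, axial F=1 N."""
    mesh = make_bar(10.0, 1.0, 4)
    mat = ElasticMaterial("bone", 3670.0, 0.0, (1,))
    K = assemble_global(mesh, [mat])
    cons = ConstraintSet(mesh.node_set("fixed_end"))
    case = area_consistent_load(mesh, "load_end", np.array([1.0, 0, 0]))
    sol = solve_linear_static(K, case, cons)
    return mesh, mat, K, cons, case, sol


def test_bar_tip_displacement_closed_form(bar_case):
    """Tip displacement delta = FL/(EA) = 10/3670 mm."""
    mesh, _, _, _, _, sol = bar_case
    tip = sol.displacements[mesh.node_set("load_end"), 0].mean()
    assert tip == pytest.approx(10.0 / 3670.0, rel=1e-9)


def test_bar_uniform_stress(bar_case):
    """Every element: axial stress F/A = 1 MPa, von Mises 1 MPa."""
    mesh, mat, _, _, _, sol = bar_case
    st = recover_stresses(mesh, [mat], sol)
    assert st.tensors[:, 0, 0] == pytest.approx(np.ones(mesh.n_elements), rel=1e-8)
    assert st.von_mises == pytest.approx(np.ones(mesh.n_elements), rel=1e-8)


def test_bar_reaction_opposes_load(bar_case):
    mesh, _, _, _, case, sol = bar_case
    fixed = mesh.node_set("fixed_end")
    assert reaction_resultant(sol, fixed) == pytest.approx([-1.0, 0, 0], abs=1e-10)
    # projection on a direction equals the matching component
    dorsal = reaction_resultant(sol, fixed, np.array([0.0, 0, 1]))
    assert dorsal == pytest.approx(reaction_resultant(sol, fixed)[2], abs=1e-14)


def test_reaction_subset_must_be_constrained(bar_case):
    mesh, _, _, _, _, sol = bar_case
    with pytest.raises(ValueError, match="not constrained"):
        reaction_resultant(sol, mesh.node_set("load_end"))


def test_zero_loads_zero_solution(bar_case):
    _, _, K, cons, _, _ = bar_case
    sol = solve_linear_static(K, LoadCase("none"), cons)
    assert np.abs(sol.displacements).max() == 0.0
    assert np.abs(sol.reactions).max() == 0.0


def test_linearity_doubling_loads(bar_case):
    mesh, _, K, cons, case, sol = bar_case
    sol2 = solve_linear_static(K, case.scaled(2.0), cons)
    assert np.allclose(sol2.displacements, 2.0 * sol.displacements, rtol=0, atol=1e-14)


def test_global_equilibrium(bar_case):
    _, _, _, _, case, sol = bar_case
    net = case.total() + sol.reactions.sum(axis=0)
    assert np.linalg.norm(net) <= 1e-8 * np.linalg.norm(case.total())


def test_fixed_nodes_do_not_move(bar_case):
    mesh, _, _, _, _, sol = bar_case
    assert np.abs(sol.displacements[mesh.node_set("fixed_end")]).max() == 0.0


def test_insufficient_constraints_detected(single_tet):
    K = assemble_global(single_tet, [BONE])
    cons = ConstraintSet(np.array([0]))  # one node cannot stop rotation
    case = LoadCase("l").add(np.array([1]), np.array([[0.0, 1.0, 0]]))
    with pytest.raises(np.linalg.LinAlgError):
        solve_linear_static(K, case, cons)


def test_nonfinite_loads_rejected(single_tet):
    K = assemble_global(single_tet, [BONE])
    cons = ConstraintSet(np.array([0, 1, 2]))
    case = LoadCase("l").add(np.array([3]), np.array([[np.nan, 0, 0]]))
    with pytest.raises(ValueError, match="non-finite"):
        solve_linear_static(K, case, cons)


def test_patch_test_uniform_strain():
    """Boundary displacements of a uniform-strain field reproduce that
    constant stress in every element, to 1e-8 relative, with a jittered
    interior node."""
    rng = np.random.default_rng(3)
    mesh = make_bar(1.0, 1.0, 2)
    coords = mesh.node_coords.copy()
    interior = np.all((coords > 1e-9) & (coords < 1 - 1e-9), axis=1)
    coords[interior] += rng.uniform(-0.1, 0.1, (interior.sum(), 3))
    mesh = TetMesh(coords, mesh.tets)
    A = np.array([[1e-3, 2e-4, 0.0], [1e-4, -5e-4, 3e-4], [0.0, 2e-4, 8e-4]])
    bnodes = np.unique(boundary_facets(mesh))
    cons = ConstraintSet(bnodes, mesh.node_coords[bnodes] @ A.T)
    K = assemble_global(mesh, [BONE])
    sol = solve_linear_static(K, LoadCase("none"), cons)
    st = recover_stresses(mesh, [BONE], sol)
    ref = st.tensors[0]
    spread = np.abs(st.tensors - ref).max() / np.abs(ref).max()
    assert spread <= 1e-8


def test_hydrostatic_strain_zero_von_mises(single_tet):
    """Uniform volumetric strain has zero deviatoric (von Mises) stress."""
    K = assemble_global(single_tet, [BONE])
    eps = 1e-3
    cons = ConstraintSet(np.arange(4), single_tet.node_coords * eps)
    sol = solve_linear_static(K, LoadCase("none"), cons)
    st = recover_stresses(single_tet, [BONE], sol)
    assert np.abs(st.von_mises).max() <= 1e-12 * np.abs(st.tensors).max()


def test_principal_decomposition_matches_eig_oracle(jaw_stage, jaw_analysis):
    """Principal values/directions agree with a per-element eigensolve."""
    from devfea.pipeline import run_full_contraction

    _, sol, st = run_full_contraction(jaw_stage, jaw_analysis)
    rng = np.random.default_rng(0)
    for e in rng.choice(jaw_stage.mesh.n_elements, 20, replace=False):
        w = np.sort(np.linalg.eigvals(st.tensors[e]).real)[::-1]
        assert st.principal_values[e] == pytest.approx(w, rel=1e-9, abs=1e-12)
        Q = st.principal_directions[e]
        assert np.allclose(Q.T @ Q, np.eye(3), atol=1e-10)
        # directions diagonalise the tensor to the principal values
        diag = Q.T @ st.tensors[e] @ Q
        assert np.allclose(np.diag(diag), st.principal_values[e], atol=1e-9)
    assert np.all(st.von_mises >= 0)
    assert np.all(np.diff(st.principal_values, axis=1) <= 1e-12)


def test_mirror_symmetric_fields(jaw_stage, jaw_analysis):
    """Symmetric phantom + symmetric loads -> mirror-symmetric solution."""
    from scipy.spatial import cKDTree

    from devfea.pipeline import run_full_contraction

    mesh = jaw_stage.mesh
    _, sol, st = run_full_contraction(jaw_stage, jaw_analysis)
    mirrored = mesh.node_coords * np.array([-1.0, 1.0, 1.0])
    d, partner = cKDTree(mesh.node_coords).query(mirrored)
    assert d.max() <= 1e-9
    u = sol.displacements
    u_mirror = u[partner] * np.array([-1.0, 1.0, 1.0])
    scale = np.abs(u).max()
    assert np.abs(u - u_mirror).max() <= 1e-8 * scale
    # element-level von Mises symmetry via element centroid matching
    cent = mesh.node_coords[mesh.tets].mean(axis=1)
    dm, epartner = cKDTree(cent).query(cent * np.array([-1.0, 1.0, 1.0]))
    assert dm.max() <= 1e-9
    vs = np.abs(st.von_mises - st.von_mises[epartner]).max()
    assert vs <= 1e-8 * st.von_mises.max()
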