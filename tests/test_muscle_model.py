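"""Muscle loads and orientation angles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from devfea.mesh import AnatomicalFrame, TetMesh
from devfea.muscles import (
    AngleTriple,
    MuscleDefinition,
    attachment_centroid,
    distribute_nodal_forces,
    muscle_direction,
    muscle_force_magnitude,
    orientation_angles,
    pair_average_angles,
)

FRAME = AnatomicalFrame()


def _mesh_with_set(coords, name="ins"):
    coords = np.asarray(coords, dtype=float)
    # pad to at least 4 nodes for a valid (dummy) tet
    while len(coords) < 4:
        coords = np.vstack([coords, coords[-1] + [0.1, 0.2, 0.3]])
    return TetMesh(coords, np.array([[0, 1, 2, 3]]),
                   node_sets={name: np.arange(len(coords))[: len(coords)]})


def test_centroid_two_nodes():
    mesh = _mesh_with_set([[0, 0, 0], [2, 0, 0], [1, 1, 0], [1, -1, 0]])
    mesh.node_sets["pair"] = np.array([0, 1])
    assert attachment_centroid(mesh, "pair") == pytest.approx([1, 0, 0])


def test_centroid_single_node_identity():
    mesh = _mesh_with_set([[0.3, 0.7, -1.1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh.node_sets["one"] = np.array([0])
    assert attachment_centroid(mesh, "one") == pytest.approx([0.3, 0.7, -1.1])


def test_centroid_matches_brute_force_mean(jaw):
    mesh, muscles = jaw
    for m in muscles:
        idx = mesh.node_sets[m.insertion_set]
        brute = np.array([mesh.node_coords[i] for i in idx]).mean(axis=0)
        assert attachment_centroid(mesh, m.insertion_set) == pytest.approx(brute)
        # centroid lies within the patch bounding box
        lo, hi = mesh.node_coords[idx].min(0), mesh.node_coords[idx].max(0)
        assert np.all(brute >= lo - 1e-12) and np.all(brute <= hi + 1e-12)


def test_muscle_direction_toward_origin_point():
    mesh = _mesh_with_set([[1, 1, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh.node_sets["one"] = np.array([0])
    m = MuscleDefinition("m", "right", "one", 0.1, origin_point=(1, 1, 1))
    assert muscle_direction(mesh, m) == pytest.approx([0, 0, 1])


def test_muscle_direction_coincident_centroids_error():
    mesh = _mesh_with_set([[1, 1, 1], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh.node_sets["one"] = np.array([0])
    m = MuscleDefinition("m", "right", "one", 0.1, origin_point=(1, 1, 1))
    with pytest.raises(ValueError, match="coincide"):
        muscle_direction(mesh, m)


def test_force_magnitude_single_and_pair():
    a = MuscleDefinition("m", "left", "s", 0.04, origin_point=(0, 0, 1))
    assert muscle_force_magnitude(a) == pytest.approx(0.1)
    l = MuscleDefinition("m", "left", "s", 0.03, origin_point=(0, 0, 1))
    r = MuscleDefinition("m", "right", "s", 0.05, origin_point=(0, 0, 1))
    # pair shares the averaged PCSA: each side gets mean(0.03, 0.05) * 2.5
    assert muscle_force_magnitude(l, r) == pytest.approx(0.1)


def test_zero_pcsa_rejected():
    with pytest.raises(ValueError, match="pcsa"):
        MuscleDefinition("m", "left", "s", 0.0, origin_point=(0, 0, 1))


def test_mismatched_specific_tension_rejected():
    l = MuscleDefinition("m", "left", "s", 0.03, origin_point=(0, 0, 1))
    r = MuscleDefinition("m", "right", "s", 0.03, origin_point=(0, 0, 1),
                         specific_tension=3.0)
    with pytest.raises(ValueError, match="specific_tension"):
        muscle_force_magnitude(l, r)


def test_distribute_100uN_over_200_nodes():
    """100 uN spread over 200 insertion nodes -> 0.5 uN per node, exact."""
    rng = np.random.default_rng(1)
    coords = np.vstack([rng.uniform(0, 1, (200, 2)).T, np.zeros(200)]).T
    mesh = TetMesh(
        np.vstack([coords, [[0, 0, -1]]]),
        np.array([[0, 1, 2, 200]]),
        node_sets={"ins": np.arange(200)},
    )
    pcsa = 1e-4 / 2.5  # so total force = 100 uN at specific tension 2.5
    m = MuscleDefinition("m", "median", "ins", pcsa, origin_point=(0.5, 0.5, 5.0))
    load = distribute_nodal_forces(mesh, m)
    assert load.total_force == pytest.approx(1e-4, rel=1e-15)
    mags = np.linalg.norm(load.nodal_forces, axis=1)
    assert np.all(mags == mags[0])
    assert mags[0] == pytest.approx(0.5e-6, rel=1e-15)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    pcsa=st.floats(1e-4, 10.0),
    n=st.integers(1, 50),
    oz=st.floats(0.5, 10.0),
)
def test_distribution_conserves_total(pcsa, n, oz):
    """Sum of nodal forces equals total x direction to 1e-12 N."""
    coords = np.column_stack(
        [np.linspace(0, 1, max(n, 4)), np.zeros(max(n, 4)), np.zeros(max(n, 4))]
    )
    mesh = TetMesh(coords, np.array([[0, 1, 2, 3]]),
                   node_sets={"ins": np.arange(n)})
    m = MuscleDefinition("m", "right", "ins", pcsa, origin_point=(0.5, 0.3, oz))
    load = distribute_nodal_forces(mesh, m)
    expected = load.total_force * load.unit_direction
    assert np.abs(load.nodal_forces.sum(axis=0) - expected).max() <= 1e-12


@pytest.mark.parametrize(
    "direction,side,expect",
    [
        ((0, 0, 1), "right", {"rca": 90.0, "mla": 90.0}),  # pure dorsal
        ((0, 1, 0), "right", {"mla": 0.0, "dva": 90.0}),  # pure rostral
        ((0, -1, 0), "right", {"mla": 180.0, "dva": -90.0}),  # pure caudal
        ((1, 0, 0), "right", {"rca": 0.0, "dva": 0.0}),  # pure lateral (right)
        ((-1, 0, 0), "left", {"rca": 0.0, "dva": 0.0}),  # pure lateral (left)
    ],
)
def test_angle_endpoint_conventions(direction, side, expect):
    t = orientation_angles(np.array(direction, dtype=float), FRAME, side)
    for key, val in expect.items():
        assert getattr(t, key) == pytest.approx(val, abs=1e-12)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    v=st.tuples(*[st.floats(-1, 1).filter(lambda x: abs(x) > 1e-3)] * 3),
    c=st.floats(1e-3, 1e3),
)
def test_angles_scale_invariant(v, c):
    d = np.array(v)
    a = orientation_angles(d, FRAME, "right")
    b = orientation_angles(c * d, FRAME, "right")
    assert a.as_tuple() == pytest.approx(b.as_tuple(), abs=1e-9)


def test_mirrored_left_right_agree():
    """Mirrored left/right directions give identical angle triples."""
    d_right = np.array([0.3, 0.5, 0.8])
    d_left = d_right * np.array([-1, 1, 1])
    tr = orientation_angles(d_right, FRAME, "right")
    tl = orientation_angles(d_left, FRAME, "left")
    assert tl.as_tuple() == pytest.approx(tr.as_tuple(), abs=1e-12)


def test_pair_average_idempotent_and_mean():
    t = AngleTriple(40.0, 30.0, 20.0)
    assert pair_average_angles(t, t) == t
    u = AngleTriple(60.0, 50.0, 40.0)
    avg = pair_average_angles(t, u)
    assert avg.as_tuple() == pytest.approx((50.0, 40.0, 30.0))


def test_bilateral_symmetry_on_phantom(jaw):
    """On the mirrored phantom, left and right muscle angles agree to 1e-9 deg."""
    mesh, muscles = jaw
    by_name = {}
    for m in muscles:
        d = muscle_direction(mesh, m)
        by_name.setdefault(m.name, {})[m.side] = orientation_angles(d, FRAME, m.side)
    for name, sides in by_name.items():
        assert sides["left"].as_tuple() == pytest.approx(
            sides["right"].as_tuple(), abs=1e-9
        )
        avg = pair_average_angles(sides["left"], sides["right"])
        assert avg.as_tuple() == pytest.approx(sides["right"].as_tuple(), abs=1e-9)
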