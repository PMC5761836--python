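"""Phantom generators: determinism, symmetry, labelling, growth scaling."""

import numpy as np
import pytest

from devfea.mesh import element_volumes, validate_mesh
from devfea.muscles import muscle_direction, orientation_angles
from devfea.mesh import AnatomicalFrame
from devfea.phantoms import PhantomSpec, make_bar, make_growth_series, make_jaw_phantom


def test_bar_volume_and_end_sets():
    mesh = make_bar(10.0, 1.0, 4)
    assert element_volumes(mesh).sum() == pytest.approx(10.0, rel=1e-12)
    fixed, load = mesh.node_set("fixed_end"), mesh.node_set("load_end")
    assert len(np.intersect1d(fixed, load)) == 0
    assert np.all(mesh.node_coords[fixed, 0] == 0.0)
    assert np.all(np.isclose(mesh.node_coords[load, 0], 10.0))
    # the sets cover the full end faces: (res+1)^2 nodes each
    assert len(fixed) == len(load) == 25


def test_bar_rejects_bad_arguments():
    with pytest.raises(ValueError):
        make_bar(-1.0, 1.0, 2)
    with pytest.raises(ValueError):
        make_bar(1.0, 1.0, 0)


def test_jaw_phantom_validates_clean(jaw):
    mesh, _ = jaw
    assert validate_mesh(mesh) == []


def test_jaw_phantom_mirror_symmetry(jaw):
    """Reflecting across the midsagittal plane maps the mesh onto itself."""
    from scipy.spatial import cKDTree

    mesh, _ = jaw
    mirrored = mesh.node_coords * np.array([-1.0, 1.0, 1.0])
    d, idx = cKDTree(mesh.node_coords).query(mirrored)
    assert d.max() <= 1e-9
    assert len(np.unique(idx)) == mesh.n_nodes  # a true permutation


def test_jaw_phantom_bridge_thinner_than_lobe():
    spec = PhantomSpec()
    by, bz = spec.bridge_size[1], spec.bridge_size[2]
    ly, lz = spec.lobe_size[1], spec.lobe_size[2]
    assert by * bz < ly * lz


def test_jaw_phantom_has_tooth_region(jaw):
    mesh, _ = jaw
    assert set(mesh.region_tags()) == {1, 2}
    # tooth caps are ventral: all their nodes in the lower lobe half
    tooth_nodes = np.unique(mesh.tets[mesh.element_region == 2])
    assert mesh.node_coords[tooth_nodes, 2].max() <= 0.21


def test_jaw_phantom_resolution_floor():
    with pytest.raises(ValueError, match="resolution too coarse"):
        PhantomSpec(resolution=1)


def test_generator_bit_reproducible(jaw):
    mesh, muscles = jaw
    mesh2, muscles2 = make_jaw_phantom(PhantomSpec())
    assert np.array_equal(mesh.node_coords, mesh2.node_coords)
    assert np.array_equal(mesh.tets, mesh2.tets)
    assert np.array_equal(mesh.element_region, mesh2.element_region)
    assert muscles == muscles2


def test_growth_series_volume_ratio():
    """Isotropic factor 1.26 per stage doubles the volume each stage."""
    series = make_growth_series(PhantomSpec(), stages=3)
    vols = [element_volumes(m).sum() for m, _ in series]
    assert vols[1] / vols[0] == pytest.approx(1.26**3, rel=1e-12)
    assert vols[2] / vols[1] == pytest.approx(1.26**3, rel=1e-12)
    # PCSA scales with the transverse cross-section (fx * fy)
    for k in (1, 2):
        ratio = series[k][1][0].pcsa / series[0][1][0].pcsa
        assert ratio == pytest.approx(1.26 ** (2 * k), rel=1e-12)


def test_growth_series_identity_factors():
    series = make_growth_series(
        PhantomSpec(growth_factor=(1.0, 1.0, 1.0)), stages=3
    )
    base, _ = series[0]
    for mesh, muscles in series[1:]:
        assert np.array_equal(mesh.node_coords, base.node_coords)
        assert muscles == series[0][1]


def test_isotropic_growth_preserves_angles():
    """Pure scaling changes no muscle directions, hence no angles."""
    frame = AnatomicalFrame()
    series = make_growth_series(PhantomSpec(), stages=3)
    ref = None
    for mesh, muscles in series:
        triples = {
            m.label: orientation_angles(
                muscle_direction(mesh, m), frame, m.side
            ).as_tuple()
            for m in muscles
        }
        if ref is None:
            ref = triples
        else:
            for k in ref:
                assert triples[k] == pytest.approx(ref[k], abs=1e-9)


def test_anisotropic_dorsal_growth_shifts_angles_dorsally():
    """Dorsal-dominant growth rotates every muscle monotonically toward 90
    deg MLA (the dorsal direction) across stages."""
    frame = AnatomicalFrame()
    aniso = [(1.1, 1.1, 1.5), (1.1, 1.1, 1.5)]
    series = make_growth_series(PhantomSpec(), stages=3, anisotropy=aniso)
    history: dict[str, list[float]] = {}
    for mesh, muscles in series:
        for m in muscles:
            t = orientation_angles(muscle_direction(mesh, m), frame, m.side)
            history.setdefault(m.label, []).append(t.mla)
    for label, mlas in history.items():
        dist = [abs(v - 90.0) for v in mlas]
        assert dist[0] > dist[1] > dist[2], (label, mlas)


def test_growth_series_argument_validation():
    with pytest.raises(ValueError):
        make_growth_series(PhantomSpec(), stages=1)
    with pytest.raises(ValueError):
        make_growth_series(PhantomSpec(), stages=3, anisotropy=[(1.0, 1.0, -1.0)] * 2)
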