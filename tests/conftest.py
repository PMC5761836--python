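import numpy as np
import pytest

from devfea.fem import default_materials
from devfea.phantoms import PhantomSpec, make_jaw_phantom
from devfea.pipeline import StageAnalysis, StageSpec


@pytest.fixture(scope="session")
def jaw():
    """Default jaw phantom: (mesh, muscle list)."""
    return make_jaw_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def jaw_stage(jaw):
    mesh, muscles = jaw
    return StageSpec(
        stage_label="6dpf",
        mesh=mesh,
        muscles=muscles,
        contact_set="contact_neurocranium",
        materials=default_materials(),
        reduction_muscle="retractor_dorsalis",
        biting_muscles=("levator_externus_4", "levator_posterior"),
    )


@pytest.fixture(scope="session")
def jaw_analysis(jaw_stage):
    """Shared stiffness/loads cache so the suite assembles K once."""
    return StageAnalysis(jaw_stage)


@pytest.fixture()
def single_tet():
    """Canonical simplex: nodes (0,0,0),(1,0,0),(0,1,0),(0,0,1)."""
    from devfea.mesh import TetMesh

    return TetMesh(
        np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
        np.array([[0, 1, 2, 3]]),
    )
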