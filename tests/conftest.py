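import numpy as np
import pytest

import plaquestress as ps
from plaquestress.validation import lame_convergence


@pytest.fixture(scope="session")
def materials():
    return ps.MaterialTable()


@pytest.fixture(scope="session")
def plaque_solution():
    """One representative stenosed-vessel FE solution (coarse profile)."""
    params = ps.GeometryParams(
        lumen_radius=4.0,
        vessel_length=18.0,
        stenosis_length=12.0,
        voxel_size=1.0,
        stenosis_degree=0.65,
        calcific_fraction=0.2,
        lipid_fraction=0.08,
        seed=7,
    )
    vol = ps.generate_vessel_labelmap(params)
    model = ps.reconstruct_atherosclerotic_wall(vol, ps.ReconstructionConfig(wall_thickness=2.0))
    report = ps.compute_component_volumes(model)
    mesh = ps.mesh_vessel(model)
    result = ps.solve_elasticity(mesh, pressure=5.33)
    return model, report, mesh, result


@pytest.fixture(scope="session")
def lame_suite():
    """Lamé thick-cylinder runs at three successive refinements."""
    return lame_convergence()


@pytest.fixture(scope="session")
def cohort():
    """The default 43/57 synthetic cohort, fully processed."""
    return ps.run_cohort(ps.RunConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
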