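import numpy as np
import pytest

from patellofem.fem.materials import MaterialParams
from patellofem.geometry import COARSE_RESOLUTION, build_knee


@pytest.fixture(scope="session")
def healthy_knee():
    return build_knee("healthy", resolution=COARSE_RESOLUTION)


@pytest.fixture(scope="session")
def dysplastic_knee():
    return build_knee("dysplastic_D", resolution=COARSE_RESOLUTION)


@pytest.fixture(scope="session")
def material():
    return MaterialParams()


@pytest.fixture(scope="session")
def healthy_fit_45(healthy_knee, material):
    """Converged healthy-knee solve at 45 deg with the strict tolerance."""
    from patellofem.model import PatellofemoralModel
    from patellofem.solver import SolverSettings

    model = PatellofemoralModel(
        healthy_knee, 45.0, material=material,
        settings=SolverSettings(
            n_load_steps=4, max_iterations=60,
            newton_tol=1e-6, penalty_stiffness=100.0,
        ),
        layers=2,
    )
    return model.fit()


@pytest.fixture(scope="session")
def study_result():
    """The bundled two-knee study at the reduced (study) resolution."""
    from patellofem.study import run_study

    return run_study()


@pytest.fixture(scope="session")
def foundation_result():
    from patellofem.benchmarks import foundation_indentation

    return foundation_indentation()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
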