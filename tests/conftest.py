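import numpy as np
import pandas as pd
import pytest

from clpnet import (
    EstimationConfig,
    PanelDataset,
    SimulationConfig,
    default_schema,
    default_true_model,
    simulate_panel,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def true_model():
    return default_true_model(seed=0)


@pytest.fixture(scope="session")
def medium_panel(true_model):
    """Complete 2-wave panel, n = 1000, used by several estimation tests."""
    data, latent = simulate_panel(true_model, SimulationConfig(1000, 2, seed=42))
    return data, latent


@pytest.fixture(scope="session")
def fast_config():
    """Smaller grid/folds for tests where the penalty path detail is not at stake."""
    return EstimationConfig(n_alphas=40, cv_folds=5, cv_seed=7)


@pytest.fixture()
def toy_panel(schema):
    """2 subjects x 2 waves, all 13 items observed and in range."""
    rng = np.random.default_rng(0)
    responses = np.zeros((2, 2, 13))
    for k, item in enumerate(schema):
        responses[:, :, k] = rng.integers(item.scale_min, item.scale_max + 1, size=(2, 2))
    aux = pd.DataFrame({"sex": [0, 1], "ethnicity": [0, 1], "age": [30.0, 60.0]})
    return PanelDataset(
        np.array(["a", "b"]), ["w1", "w2"], responses, schema, aux
    )


def small_null_model(true_model):
    """Helper: same measurement model as the default, but B = 0."""
    from clpnet.simulate import TrueModel

    return TrueModel(
        B=np.zeros((13, 13)),
        innovation_sd=np.ones(13),
        wave1_cov=true_model.wave1_cov.copy(),
        thresholds=[t.copy() for t in true_model.thresholds],
        missingness_params=true_model.missingness_params.copy(),
        schema=list(true_model.schema),
    )
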