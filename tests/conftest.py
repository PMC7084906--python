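import pytest

import pkbridge as pk
from pkbridge.population import PopPKModel


@pytest.fixture(scope="session")
def final_model():
    return pk.rat_final_model()


@pytest.fixture(scope="session")
def base_model():
    return pk.rat_base_model()


@pytest.fixture(scope="session")
def rat_design():
    return pk.StudyDesign()


@pytest.fixture(scope="session")
def study(final_model, rat_design):
    """One synthetic rat study at the reference truth."""
    return pk.simulate_dataset(final_model, rat_design, seed=42)


@pytest.fixture(scope="session")
def fitted(study, final_model):
    """Final model fitted to the session study."""
    return PopPKModel(study, final_model).fit(
        compute_se=False, presolve=True, maxfev=2000, fatol=0.02, xatol=1e-3
    )


@pytest.fixture(scope="session")
def human_params(final_model):
    return pk.extrapolate(final_model)
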