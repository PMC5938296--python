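import pytest

from vgrlab import SimulationConfig, build_default_design, simulate_study


@pytest.fixture(scope="session")
def default_design():
    return build_default_design()


@pytest.fixture(scope="session")
def default_study():
    """One full-size simulated study at the default ground truth."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down study for fast model checks."""
    cfg = SimulationConfig(
        n_patients=12,
        observer_ids=("O1", "O2", "O3"),
        criteria=(1,),
        n_replicates=3,
        seed=7,
    )
    return simulate_study(cfg)
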