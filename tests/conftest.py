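import numpy as np
import pytest

from perturbscreen.synthgen import (
    AgentSpec,
    SimSpec,
    SynergySpec,
    _dose_range,
    worked_fixtures,
)


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory):
    """Canonical synthetic screens, generated once per session."""
    out = tmp_path_factory.mktemp("fixtures")
    return worked_fixtures(out, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def two_drug_null_spec(seed: int, effect_model: str = "direct", times=(72.0,)) -> SimSpec:
    """Bliss-independent 7x7 two-drug grid (multiplicative survival)."""
    a = AgentSpec("A", _dose_range(3000.0, 7), ic50=400.0, hill=1.6, emax=0.85)
    b = AgentSpec("B", _dose_range(1000.0, 7), ic50=120.0, hill=1.2, emax=0.7)
    return SimSpec(
        experiment_type="drug_combination",
        agents=(a, b),
        combinations=(("A", "B"),),
        times=tuple(times),
        effect_model=effect_model,
        noise_sd=0.05,
        seed=seed,
    )


def two_drug_synergy_spec(seed: int, epsilon: float = 0.2, onset: float = 20.0) -> SimSpec:
    """Time-course grid with Bliss-excess synergy injected at the low-dose cell."""
    a = AgentSpec("A", _dose_range(3000.0, 7), ic50=400.0, hill=1.6, emax=0.85)
    b = AgentSpec("B", _dose_range(1000.0, 7), ic50=120.0, hill=1.2, emax=0.7)
    return SimSpec(
        experiment_type="drug_combination",
        agents=(a, b),
        combinations=(("A", "B"),),
        synergy=SynergySpec(epsilon=epsilon, onset=onset, cells=((0, 0),)),
        noise_sd=0.02,
        seed=seed,
    )
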