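import pytest

from capnotype import pipeline as pl
from capnotype.simulate import simulate_recording


def _clean(scenario, duration=60.0):
    scenario.patient.noise_sd = {}
    return simulate_recording(scenario.patient, scenario.circuit, duration,
                              interface=scenario.interface)


@pytest.fixture(scope="session")
def clean_sims():
    """One noiseless simulation per CO2-movement regime (types I, II, III)."""
    return {name: _clean(sc) for name, sc in
            zip(("I", "II", "III"), pl.demo_scenarios(0))}


@pytest.fixture(scope="session")
def noisy_sim_type3():
    """Type III scenario with default channel noise."""
    scenario = pl.demo_scenarios(0)[2]
    return simulate_recording(scenario.patient, scenario.circuit, 60.0,
                              interface=scenario.interface)
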