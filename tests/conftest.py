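import pytest
from hypothesis import HealthCheck, settings

import ionflux as ifx

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def k_ion():
    return ifx.lookup_ion("K+")


@pytest.fixture
def ideal_cal():
    """Ideal monovalent-cation electrode: 58 mV/decade, 0 mV at 1 mM."""
    return ifx.fit_calibration([(0.1, -58.0), (1.0, 0.0), (10.0, 58.0)])


@pytest.fixture
def fast_acq():
    """Short loops (1 s of 100 samples) to keep unit tests quick."""
    return ifx.AcquisitionConfig(loop_duration=1.0, start_fit=0.5)


def make_scenario(k_ion, **kw):
    """Noise- and lag-free default scenario; override via keywords."""
    el = kw.pop("electrode", ifx.ElectrodeModel(tau=0.0, drift=0.0, noise_sd=0.0))
    defaults = dict(
        ion=k_ion, bulk_conc=0.5, true_flux=0.0,
        geometry=ifx.GeometrySpec(gap0=50e-6), electrode=el, n_loops=4,
    )
    defaults.update(kw)
    return ifx.SimulationScenario(**defaults)


@pytest.fixture
def scenario_factory(k_ion):
    return lambda **kw: make_scenario(k_ion, **kw)
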