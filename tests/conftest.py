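import pytest
from hypothesis import HealthCheck, settings

from xpdtsim.materials import element_tables
from xpdtsim.phantoms import build_model
from xpdtsim.spectra import TubeConfig, generate_spectrum
from xpdtsim.transport import TransportConfig, convert_to_dose, run_transport

settings.register_profile(
    "deterministic", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tables():
    return element_tables()


@pytest.fixture(scope="session")
def spec60(tables):
    """Default 60 kVp tube spectrum."""
    return generate_spectrum(TubeConfig(kvp=60), tables)


@pytest.fixture(scope="session")
def pair60(tables, spec60):
    """Models A and B transported at 60 kVp (3e5 histories each)."""
    out = {}
    for model, seed in (("A", 101), ("B", 202)):
        ph = build_model(model)
        grid = run_transport(ph, spec60,
                             TransportConfig(n_photons=300_000, seed=seed), tables)
        out[model] = (ph, convert_to_dose(grid, ph))
    return out
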