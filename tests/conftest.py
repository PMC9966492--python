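import pytest

from emboflow import constants as C
from emboflow.synthetic import SyntheticRheometryConfig, generate_curve

ALL_PARAM_SETS = [C.ONYX18_20C, C.ONYX18_37C, C.SQUID12_20C, C.SQUID12_37C]


@pytest.fixture(params=ALL_PARAM_SETS, ids=lambda p: f"{p.polymer_label}-{p.temperature:g}C")
def sisko_params(request):
    """Each of the four published Sisko parameter sets."""
    return request.param


@pytest.fixture
def noiseless_curve(sisko_params):
    """Noiseless synthetic flow curve from the given parameter set."""
    cfg = SyntheticRheometryConfig(base_params=sisko_params, noise_sd=0.0)
    return generate_curve(cfg)
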