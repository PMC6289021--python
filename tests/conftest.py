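import pytest

from vtecea.params import load_inputs


@pytest.fixture(scope="session")
def ethr_inputs():
    return load_inputs(population="eTHR")


@pytest.fixture(scope="session")
def etkr_inputs():
    return load_inputs(population="eTKR")


@pytest.fixture(scope="session", params=["eTHR", "eTKR"])
def any_inputs(request, ethr_inputs, etkr_inputs):
    return ethr_inputs if request.param == "eTHR" else etkr_inputs
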