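import pytest

import eixpct as ei


@pytest.fixture(scope="session")
def lowres():
    return ei.lowres_preset()


@pytest.fixture(scope="session")
def highres():
    return ei.highres_preset()


@pytest.fixture(scope="session")
def ic_lowres(lowres):
    return ei.compute_ic(lowres)


@pytest.fixture(scope="session")
def ic_highres(highres):
    return ei.compute_ic(highres)
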