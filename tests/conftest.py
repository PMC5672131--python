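import pytest

from kerapower import get_model


@pytest.fixture(scope="session")
def gullstrand():
    return get_model("gullstrand")


@pytest.fixture(scope="session")
def legrand():
    return get_model("legrand")


@pytest.fixture(scope="session", params=["gullstrand", "legrand"])
def any_model(request):
    return get_model(request.param)
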