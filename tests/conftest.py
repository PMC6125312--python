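import pytest

import nlmc


@pytest.fixture
def toy():
    return nlmc.make_toy_problem()


@pytest.fixture
def expdemo():
    return nlmc.make_expdemo_problem()


@pytest.fixture
def coin():
    return nlmc.make_coin_problem()


@pytest.fixture
def stream():
    """A fresh root stream; tests that need multiple use .child(i)."""
    return nlmc.RandomStream(12345)
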