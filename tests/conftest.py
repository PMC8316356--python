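import pytest

from junctiso import build_tp63_model, build_tp73_model


@pytest.fixture(scope="session")
def tp73():
    return build_tp73_model()


@pytest.fixture(scope="session")
def tp63():
    return build_tp63_model()


# the two hand-evaluated cascade examples used across test modules
TP63_C_COUNTS = {
    "E10-E11a": 50.0, "E10-E11": 50.0,
    "E11-E14": 10.0, "E11-E12": 90.0,
    "E12-E14": 20.0, "E12-E13": 80.0,
}
TP63_C_EXPECTED = {"gamma": 50.0, "delta": 5.0, "beta": 9.0, "alpha": 36.0}

TP73_C_COUNTS = {
    "E10-E11": 80.0, "E10-E12": 10.0, "E10-E13": 5.0, "E10-E14": 5.0,
    "E12-E13": 60.0, "E12-E14": 20.0,
}
TP73_C_EXPECTED = {
    "alpha": 60.0, "beta": 20.0, "gamma+epsilon": 10.0, "zeta": 5.0, "delta": 5.0,
}
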