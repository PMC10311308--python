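import pytest

from mvntrap.model import Semantics, Space, worked_example
from mvntrap.petri import EncodingConfig
from mvntrap.series import series_from_table


@pytest.fixture(scope="session")
def example():
    """The two-variable worked example: K1=[0,1], K2=[0,2]."""
    return worked_example()


@pytest.fixture(scope="session")
def example_series(example):
    return {v: series_from_table(example, v) for v in example.variables}


@pytest.fixture(scope="session")
def example_nets(example, example_series):
    """Petri nets of the worked example, keyed by semantics."""
    from mvntrap.petri import encode

    cfg = EncodingConfig(ordering_trials=1)
    return {
        sem: encode(example, example_series, sem, cfg)
        for sem in (Semantics.GENERAL, Semantics.UNITARY)
    }


def space(**levels):
    """Shorthand: space(v1=(0,), v2=(0, 2))."""
    return Space({k: tuple(v) for k, v in levels.items()})


@pytest.fixture(scope="session")
def printed_general_spaces():
    """The six trap spaces of the worked example, general semantics."""
    return {
        "m1": space(v1=(0,), v2=(1,)),
        "m2": space(v1=(1,), v2=(1,)),
        "m3": space(v1=(0,), v2=(0, 2)),
        "m4": space(v1=(0, 1), v2=(1,)),
        "m5": space(v1=(0,), v2=(0, 1, 2)),
        "m6": space(v1=(0, 1), v2=(0, 1, 2)),
    }
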