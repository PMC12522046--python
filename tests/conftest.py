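import pytest

from rxnforge import (
    ConditionSpec,
    RDKitDepictor,
    StyleConfig,
    ToyReactionSource,
    generate_scheme,
)
from rxnforge.rng import RNGStream


@pytest.fixture(scope="session")
def depictor():
    return RDKitDepictor()  # shared: the 2D-extent cache makes layout cheap


@pytest.fixture(scope="session")
def toy_source():
    return ToyReactionSource()


@pytest.fixture(scope="session")
def style():
    return StyleConfig(seed=11)


@pytest.fixture(scope="session")
def cond_spec():
    return ConditionSpec()


@pytest.fixture(scope="session")
def scheme_pool(toy_source, style, cond_spec, depictor):
    """80 layout-only generated schemes across mixed patterns and seeds."""
    return [
        generate_scheme(
            toy_source, style, cond_spec, RNGStream(11, (i,)), render=False,
            depictor=depictor,
        )
        for i in range(80)
    ]
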