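import pytest

from morm import AnchorSpec, SyntheticConfig, fig3_fixture, random_bmkn


@pytest.fixture
def fig3():
    return fig3_fixture()


@pytest.fixture
def fig3_anchor():
    return AnchorSpec("D0", steps=2)


def make_random_net(seed: int, **overrides):
    """Small 3-ontology random network for property tests."""
    params = dict(
        seed=seed,
        n_ontologies=3,
        concepts_per_ontology=12,
        tree_branching=3,
        intra_extra_rate=0.2,
        inter_rate=0.05,
    )
    params.update(overrides)
    return random_bmkn(SyntheticConfig(**params))
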