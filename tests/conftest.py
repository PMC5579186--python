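import pytest

from cernet import inference, simulate
from cernet.types import CeRNANetwork


@pytest.fixture(scope="session")
def small_cfg():
    return simulate.small_config(seed=7)


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """A scaled-down synthetic study shared across the suite."""
    return simulate.generate_study(small_cfg)


@pytest.fixture(scope="session")
def small_candidates(small_study):
    return inference.candidate_pairs(small_study.interactions)


@pytest.fixture(scope="session")
def small_networks(small_study, small_candidates):
    return inference.infer_all_profiles(small_study.profiles, small_candidates)


@pytest.fixture
def make_net():
    """Factory building a toy ceRNA network from bare edge tuples."""

    def _make(edges, network_id="toy", level="profile", **overrides):
        net = CeRNANetwork(network_id=network_id, level=level)
        for e in edges:
            a, b = e[0], e[1]
            attrs = dict(r=0.5, p=0.001, q=0.01, n_shared=3)
            if len(e) > 2:
                attrs.update(e[2])
            attrs.update(overrides)
            net.add_edge(a, b, **attrs)
        return net

    return _make
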