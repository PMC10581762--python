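import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230664)


@pytest.fixture(scope="session")
def balanced_tree():
    from owlfield.phylo import Phylogeny
    return Phylogeny.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")


@pytest.fixture(scope="session")
def study():
    """One seeded synthetic study at the default (study-condition) settings."""
    from owlfield.simulate import SimulationConfig, simulate_study
    cfg = SimulationConfig(seed=20230664)
    tree, traits, records, individuals = simulate_study(cfg)
    return {"config": cfg, "tree": tree, "traits": traits,
            "records": records, "individuals": individuals}
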