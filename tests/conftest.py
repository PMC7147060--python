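import numpy as np
import pytest

from quartetbm.genetree import simulate_gene_tree
from quartetbm.rates import RateConfig, scenario_distance_matrix
from quartetbm.species import simulate_dated_species_tree, simulate_species_topology


def random_length_tree(n_leaves, rng):
    """Random planted topology with positive random edge lengths."""
    tree = simulate_species_topology(n_leaves, rng)
    for v in tree.preorder(include_planted=False):
        v.length = float(rng.lognormal(-1.5, 0.7))
    return tree


def make_scenario(seed, n_species=8, dup=0.7, loss=0.7, hgt=0.0,
                  cfg=None, max_tries=50):
    """A non-extinct simulated scenario with distances and colours."""
    rng = np.random.default_rng(seed)
    cfg = cfg or RateConfig()
    for _ in range(max_tries):
        S = simulate_dated_species_tree(n_species, rng)
        try:
            scn = simulate_gene_tree(S, dup, loss, hgt, rng)
        except ValueError:
            continue
        if len(set(scn.color.values())) >= 2:
            obs, color, D = scenario_distance_matrix(scn, cfg, rng)
            return scn, obs, color, D
    raise RuntimeError("could not draw a usable scenario")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
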