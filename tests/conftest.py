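import logging

import pytest

from plastovar.genemap import toy_map
from plastovar.simulate import (SimulationConfig, evolve_on_tree,
                                simulate_ancestor)

logging.getLogger("plastovar").setLevel(logging.ERROR)

TOY_TREE = "((A:0.02,B:0.02):0.01,(C:0.02,D:0.02):0.01);"


def toy_config(**kw):
    base = dict(seed=7, lsc_len=6000, ir_len=2000, ssc_len=3000,
                gene_map=toy_map(), tree=TOY_TREE)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def toy_run():
    """One evolved 4-taxon toy simulation shared across tests."""
    cfg = toy_config()
    ancestor, segments = simulate_ancestor(cfg)
    tips, truth = evolve_on_tree(segments, cfg)
    return {"cfg": cfg, "ancestor": ancestor, "segments": segments,
            "tips": tips, "truth": truth}


@pytest.fixture(scope="session")
def full_ancestor():
    """Full 113-gene ancestor at study-scale partition lengths."""
    cfg = SimulationConfig(seed=11)
    ancestor, segments = simulate_ancestor(cfg)
    return {"cfg": cfg, "ancestor": ancestor, "segments": segments}
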