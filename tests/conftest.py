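import numpy as np
import pytest

from paleodiv import (
    BDParams,
    PreservationModel,
    tree_from_newick_string,
)
from paleodiv.synthetic import generate_fossil_dataset
from paleodiv.treesim import BDSimConfig, simulate_bd_tree

TOY_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def toy_tree():
    return tree_from_newick_string(TOY_NEWICK)


@pytest.fixture(scope="session")
def random_trees():
    """A bank of small seeded birth-death trees for property tests."""
    trees = []
    for seed in range(40):
        cfg = BDSimConfig(lambda0=0.8, mu0=0.3, max_height=6.0, min_tips=4,
                          max_tips=60, seed=1000 + seed)
        trees.append(simulate_bd_tree(cfg))
    return trees


@pytest.fixture(scope="session")
def fossil_truth():
    """The standard synthetic fossil fixture: ~20 species, q = 5, NHPP."""
    return generate_fossil_dataset(
        20,
        BDParams(0.7, 0.35),
        PreservationModel(kind="NHPP", q=5.0, alpha=3.0, gamma_shape=1.5),
        age_error=0.05,
        seed=7,
    )


@pytest.fixture
def occurrence_csv(tmp_path):
    path = tmp_path / "occ.csv"
    path.write_text(
        "species,site_complex,site,subsite,formation,strat_unit,age_min,age_max,source_id\n"
        "Australopithecus afarensis,Hadar,AL-333,,Hadar Fm,SH,3.2,3.4,a1\n"
        "Australopithecus afarensis,Hadar,AL-288,,Hadar Fm,KH,3.1,3.3,a2\n"
        "Paranthropus boisei,Olduvai,FLK,,,Bed I,1.8,1.9,b1\n"
    )
    return path
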