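import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracle helper

import orthodiv as od
from orthodiv.simulate import BDParams, DEFAULT_SPECIES_TREE

SPECIES = ["Ccas", "Cper", "Csow"]


@pytest.fixture(scope="session")
def species_tree_newick() -> str:
    return DEFAULT_SPECIES_TREE


@pytest.fixture()
def four_leaf_tree():
    """Unrooted ((a1,b1),(a2,c1)): two clean two-species orthogroups."""
    return od.parse_gene_tree("((a_1:1,b_1:1)90:1,(a_2:1,c_1:1)85:1);")


@pytest.fixture()
def or10_like_tree():
    """A small mixed tree with a species-specific expansion."""
    return od.parse_gene_tree(
        "(((Ccas_g1:1,Ccas_g2:1)99:1,(Csow_g1:1,Cper_g1:1)80:1)75:1,"
        "(Ccas_g3:1,(Csow_g2:1,Cper_g2:1)88:1)90:1);"
    )


@pytest.fixture(scope="session")
def small_repertoire(tmp_path_factory):
    """A written-to-disk simulated repertoire shared across pipeline tests."""
    out = tmp_path_factory.mktemp("sim")
    specs = [
        (f"SF{i + 1:02d}", 12, BDParams(birth=0.02, death=0.01, rate_multipliers={"Ccas": 3.0}))
        for i in range(5)
    ]
    dataset = od.simulate_repertoire(DEFAULT_SPECIES_TREE, specs, seed=11, out_dir=out)
    (out / "species_tree.nwk").write_text(DEFAULT_SPECIES_TREE + "\n")
    return out, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
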