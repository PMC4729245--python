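import numpy as np
import pytest

from codonsel.seqio import LabeledTree
from codonsel.simulate import make_study_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """10-taxon study-design fixture at reduced length (shared, read-only)."""
    return make_study_fixture(seed=11, n_codons=150)


@pytest.fixture(scope="session")
def six_taxon_tree():
    """Small ultrametric-ish labeled tree with both mating-system classes."""
    labels = {
        "soc1": "social", "soc2": "social",
        "sub1": "subsocial", "sub2": "subsocial",
        "sub3": "subsocial", "sub4": "subsocial",
    }
    nwk = ("((soc1:0.04,sub1:0.16):0.08,(soc2:0.04,sub2:0.16):0.08,"
           "(sub3:0.16,sub4:0.16):0.08);")
    return LabeledTree.from_newick(nwk, labels), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
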