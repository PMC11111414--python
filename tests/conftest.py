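import numpy as np
import pytest

from radiascope import msc
from radiascope.tree import read_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def balanced4():
    return read_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")


@pytest.fixture
def caterpillar6():
    """Ultrametric 6-taxon caterpillar in Ma (ages 1..5)."""
    return read_newick("(((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5);", unit="Ma")


@pytest.fixture
def caterpillar6_model(caterpillar6):
    return msc.SpeciesTreeModel(caterpillar6.copy()).fill_defaults()


def quartet_internal_cu(model, a, b, c, d):
    """Coalescent-unit length of the species-tree path separating {a,b}|{c,d}.

    Independent closed-form helper for MSC expectations: the probability that
    a gene-tree quartet matches ab|cd is 1 - (2/3) exp(-L) with L this sum.
    """
    total = 0.0
    for clade, T, d_cu, _ in model.branch_table():
        side = clade
        ina, inb, inc, ind = a in side, b in side, c in side, d in side
        if ina and inb and not inc and not ind:
            total += d_cu
        elif inc and ind and not ina and not inb:
            total += d_cu
    return total
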