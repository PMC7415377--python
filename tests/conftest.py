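import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from phycohealth import FeatureTable, TaxonomyMap
from phycohealth.io_tables import parse_lineage


@pytest.fixture
def toy_tree():
    """Four-tip rooted tree with known branch lengths (total length 10)."""
    return TreeNode.read(["((A:1,B:2):1,(C:3,D:1):2):0;"])


@pytest.fixture
def small_table():
    data = pd.DataFrame(
        [[5, 0, 3], [2, 4, 0], [1, 1, 1]],
        index=["s1", "s2", "s3"], columns=["a1", "a2", "a3"])
    return FeatureTable(data)


@pytest.fixture
def small_taxonomy():
    tm = TaxonomyMap()
    tm.lineages = {
        "a1": parse_lineage("d__Bacteria; p__P1; c__C1; o__Rhizobiales; f__F1; g__G1"),
        "a2": parse_lineage("d__Bacteria; p__P1; c__C1; o__Rhizobiales; f__F2; g__G2"),
        "a3": parse_lineage("d__Bacteria; p__Cyanobacteria; c__Oxyphotobacteria; o__Chloroplast"),
    }
    return tm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
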