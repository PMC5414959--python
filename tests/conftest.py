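import numpy as np
import pandas as pd
import pytest

from gontogeny import PhyloTree, from_newick, parse_obo

# A small molecular-function DAG exercising every structural feature the
# pipeline cares about: multi-parent terms at unequal depths, a part_of-only
# term, a childless level-1 term, an obsolete term and an alt_id.
TOY_OBO = """\
format-version: 1.2
ontology: go-toy

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0000001
name: alpha activity
namespace: molecular_function
alt_id: GO:0000011
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0000002
name: beta activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0000003
name: gamma activity
namespace: molecular_function
is_a: GO:0000001 ! alpha activity

[Term]
id: GO:0000004
name: delta activity
namespace: molecular_function
is_a: GO:0000003 ! gamma activity
is_a: GO:0000002 ! beta activity

[Term]
id: GO:0000005
name: epsilon activity
namespace: molecular_function
is_a: GO:0000001 ! alpha activity
is_a: GO:0000003 ! gamma activity

[Term]
id: GO:0000006
name: zeta activity
namespace: molecular_function
relationship: part_of GO:0000001 ! alpha activity

[Term]
id: GO:0000007
name: eta activity
namespace: molecular_function
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0000008
name: theta activity
namespace: molecular_function
is_a: GO:0000001 ! alpha activity
is_obsolete: true
"""


@pytest.fixture(scope="session")
def toy_dag():
    return parse_obo(TOY_OBO)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def pectinate_newick(max_depth: int, prefix: str = "L") -> str:
    """Rooted ladder with one leaf at every depth 0..max_depth (two at the
    bottom); depth counts internal nodes below the root on the path."""
    inner = f"({prefix}{max_depth}a,{prefix}{max_depth}b)"
    for d in range(max_depth - 1, 0, -1):
        inner = f"({prefix}{d},{inner})"
    return f"({prefix}0,{inner});"


@pytest.fixture
def pectinate_tree():
    def build(max_depth: int) -> PhyloTree:
        return from_newick(pectinate_newick(max_depth), rooted=True)

    return build


def ladder_states(labels, step: int = 3, n_chars: int = 8) -> pd.DataFrame:
    """Homoplasy-free gradient matrix: taxon i holds state i*step in every
    character; the generating topology is the caterpillar in label order."""
    n = len(labels)
    data = np.tile((np.arange(n) * step)[:, None], (1, n_chars))
    return pd.DataFrame(data, index=list(labels))


def random_states(rng, n_taxa: int, n_chars: int, max_state: int = 31) -> pd.DataFrame:
    labels = [f"t{i}" for i in range(n_taxa)]
    return pd.DataFrame(
        rng.integers(0, max_state + 1, size=(n_taxa, n_chars)), index=labels
    )
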