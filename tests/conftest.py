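import numpy as np
import pandas as pd
import pytest

import phyloflora as pf

T4 = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture
def t4():
    """Balanced four-tip ultrametric tree of depth 2."""
    return pf.read_newick_string(T4)


@pytest.fixture
def t4_dm(t4):
    return pf.patristic_matrix(t4)


@pytest.fixture
def t4_table():
    """Taxon table putting T4's tips in two genera / two families."""
    df = pd.DataFrame({
        "species": ["A", "B", "C", "D"],
        "genus": ["G1", "G1", "G2", "G2"],
        "family": ["Fam1", "Fam1", "Fam2", "Fam2"],
        "element": ["PT", "TA", "NT", "EA"],
        "r1": [1, 1, 0, 0],
        "r2": [0, 1, 1, 0],
        "r3": [0, 0, 1, 1],
    })
    return pf.TaxonTable(data=df, regions=("r1", "r2", "r3"))


def make_table(tree, genus_of, family_of, presence=None, element=None):
    """Assemble a TaxonTable for the given species -> rank mappings."""
    species = sorted(genus_of)
    regions = sorted({r for p in (presence or {}).values() for r in p})
    if not regions:
        regions = ["r1"]
    rows = []
    for sp in species:
        row = {"species": sp, "genus": genus_of[sp], "family": family_of[sp],
               "element": (element or {}).get(sp, "UNKNOWN")}
        flags = (presence or {}).get(sp, {})
        for r in regions:
            row[r] = flags.get(r, 1 if presence is None else 0)
        rows.append(row)
    return pf.TaxonTable(data=pd.DataFrame(rows), regions=tuple(regions))


def random_community(labels, size, rng):
    return set(rng.choice(np.asarray(labels), size=size, replace=False))
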