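"""Synthetic trees, taxonomies, communities and element labels.

The generator emulates the statistical structure the analysis stages are
meant to detect — ultrametric time trees, monophyletic genus/family labels,
regional communities with controllable phylogenetic clustering or
overdispersion, and element codes drawn with stated proportions — without
attempting to model any real biogeographic process.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._treeindex import TreeIndex
from .elements import ElementVocabulary
from .io import UNKNOWN_ELEMENT, FloraMatrix, TaxonTable

__all__ = [
    "CommunitySpec",
    "simulate_tree",
    "simulate_taxonomy",
    "simulate_communities",
    "assign_elements",
    "simulate_dataset",
]

STRUCTURES = ("clustered", "overdispersed", "random")


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, model: str = "yule", birth: float = 1.0,
                  death: float = 0.0, seed=None) -> dendropy.Tree:
    """Simulate an ultrametric tree with exactly ``n_tips`` extant tips.

    Forward-time constant-rate simulation: starting from a crown split, each
    lineage branches at rate ``birth`` and (under ``birth_death``) dies at
    rate ``death``; the simulation stops at the moment the next event after
    reaching ``n_tips`` extant lineages would occur, and extinct lineages
    are pruned. Runs that go extinct are restarted. Tips are labelled
    ``sp0001`` ... in preorder; output is reproducible under ``seed``.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if model == "yule":
        death = 0.0
    elif model == "birth_death":
        if not (0.0 <= death < birth):
            raise ValueError("birth_death requires 0 <= death < birth")
    else:
        raise ValueError(f"unknown model {model!r}; expected yule or birth_death")
    if birth <= 0:
        raise ValueError("birth rate must be positive")

    rng = np.random.default_rng(seed)
    while True:
        tree = _forward_bd(n_tips, birth, death, rng)
        if tree is not None:
            return tree


def _forward_bd(n_tips, birth, death, rng):
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    extant = [root.new_child(), root.new_child()]
    for c in extant:
        c.birth_time = 0.0
    t = 0.0
    total_rate = birth + death
    while True:
        k = len(extant)
        t += rng.exponential(1.0 / (k * total_rate))
        if k == n_tips:
            end_time = t
            break
        i = int(rng.integers(k))
        node = extant[i]
        if death == 0.0 or rng.random() < birth / total_rate:
            extant[i] = node.new_child()
            extant.append(node.new_child())
            extant[i].birth_time = t
            extant[-1].birth_time = t
            node.end_time = t
        else:
            node.end_time = t
            node.alive = False
            extant.pop(i)
            if not extant:
                return None

    for node in extant:
        node.end_time = end_time
        node.alive = True
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = nd.end_time - nd.birth_time

    if death > 0.0:
        for lv in list(tree.leaf_node_iter()):
            if not getattr(lv, "alive", False):
                _prune_dead(lv)
        # a relict stem above the crown of survivors may remain; absorb it
        tree.suppress_unifurcations()

    i = 0
    for lv in tree.preorder_node_iter():
        if lv.is_leaf():
            i += 1
            taxon = dendropy.Taxon(label=f"sp{i:04d}")
            ns.add_taxon(taxon)
            lv.taxon = taxon
    return tree


def _prune_dead(leaf):
    nd = leaf
    while nd.parent_node is not None and len(nd.parent_node.child_nodes()) == 1:
        nd = nd.parent_node
    parent = nd.parent_node
    if parent is not None:
        parent.remove_child(nd)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def _leaf_counts(tree):
    counts = {}
    for nd in tree.postorder_node_iter():
        counts[nd] = 1 if nd.is_leaf() else sum(counts[c] for c in nd.child_nodes())
    return counts


def _min_label(nd):
    return min(lv.taxon.label for lv in nd.leaf_iter())


def _split_clades(seeds, target, counts, min_size=1):
    """Refine a clade cover by always splitting the largest clade, until
    exactly ``target`` disjoint monophyletic clades cover the tips.

    A clade is only split when every resulting child keeps at least
    ``min_size`` tips, so each final clade stays refinable downstream.
    """
    clades = list(seeds)
    while len(clades) < target:
        splittable = [c for c in clades if not c.is_leaf()
                      and all(counts[ch] >= min_size for ch in c.child_nodes())]
        if not splittable:
            raise ValueError(
                f"cannot partition into {target} clades of at least "
                f"{min_size} tips each: no splittable clade left")
        big = max(splittable, key=lambda nd: (counts[nd], _min_label(nd)))
        clades.remove(big)
        clades.extend(big.child_nodes())
    if len(clades) != target:
        raise ValueError(
            f"cannot partition into exactly {target} clades (polytomy overshoot)")
    if any(counts[c] < min_size for c in clades):
        raise ValueError(
            f"cannot partition into {target} clades of at least {min_size} "
            "tips each")
    return sorted(clades, key=_min_label)


def simulate_taxonomy(tree: dendropy.Tree, n_families: int,
                      genera_per_family: int, seed=None) -> pd.DataFrame:
    """Assign monophyletic family and genus labels to every tip.

    Families are ``n_families`` disjoint clades covering all tips (obtained
    by repeatedly splitting the largest clade); each family is refined the
    same way into ``genera_per_family`` genera. The splitting is
    deterministic, so ``seed`` is accepted for interface symmetry only.
    Returns a frame with columns ``species, genus, family, element``.
    """
    counts = _leaf_counts(tree)
    families = _split_clades([tree.seed_node], n_families, counts,
                             min_size=genera_per_family)
    rows = []
    for fi, fam_node in enumerate(families, start=1):
        fam = f"F{fi:02d}"
        genera = _split_clades([fam_node], genera_per_family, counts)
        for gi, gen_node in enumerate(genera, start=1):
            gen = f"{fam}g{gi:02d}"
            for lv in gen_node.leaf_iter():
                rows.append((lv.taxon.label, gen, fam, UNKNOWN_ELEMENT))
    df = pd.DataFrame(rows, columns=["species", "genus", "family", "element"])
    return df.sort_values("species", ignore_index=True)


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """One regional community: sampling structure, size and strength.

    ``strength`` interpolates between pure structure (1) and a uniform draw
    (0): ``round(strength * size)`` members are sampled under the structure,
    the rest uniformly from the remaining pool.
    """

    structure: str
    size: int
    strength: float = 1.0
    seed: int | None = None
    name: str | None = None

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}; "
                             f"expected one of {STRUCTURES}")
        if self.size < 2:
            raise ValueError("community size must be at least 2")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")


def _smallest_clade_with(tree, counts, size):
    best = None
    for nd in tree.postorder_node_iter():
        if counts[nd] >= size:
            key = (counts[nd], _min_label(nd))
            if best is None or key < best[0]:
                best = (key, nd)
    return best[1]


def _greedy_spread(d, pool_idx, k, rng):
    """Greedy maximum-dispersion selection: start from a random tip, then
    repeatedly add the tip with the greatest total patristic distance to the
    tips already chosen (a direct greedy proxy for the NP-hard max-MPD
    subset problem)."""
    chosen = [int(rng.choice(pool_idx))]
    remaining = [i for i in pool_idx if i != chosen[0]]
    sums = d[chosen[0], remaining].copy()
    while len(chosen) < k:
        j = int(np.argmax(sums))
        chosen.append(remaining[j])
        remaining.pop(j)
        sums = np.delete(sums, j) + d[chosen[-1], remaining]
    return chosen


def simulate_communities(tree: dendropy.Tree, specs) -> FloraMatrix:
    """Species-rank presence/absence matrix with one region per spec.

    clustered: members drawn from the smallest clade holding >= size tips;
    overdispersed: greedy maximum-dispersion selection on patristic
    distances; random: uniform without replacement. Each spec's ``strength``
    mixes structured and uniform picks; ``seed`` makes each region
    reproducible.
    """
    ti = TreeIndex(tree)
    labels = np.asarray(ti.labels)
    n = len(labels)
    counts = _leaf_counts(tree)
    d = None
    rows = {}
    for i, spec in enumerate(specs):
        if spec.size > n:
            raise ValueError(f"community size {spec.size} exceeds {n} tips")
        rng = np.random.default_rng(spec.seed)
        k = int(round(spec.strength * spec.size))
        all_idx = np.arange(n)
        if spec.structure == "random":
            chosen = list(rng.choice(all_idx, size=spec.size, replace=False))
        elif spec.structure == "clustered":
            clade = _smallest_clade_with(tree, counts, spec.size)
            clade_idx = ti.indices_of(lv.taxon.label for lv in clade.leaf_iter())
            chosen = list(rng.choice(clade_idx, size=k, replace=False))
        else:  # overdispersed
            if d is None:
                d = ti.patristic()
            chosen = _greedy_spread(d, list(all_idx), k, rng) if k else []
        if len(chosen) < spec.size:
            rest_pool = np.setdiff1d(all_idx, np.asarray(chosen, dtype=int))
            rest = rng.choice(rest_pool, size=spec.size - len(chosen),
                              replace=False)
            chosen = list(chosen) + list(rest)
        name = spec.name or f"R{i + 1}"
        row = np.zeros(n, dtype=np.int8)
        row[np.asarray(chosen, dtype=int)] = 1
        rows[name] = row
    data = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    data.index.name = "region"
    return FloraMatrix(rank="species", data=data)


# ---------------------------------------------------------------------------
# element labels and full datasets
# ---------------------------------------------------------------------------

DEFAULT_ELEMENT_PROPORTIONS = {"tropical": 0.5, "temperate": 0.45,
                               "unknown": 0.05}


def assign_elements(taxonomy: pd.DataFrame, vocab: ElementVocabulary,
                    proportions=None, seed=None) -> pd.DataFrame:
    """Draw one element code per genus from stated super-group proportions.

    Each genus is first assigned to tropical / temperate / unknown (default
    0.5 / 0.45 / 0.05), then a base code is drawn uniformly within the
    matching super-group; every species inherits its genus's code.
    """
    props = dict(DEFAULT_ELEMENT_PROPORTIONS if proportions is None
                 else proportions)
    total = sum(props.values())
    cats = sorted(props)
    weights = np.asarray([props[c] for c in cats], dtype=float) / total
    pools = {"tropical": sorted(vocab.groups["ALL TRO"]),
             "temperate": sorted(vocab.groups["ALL TEM"]),
             "cosmopolitan": ["COSM"], "unknown": [UNKNOWN_ELEMENT]}
    unknown_pool = {c for c in cats if c not in pools}
    if unknown_pool:
        raise ValueError(f"unknown proportion categories: {sorted(unknown_pool)}")

    rng = np.random.default_rng(seed)
    out = taxonomy.copy()
    code_of = {}
    for genus in sorted(out["genus"].unique()):
        cat = cats[int(rng.choice(len(cats), p=weights))]
        code_of[genus] = pools[cat][int(rng.integers(len(pools[cat])))]
    out["element"] = out["genus"].map(code_of)
    return out


def simulate_dataset(n_tips: int = 300, n_families: int = 12,
                     genera_per_family: int = 5, specs=None,
                     element_proportions=None, seed=None):
    """A full synthetic study: tree, taxonomy with elements, three regions.

    The default regions emulate one overdispersed, one random and one
    clustered flora of 40% of the pool each, overlapping freely — the
    qualitative layout the structure and beta stages are designed to
    resolve. Returns ``(tree, TaxonTable)``.
    """
    ss = np.random.SeedSequence(seed)
    s_elem, s1, s2, s3 = (int(s.generate_state(1)[0] % (2**31))
                          for s in ss.spawn(4))
    # not every tree admits an exact family/genus clade partition; reject
    # trees deterministically until one does
    for _ in range(100):
        s_tree = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        tree = simulate_tree(n_tips, model="yule", seed=s_tree)
        try:
            taxonomy = simulate_taxonomy(tree, n_families, genera_per_family)
            break
        except ValueError:
            continue
    else:
        raise ValueError(
            f"no feasible {n_families}x{genera_per_family} taxonomy found "
            f"for trees of {n_tips} tips")
    vocab = ElementVocabulary.default("genus")
    taxonomy = assign_elements(taxonomy, vocab,
                               proportions=element_proportions, seed=s_elem)
    if specs is None:
        size = max(2, int(0.4 * n_tips))
        specs = [
            CommunitySpec("overdispersed", size, strength=0.7, seed=s1,
                          name="south"),
            CommunitySpec("random", size, seed=s2, name="central"),
            CommunitySpec("clustered", size, strength=0.7, seed=s3,
                          name="northwest"),
        ]
    matrix = simulate_communities(tree, specs)
    presence = matrix.data.T  # taxa x regions
    merged = taxonomy.merge(presence, left_on="species", right_index=True,
                            how="left")
    region_cols = list(matrix.regions)
    merged[region_cols] = merged[region_cols].fillna(0).astype(np.int8)
    table = TaxonTable(data=merged, regions=tuple(region_cols))
    return tree, table
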