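"""Megatree grafting, BLADJ-style node dating, and rank-level tree derivation.

Taxa missing from a time-calibrated backbone are bound into their genus (or,
failing that, family) clade under one of three scenarios:

* ``S1`` — attach as a polytomy at the crown node of the smallest containing
  clade, with pendant length equal to that node's age (ultrametricity is
  preserved exactly).
* ``S2`` — attach at a uniformly chosen point within the clade: any internal
  node of the clade, or the midpoint of any pendant edge.
* ``S3`` — attach as in S1, then re-date every node not belonging to the
  original backbone by even age interpolation (:func:`bladj_smooth`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .exceptions import GraftError
from .io import TaxonTable, is_ultrametric

__all__ = [
    "CalibrationTable",
    "GraftReport",
    "graft_taxa",
    "bladj_smooth",
    "collapse_to_rank",
    "prune_to_taxa",
    "set_node_ages",
    "SCENARIOS",
]

logger = logging.getLogger("phyloflora")

SCENARIOS = ("S1", "S2", "S3")


def set_node_ages(tree: dendropy.Tree) -> None:
    """Annotate every node with ``age`` = height above its highest descendant tip.

    On an ultrametric tree this is the node's age in the tree's time units.
    """
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            nd.age = 0.0
        else:
            nd.age = max(c.age + (c.edge.length or 0.0) for c in nd.child_nodes())


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    return tree.clone(depth=1)


def _relabel_namespace(tree: dendropy.Tree) -> None:
    """Rebuild the taxon namespace after surgery so labels stay consistent."""
    ns = dendropy.TaxonNamespace()
    for lv in tree.leaf_node_iter():
        taxon = dendropy.Taxon(label=lv.taxon.label)
        lv.taxon = taxon
        ns.add_taxon(taxon)
    tree.taxon_namespace = ns


def prune_to_taxa(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Copy of ``tree`` retaining only the tips named in ``labels``."""
    labels = set(labels)
    present = {lv.taxon.label for lv in tree.leaf_node_iter()}
    missing = labels - present
    if missing:
        raise KeyError(f"taxa not on tree: {sorted(missing)[:5]}")
    out = _clone(tree)
    taxa = [lv.taxon for lv in out.leaf_node_iter() if lv.taxon.label in labels]
    out.retain_taxa(taxa)
    _relabel_namespace(out)
    return out


# ---------------------------------------------------------------------------
# Calibrations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationTable:
    """Fixed node ages keyed by internal-node label or by a tip set (MRCA)."""

    entries: tuple = ()  # tuple of (key, age); key: str label or frozenset of tips

    def __post_init__(self):
        for key, age in self.entries:
            if age < 0:
                raise GraftError(f"negative calibration age {age} for {key!r}")

    @classmethod
    def from_pairs(cls, pairs) -> "CalibrationTable":
        norm = []
        for key, age in pairs:
            if not isinstance(key, str):
                key = frozenset(key)
            norm.append((key, float(age)))
        return cls(entries=tuple(norm))

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        """CSV columns ``clade,age_myr``; ``clade`` is an internal-node label or
        a ';'-separated tip set whose MRCA is dated."""
        df = pd.read_csv(Path(path), dtype={"clade": str})
        pairs = []
        for _, row in df.iterrows():
            raw = row["clade"].strip()
            key = frozenset(p.strip() for p in raw.split(";")) if ";" in raw else raw
            pairs.append((key, float(row["age_myr"])))
        return cls.from_pairs(pairs)

    def resolve(self, tree: dendropy.Tree) -> dict:
        """Map calibration entries to node objects on ``tree`` -> age."""
        by_label = {}
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and nd.label:
                by_label[nd.label] = nd
        tips = {lv.taxon.label: lv for lv in tree.leaf_node_iter()}
        out = {}
        for key, age in self.entries:
            if isinstance(key, str):
                if key not in by_label:
                    raise GraftError(f"no internal node labelled {key!r}")
                out[by_label[key]] = age
            else:
                missing = key - tips.keys()
                if missing:
                    raise GraftError(f"calibration tips not on tree: {sorted(missing)}")
                out[_crown([tips[t] for t in key])] = age
        return out


# ---------------------------------------------------------------------------
# BLADJ-style smoothing
# ---------------------------------------------------------------------------

def bladj_smooth(tree: dendropy.Tree,
                 calibrations: CalibrationTable | None = None) -> dendropy.Tree:
    """Assign ages to undated internal nodes by even interpolation.

    Dated nodes are tips (age 0), nodes carrying a pre-existing ``age``
    attribute, and nodes named in ``calibrations`` (which override). Each
    undated node is placed on the line between its nearest dated ancestor and
    its nearest dated descendant in proportion to node counts, so that the k
    undated nodes on a chain between two dated nodes split the age interval
    into k+1 equal steps. Edge lengths are rewritten as parent age minus
    child age.
    """
    out = _clone(tree)
    dated: dict = {}
    for nd in out.postorder_node_iter():
        if nd.is_leaf():
            dated[nd] = 0.0
        elif getattr(nd, "age", None) is not None:
            dated[nd] = float(nd.age)
    if calibrations is not None:
        dated.update(calibrations.resolve(out))

    root = out.seed_node
    if root not in dated:
        raise GraftError("root age is not fixed; supply a root calibration")

    # dated ages must not increase from root to tips
    def _check(nd, anc_age):
        if nd in dated:
            if dated[nd] > anc_age + 1e-9:
                raise GraftError(
                    f"calibration conflict: node age {dated[nd]} exceeds "
                    f"ancestor age {anc_age}")
            anc_age = dated[nd]
        for c in nd.child_nodes():
            _check(c, anc_age)

    _check(root, dated[root])

    ages = dict(dated)
    for nd in out.preorder_node_iter():
        if nd in dated:
            continue
        # nearest dated ancestor
        up, k_up = nd.parent_node, 1
        while up not in dated:
            up, k_up = up.parent_node, k_up + 1
        # nearest dated descendant by breadth-first search through undated nodes
        frontier, k_down = list(nd.child_nodes()), 1
        best = None
        while best is None:
            nxt = []
            for c in frontier:
                if c in dated:
                    if best is None or dated[c] > best:
                        best = dated[c]
                else:
                    nxt.extend(c.child_nodes())
            if best is None:
                frontier, k_down = nxt, k_down + 1
        a_up, a_dn = dated[up], best
        ages[nd] = a_up - (a_up - a_dn) * k_up / (k_up + k_down)

    # enforce monotonicity without moving dated nodes: lift undated nodes above
    # their highest child, then clamp them below their parent
    for nd in out.postorder_node_iter():
        if nd not in dated and nd.child_nodes():
            ages[nd] = max(ages[nd], max(ages[c] for c in nd.child_nodes()))
    for nd in out.preorder_node_iter():
        if nd not in dated and nd.parent_node is not None:
            ages[nd] = min(ages[nd], ages[nd.parent_node])
    for nd in out.preorder_node_iter():
        nd.age = ages[nd]
        if nd.parent_node is not None:
            nd.edge.length = ages[nd.parent_node] - ages[nd]
    return out


# ---------------------------------------------------------------------------
# Grafting
# ---------------------------------------------------------------------------

@dataclass
class GraftReport:
    """Bookkeeping of how each non-backbone taxon was bound to the tree.

    The four lists partition the set of input taxa that were not already tips.
    """

    polytomy: tuple = ()
    random: tuple = ()
    bladj: tuple = ()
    unplaced: tuple = ()
    scenario: str = "S1"
    seed: int | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for how, taxa in (("polytomy", self.polytomy), ("random", self.random),
                          ("bladj", self.bladj), ("unplaced", self.unplaced)):
            rows.extend({"taxon": t, "binding": how} for t in taxa)
        return pd.DataFrame(rows, columns=["taxon", "binding"])


def _attach_polytomy(node, label, namespace):
    taxon = dendropy.Taxon(label=label)
    namespace.add_taxon(taxon)
    child = node.new_child(taxon=taxon, edge_length=node.age)
    child.age = 0.0
    return child


def _attach_half_pendant(tip, label, namespace):
    """Insert a node halfway along ``tip``'s pendant edge and attach there."""
    parent = tip.parent_node
    pendant = tip.edge.length
    mid_age = tip.age + pendant / 2.0
    parent.remove_child(tip)
    mid = parent.new_child(edge_length=parent.age - mid_age)
    mid.age = mid_age
    mid.add_child(tip)
    tip.edge.length = mid_age - tip.age
    taxon = dendropy.Taxon(label=label)
    namespace.add_taxon(taxon)
    new_tip = mid.new_child(taxon=taxon, edge_length=mid_age)
    new_tip.age = 0.0
    return new_tip, mid


def _crown(tips):
    """Most recent common ancestor of a list of tip nodes (namespace-free)."""
    if len(tips) == 1:
        return tips[0]

    def root_path(nd):
        path = []
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        path.reverse()
        return path

    paths = [root_path(t) for t in tips]
    mrca = paths[0][0]
    for level in range(min(len(p) for p in paths)):
        first = paths[0][level]
        if all(p[level] is first for p in paths):
            mrca = first
        else:
            break
    return mrca


def graft_taxa(backbone: dendropy.Tree, table: TaxonTable, scenario: str = "S1",
               seed: int | None = None,
               calibrations: CalibrationTable | None = None):
    """Bind the table's species that are absent from the backbone into the tree.

    Returns ``(tree, report)``. The backbone must be ultrametric: the pendant
    length of a grafted tip equals the age of its attachment point, which
    keeps the tree ultrametric. A species joins the crown of its genus when
    congeners are on the tree, otherwise the crown of its family; when the
    containing clade is a single tip, a new node is inserted at half that
    tip's pendant edge. Species whose family has no tips on the tree are
    reported as unplaced.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    if scenario in ("S2", "S3") and seed is None:
        raise GraftError(f"scenario {scenario} requires a seed")
    n_tips = sum(1 for _ in backbone.leaf_node_iter())
    if n_tips == 0:
        raise GraftError("backbone tree has no tips")
    if not is_ultrametric(backbone):
        raise GraftError(
            "backbone is not ultrametric; attachment-node ages are undefined")

    tree = _clone(backbone)
    set_node_ages(tree)
    backbone_nodes = {id(nd) for nd in tree.preorder_node_iter()}

    genus_of = dict(table.genus_of)
    family_of_genus = dict(table.family_of_genus)
    family_of = dict(table.family_of)

    genus_tips: dict = {}
    family_tips: dict = {}
    tip_labels = set()
    for lv in tree.leaf_node_iter():
        lab = lv.taxon.label
        tip_labels.add(lab)
        g = genus_of.get(lab)
        if g is None:
            # fall back to the binomial prefix convention for non-study tips
            g = lab.split("_")[0].split(" ")[0]
        f = family_of.get(lab, family_of_genus.get(g))
        genus_tips.setdefault(g, []).append(lv)
        if f is not None:
            family_tips.setdefault(f, []).append(lv)

    to_add = sorted(set(table.species) - tip_labels)
    rng = np.random.default_rng(seed)
    placed, unplaced = [], []
    namespace = tree.taxon_namespace

    for sp in to_add:
        g, f = genus_of[sp], family_of[sp]
        if g in genus_tips:
            clade_tips = genus_tips[g]
        elif f in family_tips:
            clade_tips = family_tips[f]
        else:
            unplaced.append(sp)
            continue

        if scenario in ("S1", "S3"):
            if len(clade_tips) == 1:
                new_tip, _ = _attach_half_pendant(clade_tips[0], sp, namespace)
            else:
                new_tip = _attach_polytomy(_crown(clade_tips), sp, namespace)
        else:  # S2: uniform choice among internal nodes and pendant midpoints
            crown = _crown(clade_tips)
            internal, pendant = [], []
            if crown.is_leaf():
                pendant.append(crown)
            else:
                for nd in crown.preorder_iter():
                    (pendant if nd.is_leaf() else internal).append(nd)
            candidates = internal + pendant
            choice = candidates[int(rng.integers(len(candidates)))]
            if choice.is_leaf():
                new_tip, _ = _attach_half_pendant(choice, sp, namespace)
            else:
                new_tip = _attach_polytomy(choice, sp, namespace)
        placed.append(sp)
        genus_tips.setdefault(g, []).append(new_tip)
        family_tips.setdefault(f, []).append(new_tip)

    if scenario == "S3":
        # re-date: keep backbone node ages as constraints, free the new nodes
        for nd in tree.preorder_node_iter():
            if id(nd) not in backbone_nodes and not nd.is_leaf():
                nd.age = None
        tree = bladj_smooth(tree, calibrations)

    lists = {"S1": "polytomy", "S2": "random", "S3": "bladj"}
    report = GraftReport(
        scenario=scenario, seed=seed, unplaced=tuple(unplaced),
        **{lists[scenario]: tuple(placed)},
    )
    if unplaced:
        logger.warning("%d taxa could not be placed (family absent from "
                       "backbone): %s", len(unplaced), ", ".join(unplaced[:5]))
    return tree, report


# ---------------------------------------------------------------------------
# Rank-level trees
# ---------------------------------------------------------------------------

def collapse_to_rank(tree: dendropy.Tree, table: TaxonTable,
                     rank: str) -> dendropy.Tree:
    """Derive a rank-level analysis tree with exactly one tip per rank taxon.

    The retained exemplar for each genus/family is the lexicographically
    first of its species present on the tree; other tips are pruned and the
    exemplar is relabelled with the rank-taxon name. At species rank the
    tree is returned unchanged (copy).
    """
    if rank == "species":
        return _clone(tree)
    mapping = table.rank_of(rank)
    tip_labels = [lv.taxon.label for lv in tree.leaf_node_iter()]
    unmapped = [t for t in tip_labels if t not in mapping]
    if unmapped:
        raise KeyError(
            f"tips not mapped to a {rank}: {sorted(unmapped)[:5]}; prune the "
            "tree to the study taxa first")
    groups: dict = {}
    for t in tip_labels:
        groups.setdefault(mapping[t], []).append(t)
    absent = set(mapping.values()) - groups.keys()
    if absent:
        logger.warning("%d %s-rank taxa have no tips on the tree and are "
                       "omitted: %s", len(absent), rank,
                       ", ".join(sorted(absent)[:5]))
    exemplar = {min(tips): name for name, tips in groups.items()}
    out = prune_to_taxa(tree, exemplar.keys())
    for lv in out.leaf_node_iter():
        lv.taxon.label = exemplar[lv.taxon.label]
    return out
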