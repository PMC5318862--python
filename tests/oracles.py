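"""Independent brute-force reference implementations used to check metrics.

These deliberately avoid the package's numeric machinery: distances come
from dendropy's own patristic matrix, spanning subtrees from direct edge
enumeration over node objects, and all means from explicit Python loops.
"""

import itertools


def distance_lookup(tree):
    """dict (label, label) -> patristic distance, via dendropy's own matrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {lv.taxon.label: lv.taxon for lv in tree.leaf_node_iter()}
    out = {}
    for a, b in itertools.product(taxa, taxa):
        out[(a, b)] = 0.0 if a == b else pdm.patristic_distance(taxa[a], taxa[b])
    return out


def mpd_brute(community, dist):
    community = sorted(community)
    total, n = 0.0, 0
    for i, a in enumerate(community):
        for b in community[i + 1:]:
            total += dist[(a, b)]
            n += 1
    return total / n


def mntd_brute(community, dist):
    community = sorted(community)
    total = 0.0
    for a in community:
        total += min(dist[(a, b)] for b in community if b != a)
    return total / len(community)


def dnn_brute(comm_a, comm_b, dist):
    def directional(xs, ys):
        return sum(min(dist[(x, y)] for y in ys) for x in xs) / len(xs)

    return 0.5 * (directional(sorted(comm_a), sorted(comm_b))
                  + directional(sorted(comm_b), sorted(comm_a)))


def _subtree_tip_labels(node):
    return {lv.taxon.label for lv in node.leaf_iter()}


def rooted_pd_brute(tree, tips):
    """Root-inclusive PD by edge enumeration: an edge belongs to the spanning
    subtree iff at least one selected tip descends from it."""
    tips = set(tips)
    total = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if _subtree_tip_labels(nd) & tips:
            total += nd.edge.length
    return total


def phylosor_brute(tree, comm_a, comm_b):
    a, b = set(comm_a), set(comm_b)
    shared = bl_a = bl_b = 0.0
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        below = _subtree_tip_labels(nd)
        in_a, in_b = bool(below & a), bool(below & b)
        if in_a:
            bl_a += nd.edge.length
        if in_b:
            bl_b += nd.edge.length
        if in_a and in_b:
            shared += nd.edge.length
    return shared / (0.5 * (bl_a + bl_b))
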