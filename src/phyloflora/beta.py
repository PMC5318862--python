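"""Between-flora phylogenetic beta diversity: PhyloSor and nearest-neighbor Dnn.

PhyloSor is the Sørensen-type similarity

    PhyloSor = BL_ij / (0.5 * (BL_i + BL_j))

where ``BL_i`` is the branch length of the subtree spanning community *i* and
the root (root-inclusive convention, applied everywhere) and ``BL_ij`` the
total length of edges lying in both spanning subtrees. Dnn is the mean
distance from each taxon of one community to its nearest relative in the
other, symmetrized by averaging the two directions. S.E.S. Dnn follows the
sign-flipped convention: positive values mean the two floras are
phylogenetically *closer* than expected under the tip-shuffle null.
"""

from __future__ import annotations

import itertools
import logging

import dendropy
import numpy as np
import pandas as pd

from ._treeindex import TreeIndex
from .exceptions import MetricUndefinedError
from .io import FloraMatrix
from .structure import DistanceMatrix, _chunk_size, make_permutations, ses_index
from .treebuild import prune_to_taxa

__all__ = ["rooted_pd", "phylosor", "dnn", "analyze_beta"]

logger = logging.getLogger("phyloflora")


def rooted_pd(tree: dendropy.Tree, tips) -> float:
    """Root-inclusive phylogenetic diversity: total branch length of the
    subtree spanning ``tips`` and the root."""
    tips = set(tips)
    if not tips:
        raise MetricUndefinedError("rooted PD of an empty taxon set is undefined")
    ti = TreeIndex(tree)
    return ti.pd_rooted(ti.indices_of(tips))


def phylosor(tree: dendropy.Tree, comm_a, comm_b) -> float:
    """Phylogenetic Sørensen similarity of two communities on one tree."""
    a, b = set(comm_a), set(comm_b)
    if not a or not b:
        raise MetricUndefinedError("PhyloSor is undefined for empty communities")
    ti = TreeIndex(tree)
    ia, ib = ti.indices_of(a), ti.indices_of(b)
    bl_a, bl_b = ti.pd_rooted(ia), ti.pd_rooted(ib)
    shared = ti.shared_length(ia, ib)
    return shared / (0.5 * (bl_a + bl_b))


def _dnn_from_cross(cross: np.ndarray) -> float:
    return 0.5 * (cross.min(axis=1).mean() + cross.min(axis=0).mean())


def dnn(dm: DistanceMatrix, comm_a, comm_b) -> float:
    """Symmetrized mean nearest-neighbor distance between two communities.

    Average of the two directional means (A into B, B into A); shared taxa
    contribute zero.
    """
    a, b = set(comm_a), set(comm_b)
    if not a or not b:
        raise MetricUndefinedError("Dnn is undefined for empty communities")
    ia, ib = dm.indices_of(a), dm.indices_of(b)
    return float(_dnn_from_cross(dm.values[np.ix_(ia, ib)]))


def _null_dnn(d: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
              perms: np.ndarray) -> np.ndarray:
    ka, kb = len(idx_a), len(idx_b)
    out = np.empty(len(perms))
    step = _chunk_size(ka * kb)
    for s in range(0, len(perms), step):
        ma = perms[s:s + step][:, idx_a]
        mb = perms[s:s + step][:, idx_b]
        g = d[ma[:, :, None], mb[:, None, :]]
        out[s:s + step] = 0.5 * (g.min(axis=2).mean(axis=1)
                                 + g.min(axis=1).mean(axis=1))
    return out


def analyze_beta(tree: dendropy.Tree, matrix: FloraMatrix,
                 n_perm: int = 999, seed=None) -> pd.DataFrame:
    """PhyloSor, observed Dnn and S.E.S. Dnn for every pair of regions.

    Tip labels of the matrix's taxa are shuffled on the taxa-pruned tree;
    the same shuffle is reused for every pair within a permutation, which
    preserves between-region overlap under the null (a pair of identical
    regions therefore has a degenerate null and an undefined S.E.S.).
    Regions with no taxa are skipped with a warning. Output columns:
    region_i, region_j, phylosor, bl_shared, bl_i, bl_j, dnn_obs,
    dnn_null_mean, dnn_null_sd, ses_dnn, p, n_perm, degenerate.
    """
    regions = list(matrix.regions)
    if len(regions) < 2:
        raise ValueError("beta diversity requires at least two regions")
    communities = {r: matrix.community(r) for r in regions}
    empty = [r for r in regions if not communities[r]]
    if empty:
        logger.warning("regions with no taxa skipped in beta analysis: %s",
                       ", ".join(empty))
        regions = [r for r in regions if communities[r]]

    pool = sorted(matrix.taxa)
    pruned = prune_to_taxa(tree, pool)
    ti = TreeIndex(pruned)
    d = ti.patristic()
    idx = {r: ti.indices_of(communities[r]) for r in regions}

    rng = np.random.default_rng(seed)
    perms = make_permutations(len(pool), n_perm, rng)
    identity = np.arange(len(pool))[None, :]

    rows = []
    for ra, rb in itertools.combinations(regions, 2):
        ia, ib = idx[ra], idx[rb]
        bl_a, bl_b = ti.pd_rooted(ia), ti.pd_rooted(ib)
        shared = ti.shared_length(ia, ib)
        ps = shared / (0.5 * (bl_a + bl_b))
        obs = _null_dnn(d, ia, ib, identity)[0]
        nulls = _null_dnn(d, ia, ib, perms)
        summ = ses_index(obs, nulls, flip_sign=True)
        rows.append(dict(region_i=ra, region_j=rb, phylosor=ps,
                         bl_shared=shared, bl_i=bl_a, bl_j=bl_b,
                         dnn_obs=summ.observed, dnn_null_mean=summ.null_mean,
                         dnn_null_sd=summ.null_sd, ses_dnn=summ.ses,
                         p=summ.p, n_perm=summ.n_perm,
                         degenerate=summ.degenerate))
    return pd.DataFrame(rows)
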