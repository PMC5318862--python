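"""Within-flora phylogenetic structure: MPD/MNTD and NRI/NTI under tip-shuffle nulls.

The net relatedness index (NRI) and nearest taxon index (NTI) are sign-flipped
standardized effect sizes of the mean pairwise distance (MPD) and the mean
nearest taxon distance (MNTD)::

    NRI = -(MPD_obs  - mean(MPD_null))  / sd(MPD_null)
    NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)

so that positive values indicate phylogenetic clustering (co-occurring taxa
closer than expected) and negative values overdispersion. Null communities
are generated by shuffling the tip labels of the pool-pruned phylogeny; the
same shuffle is shared by all regions within a permutation, which preserves
between-region overlap under the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._treeindex import TreeIndex
from .exceptions import MetricUndefinedError
from .io import FloraMatrix
from .treebuild import prune_to_taxa

__all__ = [
    "DistanceMatrix",
    "NullSummary",
    "patristic_matrix",
    "mpd",
    "mntd",
    "ses_index",
    "analyze_structure",
]

#: relative tolerance when counting null values <= observed (guards float ties)
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric patristic distance matrix with tip labels in fixed order."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")

    @property
    def index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.labels)}

    def indices_of(self, labels) -> np.ndarray:
        idx = self.index
        try:
            return np.asarray(sorted(idx[lab] for lab in labels), dtype=np.intp)
        except KeyError as exc:
            raise KeyError(
                f"taxon {exc.args[0]!r} is not in the distance matrix") from None


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length distances; labels sorted lexicographically."""
    ti = TreeIndex(tree)
    return DistanceMatrix(labels=ti.labels, values=ti.patristic())


def _community_indices(community, dm: DistanceMatrix, metric: str) -> np.ndarray:
    idx = dm.indices_of(community)
    if len(idx) < 2:
        raise MetricUndefinedError(
            f"{metric} is undefined for communities of fewer than two taxa")
    return idx


def mpd(community, dm: DistanceMatrix) -> float:
    """Mean patristic distance over all unordered pairs of community members."""
    idx = _community_indices(community, dm, "MPD")
    sub = dm.values[np.ix_(idx, idx)]
    k = len(idx)
    return float(sub.sum() / (k * (k - 1)))


def mntd(community, dm: DistanceMatrix) -> float:
    """Mean distance from each member to its nearest other community member."""
    idx = _community_indices(community, dm, "MNTD")
    sub = dm.values[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


@dataclass(frozen=True)
class NullSummary:
    """Observed metric with its permutation-null summary.

    ``ses`` is NaN when the null distribution is degenerate (sd = 0); it is
    never reported as infinity.
    """

    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p: float
    n_perm: int
    degenerate: bool


def ses_index(observed: float, nulls, flip_sign: bool = True) -> NullSummary:
    """Standardized effect size of ``observed`` against permutation nulls.

    With ``flip_sign`` (the NRI/NTI and S.E.S. Dnn convention) the SES is
    ``-(observed - mean)/sd`` and the one-sided permutation p-value is
    oriented toward clustering: ``p = (#{null <= observed} + 1)/(n + 1)``.
    """
    nulls = np.asarray(list(nulls), dtype=float)
    n = len(nulls)
    if n == 0:
        raise ValueError("empty null distribution")
    mean = float(nulls.mean())
    sd = float(nulls.std(ddof=1)) if n > 1 else 0.0
    # a null that is constant up to summation-order round-off is degenerate
    degenerate = sd <= _TIE_RTOL * max(1.0, abs(mean))
    if degenerate:
        ses = float("nan")
    else:
        ses = (observed - mean) / sd
        if flip_sign:
            ses = -ses
    tol = _TIE_RTOL * max(1.0, abs(observed))
    if flip_sign:
        count = int((nulls <= observed + tol).sum())
    else:
        count = int((nulls >= observed - tol).sum())
    p = (count + 1) / (n + 1)
    return NullSummary(observed=float(observed), null_mean=mean, null_sd=sd,
                       ses=ses, p=p, n_perm=n, degenerate=degenerate)


# ---------------------------------------------------------------------------
# permutation machinery (shared with the beta module)
# ---------------------------------------------------------------------------

def make_permutations(n_pool: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_pool) array of tip-label permutations of the pool."""
    return np.array([rng.permutation(n_pool) for _ in range(n_perm)])


def _chunk_size(cells_per_perm: int) -> int:
    # bound the scratch tensor around ~32 MB of float64
    return max(1, int(4_000_000 // max(cells_per_perm, 1)))


def null_mpd_mntd(d: np.ndarray, idx: np.ndarray, perms: np.ndarray):
    """MPD and MNTD of the community ``idx`` under each tip permutation."""
    k = len(idx)
    n = len(perms)
    out_mpd = np.empty(n)
    out_mntd = np.empty(n)
    diag = np.arange(k)
    step = _chunk_size(k * k)
    for s in range(0, n, step):
        m = perms[s:s + step][:, idx]
        g = d[m[:, :, None], m[:, None, :]]
        out_mpd[s:s + step] = g.sum(axis=(1, 2)) / (k * (k - 1))
        g[:, diag, diag] = np.inf
        out_mntd[s:s + step] = g.min(axis=2).mean(axis=1)
    return out_mpd, out_mntd


def analyze_structure(tree: dendropy.Tree, matrix: FloraMatrix,
                      pool=None, n_perm: int = 999,
                      seed=None) -> pd.DataFrame:
    """NRI and NTI per region against a shared tip-shuffle null.

    ``pool`` (default: all matrix taxa) is the taxon set whose tip labels are
    shuffled on the pool-pruned tree; every region's community must be a
    subset. Regions with fewer than two taxa are emitted as degenerate rows.
    Output columns: region, metric, observed, null_mean, null_sd, ses, p,
    n_perm, degenerate.
    """
    taxa = set(matrix.taxa)
    pool = sorted(taxa if pool is None else set(pool))
    communities = {r: matrix.community(r) for r in matrix.regions}
    for region, comm in communities.items():
        if not comm <= set(pool):
            raise ValueError(
                f"community of region {region!r} is not contained in the pool")

    rng = np.random.default_rng(seed)
    rows = []
    dm_idx = None
    if len(pool) >= 2:
        pruned = prune_to_taxa(tree, pool)
        ti = TreeIndex(pruned)
        d = ti.patristic()
        dm_idx = {lab: i for i, lab in enumerate(ti.labels)}
        perms = make_permutations(len(pool), n_perm, rng)

    for region in matrix.regions:
        comm = communities[region]
        if len(comm) < 2 or dm_idx is None:
            for metric in ("NRI", "NTI"):
                rows.append(dict(region=region, metric=metric,
                                 observed=np.nan, null_mean=np.nan,
                                 null_sd=np.nan, ses=np.nan, p=np.nan,
                                 n_perm=n_perm, degenerate=True))
            continue
        idx = np.asarray(sorted(dm_idx[t] for t in comm), dtype=np.intp)
        # observed values go through the same numeric path as the nulls
        # (identity permutation) so that exact ties are preserved
        identity = np.arange(len(pool))[None, :]
        obs_mpd, obs_mntd = null_mpd_mntd(d, idx, identity)
        null_mpds, null_mntds = null_mpd_mntd(d, idx, perms)
        for metric, obs, nulls in (("NRI", obs_mpd[0], null_mpds),
                                   ("NTI", obs_mntd[0], null_mntds)):
            summ = ses_index(obs, nulls, flip_sign=True)
            rows.append(dict(region=region, metric=metric,
                             observed=summ.observed, null_mean=summ.null_mean,
                             null_sd=summ.null_sd, ses=summ.ses, p=summ.p,
                             n_perm=summ.n_perm, degenerate=summ.degenerate))
    return pd.DataFrame(rows)
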