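"""Data model and file I/O: Newick trees, taxon tables, synonym maps, flora matrices.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package; this module adds validation (unique tips, branch lengths,
ultrametricity) on top of dendropy's Newick parser, and defines the tabular
containers used by the analysis stages.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .exceptions import NewickError, TaxonTableError

__all__ = [
    "read_newick",
    "read_newick_string",
    "write_newick",
    "is_ultrametric",
    "SynonymMap",
    "TaxonTable",
    "load_taxon_table",
    "FloraMatrix",
    "build_flora_matrix",
    "RANKS",
]

logger = logging.getLogger("phyloflora")

RANKS = ("family", "genus", "species")

UNKNOWN_ELEMENT = "UNKNOWN"

#: tokens that mark infraspecific names; such records are rejected
_INFRASPECIFIC_MARKERS = re.compile(
    r"(^|[\s_])(var\.|subsp\.|ssp\.|f\.|forma|cv\.)([\s_]|$)"
)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def _validate_tree(tree: dendropy.Tree, require_lengths: bool) -> dendropy.Tree:
    labels = [lv.taxon.label for lv in tree.leaf_node_iter()]
    if len(labels) == 0 or (len(labels) == 1 and labels[0] is None):
        raise NewickError("tree has no labelled tips")
    seen = set()
    for lab in labels:
        if lab in seen:
            raise NewickError(f"duplicate tip label {lab!r}")
        seen.add(lab)
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None:
            if require_lengths:
                raise NewickError(
                    "branch length missing on an edge but lengths are required"
                )
        elif nd.edge.length < 0:
            raise NewickError(f"negative branch length {nd.edge.length}")
    tree.is_rooted = True
    return tree


def read_newick_string(newick: str, require_lengths: bool = False) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string.

    Parameters
    ----------
    newick:
        Newick serialisation of one tree.
    require_lengths:
        If true, every edge (except the root edge) must carry a branch length.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick: {exc}") from exc
    return _validate_tree(tree, require_lengths)


def read_newick(path, require_lengths: bool = False) -> dendropy.Tree:
    """Read a rooted tree from a Newick file. See :func:`read_newick_string`."""
    text = Path(path).read_text()
    return read_newick_string(text, require_lengths=require_lengths)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise a tree to Newick; write to ``path`` if given, return the string."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )
    if not s.endswith("\n"):
        s += "\n"
    if path is not None:
        Path(path).write_text(s)
    return s


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True when all root-to-tip path lengths agree within relative tolerance."""
    depths = []
    for lv in tree.leaf_node_iter():
        d = 0.0
        nd = lv
        while nd.parent_node is not None:
            if nd.edge.length is None:
                return False
            d += nd.edge.length
            nd = nd.parent_node
        depths.append(d)
    depths = np.asarray(depths)
    span = depths.max() - depths.min()
    return bool(span <= rel_tol * max(depths.max(), 1e-300))


# ---------------------------------------------------------------------------
# Synonym map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynonymMap:
    """Functional map of verbatim names to accepted names.

    Accepted names are fixed points: applying the map twice equals applying
    it once. Names absent from the map resolve to themselves.
    """

    mapping: dict = field(default_factory=dict)
    unresolved: tuple = ()

    def __post_init__(self):
        for verbatim, accepted in self.mapping.items():
            tgt = self.mapping.get(accepted, accepted)
            if tgt != accepted:
                raise TaxonTableError(
                    f"synonym map is not idempotent: {verbatim!r} -> {accepted!r} "
                    f"-> {tgt!r}; accepted names must be fixed points"
                )

    def resolve(self, name: str) -> str:
        return self.mapping.get(name, name)

    @classmethod
    def from_csv(cls, path) -> "SynonymMap":
        """Load from a CSV with columns ``verbatim,accepted``.

        Rows whose accepted cell is empty are recorded as unresolved and the
        verbatim name resolves to itself.
        """
        df = pd.read_csv(path, dtype=str)
        missing = {"verbatim", "accepted"} - set(df.columns)
        if missing:
            raise TaxonTableError(f"synonym CSV lacks columns: {sorted(missing)}")
        mapping, unresolved = {}, []
        for _, row in df.iterrows():
            verbatim = (row["verbatim"] or "").strip()
            accepted = row["accepted"]
            accepted = "" if pd.isna(accepted) else str(accepted).strip()
            if not verbatim:
                continue
            if not accepted:
                unresolved.append(verbatim)
                continue
            if verbatim in mapping and mapping[verbatim] != accepted:
                raise TaxonTableError(
                    f"synonym map not functional: {verbatim!r} maps to both "
                    f"{mapping[verbatim]!r} and {accepted!r}"
                )
            if verbatim != accepted:
                mapping[verbatim] = accepted
        return cls(mapping=mapping, unresolved=tuple(unresolved))


# ---------------------------------------------------------------------------
# Taxon table
# ---------------------------------------------------------------------------

@dataclass
class TaxonTable:
    """Species records with genus/family assignment, element code, presence flags.

    ``data`` columns: ``species, genus, family, element`` plus one 0/1 column
    per region (order preserved from input).
    """

    data: pd.DataFrame
    regions: tuple

    def __post_init__(self):
        self.regions = tuple(self.regions)

    @property
    def species(self) -> tuple:
        return tuple(self.data["species"])

    @property
    def genus_of(self) -> dict:
        return dict(zip(self.data["species"], self.data["genus"]))

    @property
    def family_of(self) -> dict:
        return dict(zip(self.data["species"], self.data["family"]))

    @property
    def family_of_genus(self) -> dict:
        return dict(zip(self.data["genus"], self.data["family"]))

    def rank_of(self, rank: str) -> dict:
        """species -> name of its taxon at ``rank`` (identity at species rank)."""
        if rank == "species":
            return {s: s for s in self.data["species"]}
        if rank in ("genus", "family"):
            return dict(zip(self.data["species"], self.data[rank]))
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")


def _check_presence(df: pd.DataFrame, regions) -> pd.DataFrame:
    for col in regions:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.isin([0, 1])
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TaxonTableError(
                f"presence cell not in {{0,1}} for region {col!r} at data row {row}"
            )
        df[col] = vals.astype(np.int8)
    return df


def load_taxon_table(path, synonym_map: SynonymMap | None = None,
                     vocabulary=None) -> TaxonTable:
    """Load a taxon table CSV and apply name reconciliation.

    The CSV must have columns ``species, genus, family`` and one column per
    region with 0/1 presence; an ``element`` column is optional (defaults to
    UNKNOWN). Synonyms are replaced by accepted names and duplicate accepted
    names merged by OR-ing presence flags. If a vocabulary is given, element
    codes outside it are reset to UNKNOWN with a warning.
    """
    df = pd.read_csv(path, dtype=str)
    required = {"species", "genus", "family"}
    missing = required - set(df.columns)
    if missing:
        raise TaxonTableError(f"taxon table lacks columns: {sorted(missing)}")
    if "element" not in df.columns:
        df["element"] = UNKNOWN_ELEMENT
    df["element"] = df["element"].fillna(UNKNOWN_ELEMENT)
    regions = [c for c in df.columns
               if c not in ("species", "genus", "family", "element")]
    if not regions:
        raise TaxonTableError("taxon table has no region columns")

    for col in ("species", "genus", "family"):
        df[col] = df[col].fillna("").str.strip()
    for rank_col in ("genus", "family"):
        empty = df[rank_col] == ""
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise TaxonTableError(f"empty {rank_col} at data row {row}")
    bad_names = df["species"].map(
        lambda s: bool(_INFRASPECIFIC_MARKERS.search(s)))
    if bad_names.any():
        offenders = df.loc[bad_names, "species"].tolist()
        raise TaxonTableError(
            "infraspecific taxa are not modelled; remove or collapse these "
            f"names to species: {offenders[:5]}"
        )

    df = _check_presence(df, regions)

    if synonym_map is not None:
        replaced = df["species"].map(synonym_map.resolve)
        n_renamed = int((replaced != df["species"]).sum())
        if n_renamed:
            logger.info("synonym map renamed %d records", n_renamed)
        df["species"] = replaced

    if df["species"].duplicated().any():
        dupes = df.loc[df["species"].duplicated(), "species"].unique()
        logger.info("merging %d duplicate accepted names: %s",
                    len(dupes), ", ".join(dupes[:5]))
        agg = {c: "max" for c in regions}
        agg.update({"genus": "first", "family": "first", "element": "first"})
        df = (df.groupby("species", as_index=False, sort=False)
                .agg(agg)[["species", "genus", "family", "element"] + regions])

    if vocabulary is not None:
        known = set(vocabulary.codes) | {UNKNOWN_ELEMENT}
        bad = ~df["element"].isin(known)
        if bad.any():
            logger.warning(
                "%d records carry element codes outside the vocabulary; "
                "set to UNKNOWN", int(bad.sum()))
            df.loc[bad, "element"] = UNKNOWN_ELEMENT

    df = df.reset_index(drop=True)
    return TaxonTable(data=df, regions=tuple(regions))


# ---------------------------------------------------------------------------
# Flora matrix
# ---------------------------------------------------------------------------

@dataclass
class FloraMatrix:
    """Binary regions-by-taxa incidence matrix at a single rank.

    ``data`` is indexed by region (input order) with lexicographically sorted
    taxon columns and int8 cells in {0, 1}.
    """

    rank: str
    data: pd.DataFrame

    @property
    def regions(self) -> tuple:
        return tuple(self.data.index)

    @property
    def taxa(self) -> tuple:
        return tuple(self.data.columns)

    def community(self, region: str) -> set:
        row = self.data.loc[region]
        return set(row.index[row.to_numpy(dtype=bool)])

    def restrict(self, taxa) -> "FloraMatrix":
        """Matrix restricted to the given taxa (intersection, sorted)."""
        keep = sorted(set(taxa) & set(self.data.columns))
        return FloraMatrix(rank=self.rank, data=self.data[keep])


def build_flora_matrix(table: TaxonTable, rank: str) -> FloraMatrix:
    """Presence/absence matrix at a rank; genus/family presence is the OR over
    constituent species. Taxa absent from every region are dropped (logged)."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    df = table.data
    regions = list(table.regions)
    key = "species" if rank == "species" else rank
    wide = df.groupby(key, sort=True)[regions].max().T  # regions x taxa
    wide = wide.loc[regions]
    empty = wide.columns[(wide.sum(axis=0) == 0).to_numpy()]
    if len(empty):
        logger.warning("dropping %d %s-rank taxa present in no region: %s",
                       len(empty), rank, ", ".join(list(empty)[:5]))
        wide = wide.drop(columns=list(empty))
    wide = wide.astype(np.int8)
    wide.columns.name = None
    wide.index.name = "region"
    return FloraMatrix(rank=rank, data=wide)
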