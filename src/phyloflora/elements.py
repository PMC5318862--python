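"""Geographical-distribution elements: vocabularies and taxon partitioning.

Floristic elements classify genera (or families) by their global
distribution pattern — pantropic, north temperate, endemic, and so on.
Analyses are then run per element group; super-groups pool the tropical or
the temperate base codes (cosmopolitan taxa belong to neither).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .io import UNKNOWN_ELEMENT, TaxonTable

__all__ = ["ElementVocabulary", "partition_by_element"]

logger = logging.getLogger("phyloflora")

ELEMENT_RANKS = ("genus", "family")


@dataclass(frozen=True)
class ElementVocabulary:
    """Element codes at one rank plus super-group definitions.

    Super-groups always include ``ALL TAXA`` (union of all non-inert base
    codes) and ``COSM`` (the cosmopolitan singleton) in addition to the
    groups declared in the vocabulary file.
    """

    rank: str
    codes: dict = field(default_factory=dict)
    supergroups: dict = field(default_factory=dict)
    inert: tuple = ()

    def __post_init__(self):
        if self.rank not in ELEMENT_RANKS:
            raise ValueError(
                f"element vocabularies are defined at ranks {ELEMENT_RANKS}, "
                f"not {self.rank!r}")
        for name, members in self.supergroups.items():
            extra = set(members) - set(self.codes)
            if extra:
                raise ValueError(
                    f"super-group {name!r} references unknown codes {sorted(extra)}")

    @property
    def groups(self) -> dict:
        """All resolvable group names -> set of base codes."""
        out = {code: {code} for code in self.codes if code not in self.inert}
        for name, members in self.supergroups.items():
            out[name] = set(members)
        out.setdefault("ALL TAXA", set(self.codes) - set(self.inert))
        return out

    @classmethod
    def from_dict(cls, rank: str, spec: dict) -> "ElementVocabulary":
        return cls(rank=rank, codes=dict(spec.get("codes", {})),
                   supergroups={k: list(v) for k, v in
                                spec.get("supergroups", {}).items()},
                   inert=tuple(spec.get("inert", ())))

    @classmethod
    def from_yaml(cls, path, rank: str) -> "ElementVocabulary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if rank not in doc:
            raise ValueError(f"vocabulary file has no {rank!r} section")
        return cls.from_dict(rank, doc[rank])

    @classmethod
    def default(cls, rank: str) -> "ElementVocabulary":
        """The packaged vocabulary (genus: 15 codes + inert ESHD; family:
        a documented placeholder set the user can override)."""
        ref = resources.files("phyloflora.data") / "elements.yaml"
        with resources.as_file(ref) as path:
            return cls.from_yaml(path, rank)


def element_codes_at_rank(table: TaxonTable, rank: str) -> dict:
    """Rank-taxon -> element code, from the per-species element column.

    A rank taxon whose species carry conflicting codes is demoted to UNKNOWN
    with a warning (mirrors the exclusion of taxa with unclear distribution).
    """
    if rank not in ELEMENT_RANKS:
        raise ValueError(f"element analyses are defined at ranks "
                         f"{ELEMENT_RANKS}, not {rank!r}")
    out: dict = {}
    conflicts = []
    for taxon, sub in table.data.groupby(rank, sort=True):
        codes = set(sub["element"]) - {UNKNOWN_ELEMENT}
        if len(codes) == 1:
            out[taxon] = next(iter(codes))
        else:
            if len(codes) > 1:
                conflicts.append(taxon)
            out[taxon] = UNKNOWN_ELEMENT
    if conflicts:
        logger.warning("%d %s-rank taxa carry conflicting element codes; "
                       "set to UNKNOWN: %s", len(conflicts), rank,
                       ", ".join(conflicts[:5]))
    return out


def partition_by_element(table: TaxonTable, vocab: ElementVocabulary,
                         group: str) -> set:
    """Taxa (at the vocabulary's rank) whose element code lies in ``group``.

    ``group`` may be a base code or a super-group name. UNKNOWN-coded taxa
    are never returned; their count is logged.
    """
    groups = vocab.groups
    if group not in groups:
        raise ValueError(
            f"unknown element group {group!r}; valid options: "
            f"{sorted(groups)}")
    wanted = groups[group]
    codes = element_codes_at_rank(table, vocab.rank)
    excluded = sum(1 for c in codes.values() if c == UNKNOWN_ELEMENT)
    if excluded:
        logger.info("%d %s-rank taxa with UNKNOWN element excluded from "
                    "group %r", excluded, vocab.rank, group)
    return {taxon for taxon, code in codes.items() if code in wanted}
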