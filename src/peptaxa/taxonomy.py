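"""Fixed-ladder taxonomic lineages and the lowest common ancestor.

Gut-microbiome reference collections such as CGR2 annotate every strain with
a flat eight-level rank table (root, superkingdom, phylum, class, order,
family, genus, species).  This module represents such lineages, normalizes
legacy/current phylum synonyms (Firmicutes vs Bacillota and friends) onto one
vocabulary, and computes the lowest common ancestor (LCA) of a set of
lineages: the deepest rank at which every lineage names the same taxon.

A peptide whose matching proteins span two superkingdoms — or whose LCA lands
exactly at superkingdom — is reported at ``Root``: an annotation that carries
no taxonomic information below the root is treated as uninformative rather
than left blank, so every peptide receives *some* assignment.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "RANKS",
    "SUB_ROOT_RANKS",
    "ROOT_NAME",
    "Lineage",
    "TaxonomicAssignment",
    "lca",
    "normalize_phylum_name",
]

#: Rank ladder from coarsest to finest.  ``root`` is implicit in every lineage.
RANKS: tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Ranks below root, in ladder order — the columns of a lineage table.
SUB_ROOT_RANKS: tuple[str, ...] = RANKS[1:]

ROOT_NAME = "Root"

_PHYLUM_INDEX = RANKS.index("phylum")


def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    src = resources.files("peptaxa.data").joinpath("phylum_synonyms.tsv")
    with src.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            table[row["legacy"]] = row["canonical"]
            table[row["canonical"]] = row["canonical"]
    return table


_PHYLUM_SYNONYMS = _load_synonyms()


def normalize_phylum_name(name: str) -> str:
    """Map a phylum name onto the canonical (current) vocabulary.

    Legacy names (e.g. ``Firmicutes``) become their current equivalents
    (``Bacillota``); canonical names are fixed points; unknown names pass
    through unchanged.
    """
    return _PHYLUM_SYNONYMS.get(name, name)


@dataclass(frozen=True)
class Lineage:
    """An ordered root-to-leaf taxon assignment on the fixed rank ladder.

    ``names[0]`` is always ``Root``; ``names[i]`` is the taxon at ``RANKS[i]``.
    A lineage may terminate early (unranked below some level) but never has
    gaps: ranks are filled contiguously from the root down.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.names or self.names[0] != ROOT_NAME:
            raise ValueError("lineage must start at Root")
        if len(self.names) > len(RANKS):
            raise ValueError(
                f"lineage deeper than the {len(RANKS)}-level rank ladder"
            )
        if any(not n for n in self.names):
            raise ValueError("lineage has a gap (empty taxon above the terminal rank)")

    @classmethod
    def from_ranks(cls, assignment: Mapping[str, str]) -> "Lineage":
        """Build a lineage from a rank→taxon mapping (e.g. a TSV row).

        Empty/missing cells terminate the lineage; a non-empty cell below an
        empty one is a gap and raises ``ValueError``.
        """
        names: list[str] = [ROOT_NAME]
        terminated = False
        for rank in SUB_ROOT_RANKS:
            taxon = (assignment.get(rank) or "").strip()
            if not taxon:
                terminated = True
            elif terminated:
                raise ValueError(
                    f"gap in lineage: rank {rank!r} named but a shallower rank is empty"
                )
            else:
                names.append(taxon)
        return cls(tuple(names))

    @property
    def depth_rank(self) -> str:
        """The deepest rank this lineage resolves to."""
        return RANKS[len(self.names) - 1]

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple(zip(RANKS, self.names))

    def at(self, rank: str) -> str | None:
        """Taxon name at ``rank``, or None if the lineage stops above it."""
        i = RANKS.index(rank)
        return self.names[i] if i < len(self.names) else None

    def normalized(self) -> "Lineage":
        """Return a copy with the phylum name mapped to canonical vocabulary."""
        if len(self.names) <= _PHYLUM_INDEX:
            return self
        names = list(self.names)
        names[_PHYLUM_INDEX] = normalize_phylum_name(names[_PHYLUM_INDEX])
        return Lineage(tuple(names))

    def __str__(self) -> str:  # pipe-joined, root first
        return "|".join(self.names)

    @classmethod
    def parse(cls, text: str) -> "Lineage":
        return cls(tuple(text.split("|")))


@dataclass(frozen=True)
class TaxonomicAssignment:
    """LCA result for one peptide: the resolved taxon, its rank, and the
    lineage prefix ending at that taxon."""

    taxon: str
    rank: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if self.lineage.depth_rank != self.rank:
            raise ValueError("assignment rank must equal the lineage's deepest rank")
        if self.lineage.names[-1] != self.taxon:
            raise ValueError("assignment taxon must terminate the lineage")


_ROOT_ASSIGNMENT = TaxonomicAssignment(ROOT_NAME, "root", Lineage((ROOT_NAME,)))


def lca(lineages: Iterable[Lineage]) -> TaxonomicAssignment:
    """Lowest common ancestor of a non-empty set of lineages.

    Phylum synonyms are normalized first, so e.g. Firmicutes/Bacillota never
    split a group.  The result is the deepest (rank, taxon) on which *all*
    lineages agree.  Agreement only at root or superkingdom reports
    ``(root, "Root")``: a superkingdom-level call is reclassified under Root.
    """
    normed = [lin.normalized() for lin in lineages]
    if not normed:
        raise ValueError("lca of an empty set of lineages is undefined")
    first = normed[0].names
    depth = min(len(lin.names) for lin in normed)
    common = 0  # index of deepest agreeing level
    for i in range(depth):
        if all(lin.names[i] == first[i] for lin in normed[1:]):
            common = i
        else:
            break
    if common <= RANKS.index("superkingdom"):
        return _ROOT_ASSIGNMENT
    prefix = Lineage(first[: common + 1])
    return TaxonomicAssignment(first[common], RANKS[common], prefix)
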