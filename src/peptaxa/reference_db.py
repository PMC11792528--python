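"""Non-redundant protein reference database construction.

Builds a searchable protein database from a collection of per-strain proteome
FASTAs in the style of DBCGR2: proteomes are merged, sequences that are 100%
identical over their full length are collapsed to a single representative
(clustering at 100% identity with full-length coverage reduces to exact
duplicate removal, so this is implemented as hash-based string dedup), and
each retained protein carries its source strain, taxonomic lineage, and
optional KEGG ortholog (KO).

The mapping from every removed (redundant) protein ID to its retained
representative is preserved, so search results produced against the
*pre*-dedup database still resolve.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .taxonomy import SUB_ROOT_RANKS, Lineage

__all__ = [
    "ProteinRecord",
    "ReferenceCollection",
    "merge_proteomes",
    "deduplicate_exact",
    "census_taxa",
    "write_database",
    "read_database",
    "load_taxonomy_table",
    "load_ko_table",
]

_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")
_KO_RE = re.compile(r"^K\d{5}$")


class DatabaseError(ValueError):
    """Raised for malformed inputs or unresolvable annotation."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its source strain, lineage, and optional KO."""

    protein_id: str
    sequence: str
    strain_id: str
    lineage: Lineage
    ko: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatabaseError(f"empty sequence for protein {self.protein_id!r}")
        if not _AA_RE.match(self.sequence):
            raise DatabaseError(
                f"protein {self.protein_id!r}: sequence contains characters "
                "outside the amino-acid alphabet (ACDEFGHIKLMNPQRSTVWY + X)"
            )
        if self.ko is not None and not _KO_RE.match(self.ko):
            raise DatabaseError(
                f"protein {self.protein_id!r}: malformed KO {self.ko!r}"
            )


@dataclass
class ReferenceCollection:
    """A set of protein records plus the redundant→representative ID map."""

    records: list[ProteinRecord]
    dedup_map: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def by_id(self) -> dict[str, ProteinRecord]:
        return {r.protein_id: r for r in self.records}

    @property
    def taxon_census(self) -> dict[str, int]:
        return census_taxa(self)

    def resolve(self, protein_id: str) -> ProteinRecord:
        """Look up a protein by ID, following dedup indirection."""
        rep = self.dedup_map.get(protein_id, protein_id)
        try:
            return self.by_id[rep]
        except KeyError:
            raise DatabaseError(f"unknown protein id {protein_id!r}") from None

    def lineage_map(self) -> dict[str, Lineage]:
        return {r.protein_id: r.lineage for r in self.records}

    def ko_map(self) -> dict[str, str | None]:
        return {r.protein_id: r.ko for r in self.records}


def load_taxonomy_table(path: str | Path) -> tuple[dict[str, Lineage], dict[str, str]]:
    """Read a lineage TSV keyed by strain_id or protein_id.

    Columns: one of ``strain_id``/``protein_id`` (or both), then the ladder
    ranks superkingdom…species.  Returns ``(key → Lineage, protein_id →
    strain_id)``; the second map is empty for strain-keyed tables.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    key_cols = [c for c in ("protein_id", "strain_id") if c in df.columns]
    if not key_cols:
        raise DatabaseError(
            f"{path}: taxonomy table needs a strain_id or protein_id column"
        )
    lineages: dict[str, Lineage] = {}
    strains: dict[str, str] = {}
    for _, row in df.iterrows():
        lin = Lineage.from_ranks(row)
        for col in key_cols:
            if row[col]:
                lineages[row[col]] = lin
        if "protein_id" in df.columns and "strain_id" in df.columns:
            if row["protein_id"] and row["strain_id"]:
                strains[row["protein_id"]] = row["strain_id"]
    return lineages, strains


def load_ko_table(path: str | Path) -> dict[str, str]:
    """Read a two-column (protein_id, ko) TSV; empty KO cells are skipped."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    for col in ("protein_id", "ko"):
        if col not in df.columns:
            raise DatabaseError(f"{path}: KO table missing column {col!r}")
    return {
        row.protein_id: row.ko for row in df.itertuples() if row.ko
    }


def merge_proteomes(
    fasta_paths: Sequence[str | Path],
    taxonomy_table: Mapping[str, Lineage],
    ko_table: Mapping[str, str] | None = None,
    strain_table: Mapping[str, str] | None = None,
) -> ReferenceCollection:
    """Combine per-strain proteome FASTAs into one (pre-dedup) collection.

    Each FASTA record's first header token is its protein_id.  The strain of
    a protein is taken from ``strain_table`` when given, otherwise from the
    FASTA file's stem (one file per strain).  Lineages resolve by protein_id
    first, then by strain_id; any protein that resolves neither way is a hard
    error listing the offending IDs.  Record order is deterministic: file
    order, then record order within each file.
    """
    ko_table = ko_table or {}
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    unresolved: list[str] = []
    for path in fasta_paths:
        path = Path(path)
        file_strain = path.stem
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            pid = rec.id
            if not pid:
                raise DatabaseError(f"{path}: record {i + 1} has no identifier")
            if pid in seen:
                raise DatabaseError(f"duplicate protein id {pid!r} (in {path})")
            seen.add(pid)
            strain = (strain_table or {}).get(pid, file_strain)
            lineage = taxonomy_table.get(pid) or taxonomy_table.get(strain)
            if lineage is None:
                unresolved.append(f"{pid} (strain {strain})")
                continue
            seq = str(rec.seq).upper()
            if not seq:
                raise DatabaseError(f"{path}: empty sequence for {pid!r}")
            records.append(
                ProteinRecord(pid, seq, strain, lineage, ko_table.get(pid))
            )
    if unresolved:
        shown = ", ".join(unresolved[:10])
        more = "" if len(unresolved) <= 10 else f" (+{len(unresolved) - 10} more)"
        raise DatabaseError(f"no taxonomy for: {shown}{more}")
    return ReferenceCollection(records)


def deduplicate_exact(collection: ReferenceCollection) -> ReferenceCollection:
    """Remove sequences that are 100% identical over their full length.

    Exactly one representative is retained per distinct sequence string: the
    record with the lexicographically smallest protein_id among the
    duplicates.  Comparison is on raw strings — no I/L equivalence, and
    ``X``-containing sequences are compared verbatim.  The returned
    collection's dedup_map records every removed ID → its representative,
    composed with any pre-existing map.  Idempotent.
    """
    if not collection.records:
        raise DatabaseError("cannot deduplicate an empty collection")
    rep_for_seq: dict[str, ProteinRecord] = {}
    for rec in collection.records:
        cur = rep_for_seq.get(rec.sequence)
        if cur is None or rec.protein_id < cur.protein_id:
            rep_for_seq[rec.sequence] = rec
    kept_ids = {r.protein_id for r in rep_for_seq.values()}
    records = [r for r in collection.records if r.protein_id in kept_ids]
    dedup_map = {
        r.protein_id: rep_for_seq[r.sequence].protein_id
        for r in collection.records
        if r.protein_id not in kept_ids
    }
    # re-point prior indirections whose representative was itself removed
    for old, rep in collection.dedup_map.items():
        dedup_map[old] = dedup_map.get(rep, rep)
    return ReferenceCollection(records, dedup_map)


def census_taxa(collection: ReferenceCollection) -> dict[str, int]:
    """Distinct taxon names at each sub-root rank over all records' lineages."""
    names: dict[str, set[str]] = {rank: set() for rank in SUB_ROOT_RANKS}
    for rec in collection.records:
        for rank in SUB_ROOT_RANKS:
            taxon = rec.lineage.at(rank)
            if taxon is not None:
                names[rank].add(taxon)
    return {rank: len(found) for rank, found in names.items()}


def _wrap(seq: str, width: int = 60) -> Iterable[str]:
    for i in range(0, len(seq), width):
        yield seq[i : i + width]


def write_database(collection: ReferenceCollection, out_prefix: str | Path) -> dict[str, Path]:
    """Write a deduplicated collection as FASTA + annotation TSVs.

    Emits ``<prefix>.fasta`` (60-char wrapped), ``<prefix>.taxonomy.tsv``
    (protein_id, strain_id, rank columns), ``<prefix>.ko.tsv`` and
    ``<prefix>.dedup.tsv`` (redundant_id, representative_id).  Round-trips
    losslessly through :func:`read_database`.
    """
    if not collection.records:
        raise DatabaseError("refusing to write an empty database")
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "taxonomy": Path(f"{prefix}.taxonomy.tsv"),
        "ko": Path(f"{prefix}.ko.tsv"),
        "dedup": Path(f"{prefix}.dedup.tsv"),
    }
    with open(paths["fasta"], "w") as fa:
        for rec in collection.records:
            fa.write(f">{rec.protein_id}\n")
            for line in _wrap(rec.sequence):
                fa.write(line + "\n")
    tax_rows = []
    for rec in collection.records:
        row = {"protein_id": rec.protein_id, "strain_id": rec.strain_id}
        for rank in SUB_ROOT_RANKS:
            row[rank] = rec.lineage.at(rank) or ""
        tax_rows.append(row)
    pd.DataFrame(tax_rows).to_csv(paths["taxonomy"], sep="\t", index=False)
    pd.DataFrame(
        [
            {"protein_id": r.protein_id, "ko": r.ko or ""}
            for r in collection.records
        ]
    ).to_csv(paths["ko"], sep="\t", index=False)
    pd.DataFrame(
        sorted(collection.dedup_map.items()),
        columns=["redundant_id", "representative_id"],
    ).to_csv(paths["dedup"], sep="\t", index=False)
    return paths


def read_database(prefix: str | Path) -> ReferenceCollection:
    """Load a database written by :func:`write_database`."""
    prefix = Path(prefix)
    lineages, strains = load_taxonomy_table(f"{prefix}.taxonomy.tsv")
    ko = load_ko_table(f"{prefix}.ko.tsv")
    collection = merge_proteomes(
        [prefix.with_suffix(".fasta")], lineages, ko, strain_table=strains
    )
    dedup = pd.read_csv(f"{prefix}.dedup.tsv", sep="\t", dtype=str)
    collection.dedup_map = dict(
        zip(dedup["redundant_id"], dedup["representative_id"])
    )
    return collection
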