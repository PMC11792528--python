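"""Peptide-centric taxonomic annotation (the pepTaxa algorithm).

Every identified peptide maps to a group of database proteins; each protein
carries a full lineage from the reference collection.  The peptide's
taxonomic annotation is the lowest common ancestor (LCA) of those lineages —
the most specific taxon consistent with *all* of its matching proteins.
Because every reference protein has a lineage, every resolvable microbial
peptide receives an assignment: a group spanning phyla still yields
``Root`` rather than no annotation, so annotation coverage is 100% by
construction.

Protein IDs retired by database deduplication are resolved through the
redundant→representative map first, so search results produced against the
pre-dedup database annotate identically.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .peptide_io import PeptideObservation
from .taxonomy import RANKS, Lineage, TaxonomicAssignment, lca

__all__ = [
    "annotate_peptide",
    "annotate_table",
    "rank_distribution",
    "write_annotated_table",
]


class AnnotationError(KeyError):
    """A protein ID in a search result that the database cannot resolve."""


def _group_lineages(
    group: Sequence[str],
    protein_taxonomy: Mapping[str, Lineage],
    dedup_map: Mapping[str, str] | None,
) -> list[Lineage]:
    dedup_map = dedup_map or {}
    lineages = []
    for pid in group:
        rep = dedup_map.get(pid, pid)
        try:
            lineages.append(protein_taxonomy[rep])
        except KeyError:
            raise AnnotationError(
                f"protein id {pid!r} not in the reference taxonomy "
                "(database/result mismatch)"
            ) from None
    return lineages


def annotate_peptide(
    ob: PeptideObservation,
    protein_taxonomy: Mapping[str, Lineage],
    dedup_map: Mapping[str, str] | None = None,
) -> TaxonomicAssignment:
    """LCA taxonomic assignment of one peptide from its protein group."""
    return lca(_group_lineages(ob.protein_group, protein_taxonomy, dedup_map))


def annotate_table(
    observations: Sequence[PeptideObservation],
    protein_taxonomy: Mapping[str, Lineage],
    dedup_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Annotate a batch of (filtered, microbial) peptides.

    Returns one row per peptide, sorted by sequence, with columns
    ``sequence``, ``rank``, ``taxon``, ``lineage`` (pipe-joined from Root)
    and one ``intensity_<sample>`` column per sample.
    """
    samples = sorted({s for ob in observations for s in ob.intensities})
    rows = []
    for ob in sorted(observations, key=lambda o: o.sequence):
        assignment = annotate_peptide(ob, protein_taxonomy, dedup_map)
        row: dict[str, object] = {
            "sequence": ob.sequence,
            "rank": assignment.rank,
            "taxon": assignment.taxon,
            "lineage": str(assignment.lineage),
        }
        for s in samples:
            row[f"intensity_{s}"] = ob.intensity(s)
        rows.append(row)
    columns = ["sequence", "rank", "taxon", "lineage"] + [
        f"intensity_{s}" for s in samples
    ]
    return pd.DataFrame(rows, columns=columns)


def rank_distribution(
    annotated: pd.DataFrame, weight: str = "count"
) -> pd.Series:
    """Fraction of the annotated table resolved at each taxonomic rank.

    ``weight="count"`` counts peptides; ``weight="intensity"`` sums each
    peptide's total intensity over all samples.  Fractions are indexed by the
    full rank ladder (Root first) and sum to 1.
    """
    if annotated.empty:
        raise ValueError("rank_distribution of an empty table")
    if weight == "count":
        weights = pd.Series(1.0, index=annotated.index)
    elif weight == "intensity":
        cols = [c for c in annotated.columns if c.startswith("intensity_")]
        weights = annotated[cols].sum(axis=1)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight")
    by_rank = weights.groupby(annotated["rank"]).sum() / total
    return by_rank.reindex(RANKS, fill_value=0.0).rename("fraction")


def write_annotated_table(annotated: pd.DataFrame, path) -> None:
    annotated.to_csv(path, sep="\t", index=False)
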