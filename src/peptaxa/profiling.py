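"""Intensity-weighted taxonomic profiles, headline ratios, and peptide-set
comparisons.

Community composition is quantified by summed peptide intensity: at a chosen
rank, each peptide contributes its intensity to the taxon its lineage names
at that rank.  Peptides whose LCA is coarser than the requested rank are
kept visible in an explicit ``Unannotated-at-rank`` entry rather than
silently dropped, so total intensity is conserved and testable.  Low-
abundance taxa (default < 2% relative abundance) merge into an ``others``
bin for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .peptide_io import PeptideObservation
from .taxonomy import RANKS, normalize_phylum_name

__all__ = [
    "CompositionProfile",
    "composition_at_rank",
    "composition_table",
    "fb_ratio",
    "mh_ratio",
    "peptide_overlap",
]

UNANNOTATED = "Unannotated-at-rank"
OTHERS = "others"


@dataclass
class CompositionProfile:
    """Relative abundance of taxa at one rank in one sample."""

    rank: str
    sample: str
    entries: dict[str, float] = field(default_factory=dict)
    others: float = 0.0
    total_intensity: float = 0.0

    def fraction(self, taxon: str) -> float:
        if taxon == OTHERS:
            return self.others
        return self.entries.get(taxon, 0.0)


def _intensity_column(annotated: pd.DataFrame, sample: str) -> pd.Series:
    col = f"intensity_{sample}"
    if col not in annotated.columns:
        raise KeyError(f"no intensity column for sample {sample!r}")
    return annotated[col].astype(float)


def composition_at_rank(
    annotated: pd.DataFrame,
    rank: str,
    sample: str,
    others_threshold: float = 0.02,
) -> CompositionProfile:
    """Intensity-weighted taxonomic composition at ``rank`` for ``sample``.

    Peptide intensities aggregate by the taxon each peptide's lineage names
    at ``rank``; LCAs coarser than ``rank`` aggregate under
    ``Unannotated-at-rank`` (never merged into others).  Named taxa with
    relative abundance below ``others_threshold`` merge into ``others``.
    Fractions (entries + others) sum to 1.
    """
    if rank not in RANKS or rank == "root":
        raise ValueError(f"unknown rank {rank!r}")
    depth = RANKS.index(rank)
    intens = _intensity_column(annotated, sample)
    total = intens.sum()
    if annotated.empty or total <= 0:
        raise ValueError(f"no intensity for sample {sample!r}")
    sums: dict[str, float] = {}
    for lineage_str, x in zip(annotated["lineage"], intens):
        names = lineage_str.split("|")
        taxon = names[depth] if len(names) > depth else UNANNOTATED
        sums[taxon] = sums.get(taxon, 0.0) + x
    entries: dict[str, float] = {}
    others = 0.0
    for taxon, x in sums.items():
        frac = x / total
        if taxon != UNANNOTATED and frac < others_threshold:
            others += frac
        else:
            entries[taxon] = frac
    return CompositionProfile(rank, sample, entries, others, float(total))


def composition_table(
    annotated: pd.DataFrame,
    rank: str,
    samples: Sequence[str],
    others_threshold: float = 0.02,
) -> pd.DataFrame:
    """Tidy per-sample composition: columns (sample, rank, taxon, fraction)."""
    rows = []
    for sample in samples:
        prof = composition_at_rank(annotated, rank, sample, others_threshold)
        for taxon, frac in sorted(prof.entries.items()):
            rows.append(
                {"sample": sample, "rank": rank, "taxon": taxon, "fraction": frac}
            )
        if prof.others > 0:
            rows.append(
                {"sample": sample, "rank": rank, "taxon": OTHERS, "fraction": prof.others}
            )
    return pd.DataFrame(rows, columns=["sample", "rank", "taxon", "fraction"])


def _phylum_intensity(annotated: pd.DataFrame, sample: str, phylum: str) -> float:
    depth = RANKS.index("phylum")
    intens = _intensity_column(annotated, sample)
    target = normalize_phylum_name(phylum)
    total = 0.0
    for lineage_str, x in zip(annotated["lineage"], intens):
        names = lineage_str.split("|")
        if len(names) > depth and normalize_phylum_name(names[depth]) == target:
            total += x
    return total


def fb_ratio(annotated: pd.DataFrame, sample: str) -> float:
    """Firmicutes/Bacteroidetes (Bacillota/Bacteroidota) intensity ratio.

    Summed intensity of peptides whose lineage contains phylum Bacillota
    divided by the same for Bacteroidota, with synonym names normalized
    first.  Zero Bacteroidota intensity makes the ratio undefined (error).
    """
    bacillota = _phylum_intensity(annotated, sample, "Bacillota")
    bacteroidota = _phylum_intensity(annotated, sample, "Bacteroidota")
    if bacteroidota <= 0:
        raise ZeroDivisionError(
            f"no Bacteroidota intensity in sample {sample!r}: F/B ratio undefined"
        )
    return bacillota / bacteroidota


def mh_ratio(
    observations: Sequence[PeptideObservation], sample: str
) -> float:
    """Summed microbial ÷ summed host peptide intensity in one sample.

    Observations must be origin-classified; the ambiguous class is excluded
    from both numerator and denominator.
    """
    microbial = host = 0.0
    for ob in observations:
        if ob.origin_class is None:
            raise ValueError("observations must be origin-classified first")
        if ob.origin_class == "microbial":
            microbial += ob.intensity(sample)
        elif ob.origin_class == "host":
            host += ob.intensity(sample)
    if host <= 0:
        raise ZeroDivisionError(
            f"no host intensity in sample {sample!r}: M/H ratio undefined"
        )
    return microbial / host


def peptide_overlap(result_sets: Mapping[str, set[str]]) -> dict[str, int]:
    """Venn-partition counts for ≥2 named peptide sets.

    Region keys are "&"-joined sorted set names — e.g. for sets A and B the
    keys are ``A`` (A only), ``B``, and ``A&B`` (shared).  Every region of
    the partition is reported, including empty ones; counts sum to the size
    of the union.
    """
    if len(result_sets) < 2:
        raise ValueError("peptide_overlap needs at least two sets")
    names = sorted(result_sets)
    membership: dict[str, frozenset[str]] = {}
    for name in names:
        for pep in result_sets[name]:
            membership[pep] = membership.get(pep, frozenset()) | {name}
    counts: dict[str, int] = {}
    # all non-empty subsets of names, in a stable order
    for mask in range(1, 2 ** len(names)):
        subset = frozenset(n for i, n in enumerate(names) if mask >> i & 1)
        key = "&".join(sorted(subset))
        counts[key] = 0
    for region in membership.values():
        counts["&".join(sorted(region))] += 1
    return counts
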