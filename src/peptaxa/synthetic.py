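"""Synthetic miniature gut-metaproteome fixtures with known ground truth.

Generates a small CGR2-like reference — a taxonomy tree on the fixed
eight-rank ladder, per-strain proteomes with planted exact duplicates and
ortholog families shared across strains — together with a matching
MaxQuant-dialect peptide table (tryptic peptides, log-normal intensities,
host-proteome and decoy/contaminant rows) and per-peptide truth tables
(source strains, true LCA, true consensus KO).  Every stage of the pipeline
is thereby testable without downloading reference genomes.

Ortholog families drive LCA coarsening: the family's member proteins in
different strains are mutated copies of one base sequence, with mutations
restricted to non-K/R/P positions (and non-K/R/P replacements) so the
tryptic cleavage structure is preserved — unmutated fragments are exactly
shared across the family, producing peptides whose protein groups span
strains, species, genera, or phyla.  Unmutated member copies are exact
duplicates, exercising database deduplication.

Truth values are computed by code paths independent of the package's
annotation modules (a local longest-common-prefix LCA and a local consensus
rule), so end-to-end agreement is a real check, not a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _mzparser

from .reference_db import ProteinRecord, ReferenceCollection
from .taxonomy import RANKS, ROOT_NAME, SUB_ROOT_RANKS, Lineage

__all__ = [
    "SimulationConfig",
    "simulate_reference",
    "digest_tryptic",
    "simulate_peptide_table",
    "simulate_ko_pathway_table",
    "write_simulation",
]

_TRYPSIN_RULE = r"[KR](?=[^P])"  # cleave after K/R except before P

_PHYLUM_POOL = (
    "Bacillota",
    "Bacteroidota",
    "Actinomycetota",
    "Pseudomonadota",
    "Verrucomicrobiota",
    "Fusobacteriota",
)

_RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# elevated K/R frequency yields realistic tryptic peptide lengths
_RESIDUE_P = np.array(
    [0.055 if r not in "KRP" else (0.07 if r in "KR" else 0.03) for r in _RESIDUES]
)
_RESIDUE_P /= _RESIDUE_P.sum()
_NON_KRP = np.array([r for r in _RESIDUES if r not in "KRP"])

_SPREAD_RANKS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic data set.

    The tree is a balanced hierarchy: ``n_phyla`` phyla, each branching by
    the per-rank factors below, ending in ``strains_per_species`` strains.
    ``shared_protein_fraction`` is the probability that a protein belongs to
    a cross-strain ortholog family (driving LCA coarsening); trypsin
    digestion allows up to ``missed_cleavages_max`` missed cleavages
    (default two, the usual search setting) and peptides of 7–30 residues.
    Intensities are log-normal on the raw MS scale (median ≈ 9e6 at the
    default ``intensity_mu``).
    """

    n_phyla: int = 4
    classes_per_phylum: int = 1
    orders_per_class: int = 1
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 1
    proteins_per_strain: int = 12
    protein_length: tuple[int, int] = (120, 360)
    shared_protein_fraction: float = 0.25
    duplicate_copy_rate: float = 0.25  # chance a shared-family member is unmutated
    mutation_rate: float = 0.02
    missed_cleavages_max: int = 2
    peptide_length_range: tuple[int, int] = (7, 30)
    n_peptides: int | None = 600
    host_fraction: float = 0.1
    n_host_proteins: int = 6
    intensity_mu: float = 16.0
    intensity_sigma: float = 1.5
    dropout_rate: float = 0.1
    n_samples: int = 8
    n_groups: int = 2
    decoy_rate: float = 0.05
    contaminant_rate: float = 0.02
    n_kos: int = 30
    ko_agreement: float = 0.8
    ko_missing_rate: float = 0.2
    n_pathways: int = 10
    kos_per_pathway: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "shared_protein_fraction",
            "duplicate_copy_rate",
            "mutation_rate",
            "host_fraction",
            "dropout_rate",
            "decoy_rate",
            "contaminant_rate",
            "ko_agreement",
            "ko_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        sizes = (
            self.n_phyla,
            self.classes_per_phylum,
            self.orders_per_class,
            self.families_per_order,
            self.genera_per_family,
            self.species_per_genus,
            self.strains_per_species,
            self.proteins_per_strain,
        )
        if any(s < 1 for s in sizes):
            raise ValueError("tree sizes and proteins_per_strain must be ≥ 1")

    @property
    def samples(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]

    @property
    def groups(self) -> dict[str, str]:
        per = max(1, -(-self.n_samples // self.n_groups))
        return {s: f"G{i // per + 1}" for i, s in enumerate(self.samples)}


def digest_tryptic(
    sequence: str,
    missed_max: int = 2,
    length_range: tuple[int, int] | None = (7, 30),
) -> list[str]:
    """In-silico tryptic digest: cleave after K/R except before P.

    Emits every fragment carrying 0..``missed_max`` missed cleavages, filtered
    to ``length_range`` (inclusive; None disables the filter), ordered by
    start position then span.  An empty sequence yields an empty list.
    """
    if not sequence:
        return []
    lo, hi = length_range if length_range is not None else (1, len(sequence))
    frags = [
        (start, pep)
        for start, pep in _mzparser.icleave(
            sequence,
            _TRYPSIN_RULE,
            missed_cleavages=missed_max,
            min_length=lo,
            max_length=hi,
            regex=True,
        )
    ]
    frags.sort(key=lambda t: (t[0], len(t[1])))
    return [pep for _, pep in frags]


def _random_protein(rng: np.random.Generator, length_range: tuple[int, int]) -> str:
    n = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(rng.choice(_RESIDUES, size=n, p=_RESIDUE_P))


def _mutate(rng: np.random.Generator, base: str, rate: float) -> str:
    """Substitute ~rate of the non-K/R/P positions with non-K/R/P residues,
    preserving the cleavage-site structure of ``base``."""
    positions = [i for i, r in enumerate(base) if r not in "KRP"]
    if not positions:
        return base
    k = max(1, int(round(rate * len(positions))))
    chosen = rng.choice(len(positions), size=min(k, len(positions)), replace=False)
    seq = list(base)
    for idx in chosen:
        pos = positions[idx]
        options = _NON_KRP[_NON_KRP != seq[pos]]
        seq[pos] = str(rng.choice(options))
    return "".join(seq)


def _build_tree(config: SimulationConfig) -> dict[str, Lineage]:
    """strain_id → Lineage over a balanced tree with deterministic names."""
    lineages: dict[str, Lineage] = {}
    counter = 0
    for p in range(config.n_phyla):
        phylum = (
            _PHYLUM_POOL[p] if p < len(_PHYLUM_POOL) else f"Phylum{p + 1}"
        )
        for c in range(config.classes_per_phylum):
            cls = f"{phylum}_c{c + 1}"
            for o in range(config.orders_per_class):
                order = f"{cls}_o{o + 1}"
                for f in range(config.families_per_order):
                    fam = f"{order}_f{f + 1}"
                    for g in range(config.genera_per_family):
                        genus = f"{fam}_g{g + 1}"
                        for s in range(config.species_per_genus):
                            species = f"{genus}_sp{s + 1}"
                            for _ in range(config.strains_per_species):
                                counter += 1
                                strain = f"S{counter:03d}"
                                lineages[strain] = Lineage(
                                    (
                                        ROOT_NAME,
                                        "Bacteria",
                                        phylum,
                                        cls,
                                        order,
                                        fam,
                                        genus,
                                        species,
                                    )
                                )
    return lineages


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ReferenceCollection, dict]:
    """Generate the pre-dedup reference collection plus ground truth.

    Returns ``(collection, truth)`` where truth holds the strain taxonomy,
    the protein→KO table, and a families table (protein_id, family_id,
    mutated) from which the planted exact duplicates can be derived.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    strain_lineages = _build_tree(config)
    strains = list(strain_lineages)
    ancestors: dict[str, dict[str, str]] = {
        st: {rank: strain_lineages[st].at(rank) for rank in _SPREAD_RANKS}
        for st in strains
    }
    ko_pool = [f"K{i + 1:05d}" for i in range(config.n_kos)]

    slots = {st: config.proteins_per_strain for st in strains}
    next_idx = {st: 0 for st in strains}
    records: list[ProteinRecord] = []
    family_rows: list[dict] = []
    family_id = 0
    for st in strains:
        while slots[st] > 0:
            family_id += 1
            shared = (
                config.shared_protein_fraction > 0
                and rng.random() < config.shared_protein_fraction
            )
            if shared:
                rank = _SPREAD_RANKS[int(rng.integers(len(_SPREAD_RANKS)))]
                node = ancestors[st][rank]
                members = [
                    m
                    for m in strains
                    if ancestors[m][rank] == node and (m == st or slots[m] > 0)
                ]
            else:
                members = [st]
            base = _random_protein(rng, config.protein_length)
            if rng.random() < config.ko_agreement:
                family_kos = {m: str(rng.choice(ko_pool)) for m in members}
                shared_ko = family_kos[members[0]]
                family_kos = {m: shared_ko for m in members}
            else:
                family_kos = {
                    m: (
                        None
                        if rng.random() < config.ko_missing_rate
                        else str(rng.choice(ko_pool))
                    )
                    for m in members
                }
            for j, m in enumerate(members):
                mutated = j > 0 and rng.random() >= config.duplicate_copy_rate
                seq = _mutate(rng, base, config.mutation_rate) if mutated else base
                next_idx[m] += 1
                pid = f"{m}_P{next_idx[m]:04d}"
                records.append(
                    ProteinRecord(pid, seq, m, strain_lineages[m], family_kos[m])
                )
                family_rows.append(
                    {"protein_id": pid, "family_id": family_id, "mutated": mutated}
                )
                slots[m] -= 1
    records.sort(key=lambda r: r.protein_id)
    truth = {
        "strain_lineages": strain_lineages,
        "ko_table": {r.protein_id: r.ko for r in records if r.ko},
        "families": pd.DataFrame(family_rows).sort_values("protein_id").reset_index(drop=True),
    }
    return ReferenceCollection(records), truth


def _truth_lca(name_vectors: Sequence[Sequence[str]]) -> tuple[str, str]:
    """Independent longest-common-prefix LCA on lineage name vectors,
    with superkingdom-level agreement reported at Root."""
    depth = min(len(v) for v in name_vectors)
    common = 0
    for i in range(depth):
        if len({v[i] for v in name_vectors}) == 1:
            common = i
        else:
            break
    if common <= 1:  # root or superkingdom → Root
        return "root", ROOT_NAME
    return RANKS[common], name_vectors[0][common]


def _truth_consensus_ko(kos: Sequence[str | None]) -> str | None:
    distinct = set(kos)
    if len(distinct) == 1 and None not in distinct:
        return next(iter(distinct))
    return None


def _digest_index(
    records: Sequence[ProteinRecord], config: SimulationConfig
) -> dict[str, list[str]]:
    index: dict[str, list[str]] = {}
    for rec in records:
        for pep in set(
            digest_tryptic(
                rec.sequence, config.missed_cleavages_max, config.peptide_length_range
            )
        ):
            index.setdefault(pep, []).append(rec.protein_id)
    return index


def simulate_peptide_table(
    reference: ReferenceCollection, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit a MaxQuant-dialect ``peptides.txt`` table plus per-peptide truth.

    Protein groups list *all* reference (pre-dedup) proteins whose digest
    contains the peptide.  Intensities are log-normal with a per-peptide
    offset; a ``dropout_rate`` fraction quantify as 0 per sample.  Host
    peptides come from a small synthetic host proteome (``HOST_*`` IDs);
    decoy rows are reversed microbial peptides flagged ``Reverse +`` and
    contaminant rows are flagged ``Potential contaminant +``.

    Truth columns: peptide, origin, proteins, true_strains, true_rank,
    true_taxon, true_ko — LCA and KO computed by independent local rules.
    ``true_strains`` lists every source strain of the pre-dedup group; the
    true LCA and KO are computed over the *deduplicated* representatives
    (smallest protein_id per identical sequence, collapsed inline here),
    because that is all the information the searched non-redundant database
    retains.
    """
    rng = np.random.default_rng([config.seed, 1])
    by_id = reference.by_id
    # independent exact-duplicate collapse: smallest id per sequence string
    rep_of_seq: dict[str, str] = {}
    for rec in reference.records:
        cur = rep_of_seq.get(rec.sequence)
        if cur is None or rec.protein_id < cur:
            rep_of_seq[rec.sequence] = rec.protein_id
    representative = {
        rec.protein_id: rep_of_seq[rec.sequence] for rec in reference.records
    }
    index = _digest_index(reference.records, config)
    microbial = sorted(index)
    if config.n_peptides is not None and len(microbial) > config.n_peptides:
        pick = rng.choice(len(microbial), size=config.n_peptides, replace=False)
        microbial = [microbial[i] for i in sorted(pick)]

    host_records = [
        (f"HOST_P{i + 1:02d}", _random_protein(rng, (250, 500)))
        for i in range(config.n_host_proteins)
    ]
    host_index: dict[str, list[str]] = {}
    for pid, seq in host_records:
        for pep in set(
            digest_tryptic(seq, config.missed_cleavages_max, config.peptide_length_range)
        ):
            if pep not in index:  # keep microbial/host truth unambiguous
                host_index.setdefault(pep, []).append(pid)
    host_pool = sorted(host_index)
    n_host = int(round(config.host_fraction * len(microbial) / max(1e-9, 1 - config.host_fraction)))
    n_host = min(n_host, len(host_pool))
    host_pick = rng.choice(len(host_pool), size=n_host, replace=False)
    host_peps = [host_pool[i] for i in sorted(host_pick)]

    samples = config.samples

    def intensity_row(row: dict) -> None:
        offset = rng.normal(0.0, 0.5)
        for s in samples:
            if rng.random() < config.dropout_rate:
                row[f"Intensity {s}"] = 0.0
            else:
                row[f"Intensity {s}"] = float(
                    rng.lognormal(config.intensity_mu + offset, config.intensity_sigma)
                )

    rows: list[dict] = []
    truth_rows: list[dict] = []
    for pep in microbial:
        group = sorted(index[pep])
        row = {"Sequence": pep, "Proteins": ";".join(group), "Reverse": "", "Potential contaminant": ""}
        intensity_row(row)
        rows.append(row)
        reps = sorted({representative[p] for p in group})
        vectors = [list(by_id[p].lineage.names) for p in reps]
        rank, taxon = _truth_lca(vectors)
        truth_rows.append(
            {
                "peptide": pep,
                "origin": "microbial",
                "proteins": ";".join(group),
                "true_strains": ";".join(sorted({by_id[p].strain_id for p in group})),
                "true_rank": rank,
                "true_taxon": taxon,
                "true_ko": _truth_consensus_ko([by_id[p].ko for p in reps]) or "",
            }
        )
    for pep in host_peps:
        group = sorted(host_index[pep])
        row = {"Sequence": pep, "Proteins": ";".join(group), "Reverse": "", "Potential contaminant": ""}
        intensity_row(row)
        rows.append(row)
        truth_rows.append(
            {
                "peptide": pep,
                "origin": "host",
                "proteins": ";".join(group),
                "true_strains": "",
                "true_rank": "",
                "true_taxon": "",
                "true_ko": "",
            }
        )

    n_real = len(rows)
    n_decoy = int(round(config.decoy_rate * n_real))
    forward = set(microbial) | set(host_peps)
    decoys: list[str] = []
    for i in sorted(rng.choice(len(microbial), size=min(n_decoy * 2, len(microbial)), replace=False)):
        rev = microbial[i][::-1]
        if rev not in forward and rev not in decoys:
            decoys.append(rev)
        if len(decoys) == n_decoy:
            break
    for j, pep in enumerate(decoys):
        row = {
            "Sequence": pep,
            "Proteins": f"REV__D{j + 1:03d}",
            "Reverse": "+",
            "Potential contaminant": "",
        }
        intensity_row(row)
        rows.append(row)
    n_contam = int(round(config.contaminant_rate * n_real))
    for j in range(n_contam):
        pep = "".join(rng.choice(_NON_KRP, size=int(rng.integers(8, 20)))) + "K"
        row = {
            "Sequence": pep,
            "Proteins": f"CON__P{j + 1:03d}",
            "Reverse": "",
            "Potential contaminant": "+",
        }
        intensity_row(row)
        rows.append(row)

    columns = ["Sequence", "Proteins", "Reverse", "Potential contaminant"] + [
        f"Intensity {s}" for s in samples
    ]
    table = pd.DataFrame(rows, columns=columns)
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "peptide",
            "origin",
            "proteins",
            "true_strains",
            "true_rank",
            "true_taxon",
            "true_ko",
        ],
    )
    return table, truth


def simulate_ko_pathway_table(config: SimulationConfig) -> pd.DataFrame:
    """Random KO→pathway membership over the simulation's KO pool."""
    rng = np.random.default_rng([config.seed, 2])
    ko_pool = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    rows = []
    for p in range(config.n_pathways):
        pid = f"path:ko{p + 1:05d}"
        size = min(config.kos_per_pathway, len(ko_pool))
        for i in sorted(rng.choice(len(ko_pool), size=size, replace=False)):
            rows.append(
                {"ko": ko_pool[i], "pathway_id": pid, "pathway_name": f"Pathway {p + 1}"}
            )
    return pd.DataFrame(rows, columns=["ko", "pathway_id", "pathway_name"])


def write_simulation(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a full fixture set: per-strain FASTAs, annotation tables,
    ``peptides.txt``, KO→pathway table, and truth tables."""
    out = Path(out_dir)
    (out / "proteomes").mkdir(parents=True, exist_ok=True)
    reference, truth = simulate_reference(config)
    by_strain: dict[str, list[ProteinRecord]] = {}
    for rec in reference.records:
        by_strain.setdefault(rec.strain_id, []).append(rec)
    for strain, recs in by_strain.items():
        with open(out / "proteomes" / f"{strain}.fasta", "w") as fh:
            for rec in recs:
                fh.write(f">{rec.protein_id}\n")
                for i in range(0, len(rec.sequence), 60):
                    fh.write(rec.sequence[i : i + 60] + "\n")
    tax_rows = [
        {"strain_id": st, **{r: lin.at(r) or "" for r in SUB_ROOT_RANKS}}
        for st, lin in truth["strain_lineages"].items()
    ]
    paths = {
        "proteome_dir": out / "proteomes",
        "taxonomy": out / "taxonomy.tsv",
        "ko": out / "ko.tsv",
        "peptides": out / "peptides.txt",
        "ko_pathway": out / "ko_pathway.tsv",
        "truth_peptides": out / "truth_peptides.tsv",
        "truth_families": out / "truth_families.tsv",
    }
    pd.DataFrame(tax_rows).to_csv(paths["taxonomy"], sep="\t", index=False)
    pd.DataFrame(
        [{"protein_id": pid, "ko": ko} for pid, ko in sorted(truth["ko_table"].items())]
    ).to_csv(paths["ko"], sep="\t", index=False)
    table, pep_truth = simulate_peptide_table(reference, config)
    table.to_csv(paths["peptides"], sep="\t", index=False)
    simulate_ko_pathway_table(config).to_csv(paths["ko_pathway"], sep="\t", index=False)
    pep_truth.to_csv(paths["truth_peptides"], sep="\t", index=False)
    truth["families"].to_csv(paths["truth_families"], sep="\t", index=False)
    return paths
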