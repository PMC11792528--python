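# peptaxa

Peptide-centric taxonomic and functional annotation for gut-microbiome
metaproteomics.

In bottom-up metaproteomics, a search engine matches tandem-MS spectra
against a protein database and reports, for each identified peptide, the
*group* of database proteins it is consistent with. When the database is
built from cultivated reference genomes — every entry carrying a full
taxonomic lineage and a KEGG ortholog (KO) — the peptide itself becomes the
unit of annotation. `peptaxa` implements that workflow:

1. **Reference database construction** — merge per-strain proteome FASTAs
   into one collection and remove sequences that are 100% identical over
   their full length, keeping a map from every removed ID to its retained
   representative.
2. **Taxonomic annotation** — assign each peptide the **lowest common
   ancestor (LCA)** of its protein group's lineages on the fixed ladder
   root → superkingdom → phylum → class → order → family → genus → species.
   Because every reference protein has a lineage, *every* peptide receives
   an assignment; groups that agree only at superkingdom (or not at all)
   report `Root`. Legacy/current phylum synonyms (Firmicutes/Bacillota,
   Bacteroidetes/Bacteroidota, …) are normalized before the LCA so they
   never split a group.
3. **Functional annotation** — a peptide inherits a KO only under **strict
   consensus**: all group members must carry the same KO; any disagreement
   or missing KO leaves it unmapped. Mapped peptides join KO→pathway
   membership to form pathway peptide sets, scored per sample with a
   GSVA-style rank-based enrichment statistic and tested for group effects
   (one-way ANOVA + Benjamini–Hochberg).
4. **Profiling** — intensity-weighted taxonomic composition at any rank
   (with an explicit `Unannotated-at-rank` entry and an `others` bin below a
   2% default threshold), the Bacillota/Bacteroidota (F/B) intensity ratio,
   the microbe/host (M/H) intensity ratio, and Venn overlaps of peptide
   sets from different searches.

A fully seeded synthetic-data module generates miniature reference
collections and matching MaxQuant-dialect `peptides.txt` tables with known
per-peptide ground truth, so the entire pipeline is testable end to end
without downloading genomes.

## The core statistic

For a peptide *q* with protein group *G(q)* and per-protein lineages
ℓ(p) = (root, …, species), the assignment is

    taxon(q) = LCA{ ℓ(p) : p ∈ G(q) }

the deepest rank at which all lineages name the same taxon (name-based
agreement on a flat eight-rank table). For pathway enrichment, intensities
x are transformed to log2(x+1) and ranked within each sample; with
symmetric rank statistic r_i = rank_i − (p+1)/2, a KS-like random walk over
the list ordered by decreasing expression takes steps +|r_i|^τ / Σ_set|r|^τ
inside the set (τ = 1) and −1/(p−m) outside; the enrichment score is the
walk's signed maximum deviation, bounded in [−1, 1].

## Worked example

Generate a synthetic study (32 strains, 4 phyla, 8 samples), build the
database, and annotate:

```
$ peptaxa simulate --seed 1 --out-dir sim
$ peptaxa build-db --fasta-dir sim/proteomes --taxonomy sim/taxonomy.tsv \
      --ko sim/ko.tsv --out-prefix db
384 sequences merged; 347 non-redundant retained
census: 32 species, 16 genus, 8 family, 4 phylum

$ peptaxa annotate --peptides sim/peptides.txt --db-prefix db --out annotated.tsv
600 microbial peptides annotated (100% coverage)
  order: 10.5%
  family: 2.8%
  genus: 0.8%
  species: 85.8%

$ peptaxa ko-map --peptides sim/peptides.txt --db-prefix db --out pep2ko.tsv
587/667 peptides consensus-mapped to a KO
```

The 384 simulated proteins collapse to 347 non-redundant sequences (37
planted exact duplicates removed). Every one of the 600 microbial peptides
gets a taxonomic rank: most resolve to species, while peptides from
ortholog families shared across strains coarsen to genus, family or order —
exactly the LCA behavior the annotation is designed to expose. The first
rows of `annotated.tsv`:

```
sequence         rank     taxon                           lineage
ACGAKMDLMAVFRAK  species  Pseudomonadota_c1_o1_f2_g2_sp2  Root|Bacteria|Pseudomonadota|…
ACLACLQQKHDRR    species  Actinomycetota_c1_o1_f2_g2_sp1  Root|Bacteria|Actinomycetota|…
```

Further commands: `peptaxa profile` (per-sample composition at a rank),
`peptaxa compare` (Venn counts across result sets), and `peptaxa enrich`
(pathway scores + significance). Everything is also available as a library
(`import peptaxa`).

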