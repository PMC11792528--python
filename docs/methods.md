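# Methods

## Scope and model

`peptaxa` annotates bottom-up metaproteomic search results at the peptide
level against a cultivated-genome reference database. The pipeline assumes:

- every reference protein carries a complete, gap-free lineage on a fixed
  eight-rank ladder (root, superkingdom, phylum, class, order, family,
  genus, species) and optionally one KEGG ortholog (KO);
- the search engine reports, per peptide, the full set of database proteins
  consistent with it (MaxQuant's semicolon-separated `Proteins` column);
- decoys and contaminants are flagged upstream (FDR control itself is out
  of scope) and are removed before annotation.

## Database construction

Per-strain proteomes are merged in deterministic order (file order, then
record order). Deduplication removes sequences that are 100% identical over
their full length; at that identity and coverage, clustering reduces to
exact string equality, so it is implemented as hash-based duplicate removal
rather than via an external clustering binary. Comparison is on raw
residue strings: no I/L equivalence, `X` retained verbatim. The
representative of a duplicate set is the lexicographically smallest
protein ID — the tie-break is otherwise arbitrary, and this choice makes
output independent of input order. Every removed ID maps to its
representative; the map composes under repeated deduplication, so results
searched against the pre-dedup database still resolve. Dedup is global
(within and across strains).

## Taxonomic LCA

Agreement is name-based: two lineages share a node iff the (rank, name)
pair matches. This avoids any dependence on an external taxonomy dump but
means homonyms at the same rank would merge (not an issue for the flat
per-strain tables the pipeline consumes). Phylum synonyms are normalized
*before* the LCA from a small editable table shipped with the package
(Firmicutes→Bacillota, Bacteroidetes→Bacteroidota,
Actinobacteria→Actinomycetota, Tenericutes→Mycoplasmatota; unknown names
pass through), so vocabulary drift between annotation sources never splits
a group. An LCA that lands at superkingdom carries no information below the
root and is reclassified as `Root`; consequently the pipeline has no
"unannotated" state — coverage of resolvable peptides is 100% by
construction, and the interesting signal is *where* on the ladder peptides
resolve.

Peptides whose protein group mixes microbial and host proteins are classed
`ambiguous` and excluded from both microbial profiling and the
microbe/host ratio; exclusion avoids double counting either side.

## Profiling

Composition at a rank aggregates peptide intensity by the taxon each
peptide's lineage names at that rank. Peptides whose LCA is coarser than
the requested rank appear as an explicit `Unannotated-at-rank` entry rather
than being dropped — this keeps total intensity conserved and the closure
(fractions sum to 1) testable. Named taxa below a relative-abundance
threshold (default 2%, configurable) merge into `others`; the
`Unannotated-at-rank` entry is never merged. The F/B ratio is the summed
intensity of peptides whose lineage contains phylum Bacillota divided by
the same for Bacteroidota (after synonym normalization); it is undefined
(an error) when Bacteroidota intensity is zero.

## Consensus KO and pathway enrichment

The peptide→KO rule is strict consensus: a peptide is annotated with a KO
only if every protein in its group carries that same KO. Any disagreement,
any member lacking a KO, or an all-absent group leaves the peptide
unmapped. The partial-agreement case (some members annotated, some not) is
deliberately treated as disagreement — the conservative reading, chosen so
that a KO is never asserted on partial evidence.

Pathway peptide sets are the relational join of the peptide→KO map with a
user-supplied KO→pathway table; sets smaller than `min_size` (default 5)
are dropped as unstable to score.

Enrichment uses the kernel-free rank variant of gene set variation
analysis. Per sample: intensities → log2(x+1) → average ranks (ties
averaged) → symmetric rank statistic r_i = rank_i − (p+1)/2. Walking down
the list ordered by decreasing expression (ties broken by peptide name for
determinism), in-set positions add |r_i|^τ normalized by the in-set total
(τ = 1), out-of-set positions subtract 1/(p−m). The score is the walk's
signed maximum deviation (default) or the sum of its maximum positive and
negative deviations (`method="diff"`); both are bounded in [−1, 1], and
both are invariant to any strictly monotone per-sample transform of the
intensities because only ranks enter. Degenerate case: a set containing
every peptide makes the out-step denominator zero; the walk is then
compared against the uniform ECDF ℓ/p, which keeps it defined and yields a
small score (the weighted in-set ECDF deviates mildly from uniform under
τ = 1).

Group effects on scores are tested per pathway with one-way ANOVA across
sample labels and Benjamini–Hochberg adjustment across pathways. Pathways
with identical scores everywhere are assigned p = 1 (no evidence of an
effect, rather than an undefined F statistic). The default flagging
threshold is adjusted p < 1e-6, chosen to be stringent for exploratory
per-sample scores; the raw p-value column is also returned and is the
correct object for type-I-error calibration (under a complete null, BH
flags far fewer than α of pathways by design).

## Synthetic data generator

The generator emulates a small cultivated-reference study: a balanced
taxonomy tree (default 4 phyla → 8 families → 16 genera → 32 species, one
strain each), 12 proteins per strain of 120–360 residues drawn from a
uniform residue model with elevated K/R frequency (so tryptic peptide
lengths are realistic), and a peptide table over 8 samples in 2 groups.
Key mechanisms:

- **Ortholog families.** With probability `shared_protein_fraction`
  (default 0.25) a protein belongs to a family spanning all strains under a
  random ancestor node (phylum…species). Members are mutated copies of one
  base sequence; mutations touch only non-K/R/P positions and substitute
  only non-K/R/P residues, preserving the cleavage-site structure so that
  unmutated tryptic fragments are *exactly* shared across members. These
  shared peptides are what coarsen the LCA.
- **Planted duplicates.** A family member is an unmutated copy of the base
  with probability `duplicate_copy_rate` (0.25), producing exact
  cross-strain duplicates that exercise deduplication.
- **Digestion.** Trypsin: cleave after K/R except before P, up to 2 missed
  cleavages (the usual search setting), peptides of 7–30 residues
  (a typical identification window; configurable). Implemented over
  `pyteomics.parser.icleave`.
- **Quantities.** Intensities are log-normal on the raw MS scale
  (underlying mean 16, σ 1.5 → median ≈ 9×10⁶) with a per-peptide offset
  and 10% per-sample dropout (zeros). 10% of peptides come from a small
  synthetic host proteome (`HOST_*` IDs); 5% decoy rows (reversed
  sequences, `Reverse +`) and 2% contaminant rows are injected.
- **Truth tables.** Per peptide: source strains, true LCA, true consensus
  KO — computed by local longest-common-prefix and consensus rules coded
  independently of the annotation modules. Truth LCA/KO are evaluated over
  deduplicated representatives (collapsed inline by smallest protein ID),
  because the searched non-redundant database retains only the
  representative's lineage and KO; the pre-dedup source strains are still
  recorded separately.

All draws derive from a single seed (`numpy.random.default_rng` with
seeded substreams per stage), so every output is byte-reproducible.

What the generator does *not* emulate: spectrum-level noise and FDR
behavior, realistic (non-log-normal) abundance structure, shared peptides
between genuinely unrelated sequences, modified peptides, and database
incompleteness (every simulated peptide's true source is in the
reference). Passing tests therefore demonstrate the correctness of the
annotation logic, not search-engine performance on real data.

## Numerical and design choices

- Zero and missing intensities both mean "not quantified" (0), matching
  MaxQuant convention; sequences with modification annotations or
  whitespace are rejected rather than silently cleaned.
- Annotated tables are sorted by peptide sequence; duplicate-set
  representatives, TSV column orders, and walk tie-breaks are all
  deterministic, so byte-identical inputs give byte-identical outputs.
- Composition profiles conserve intensity to ~1e-9 relative (float64
  summation); the closure check in the test suite asserts 1e-9 absolute on
  fraction sums.
- Per-group summaries (e.g. mean M/H per group) are arithmetic means over
  samples within the group label.
- Problem sizes in the test suite and acceptance script (≈350-sequence
  references, 600-peptide tables, 100-pathway × 100-replicate null
  calibration) were chosen as the smallest sizes at which every mechanism
  of interest (LCA coarsening, dedup indirection, consensus failures,
  enrichment calibration) occurs many times per run.

## Known limitations

- Name-based LCA cannot distinguish homonymous taxa and does not model
  intermediate unranked nodes.
- The strict-consensus KO rule discards peptides whose groups have partial
  KO coverage; sensitivity is traded for precision.
- The enrichment scorer is one member of the GSVA family (rank-only
  kernel, τ = 1); other published variants (Gaussian-kernel ECDF,
  difference scoring) can give different scores on the same data, and only
  the difference-scoring alternative is exposed as an option.
- No automatic sample-quality filter is provided; removing low-quality
  samples is left to the analyst.
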