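# Methods

## Problem

Draft bacterial genomes consist of many contigs, and genes that span a
contig boundary are predicted as truncated "partial" ORFs — flagged by the
gene caller whenever a predicted gene abuts a contig end.  Fragmentation
inflates gene counts (several fragments of one gene are each annotated
separately) and deflates domain-level annotation (short fragments miss
their database hit).  `orflink` quantifies fragmentation, links fragments
of one gene using complete homologs in related genomes, validates the links
against scaffold layouts, and corrects annotation rates.

## Truncation model

Gene callers record a two-bit edge flag per predicted gene (left-edge
partial, right-edge partial, in contig coordinates).  We normalize this to
a coding-strand truncation state: on the plus strand a left-edge gene is
missing its start (5'-truncated); on the minus strand the same edge means
a missing stop (3'-truncated).  The four states are `NONE`, `FIVE_PRIME`,
`THREE_PRIME`, `BOTH`.  All downstream constraints (truncation budget,
end-order, scaffold gap-facing checks) are phrased in these coding-strand
terms and converted back to contig edges only where scaffolds are involved.

## Genome statistics

* **N50** — the smallest contig length `L` such that contigs of length
  `>= L` contain at least half the assembly.  When the running sum first
  meets exactly half the total, that contig's length is taken (the
  "greater than or equal" reading); an exhaustive threshold-search oracle
  backs this in the tests.
* **%GC deviation** — `|GC/(A+C+G+T) − 0.5|`, pooled over all contigs;
  ambiguity codes are excluded from numerator and denominator.  Pooling
  (rather than averaging per-contig fractions) matches the formula as
  written and weights contigs by length.
* **% partial ORFs** — partial / (partial + complete), full precision
  internally; percentages are rounded half-up to one decimal only at
  reporting time (`round_pct`), so printed one-decimal values can be
  reproduced exactly from raw counts.

## Homology machinery

Pairwise proteome searches use a built-in Smith–Waterman local aligner
(BLOSUM62; affine gaps costing 11 + k·1 for a gap of length k, the common
protein-search default) with a shared-4-mer prefilter: each query is
aligned only against the five subjects sharing the most 4-mers (at least
two).  Percent identity is identities over all alignment columns, gap
columns included.  The raw alignment score is used for ranking; e-value
statistics, compositional adjustment and low-complexity filtering are not
modeled — externally produced 12-column hit tables can be supplied wherever
exactness to a production search tool matters.

**AAI** (average amino acid identity): bidirectional best hits between two
proteomes, restricted to pairs of intact proteins with ≥ 30% identity and
alignment length ≥ 70% of *both* protein lengths; the per-pair identity is
the mean of the two directional identities, and the AAI is the unweighted
mean over kept pairs.  Per-pair weighting by alignment length was rejected:
the classical AAI definition averages identities across orthologous pairs.
Distances are `100 − AAI` (any strictly decreasing transform preserves the
neighbor-joining topology), averaged over the two search directions so the
matrix is symmetric by construction.

**Neighbor joining** is implemented in-package with the standard Q
criterion and branch-length formulas, lexicographic tie-breaking on taxon
pairs, and clamping of negative branch lengths to zero — determinism and
exact additive-matrix recovery were the requirements; a reference NJ
implementation serves as an independent oracle in the tests.

## Fragment linkage

For a target genome and one reference proteome:

1. **Placements** — keep fragment→reference hits onto *complete* reference
   proteins with identity ≥ `min_identity_pct` and aligned fraction of the
   *fragment* ≥ `min_overlap_frac` (coverage is measured on the fragment —
   a true fragment can never cover its full-length homolog; a
   reference-coverage mode exists for sensitivity analysis).  One placement
   (highest score) per fragment × reference protein.
2. **Assembly** — per reference protein, greedy and deterministic:
   placements sorted by descending identity (ties by fragment id); the top
   unused placement seeds a set, and subsequent placements join when
   (a) their reference-interval overlap with every member is
   ≤ `max_fragment_overlap_aa`, (b) their identity is within
   `max_identity_spread_pct` of the seed's, (c) at most two members are
   single-end-truncated after joining (interior, both-end-truncated
   fragments are unlimited), and (d) with `enforce_end_order` on, a
   start-containing (3'-truncated) member is leftmost by reference start
   and a stop-containing (5'-truncated) member rightmost.  Sets need ≥ 2
   members; seeding repeats until placements are exhausted.
3. **Conflict resolution** — sets sharing any fragment conflict; the one
   with higher mean identity to its reference wins (ties: more members,
   then lexicographic reference ids).  Resolution is a single global sort
   and sweep, so it is independent of input order and of the order in which
   references were processed — a later, closer reference genome *replaces*
   an earlier set whenever it backs the same fragments at higher identity.
4. **Reciprocity and multiple references** — genome pairs are searched in
   both directions; across an ordered reference series, cumulative and
   per-reference newly-linked counts are reported (linkage curves).

Defaults: identity ≥ 30%, fragment coverage ≥ 0.70, identity spread ≤ 40
(the spread cap is the one threshold for which a published calibration is
available, held constant at 40% in the original parameter surfaces),
member overlap ≤ 10 aa, end-order enforced.  The `grid` subcommand
re-derives the identity/coverage surface on any dataset with scaffold
truth; the other defaults are package choices, not published optima.

The spread threshold is deliberately read as a *maximum* allowed
difference between member identities: a minimum-difference reading would
forbid equally-diverged true fragments of one gene, and the published
calibration value (40%) only makes sense as a cap.  Likewise the
truncation budget is read as "at most two single-end-truncated members per
set" rather than "one of each kind"; the weaker reading is configurable.

`enforce_end_order` is on by default although only the count constraint is
strictly required: the fragment carrying the start must precede the
fragment carrying the stop on the reference for a true split gene.  The
flag allows the looser behavior for comparison.

**Correction** — each conflict-free set becomes one gene-level unit
(`merge_inventory`), giving `n_orfs − Σ(|set| − 1)` units.  A merged unit
counts as annotated iff *any* member is; this single rule is what removes
duplicated annotations when rates are recomputed after correction.

## Scaffold validation

Scaffold maps (AGP component lines or 3-column TSV) are homology-free
ground truth.  A linked pair is **TRUE** when its two fragments lie on
distinct contigs at consecutive ranks of one scaffold and each fragment's
truncated side faces the inter-contig gap after applying contig
orientation; **FALSE** when both contigs are placed but the condition
fails; **UNKNOWN** when either contig is unplaced.  This is the strictest
defensible reading of "adjacent location"; `require_orientation=False`
(`--rank-only`) relaxes it to rank adjacency alone, since the original
criterion cannot be pinned down further.  Counting is fragment-level (a
fragment is TRUE only if every consecutive-member pair it joins is TRUE),
because linkage efficacy is reported as a percentage of each genome's
partial-ORF total; UNKNOWN fragments stay out of the false-positive
denominator (a genome without scaffolds yields only UNKNOWNs, reported as
such rather than as 0%).

## Synthetic fixtures

`synth_fixtures` generates the full study setup from one seed:

* Random proteins (uniform over the 20 residues), default 1,000 genes of
  100–400 aa — bacterial-like gene lengths, enough genes that Poisson
  breakage yields several hundred fragments.
* Breaks per gene ~ Poisson(0.5) — a moderately fragmented draft, roughly
  the mid-range of real draft assemblies.  Break positions are uniform
  within the gene but kept ≥ 30 aa (`min_fragment_aa`) from every piece
  boundary by rejection sampling, emulating the caller's minimum gene
  length by construction; with `enforce_min_piece=False` breaks are fully
  uniform and undersized pieces are *dropped* (their contigs remain, the
  truth table records the loss) — useful for studying unrecoverable genes.
* Each piece lands at the correct end of its own contig (first piece
  3'-truncated, interior pieces both-end, last 5'-truncated), with
  reverse-translated nucleotide sequence (uniform codon choice) and random
  intergenic padding on non-broken sides.  An optional fraction of contigs
  is stored reverse-complemented (minus-strand ORFs, '−' scaffold
  orientation) to exercise orientation handling.
* The reference proteome is the source proteome with independent residue
  substitution at rate `reference_divergence` (default 0.05, i.e. ~95%
  AAI, a close relative within the species boundary); decoy paralogs
  (near-identical gene copies) can be planted to bait false links, the
  mechanism by which repetitive multi-modular genes mislead linkage in
  real data.
* Scaffolds record the true contig order per broken gene for
  `scaffold_fraction` of genes (default 1.0).

Because sequences are random, homology exists only where planted: passing
tests demonstrate the algorithmic behavior (recovery, guards, determinism)
under controlled divergence, not performance on real proteome composition,
repeat content, or gene-caller flag errors — the original observation that
truncation flags are themselves error-prone in real data is out of the
simulator's reach.

## Numerical choices

* All randomness flows from a single integer seed; sub-streams are derived
  by small fixed offsets.  Identical inputs, in any order, give identical
  outputs (placements, assembly and conflict resolution all have total
  deterministic orderings).
* Percentages are full precision internally; `round_pct` rounds half-up at
  reporting time only.
* Pearson correlations use the exact t-distribution two-sided p on n−2 df;
  zero-variance input is a domain error surfaced per row rather than a NaN.
* Degenerate inputs: empty assemblies, empty proteomes, all-ambiguous
  sequences, zero surviving AAI pairs, and zero partial ORFs alongside
  nonempty sets all raise typed errors (`DomainError`/`IntegrityError`)
  instead of propagating NaNs.

## Problem sizes

The bundled test-and-acceptance runs use 1,000-gene genomes for the
headline recovery run and 25–200-gene genomes for unit-level checks —
sizes at which the built-in aligner completes a full run in seconds while
still planting hundreds of splits.  The same code paths scale to real
proteomes; for genome panels at survey scale, precomputed hit tables from
an external search tool are the intended input.

## Full-scale reproduction recipe (informative)

Reproducing a survey over real draft genomes is a data-retrieval exercise,
not a desk-scale test; the workflow is:

1. Download draft-genome contig FASTAs and run a gene caller (e.g.
   Prodigal) to obtain protein FASTAs with edge-partial flags; `stats`
   over each genome reproduces the per-genome quality table (contigs,
   genome size, N50, complete/partial ORFs, % partial).
2. All-vs-all BLASTP between predicted proteomes (`-e 1e-05 -F F`,
   tabular 12-column output) supplies hit tables for both `aai`/`tree`
   (relatedness ordering) and `link`.
3. `link` each target against references ordered by decreasing AAI;
   `eval` against each genome's scaffold map (AGP from the assembly
   submission) yields the true/false linked-fragment percentages, and the
   pooled false rate across genomes gives the overall false-positive
   bound; `grid` re-derives the threshold surfaces.
4. `correct` + `impact` with real COG/Pfam/KEGG term tables reproduce the
   annotation-bias correlations before and after correction.

## Known limitations

* The built-in aligner reports no e-values; ranking uses raw scores.
  Results with external hit tables may differ slightly in tie cases.
* Linkage is protein-space only; nucleotide-level linkage of very close
  genomes is out of scope.
* The simulator does not model mis-set truncation flags, sequencing error,
  or compositional bias (a high-GC codon model exists but is optional);
  absolute recall/false-link numbers on synthetic data are upper bounds on
  real-data behavior.
* Scaffold validation cannot see links that skip an intervening contig
  whose piece was too short to call — such links are counted FALSE by the
  rank-adjacency rule even when biologically correct.
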