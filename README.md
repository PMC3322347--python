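# orflink

Homology-based linkage of partial ORFs in fragmented bacterial draft
genomes — plus the quality metrics, AAI/tree machinery, scaffold-based
validation and annotation-rate correction that go with it.

## The problem

Draft genome assemblies are collections of contigs, and any gene spanning a
contig boundary is predicted as a truncated **partial ORF** (the gene
caller flags genes bounded by a contig end).  Fragmentation biases
comparative genomics in both directions: several fragments of one gene are
each counted and annotated separately (over-annotation), while fragments
too short to hit their domain database are missed (under-annotation).

`orflink` mitigates the first bias by *linking* partial ORFs that derive
from a single gene, using complete homologs in related genomes as
scaffolds: fragments of one target genome that align to disjoint stretches
of the same complete reference protein, at similar identity and with
biologically consistent truncated ends, are grouped into a **fragment
set**.  Sets compete across multiple reference genomes — a set is replaced
whenever another reference supports the same fragments at higher mean
identity.  Each conflict-free set then counts as one gene-level unit when
statistics and annotation rates are recomputed.

Linkage stringency is controlled by four thresholds: minimum percent
identity to the reference homolog (default 30%), minimum aligned fraction
of the fragment (0.70), maximum spread of member identities to the shared
reference (40 percentage points), and maximum member overlap on the
reference (10 aa) — with at most two single-end-truncated members per set.
Validation uses scaffold maps as homology-free truth: a linked pair is a
true positive when its contigs are consecutive in a scaffold and the
truncated ends face the inter-contig gap.

Relatedness between genomes is measured as **AAI** (average amino acid
identity): the unweighted mean identity over bidirectional best-hit pairs
of intact proteins with ≥ 30% identity over ≥ 70% of both protein lengths;
`100 − AAI` distances feed a neighbor-joining tree.

## Worked example

Everything below is generated — no downloads.  `simulate` fragments a
random 1,000-gene proteome into contig-terminal partial ORFs and creates a
5%-diverged reference proteome plus scaffold truth:

```sh
orflink simulate --seed 1 --out-dir fx
orflink link --target fx/target_proteins.faa \
             --reference fx/reference_proteins.faa --out sets.tsv
```

which prints (seed 1):

```
linked_fragments        911
partial_orfs    911
pct_partial_linked      100.0
reference       reference_proteins      new=911 cumulative=911
```

Every one of the 911 partial ORFs was placed into a fragment set using the
close reference — expected here, because every planted fragment is ≥ 30 aa
and the reference is only 5% diverged.  `sets.tsv` holds one row per set
member (set id, member rank on the reference, identity, reference
protein), headed by a comment line echoing the thresholds used.
Validating against the scaffold truth:

```sh
orflink eval --sets sets.tsv --proteins fx/target_proteins.faa \
             --scaffolds fx/scaffolds.tsv --out eval.tsv
```

```
genome_id        n_linked_fragments  n_true  n_false  n_unknown  pct_true_of_partial  pct_false_of_partial
target_proteins  911                 911     0        0          100.0                0.0
```

No linked pair contradicts the scaffold layout.  On harder conditions
(more divergent references, decoy paralogs via `--paralogs`, unscaffolded
contigs) the true/false/unknown partition becomes informative, and
`orflink grid` maps how linkage counts and the true-positive fraction
respond to the identity/coverage/spread thresholds.

Other subcommands: `stats` (N50, %GC deviation, % partial ORFs per
genome), `aai` and `tree` (proteome relatedness), `correct` (annotation
rate before/after set-merging) and `impact` (correlations between genome
quality and annotation rate).

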