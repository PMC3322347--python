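"""Self-contained synthetic fixtures with ground truth.

The generator emulates the inputs the toolkit consumes in practice: a clean
proteome is fragmented into contig-terminal partial ORFs (with correct
caller-style truncation flags and reverse-translated nucleotide contigs), a
diverged copy of the proteome stands in for a related reference genome, and
scaffold maps record the true contig order so linkage results can be
validated.  All randomness flows from the single config seed.

What it does NOT emulate: read-level sequencing or assembly (breaks are
imposed directly), gene-calling errors in the truncation flags, and real
protein families — sequences are random over the 20 residues, so homology
exists only where the generator plants it (diverged copies and decoy
paralogs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from orflink.io_formats import (
    ConfigError,
    ContigRecord,
    FragmentSet,
    OrfRecord,
    ScaffoldCollection,
    ScaffoldEntry,
    ScaffoldMap,
    Truncation,
    write_contigs,
    write_hits,
    write_proteins,
    write_scaffold_map,
)
from orflink.homology import search_proteome

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard-code codons per residue, for reverse translation of fixtures
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"],
    "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
}
_STOPS = ["TAA", "TAG", "TGA"]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic genome.

    Defaults describe a moderately fragmented draft: 1,000 genes of
    100-400 aa, on average one break per two genes (Poisson), every piece at
    least 30 aa (the caller-minimum regime), a reference proteome at 5%
    residue divergence (~95% AAI, i.e. a close relative), full scaffold
    coverage, and no decoy paralogs unless requested.
    """

    seed: int = 0
    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (100, 400)
    break_rate: float = 0.5  # Poisson mean breaks per gene
    min_fragment_aa: int = 30
    enforce_min_piece: bool = True  # place breaks so every piece >= min_fragment_aa
    reference_divergence: float = 0.05
    paralog_count: int = 0
    paralog_divergence: float = 0.03
    scaffold_fraction: float = 1.0
    minus_strand_fraction: float = 0.0
    gc_codon_bias: float = 0.0  # >0 prefers G/C-rich codons (actinomycete-like)
    genome_id: str = "target"
    reference_genome_id: str = "reference"

    def __post_init__(self) -> None:
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ConfigError("gene_length_range must satisfy 0 < min <= max")
        if self.min_fragment_aa < 1:
            raise ConfigError("min_fragment_aa must be >= 1")
        if not (0.0 <= self.reference_divergence < 1.0):
            raise ConfigError("reference_divergence must lie in [0, 1)")
        if self.break_rate < 0 or self.n_genes < 1:
            raise ConfigError("break_rate must be >= 0 and n_genes >= 1")
        if not (0.0 <= self.scaffold_fraction <= 1.0):
            raise ConfigError("scaffold_fraction must lie in [0, 1]")
        if not (0.0 <= self.minus_strand_fraction <= 1.0):
            raise ConfigError("minus_strand_fraction must lie in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth of one fixture, keyed by original gene."""

    gene_fragments: dict[str, list[str]] = field(default_factory=dict)  # surviving, in order
    dropped_pieces: dict[str, list[int]] = field(default_factory=dict)  # aa lengths lost
    adjacent_pairs: set[frozenset[str]] = field(default_factory=set)  # truly gap-adjacent
    paralog_genes: set[str] = field(default_factory=set)

    @property
    def n_recoverable_pairs(self) -> int:
        return len(self.adjacent_pairs)


@dataclass
class FixtureBundle:
    config: FixtureConfig
    source_proteome: list[tuple[str, str]]  # (gene_id, aa_sequence), pre-fragmentation
    orfs: list[OrfRecord]  # target genome's predicted proteome (complete + partial)
    contigs: list[ContigRecord]
    scaffolds: ScaffoldCollection
    truth: TruthTable

    @property
    def fragments(self) -> list[OrfRecord]:
        return [o for o in self.orfs if o.is_partial]


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence == 0.0:
        return seq
    out = []
    for aa in seq:
        if rng.random() < divergence:
            choices = [c for c in AMINO_ACIDS if c != aa]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(aa)
    return "".join(out)


def generate_proteome(config: FixtureConfig) -> list[tuple[str, str]]:
    """The clean, complete source proteome: (gene_id, sequence) pairs.

    Residues are uniform over the 20 standard amino acids; decoy paralogs
    (near-identical copies of randomly chosen genes) are appended when
    configured, to bait false links downstream.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    genes = [
        (f"gene_{i:04d}", _random_protein(rng, int(rng.integers(lo, hi + 1))))
        for i in range(config.n_genes)
    ]
    for p in range(config.paralog_count):
        src_idx = int(rng.integers(config.n_genes))
        src_id, src_seq = genes[src_idx]
        genes.append((f"{src_id}_par{p}", _mutate(src_seq, config.paralog_divergence, rng)))
    return genes


def mutate_proteome(
    proteome: Sequence[tuple[str, str]], divergence: float, seed: int, genome_id: str = "reference"
) -> list[OrfRecord]:
    """A diverged complete copy of the proteome, as one intact ORF per contig.

    Each residue substitutes independently with probability ``divergence``,
    so expected pairwise identity is 100*(1 - divergence) percent — emulating
    a related reference genome.
    """
    rng = np.random.default_rng(seed)
    orfs = []
    for gene_id, seq in proteome:
        mutated = _mutate(seq, divergence, rng)
        contig_id = f"{genome_id}_{gene_id}"
        orfs.append(
            OrfRecord(
                orf_id=f"{contig_id}_1",
                genome_id=genome_id,
                contig_id=contig_id,
                start=1,
                end=3 * len(mutated) + 3,
                strand=1,
                aa_sequence=mutated,
                truncation=Truncation.NONE,
            )
        )
    return orfs


def _reverse_translate(seq: str, rng: np.random.Generator, gc_bias: float = 0.0) -> str:
    """Uniform codon choice, optionally weighted toward G/C-rich codons by
    (1 + gc_bias)^(#GC in codon) to emulate high-GC genomes."""
    out = []
    for aa in seq:
        codons = _CODONS[aa]
        if gc_bias > 0.0:
            weights = np.array(
                [(1.0 + gc_bias) ** sum(c in "GC" for c in codon) for codon in codons]
            )
            out.append(codons[rng.choice(len(codons), p=weights / weights.sum())])
        else:
            out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def _random_nt(rng: np.random.Generator, length: int, gc_bias: float = 0.0) -> str:
    p_gc = (0.5 + gc_bias / (2.0 * (1.0 + gc_bias))) / 1.0 if gc_bias > 0 else 0.5
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))


def _draw_breaks(
    rng: np.random.Generator, length: int, config: FixtureConfig
) -> list[int]:
    """Break positions (aa offsets, 0 < b < length) for one gene."""
    k = int(rng.poisson(config.break_rate))
    if k == 0:
        return []
    if not config.enforce_min_piece:
        cuts = sorted(rng.choice(np.arange(1, length), size=min(k, length - 1), replace=False))
        return [int(c) for c in cuts]
    m = config.min_fragment_aa
    while k > 0:
        if (k + 1) * m <= length:
            for _ in range(200):
                cuts = sorted(
                    rng.choice(np.arange(1, length), size=k, replace=False)
                )
                pieces = np.diff([0, *cuts, length])
                if (pieces >= m).all():
                    return [int(c) for c in cuts]
        k -= 1  # gene too short (or unlucky) for k breaks; relax
    return []


def fragment_genome(
    proteome: Sequence[tuple[str, str]], config: FixtureConfig
) -> FixtureBundle:
    """Break genes across contig ends and emit the resulting draft genome.

    Per gene, a Poisson number of breaks is placed (kept clear of the
    ``min_fragment_aa`` margins by default); the first piece keeps the start
    codon and loses its stop (3'-truncated), interior pieces lose both ends,
    and the last piece keeps the stop (5'-truncated).  Each piece lands at
    the appropriate end of its own contig, contigs of one broken gene are
    ordered into a scaffold for ``scaffold_fraction`` of genes, and a
    fraction of contigs may be stored reverse-complemented (minus-strand
    ORFs, '-' scaffold orientation).  Pieces shorter than the caller minimum
    are dropped from the proteome but their contigs remain, and the truth
    table records the loss.
    """
    rng = np.random.default_rng(config.seed + 1)
    orfs: list[OrfRecord] = []
    contigs: list[ContigRecord] = []
    scaffolds: list[ScaffoldMap] = []
    truth = TruthTable()
    truth.paralog_genes = {g for g, _ in proteome if "_par" in g}

    for gene_id, seq in proteome:
        cuts = _draw_breaks(rng, len(seq), config)
        bounds = [0, *cuts, len(seq)]
        pieces = [seq[bounds[i] : bounds[i + 1]] for i in range(len(bounds) - 1)]
        scaffolded = len(pieces) > 1 and rng.random() < config.scaffold_fraction
        entries: list[ScaffoldEntry] = []
        surviving: list[str] = []
        prev_survived = False
        for j, piece in enumerate(pieces):
            many = len(pieces) > 1
            contig_id = f"{gene_id}_c{j}" if many else f"{gene_id}_c"
            first, last = j == 0, j == len(pieces) - 1
            nt = _reverse_translate(piece, rng, config.gc_codon_bias)
            if first:
                pad = _random_nt(rng, int(rng.integers(30, 101)), config.gc_codon_bias)
                contig_seq = pad + nt
                start, end = len(pad) + 1, len(contig_seq)
            elif last:
                pad = _random_nt(rng, int(rng.integers(30, 101)), config.gc_codon_bias)
                contig_seq = nt + _STOPS[rng.integers(3)] + pad
                start, end = 1, len(nt) + 3
            else:
                contig_seq = nt
                start, end = 1, len(nt)
            if many:
                truncation = (
                    Truncation.THREE_PRIME
                    if first
                    else Truncation.FIVE_PRIME
                    if last
                    else Truncation.BOTH
                )
            else:
                pad3 = _random_nt(rng, int(rng.integers(30, 101)), config.gc_codon_bias)
                contig_seq = contig_seq + _STOPS[rng.integers(3)] + pad3
                end = end + 3
                truncation = Truncation.NONE
            strand = 1
            if rng.random() < config.minus_strand_fraction:
                strand = -1
                new_start = len(contig_seq) - end + 1
                new_end = len(contig_seq) - start + 1
                contig_seq = _revcomp(contig_seq)
                start, end = new_start, new_end
            contigs.append(
                ContigRecord(contig_id=contig_id, genome_id=config.genome_id, sequence=contig_seq)
            )
            orf_id = f"{contig_id}_1"
            dropped = many and len(piece) < config.min_fragment_aa
            if dropped:
                truth.dropped_pieces.setdefault(gene_id, []).append(len(piece))
                prev_survived = False
            else:
                orfs.append(
                    OrfRecord(
                        orf_id=orf_id,
                        genome_id=config.genome_id,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        aa_sequence=piece,
                        truncation=truncation,
                    )
                )
                if many:
                    if prev_survived:
                        truth.adjacent_pairs.add(frozenset((surviving[-1], orf_id)))
                    surviving.append(orf_id)
                    prev_survived = True
            if scaffolded:
                entries.append(
                    ScaffoldEntry(
                        rank=j + 1,
                        contig_id=contig_id,
                        orientation="+" if strand == 1 else "-",
                    )
                )
        if len(pieces) > 1:
            truth.gene_fragments[gene_id] = surviving
        if entries:
            scaffolds.append(ScaffoldMap(scaffold_id=f"scf_{gene_id}", entries=entries))

    return FixtureBundle(
        config=config,
        source_proteome=list(proteome),
        orfs=orfs,
        contigs=contigs,
        scaffolds=ScaffoldCollection(scaffolds),
        truth=truth,
    )


def make_fixture(config: FixtureConfig = FixtureConfig()) -> tuple[FixtureBundle, list[OrfRecord]]:
    """Generate the full study setup: fragmented target + diverged reference."""
    proteome = generate_proteome(config)
    bundle = fragment_genome(proteome, config)
    reference = mutate_proteome(
        proteome,
        config.reference_divergence,
        config.seed + 2,
        genome_id=config.reference_genome_id,
    )
    return bundle, reference


def linkage_recall(sets: Sequence[FragmentSet], truth: TruthTable) -> tuple[int, int, float]:
    """(recovered, recoverable, recall) for planted gap-adjacent pairs.

    A truth pair counts as recovered when its two fragments are consecutive
    members of one emitted set.
    """
    emitted: set[frozenset[str]] = set()
    for fs in sets:
        for m1, m2 in zip(fs.members, fs.members[1:]):
            emitted.add(frozenset((m1, m2)))
    recoverable = truth.n_recoverable_pairs
    recovered = len(truth.adjacent_pairs & emitted)
    return recovered, recoverable, (recovered / recoverable if recoverable else float("nan"))


def planted_annotations(
    bundle: FixtureBundle,
    annotate_fraction: float = 0.7,
    term_category: str | None = None,
    seed: int | None = None,
):
    """Annotation table emulating per-fragment database hits.

    Each source gene carries one synthetic term with probability
    ``annotate_fraction``; every predicted ORF deriving from an annotated
    gene inherits that term, so fragments of one gene are each 'annotated'
    separately — the over-annotation that set-merging corrects.
    """
    from orflink.io_formats import AnnotationTable

    rng = np.random.default_rng(bundle.config.seed + 3 if seed is None else seed)
    table = AnnotationTable()
    fragments_of = dict(bundle.truth.gene_fragments)
    for gene_id, _ in bundle.source_proteome:
        if rng.random() >= annotate_fraction:
            continue
        term = f"TERM_{gene_id}"
        if term_category is not None:
            table.categories[term] = term_category
        members = fragments_of.get(gene_id, [f"{gene_id}_c_1"])
        for orf_id in members:
            table.terms.setdefault(orf_id, set()).add(term)
    return table


def emit_fixture(
    bundle: FixtureBundle,
    reference: Sequence[OrfRecord],
    directory: str | Path,
    include_hits: bool = False,
) -> dict[str, Path]:
    """Write the fixture as the plain-text files the toolkit consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": directory / "target_proteins.faa",
        "contigs": directory / "target_contigs.fna",
        "scaffolds": directory / "scaffolds.tsv",
        "reference": directory / "reference_proteins.faa",
        "truth": directory / "truth.tsv",
    }
    write_proteins(bundle.orfs, paths["proteins"])
    write_contigs(bundle.contigs, paths["contigs"])
    write_scaffold_map(bundle.scaffolds, paths["scaffolds"])
    write_proteins(reference, paths["reference"])
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tfragment_rank\tfragment_id\n")
        for gene_id, frags in sorted(bundle.truth.gene_fragments.items()):
            for rank, frag in enumerate(frags, 1):
                fh.write(f"{gene_id}\t{rank}\t{frag}\n")
    if include_hits:
        paths["hits"] = directory / "fragment_hits.tsv"
        hits = search_proteome(bundle.fragments, list(reference))
        write_hits(hits, paths["hits"])
    return paths
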