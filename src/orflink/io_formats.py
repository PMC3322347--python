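"""File formats and core record types.

Every external file the toolkit touches is read and written here: protein
FASTA with gene-caller headers (coordinates, strand and the two-bit
edge-partial flag), GFF3 as an alternative source of the same metadata,
12-column tabular hit files, AGP / TSV scaffold maps, fragment-set tables and
ORF-to-term annotation tables.

Conventions
-----------
* Nucleotide coordinates are 1-based inclusive on the parent contig.
* Amino-acid coordinates in hits are 1-based inclusive on the translated
  sequence as given.
* Truncation is expressed on the coding strand: ``FIVE_PRIME`` means the
  start of the protein is missing (the gene runs off a contig end upstream),
  ``THREE_PRIME`` means the stop is missing, ``BOTH`` means both.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class OrflinkError(Exception):
    """Base class for all toolkit errors."""


class ParseError(OrflinkError):
    """A file could not be parsed; the message names the offending record."""


class IntegrityError(OrflinkError):
    """Inputs are individually well-formed but mutually inconsistent."""


class ConfigError(OrflinkError):
    """An invalid parameter or dialect was requested."""


class Truncation(enum.Enum):
    """Which coding-strand end(s) of a predicted protein are missing."""

    NONE = "none"
    FIVE_PRIME = "5prime"
    THREE_PRIME = "3prime"
    BOTH = "both"

    @property
    def is_partial(self) -> bool:
        return self is not Truncation.NONE

    @property
    def single_ended(self) -> bool:
        return self in (Truncation.FIVE_PRIME, Truncation.THREE_PRIME)


def truncation_from_edge_flags(left_edge: bool, right_edge: bool, strand: int) -> Truncation:
    """Map contig-edge partial flags to coding-strand truncation.

    ``left_edge``/``right_edge`` say whether the gene abuts the left/right
    end of the contig (the caller's two-bit ``partial`` flag).  On the plus
    strand the left contig edge is the 5' side of the gene; on the minus
    strand it is the 3' side.
    """
    if strand not in (1, -1):
        raise ConfigError(f"strand must be +1 or -1, got {strand!r}")
    if left_edge and right_edge:
        return Truncation.BOTH
    if not left_edge and not right_edge:
        return Truncation.NONE
    if left_edge:
        return Truncation.FIVE_PRIME if strand == 1 else Truncation.THREE_PRIME
    return Truncation.THREE_PRIME if strand == 1 else Truncation.FIVE_PRIME


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    genome_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfRecord:
    """One predicted protein with its genomic location and truncation state."""

    orf_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive, start <= end
    end: int
    strand: int  # +1 or -1
    aa_sequence: str
    truncation: Truncation = Truncation.NONE

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParseError(f"ORF {self.orf_id}: start {self.start} > end {self.end}")
        if self.strand not in (1, -1):
            raise ParseError(f"ORF {self.orf_id}: strand must be +1/-1")
        if not self.aa_sequence:
            raise ParseError(f"ORF {self.orf_id}: empty amino-acid sequence")

    @property
    def length_aa(self) -> int:
        return len(self.aa_sequence)

    @property
    def is_partial(self) -> bool:
        return self.truncation.is_partial

    def truncated_contig_edges(self) -> frozenset[str]:
        """The contig edges ('left'/'right') this ORF's missing ends abut."""
        edges = set()
        t = self.truncation
        if t in (Truncation.FIVE_PRIME, Truncation.BOTH):
            edges.add("left" if self.strand == 1 else "right")
        if t in (Truncation.THREE_PRIME, Truncation.BOTH):
            edges.add("right" if self.strand == 1 else "left")
        return frozenset(edges)


@dataclass(frozen=True)
class HitRecord:
    """One pairwise local-alignment hit in the standard 12-column layout."""

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ParseError(f"hit {self.query_id}->{self.subject_id}: pident out of range")
        if self.q_start > self.q_end or self.s_start > self.s_end:
            raise ParseError(
                f"hit {self.query_id}->{self.subject_id}: interval start exceeds end"
            )


@dataclass(frozen=True)
class ScaffoldEntry:
    rank: int  # consecutive from 1 within a scaffold
    contig_id: str
    orientation: str  # '+' or '-'


@dataclass
class ScaffoldMap:
    """Ordered, oriented contig layout of one scaffold."""

    scaffold_id: str
    entries: list[ScaffoldEntry] = field(default_factory=list)

    def contig_ids(self) -> list[str]:
        return [e.contig_id for e in self.entries]


class ScaffoldCollection:
    """All scaffolds of a genome, indexed by contig for adjacency queries."""

    def __init__(self, scaffolds: Iterable[ScaffoldMap]):
        self.scaffolds: dict[str, ScaffoldMap] = {}
        self._by_contig: dict[str, tuple[str, ScaffoldEntry]] = {}
        for sc in scaffolds:
            self.scaffolds[sc.scaffold_id] = sc
            for entry in sc.entries:
                if entry.contig_id in self._by_contig:
                    raise IntegrityError(
                        f"contig {entry.contig_id} appears in more than one scaffold entry"
                    )
                self._by_contig[entry.contig_id] = (sc.scaffold_id, entry)

    def __len__(self) -> int:
        return len(self.scaffolds)

    def placement(self, contig_id: str) -> tuple[str, ScaffoldEntry] | None:
        return self._by_contig.get(contig_id)


@dataclass
class FragmentSet:
    """Partial ORFs from one genome linked via one complete reference homolog.

    Members are ordered by ascending start position on the reference protein,
    so consecutive members are the pairs a scaffold can corroborate.
    """

    set_id: str
    genome_id: str
    members: list[str]
    member_identities: list[float]
    reference_protein_id: str
    reference_genome_id: str

    def __post_init__(self) -> None:
        if len(self.members) != len(self.member_identities):
            raise IntegrityError(f"set {self.set_id}: members/identities length mismatch")
        if len(self.members) != len(set(self.members)):
            raise IntegrityError(f"set {self.set_id}: duplicate members")

    @property
    def mean_identity(self) -> float:
        return sum(self.member_identities) / len(self.member_identities)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class AnnotationTable:
    """ORF -> annotation terms, with an optional term -> category map."""

    terms: dict[str, set[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    unknown_orf_ids: set[str] = field(default_factory=set)

    def terms_for(self, orf_id: str) -> set[str]:
        return self.terms.get(orf_id, set())

    def is_annotated(self, orf_id: str) -> bool:
        return bool(self.terms.get(orf_id))


# ---------------------------------------------------------------------------
# Protein FASTA with caller-style headers
# ---------------------------------------------------------------------------

# >orf_1_2 # 300 # 980 # 1 # ID=1_2;partial=00;start_type=ATG
_CALLER_HEADER = re.compile(
    r"^(?P<id>\S+)\s*#\s*(?P<start>\d+)\s*#\s*(?P<end>\d+)\s*#\s*(?P<strand>-?1)\s*#\s*(?P<attrs>.*)$"
)


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if "=" in chunk:
            k, _, v = chunk.partition("=")
            out[k.strip()] = v.strip()
    return out


def _contig_of(orf_id: str, attrs: dict[str, str]) -> str:
    if "contig" in attrs:
        return attrs["contig"]
    # caller convention: ORF ids are <contig_id>_<serial>
    if "_" in orf_id:
        return orf_id.rsplit("_", 1)[0]
    raise ParseError(f"cannot derive contig id for ORF {orf_id}; add a contig= attribute")


def read_proteins(
    path: str | Path,
    dialect: str = "caller-header",
    genome_id: str | None = None,
    gff_path: str | Path | None = None,
) -> list[OrfRecord]:
    """Read a predicted proteome and normalize truncation flags.

    ``caller-header`` expects FASTA description lines of the form
    ``id # start # end # strand # key=value;...`` with a two-character
    ``partial`` flag (left-edge bit, right-edge bit).  ``gff3`` reads plain
    FASTA plus a companion GFF3 whose ``ID`` attributes match the FASTA ids
    and which carries the same ``partial`` attribute.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    if dialect == "caller-header":
        return _read_proteins_caller(path, genome_id)
    if dialect == "gff3":
        if gff_path is None:
            gff_path = path.with_suffix(".gff")
        return _read_proteins_gff3(path, Path(gff_path), genome_id)
    raise ConfigError(f"unknown proteome dialect {dialect!r}")


def _read_proteins_caller(path: Path, genome_id: str) -> list[OrfRecord]:
    orfs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _CALLER_HEADER.match(rec.description)
        if m is None:
            raise ParseError(f"{path}: malformed caller header for record {rec.id!r}")
        attrs = _parse_attrs(m.group("attrs"))
        flag = attrs.get("partial", "00")
        if len(flag) != 2 or any(c not in "01" for c in flag):
            raise ParseError(f"{path}: bad partial flag {flag!r} on record {rec.id!r}")
        strand = int(m.group("strand"))
        orfs.append(
            OrfRecord(
                orf_id=m.group("id"),
                genome_id=genome_id,
                contig_id=_contig_of(m.group("id"), attrs),
                start=int(m.group("start")),
                end=int(m.group("end")),
                strand=strand,
                aa_sequence=str(rec.seq).rstrip("*"),
                truncation=truncation_from_edge_flags(flag[0] == "1", flag[1] == "1", strand),
            )
        )
    return orfs


def _read_proteins_gff3(fasta_path: Path, gff_path: Path, genome_id: str) -> list[OrfRecord]:
    meta: dict[str, tuple[str, int, int, int, str]] = {}
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{gff_path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            seqid, _, ftype, start, end, _, strand, _, attr_text = cols
            if ftype not in ("CDS", "gene"):
                continue
            attrs = _parse_attrs(attr_text)
            if "ID" not in attrs:
                raise ParseError(f"{gff_path}:{lineno}: CDS line lacks an ID attribute")
            meta[attrs["ID"]] = (
                seqid,
                int(start),
                int(end),
                1 if strand != "-" else -1,
                attrs.get("partial", "00"),
            )
    orfs = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta:
            raise ParseError(f"{fasta_path}: record {rec.id!r} has no matching GFF3 CDS")
        seqid, start, end, strand, flag = meta[rec.id]
        orfs.append(
            OrfRecord(
                orf_id=rec.id,
                genome_id=genome_id,
                contig_id=seqid,
                start=start,
                end=end,
                strand=strand,
                aa_sequence=str(rec.seq).rstrip("*"),
                truncation=truncation_from_edge_flags(flag[0] == "1", flag[1] == "1", strand),
            )
        )
    return orfs


def write_proteins(orfs: Sequence[OrfRecord], path: str | Path) -> None:
    """Write a proteome as FASTA with caller-style headers (round-trippable)."""
    records = []
    for orf in orfs:
        left = orf.truncated_contig_edges()
        flag = ("1" if "left" in left else "0") + ("1" if "right" in left else "0")
        desc = (
            f"{orf.orf_id} # {orf.start} # {orf.end} # {orf.strand} "
            f"# ID={orf.orf_id};partial={flag};contig={orf.contig_id}"
        )
        records.append(SeqRecord(Seq(orf.aa_sequence), id=orf.orf_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_contigs(path: str | Path, genome_id: str | None = None) -> list[ContigRecord]:
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    return [
        ContigRecord(contig_id=rec.id, genome_id=genome_id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_contigs(contigs: Sequence[ContigRecord], path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(c.sequence), id=c.contig_id, description="") for c in contigs],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# 12-column tabular hits
# ---------------------------------------------------------------------------

def read_hits(path: str | Path) -> list[HitRecord]:
    """Read a 12-column (qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore) tabular hit file, preserving row order."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 12:
                raise ParseError(f"{path}:{lineno}: expected 12 columns, got {len(cols)}")
            try:
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pident=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits(hits: Sequence[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pident:.2f}\t{h.align_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Scaffold maps (AGP v2.0 component lines, or 3-column TSV)
# ---------------------------------------------------------------------------

def read_scaffold_map(path: str | Path, dialect: str = "tsv") -> ScaffoldCollection:
    """Read scaffold layouts; ranks are assigned by file order per scaffold."""
    if dialect == "tsv":
        return _read_scaffold_tsv(Path(path))
    if dialect == "agp":
        return _read_scaffold_agp(Path(path))
    raise ConfigError(f"unknown scaffold dialect {dialect!r}")


def _normalize_orientation(text: str, where: str) -> str:
    if text in ("+", "plus", "1"):
        return "+"
    if text in ("-", "minus", "-1"):
        return "-"
    # AGP uses '?', '0' and 'na' for unknown; treat as '+'
    if text in ("?", "0", "na"):
        return "+"
    raise ParseError(f"{where}: bad orientation {text!r}")


def _build_collection(rows: list[tuple[str, str, str]], source: str) -> ScaffoldCollection:
    scaffolds: dict[str, ScaffoldMap] = {}
    for scaffold_id, contig_id, orientation in rows:
        sc = scaffolds.setdefault(scaffold_id, ScaffoldMap(scaffold_id))
        sc.entries.append(
            ScaffoldEntry(rank=len(sc.entries) + 1, contig_id=contig_id, orientation=orientation)
        )
    try:
        return ScaffoldCollection(scaffolds.values())
    except IntegrityError as exc:
        raise IntegrityError(f"{source}: {exc}") from exc


def _read_scaffold_tsv(path: Path) -> ScaffoldCollection:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            if lineno == 1 and cols[0].lower() in ("scaffold_id", "scaffold"):
                continue
            rows.append((cols[0], cols[1], _normalize_orientation(cols[2], f"{path}:{lineno}")))
    return _build_collection(rows, str(path))


def _read_scaffold_agp(path: Path) -> ScaffoldCollection:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 8:
                raise ParseError(f"{path}:{lineno}: short AGP line")
            component_type = cols[4]
            if component_type in ("N", "U"):  # gap lines carry no component
                continue
            orientation = cols[8] if len(cols) > 8 else "+"
            rows.append((cols[0], cols[5], _normalize_orientation(orientation, f"{path}:{lineno}")))
    return _build_collection(rows, str(path))


def write_scaffold_map(collection: ScaffoldCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold_id\tcontig_id\torientation\n")
        for sc in collection.scaffolds.values():
            for entry in sc.entries:
                fh.write(f"{sc.scaffold_id}\t{entry.contig_id}\t{entry.orientation}\n")


# ---------------------------------------------------------------------------
# Fragment-set tables (one row per member, shared set id)
# ---------------------------------------------------------------------------

_FRAGSET_COLUMNS = [
    "set_id",
    "genome_id",
    "member_rank",
    "fragment_id",
    "member_identity",
    "reference_protein_id",
    "reference_genome_id",
    "mean_identity",
]


def write_fragment_sets(
    sets: Sequence[FragmentSet], path: str | Path, header_comment: str | None = None
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.rstrip("\n").split("\n"):
                fh.write(line if line.startswith("#") else f"# {line}")
                fh.write("\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_FRAGSET_COLUMNS)
        for fs in sets:
            for rank, (member, ident) in enumerate(zip(fs.members, fs.member_identities), 1):
                writer.writerow(
                    [
                        fs.set_id,
                        fs.genome_id,
                        rank,
                        member,
                        repr(ident),
                        fs.reference_protein_id,
                        fs.reference_genome_id,
                        repr(fs.mean_identity),
                    ]
                )


def read_fragment_sets(path: str | Path) -> list[FragmentSet]:
    order: list[str] = []
    partial: dict[str, FragmentSet] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = None
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if header is None:
                header = row
                if header != _FRAGSET_COLUMNS:
                    raise ParseError(f"{path}: unexpected fragment-set header {header!r}")
                continue
            set_id, genome_id, rank, member, ident, ref_prot, ref_gen, _ = row
            if set_id not in partial:
                order.append(set_id)
                partial[set_id] = FragmentSet(
                    set_id=set_id,
                    genome_id=genome_id,
                    members=[],
                    member_identities=[],
                    reference_protein_id=ref_prot,
                    reference_genome_id=ref_gen,
                )
            fs = partial[set_id]
            if int(rank) != len(fs.members) + 1:
                raise IntegrityError(f"{path}: member ranks of set {set_id} are not consecutive")
            fs.members.append(member)
            fs.member_identities.append(float(ident))
    return [partial[s] for s in order]


# ---------------------------------------------------------------------------
# Annotation tables (orf_id <tab> term [<tab> term ...]); category map TSV
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    known_orf_ids: Iterable[str] | None = None,
    category_path: str | Path | None = None,
) -> AnnotationTable:
    """Load ORF -> term assignments; ids absent from ``known_orf_ids`` are
    flagged in ``unknown_orf_ids`` rather than rejected."""
    known = set(known_orf_ids) if known_orf_ids is not None else None
    table = AnnotationTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError(f"{path}:{lineno}: expected orf_id<TAB>term")
            orf_id, terms = cols[0], [c for c in cols[1:] if c]
            if known is not None and orf_id not in known:
                table.unknown_orf_ids.add(orf_id)
            table.terms.setdefault(orf_id, set()).update(terms)
    if category_path is not None:
        with open(category_path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, _, category = line.partition("\t")
                if category:
                    table.categories[term] = category
    return table


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for orf_id in sorted(table.terms):
            for term in sorted(table.terms[orf_id]):
                fh.write(f"{orf_id}\t{term}\n")
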