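"""Genome and gene-model I/O: FASTA, GFF3, spliced CDS assembly, ORF finding, translation.

Coordinates follow GFF3 at every public interface: 1-based, inclusive on both
ends. Conversion to Python's 0-based half-open slices happens in exactly one
place (:func:`to_slice`) so off-by-one reasoning is localized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = {"TAA", "TAG", "TGA"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeIOError(ValueError):
    """Raised on malformed inputs or invariant violations."""


def to_slice(start: int, end: int) -> slice:
    """Convert 1-based inclusive (start, end) to a Python slice.

    The single authorized 1-based → 0-based conversion point.
    """
    if start < 1 or end < start:
        raise GenomeIOError(f"invalid 1-based interval ({start}, {end})")
    return slice(start - 1, end)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A chromosome or scaffold: identifier plus uppercase A/C/G/T/N sequence."""

    chrom_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chrom_id:
            raise GenomeIOError("empty chromosome id")
        if not self.sequence:
            raise GenomeIOError(f"{self.chrom_id}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - NUCLEOTIDES
        if bad:
            raise GenomeIOError(
                f"{self.chrom_id}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


BIOTYPES = {"putative_functional", "pseudogene", "partial", "unclassified"}


@dataclass
class GeneModel:
    """A stranded, exon-structured (CDS-only) gene model on a chromosome.

    ``exons`` are (start, end) pairs in 1-based inclusive genomic coordinates,
    sorted ascending by start and non-overlapping regardless of strand.
    """

    gene_id: str
    transcript_id: str
    chrom_id: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "unclassified"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise GenomeIOError(f"{self.transcript_id}: strand must be '+' or '-'")
        if self.biotype not in BIOTYPES:
            raise GenomeIOError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        if not self.exons:
            raise GenomeIOError(f"{self.transcript_id}: no exons")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise GenomeIOError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s < 1:
                raise GenomeIOError(f"{self.transcript_id}: exon start {s} < 1")
            if s <= prev_end:
                raise GenomeIOError(f"{self.transcript_id}: overlapping exons")
            prev_end = e
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        """Genomic (start, end) of introns, ascending, 1-based inclusive."""
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        ]

    def exon_lengths_nt(self) -> list[int]:
        """Coding exon lengths in nt, in 5'→3' transcript order."""
        lens = [e - s + 1 for s, e in self.exons]
        return lens if self.strand == "+" else lens[::-1]

    def intron_lengths_nt(self) -> list[int]:
        lens = [e - s + 1 for s, e in self.introns()]
        return lens if self.strand == "+" else lens[::-1]


@dataclass
class TranscriptRecord:
    """A spliced coding sequence in transcript (5'→3') orientation."""

    transcript_id: str
    cds: str
    complete: bool = False

    def __len__(self) -> int:
        return len(self.cds)


@dataclass
class ProteinRecord:
    """Translated peptide over the 20 standard amino acids plus X."""

    protein_id: str
    residues: str
    complete: bool = True
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        bad = set(residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise GenomeIOError(f"{self.protein_id}: invalid residues {sorted(bad)}")
        self.residues = residues
        n_x = residues.count("X")
        self.degenerate = bool(residues) and (n_x / len(residues)) >= 0.10

    @property
    def length(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Read a multi-record nucleotide FASTA into ``{chrom_id: GenomeSequence}``.

    Duplicate IDs and empty files are rejected; sequences are uppercased.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    records: dict[str, GenomeSequence] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise GenomeIOError(f"{path}: duplicate FASTA id {rec.id!r}")
            records[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    if not records:
        raise GenomeIOError(f"{path}: empty or non-FASTA input")
    return records


def read_protein_fasta(path: str | Path) -> dict[str, ProteinRecord]:
    """Read a protein FASTA into ``{protein_id: ProteinRecord}``."""
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    records: dict[str, ProteinRecord] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise GenomeIOError(f"{path}: duplicate FASTA id {rec.id!r}")
            records[rec.id] = ProteinRecord(rec.id, str(rec.seq).rstrip("*"))
    if not records:
        raise GenomeIOError(f"{path}: empty or non-FASTA input")
    return records


def write_fasta(
    sequences: Mapping[str, str] | Iterable[GenomeSequence],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write sequences in deterministic (insertion) order, wrapped at ``width``."""
    if not isinstance(sequences, Mapping):
        sequences = {s.chrom_id: s.sequence for s in sequences}
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 (gene / mRNA / CDS subset)
# ---------------------------------------------------------------------------

_GFF_COLS = 9


def _gff_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GenomeIOError(f"GFF3 line {lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(
    path: str | Path,
    genome: Mapping[str, GenomeSequence] | None = None,
) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into :class:`GeneModel` objects.

    CDS features are grouped per transcript via their ``Parent`` attribute;
    each mRNA's ``Parent`` links it to its gene. When ``genome`` is given,
    exon coordinates are bounds-checked against chromosome lengths.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")

    mrna_to_gene: dict[str, str] = {}
    mrna_meta: dict[str, tuple[str, str]] = {}  # id -> (chrom, strand)
    cds_by_mrna: dict[str, list[tuple[int, int]]] = {}
    gene_biotype: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise GenomeIOError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise GenomeIOError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = _gff_attributes(attr_s, lineno)
            if ftype == "gene":
                gid = attrs.get("ID")
                if not gid:
                    raise GenomeIOError(f"{path}:{lineno}: gene without ID")
                bt = attrs.get("biotype", "unclassified")
                gene_biotype[gid] = bt if bt in BIOTYPES else "unclassified"
            elif ftype == "mRNA":
                mid = attrs.get("ID")
                if not mid:
                    raise GenomeIOError(f"{path}:{lineno}: mRNA without ID")
                mrna_to_gene[mid] = attrs.get("Parent", mid)
                mrna_meta[mid] = (chrom, strand)
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                if not parent:
                    raise GenomeIOError(f"{path}:{lineno}: CDS without Parent")
                if parent in mrna_meta:
                    pchrom, pstrand = mrna_meta[parent]
                    if pstrand != strand:
                        raise GenomeIOError(
                            f"{path}:{lineno}: CDS strand {strand!r} conflicts with "
                            f"mRNA {parent} strand {pstrand!r}"
                        )
                    if pchrom != chrom:
                        raise GenomeIOError(
                            f"{path}:{lineno}: CDS chrom {chrom!r} conflicts with mRNA {parent}"
                        )
                else:
                    mrna_meta[parent] = (chrom, strand)
                    mrna_to_gene.setdefault(parent, parent)
                cds_by_mrna.setdefault(parent, []).append((start, end))
                prev = cds_by_mrna[parent]
                if len({s for s in prev}) != len(prev):
                    raise GenomeIOError(f"{path}:{lineno}: duplicated CDS feature")
            # other feature types ignored (subset parser)

    models: list[GeneModel] = []
    for mid in sorted(cds_by_mrna):
        chrom, strand = mrna_meta[mid]
        gid = mrna_to_gene.get(mid, mid)
        model = GeneModel(
            gene_id=gid,
            transcript_id=mid,
            chrom_id=chrom,
            strand=strand,
            exons=cds_by_mrna[mid],
            biotype=gene_biotype.get(gid, "unclassified"),
        )
        if genome is not None:
            if chrom not in genome:
                raise GenomeIOError(f"{mid}: unknown chromosome {chrom!r}")
            if model.end > len(genome[chrom]):
                raise GenomeIOError(
                    f"{mid}: exon end {model.end} beyond chromosome "
                    f"{chrom} length {len(genome[chrom])}"
                )
        models.append(model)
    return models


def write_gff3(
    models: Sequence[GeneModel],
    path: str | Path,
    seq_lengths: Mapping[str, int] | None = None,
) -> None:
    """Emit gene/mRNA/CDS rows, deterministically ordered by (chrom, start, id)."""
    ordered = sorted(models, key=lambda m: (m.chrom_id, m.start, m.transcript_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for chrom in sorted(seq_lengths):
                fh.write(f"##sequence-region {chrom} 1 {seq_lengths[chrom]}\n")
        seen_genes: set[str] = set()
        for m in ordered:
            if m.gene_id not in seen_genes:
                seen_genes.add(m.gene_id)
                fh.write(
                    f"{m.chrom_id}\ttpsfam\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id};biotype={m.biotype}\n"
                )
            fh.write(
                f"{m.chrom_id}\ttpsfam\tmRNA\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.transcript_id};Parent={m.gene_id}\n"
            )
            # CDS phase column: cumulative coding length determines the frame offset
            exon_order = m.exons if m.strand == "+" else m.exons[::-1]
            cum = 0
            phases = []
            for s, e in exon_order:
                phases.append((3 - cum % 3) % 3)
                cum += e - s + 1
            if m.strand == "-":
                phases = phases[::-1]
                exon_order = exon_order[::-1]
            for (s, e), ph in zip(exon_order, phases):
                fh.write(
                    f"{m.chrom_id}\ttpsfam\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph}\t"
                    f"ID=cds-{m.transcript_id};Parent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# CDS assembly and translation
# ---------------------------------------------------------------------------

def extract_cds(model: GeneModel, genome: GenomeSequence | Mapping[str, GenomeSequence]) -> TranscriptRecord:
    """Splice exon substrings into the transcript-orientation CDS.

    Minus-strand models are reverse-complemented with exon order reversed.
    """
    if not isinstance(genome, GenomeSequence):
        if model.chrom_id not in genome:
            raise GenomeIOError(f"{model.transcript_id}: chromosome {model.chrom_id!r} not in genome")
        genome = genome[model.chrom_id]
    if genome.chrom_id != model.chrom_id:
        raise GenomeIOError(
            f"{model.transcript_id}: model chrom {model.chrom_id!r} != genome {genome.chrom_id!r}"
        )
    if model.end > len(genome):
        raise GenomeIOError(f"{model.transcript_id}: exon beyond chromosome end")
    parts = [genome.sequence[to_slice(s, e)] for s, e in model.exons]
    cds = "".join(parts)
    if model.strand == "-":
        cds = reverse_complement(cds)
    complete = (
        len(cds) % 3 == 0
        and cds.startswith("ATG")
        and cds[-3:] in STOP_CODONS
        and _first_stop_index(cds) == len(cds) // 3 - 1
    )
    return TranscriptRecord(model.transcript_id, cds, complete=complete)


def _first_stop_index(cds: str) -> int:
    """Codon index of the first stop, or -1 if none."""
    for i in range(0, len(cds) - len(cds) % 3, 3):
        if cds[i : i + 3] in STOP_CODONS:
            return i // 3
    return -1


def translate(cds: str, protein_id: str = "protein") -> ProteinRecord:
    """Translate a CDS with the standard genetic code.

    Residues run up to (not including) the first stop codon; the record is
    flagged ``complete`` only when exactly one stop terminates the frame.
    Codons containing N translate to X (positional bookkeeping preserved).
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise GenomeIOError(f"{protein_id}: CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds).translate(table=1))
    stop = aa.find("*")
    if stop == -1:
        residues, complete = aa, False
    else:
        residues = aa[:stop]
        complete = stop == len(aa) - 1
    return ProteinRecord(protein_id, residues, complete=complete)


def find_longest_orf(seq: str, min_len_nt: int = 300) -> TranscriptRecord:
    """Longest ATG→stop open reading frame on either strand.

    Ties are broken by earliest start on the plus strand (then earliest on
    the minus strand). Returns an empty, incomplete record when no ORF of at
    least ``min_len_nt`` exists.
    """
    seq = seq.upper()
    best: tuple[int, int, int, str] | None = None  # (-len, strand_rank, start, orf)
    for strand_rank, s in enumerate((seq, reverse_complement(seq))):
        for frame in range(3):
            start: int | None = None
            for i in range(frame, len(s) - 2, 3):
                codon = s[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        orf = s[start : i + 3]
                        key = (-len(orf), strand_rank, start, orf)
                        if best is None or key < best:
                            best = key
                        start = None
                elif start is None and codon == "ATG":
                    start = i
    if best is None or -best[0] < min_len_nt:
        return TranscriptRecord("orf", "", complete=False)
    return TranscriptRecord("orf", best[3], complete=True)
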