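"""Locus-level transcript models and the splice-junction reference.

Expression is quantified per locus: the exons of all transcript variants of
a gene are merged into one combined model representing total locus
expression. To account for incomplete cap-site knowledge, the 5' end of each
model is extended by up to 100 bases — but never beyond the 3' end of an
upstream nearby exon of another gene on the same strand. For nuclei, the
whole locus (extension through last exon, introns included) is used instead.

Reads that fail genomic alignment are rescued on an artificial junction
reference holding every splice junction a read could span: for each exon
pair of a locus, (read_length - 1) bases of flank from each side, with a
lift table translating junction coordinates back to genomic positions.

All coordinates are 0-based half-open, matching refFlat.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

DEFAULT_EXTENSION = 100
DEFAULT_READ_LENGTH = 45


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class TranscriptModel:
    """One refFlat row: a transcript with its exon structure."""

    gene_name: str
    name: str
    chrom: str
    strand: str
    exons: list[Interval]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.name} has no exons")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in transcript {self.name}")
        if any(s >= e for s, e in self.exons):
            raise ValueError(f"empty exon in transcript {self.name}")


@dataclass
class LocusModel:
    """Merged exon model of one gene locus, with 5' extension."""

    gene_name: str
    chrom: str
    strand: str
    merged_exons: list[Interval]
    extended_start: int = field(default=-1)
    extended_end: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.extended_start < 0:
            self.extended_start = self.merged_exons[0][0]
        if self.extended_end < 0:
            self.extended_end = self.merged_exons[-1][1]

    @property
    def start(self) -> int:
        return self.merged_exons[0][0]

    @property
    def end(self) -> int:
        return self.merged_exons[-1][1]

    @property
    def whole_locus(self) -> Interval:
        """Extension through last exon, introns included (nuclei counting)."""
        return (self.extended_start, self.extended_end)

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the (extended) locus 5' end."""
        return self.extended_start if self.strand == "+" else self.extended_end - 1

    def extended_exons(self) -> list[Interval]:
        """Merged exons with the 5'-terminal exon grown by the extension."""
        exons = list(self.merged_exons)
        if self.strand == "+":
            exons[0] = (self.extended_start, exons[0][1])
        else:
            exons[-1] = (exons[-1][0], self.extended_end)
        return exons


REFFLAT_COLUMNS = (
    "geneName name chrom strand txStart txEnd cdsStart cdsEnd "
    "exonCount exonStarts exonEnds"
).split()


def load_refflat(path: str) -> list[TranscriptModel]:
    """Parse a UCSC refFlat table into transcript models.

    exonStarts/exonEnds are comma-separated 0-based half-open lists; a row
    whose exon lists disagree with exonCount, or with txStart > txEnd, is a
    hard error naming the offending line.
    """
    models: list[TranscriptModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ValueError(f"{path}:{lineno}: expected 11 refFlat columns")
            gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            tx_start, tx_end = int(fields[4]), int(fields[5])
            if tx_start > tx_end:
                raise ValueError(f"{path}:{lineno}: txStart > txEnd")
            n_exons = int(fields[8])
            starts = [int(x) for x in fields[9].rstrip(",").split(",") if x]
            ends = [int(x) for x in fields[10].rstrip(",").split(",") if x]
            if len(starts) != n_exons or len(ends) != n_exons:
                raise ValueError(
                    f"{path}:{lineno}: exonCount={n_exons} but "
                    f"{len(starts)} starts / {len(ends)} ends"
                )
            models.append(
                TranscriptModel(gene, name, chrom, strand, list(zip(starts, ends)))
            )
    return models


def write_refflat(models: Iterable[TranscriptModel], path: str) -> None:
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                f"{m.gene_name}\t{m.name}\t{m.chrom}\t{m.strand}\t"
                f"{m.exons[0][0]}\t{m.exons[-1][1]}\t{m.exons[0][0]}\t"
                f"{m.exons[-1][1]}\t{len(m.exons)}\t{starts}\t{ends}\n"
            )


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted disjoint list."""
    merged: list[Interval] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_locus_models(models: Sequence[TranscriptModel]) -> list[LocusModel]:
    """Merge transcript variants into combined per-locus exon models.

    Transcripts are grouped by (gene name, chromosome, strand); a gene name
    appearing on two chromosomes or strands yields separate loci with a
    warning. Output order is deterministic (chrom, start, gene).
    """
    groups: dict[tuple[str, str, str], list[TranscriptModel]] = {}
    for m in models:
        groups.setdefault((m.gene_name, m.chrom, m.strand), []).append(m)
    by_name: dict[str, int] = {}
    for gene, _, _ in groups:
        by_name[gene] = by_name.get(gene, 0) + 1
    for gene, n in by_name.items():
        if n > 1:
            logger.warning("gene %s maps to %d chromosome/strand loci", gene, n)
    loci = [
        LocusModel(
            gene, chrom, strand,
            merge_intervals(ex for m in group for ex in m.exons),
        )
        for (gene, chrom, strand), group in groups.items()
    ]
    loci.sort(key=lambda l: (l.chrom, l.start, l.gene_name))
    return loci


def extend_5prime(
    loci: Sequence[LocusModel],
    extension: int = DEFAULT_EXTENSION,
    chrom_lengths: dict[str, int] | None = None,
) -> list[LocusModel]:
    """Extend each locus 5' end by up to ``extension`` bases.

    The extension is clamped at the chromosome boundary and stops exactly at
    the 3' end of the nearest exon of *another* gene on the same strand, if
    that exon end lies inside the extension window (an exon farther upstream
    cannot constrain it). Antisense overlaps do not constrain the extension.
    Returns new LocusModel objects; input order is preserved.
    """
    out: list[LocusModel] = []
    for locus in loci:
        ext_start, ext_end = locus.start, locus.end
        if locus.strand == "+":
            lo = max(0, locus.start - extension)
            bound = lo
            for other in loci:
                if (
                    other.gene_name == locus.gene_name
                    or other.chrom != locus.chrom
                    or other.strand != locus.strand
                ):
                    continue
                for _, exon_end in other.merged_exons:
                    if lo < exon_end <= locus.start:
                        bound = max(bound, exon_end)
            ext_start = bound
        else:
            hi = locus.end + extension
            if chrom_lengths and locus.chrom in chrom_lengths:
                hi = min(hi, chrom_lengths[locus.chrom])
            bound = hi
            for other in loci:
                if (
                    other.gene_name == locus.gene_name
                    or other.chrom != locus.chrom
                    or other.strand != locus.strand
                ):
                    continue
                for exon_start, _ in other.merged_exons:
                    if locus.end <= exon_start < hi:
                        bound = min(bound, exon_start)
            ext_end = bound
        out.append(
            LocusModel(
                locus.gene_name, locus.chrom, locus.strand,
                list(locus.merged_exons), ext_start, ext_end,
            )
        )
    return out


def whole_locus_intervals(loci: Sequence[LocusModel]) -> list[tuple[str, int, int, str, str]]:
    """(chrom, start, end, gene, strand) rows spanning extension..last exon.

    Adjacent loci may overlap; overlaps are preserved, never merged.
    """
    return [
        (l.chrom, l.whole_locus[0], l.whole_locus[1], l.gene_name, l.strand)
        for l in loci
    ]


@dataclass
class JunctionContig:
    """One splice junction: donor-side and acceptor-side genomic flanks."""

    name: str
    chrom: str
    strand: str
    gene_name: str
    left: Interval  # genomic donor-side flank
    right: Interval  # genomic acceptor-side flank
    sequence: str

    @property
    def joint(self) -> int:
        """Local coordinate of the first acceptor-side base."""
        return self.left[1] - self.left[0]

    def lift(self, local: int) -> int:
        """Map a junction-local coordinate to its genomic position."""
        if not 0 <= local < len(self.sequence):
            raise IndexError(f"position {local} outside junction {self.name}")
        if local < self.joint:
            return self.left[0] + local
        return self.right[0] + (local - self.joint)


@dataclass
class JunctionReference:
    """All splice junctions of a locus set, as alignable contigs."""

    contigs: dict[str, JunctionContig]

    def sequences(self) -> dict[str, str]:
        return {name: c.sequence for name, c in self.contigs.items()}

    def write_fasta(self, path: str) -> None:
        with open(path, "w") as fh:
            for name, c in self.contigs.items():
                fh.write(f">{name}\n{c.sequence}\n")

    def write_lift_table(self, path: str) -> None:
        """TSV: junction name, chrom, strand, gene, block starts/ends."""
        with open(path, "w") as fh:
            fh.write(
                "junction\tchrom\tstrand\tgene\tleft_start\tleft_end\t"
                "right_start\tright_end\n"
            )
            for name, c in self.contigs.items():
                fh.write(
                    f"{name}\t{c.chrom}\t{c.strand}\t{c.gene_name}\t"
                    f"{c.left[0]}\t{c.left[1]}\t{c.right[0]}\t{c.right[1]}\n"
                )


def read_junction_reference(fasta_path: str, lift_table_path: str) -> JunctionReference:
    """Reload a junction reference from its FASTA + lift-table TSV."""
    seqs = load_genome_fasta(fasta_path)
    contigs: dict[str, JunctionContig] = {}
    with open(lift_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = [
            "junction", "chrom", "strand", "gene",
            "left_start", "left_end", "right_start", "right_end",
        ]
        if header != expected:
            raise ValueError(f"unexpected lift-table header: {header}")
        for line in fh:
            name, chrom, strand, gene, ls, le, rs, re_ = line.rstrip("\n").split("\t")
            if name not in seqs:
                raise ValueError(f"junction {name} missing from {fasta_path}")
            contigs[name] = JunctionContig(
                name, chrom, strand, gene,
                (int(ls), int(le)), (int(rs), int(re_)), seqs[name],
            )
    return JunctionReference(contigs)


def build_junction_reference(
    loci: Sequence[LocusModel],
    genome: dict[str, str],
    read_length: int = DEFAULT_READ_LENGTH,
) -> JunctionReference:
    """Build the artificial junction reference from merged locus models.

    For every ordered pair of exons within a locus (donor genomically before
    acceptor), a contig of (read_length - 1) bases from each side of the
    junction is emitted — the maximum span a read of that length can cover.
    Flanks are truncated where an exon is shorter than the flank.
    """
    flank = read_length - 1
    contigs: dict[str, JunctionContig] = {}
    for locus in loci:
        if locus.chrom not in genome:
            raise KeyError(f"chromosome {locus.chrom} missing from genome")
        chrom_seq = genome[locus.chrom]
        exons = locus.merged_exons
        for i, j in combinations(range(len(exons)), 2):
            (ds, de), (as_, ae) = exons[i], exons[j]
            left = (max(ds, de - flank), de)
            right = (as_, min(ae, as_ + flank))
            seq = chrom_seq[left[0]:left[1]] + chrom_seq[right[0]:right[1]]
            name = f"{locus.gene_name}|{locus.chrom}|{i}|{j}"
            contigs[name] = JunctionContig(
                name, locus.chrom, locus.strand, locus.gene_name, left, right, seq
            )
    return JunctionReference(contigs)


def translate_junction_alignment(
    reference: JunctionReference, junction_name: str, start: int, length: int
) -> list[tuple[str, int, int]]:
    """Translate a junction-contig alignment back to genomic blocks.

    Returns one (chrom, start, end) block if the alignment lies entirely on
    one side of the joint, else two blocks abutting the exon boundaries.
    Zero-length or out-of-range alignments are hard errors.
    """
    if length <= 0:
        raise ValueError("zero-length alignment")
    try:
        contig = reference.contigs[junction_name]
    except KeyError as exc:
        raise KeyError(f"unknown junction contig {junction_name!r}") from exc
    end = start + length
    if start < 0 or end > len(contig.sequence):
        raise ValueError(
            f"alignment [{start},{end}) outside junction {junction_name} "
            f"of length {len(contig.sequence)}"
        )
    joint = contig.joint
    if end <= joint:
        return [(contig.chrom, contig.left[0] + start, contig.left[0] + end)]
    if start >= joint:
        return [
            (contig.chrom, contig.right[0] + start - joint, contig.right[0] + end - joint)
        ]
    return [
        (contig.chrom, contig.left[0] + start, contig.left[1]),
        (contig.chrom, contig.right[0], contig.right[0] + end - joint),
    ]


def load_genome_fasta(path: str) -> dict[str, str]:
    """Read a genome FASTA into a {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_genome_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def locus_spliced_sequence(locus: LocusModel, genome: dict[str, str]) -> str:
    """5'->3' mRNA sequence of the merged (unextended) locus model."""
    chrom_seq = genome[locus.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in locus.merged_exons)
    return seq if locus.strand == "+" else reverse_complement(seq)


def write_locus_bed(loci: Sequence[LocusModel], path: str) -> None:
    """BED-like TSV: chrom, start, end, gene, strand, extended_start/end."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene\tstrand\textended_start\textended_end\n")
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.gene_name}\t{l.strand}\t"
                f"{l.extended_start}\t{l.extended_end}\n"
            )
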