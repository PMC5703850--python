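"""Read alignment: a built-in ungapped aligner plus SAM ingest.

The mapping contract mirrors a Bowtie-1-style run: ungapped end-to-end
alignment with up to three mismatches, reporting all alternative mappings up
to a cap of 24 — a read exceeding the cap is suppressed entirely. Reads that
fail genomic alignment are realigned against the artificial splice-junction
reference and their coordinates lifted back to genomic blocks.

The built-in aligner is exact for its contract (it enumerates every position
on both strands within the mismatch budget, using a pigeonhole seed index)
and is intended for toy-scale references; production data should use an
external aligner and flow in through :func:`ingest_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pysam

from .read_processing import ProcessedRead, parse_tagged_id, tag_read_id
from .reference_model import (
    JunctionReference,
    reverse_complement,
    translate_junction_alignment,
)
from .plate_layout import WellAddress

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 3
DEFAULT_MAX_HITS = 24

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class Mapping:
    """One candidate placement of a read: blocks are 0-based half-open."""

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mismatches: int = 0

    @property
    def pos(self) -> int:
        """Leftmost genomic base."""
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the read's 5' base (strand-aware)."""
        return self.blocks[0][0] if self.strand == "+" else self.blocks[-1][1] - 1

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class ReadAlignment:
    read_id: str
    well: WellAddress | None
    umi: str
    payload: str = ""
    mappings: list[Mapping] = field(default_factory=list)
    suppressed: bool = False

    @property
    def mapping_status(self) -> str:
        if self.suppressed:
            return "suppressed"
        if not self.mappings:
            return "unmapped"
        return "unique" if len(self.mappings) == 1 else "multi"


class NaiveAligner:
    """Exhaustive ungapped Hamming-distance aligner over small references.

    Uses the pigeonhole principle: a read with at most ``max_mismatches``
    mismatches split into ``max_mismatches + 1`` disjoint seeds has at least
    one mismatch-free seed, so an exact k-mer index over the reference finds
    every hit. N (in read or reference) always counts as a mismatch.
    """

    def __init__(
        self,
        sequences: dict[str, str],
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        max_hits: int = DEFAULT_MAX_HITS,
    ):
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.max_mismatches = max_mismatches
        self.max_hits = max_hits
        self._indexes: dict[int, dict[str, dict[str, list[int]]]] = {}

    def _index_for(self, k: int) -> dict[str, dict[str, list[int]]]:
        if k not in self._indexes:
            idx: dict[str, dict[str, list[int]]] = {}
            for name, seq in self.sequences.items():
                kmers: dict[str, list[int]] = {}
                for p in range(len(seq) - k + 1):
                    kmer = seq[p:p + k]
                    if "N" in kmer:
                        continue
                    kmers.setdefault(kmer, []).append(p)
                idx[name] = kmers
            self._indexes[k] = idx
        return self._indexes[k]

    @staticmethod
    def _mismatches(a: str, b: str, budget: int) -> int:
        mm = 0
        for x, y in zip(a, b):
            if x != y or x == "N":
                mm += 1
                if mm > budget:
                    return mm
        return mm

    def _hits_one_strand(self, query: str, strand: str) -> Iterator[Mapping]:
        L = len(query)
        budget = self.max_mismatches
        n_seeds = budget + 1
        seed_len = L // n_seeds
        if seed_len < 1:
            # read shorter than the seed budget: brute scan
            for name, seq in self.sequences.items():
                for p in range(len(seq) - L + 1):
                    mm = self._mismatches(query, seq[p:p + L], budget)
                    if mm <= budget:
                        yield Mapping(name, strand, ((p, p + L),), mm)
            return
        index = self._index_for(seed_len)
        for name, seq in self.sequences.items():
            if len(seq) < L:
                continue
            kmers = index[name]
            seen: set[int] = set()
            for i in range(n_seeds):
                o = i * seed_len
                for p in kmers.get(query[o:o + seed_len], ()):
                    pos = p - o
                    if pos < 0 or pos + L > len(seq) or pos in seen:
                        continue
                    seen.add(pos)
                    mm = self._mismatches(query, seq[pos:pos + L], budget)
                    if mm <= budget:
                        yield Mapping(name, strand, ((pos, pos + L),), mm)

    def align(self, payload: str) -> list[Mapping]:
        """All mappings of the payload (both strands) within the budget.

        Returns the complete list, deterministically ordered; the 24-hit
        suppression cap is applied by :func:`align_naive`, not here.
        """
        payload = payload.upper()
        if not payload:
            return []
        bad = set(payload) - _VALID_BASES
        if bad:
            raise ValueError(f"payload contains non-ACGTN characters: {sorted(bad)}")
        hits = list(self._hits_one_strand(payload, "+"))
        hits += list(self._hits_one_strand(reverse_complement(payload), "-"))
        hits.sort(key=lambda m: (m.chrom, m.pos, m.strand))
        return hits


def align_naive(
    read: ProcessedRead,
    aligner: NaiveAligner,
) -> ReadAlignment:
    """Align one processed read; apply the alternative-mapping cap."""
    mappings = aligner.align(read.payload)
    alignment = ReadAlignment(
        read_id=tag_read_id(read),
        well=read.well,
        umi=read.umi,
        payload=read.payload,
    )
    if len(mappings) > aligner.max_hits:
        alignment.suppressed = True
    else:
        alignment.mappings = mappings
    return alignment


def align_reads(
    reads: Iterable[ProcessedRead], aligner: NaiveAligner
) -> Iterator[ReadAlignment]:
    for read in reads:
        if read.kept:
            yield align_naive(read, aligner)


def realign_unmapped(
    alignments: Iterable[ReadAlignment],
    junction_reference: JunctionReference,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
) -> Iterator[ReadAlignment]:
    """Second-pass alignment of unmapped reads on the junction reference.

    Junction hits are translated back to genomic split alignments; hits from
    different junction contigs that lift to identical genomic blocks are
    deduplicated. Mapped reads pass through untouched; reads without
    junction hits stay unmapped.
    """
    junction_aligner = NaiveAligner(
        junction_reference.sequences(), max_mismatches, max_hits=10**9
    )
    for alignment in alignments:
        if alignment.mapping_status != "unmapped" or not alignment.payload:
            yield alignment
            continue
        genomic: dict[tuple, Mapping] = {}
        for hit in junction_aligner.align(alignment.payload):
            blocks = translate_junction_alignment(
                junction_reference, hit.chrom, hit.pos, hit.end - hit.pos
            )
            mapping = Mapping(
                blocks[0][0],
                hit.strand,
                tuple((s, e) for _, s, e in blocks),
                hit.mismatches,
            )
            key = (mapping.chrom, mapping.strand, mapping.blocks)
            if key not in genomic or mapping.mismatches < genomic[key].mismatches:
                genomic[key] = mapping
        mappings = sorted(genomic.values(), key=lambda m: (m.chrom, m.pos, m.strand))
        if len(mappings) > max_hits:
            alignment.suppressed = True
        else:
            alignment.mappings = mappings
        yield alignment


def write_sam(
    alignments: Iterable[ReadAlignment],
    reference_lengths: dict[str, int],
    path: str,
) -> None:
    """Write alignments as plain SAM (primary + secondary records, NM tags).

    Unmapped reads are emitted as unmapped records so the stream round-trips
    through :func:`ingest_sam` losslessly; suppressed reads are omitted.
    """
    names = list(reference_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": reference_lengths[n]} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for alignment in alignments:
            if alignment.suppressed:
                continue
            if not alignment.mappings:
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = alignment.read_id
                rec.query_sequence = alignment.payload
                rec.is_unmapped = True
                rec.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(alignment.payload)
                )
                out.write(rec)
                continue
            for i, m in enumerate(alignment.mappings):
                rec = pysam.AlignedSegment(out.header)
                rec.query_name = alignment.read_id
                rec.reference_id = tid[m.chrom]
                rec.reference_start = m.pos
                rec.is_reverse = m.strand == "-"
                rec.is_secondary = i > 0
                seq = (
                    alignment.payload
                    if m.strand == "+"
                    else reverse_complement(alignment.payload)
                )
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                cigar = []
                prev_end = None
                for bs, be in m.blocks:
                    if prev_end is not None:
                        cigar.append((3, bs - prev_end))  # N: intron skip
                    cigar.append((0, be - bs))  # M
                    prev_end = be
                rec.cigartuples = cigar
                rec.set_tag("NM", m.mismatches)
                out.write(rec)


def ingest_sam(
    path: str,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    max_hits: int = DEFAULT_MAX_HITS,
    missing_nm: str = "drop",
) -> list[ReadAlignment]:
    """Read SAM/BAM from an external aligner into ReadAlignment objects.

    Well and UMI are recovered from the ``:WELL:...:UMI:...`` read-ID
    convention. Mappings with NM > ``max_mismatches`` are dropped; a read
    retaining more than ``max_hits`` mappings is suppressed. Records without
    an NM tag are dropped with a warning (``missing_nm='zero'`` assumes 0).
    """
    if missing_nm not in ("drop", "zero"):
        raise ValueError("missing_nm must be 'drop' or 'zero'")
    reads: dict[str, ReadAlignment] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh:
            name = rec.query_name
            if name not in reads:
                try:
                    _, well, umi = parse_tagged_id(name)
                except ValueError:
                    well, umi = None, ""
                payload = rec.query_sequence or ""
                if rec.is_mapped and rec.is_reverse:
                    payload = reverse_complement(payload)
                reads[name] = ReadAlignment(name, well, umi, payload)
            alignment = reads[name]
            if rec.is_unmapped:
                continue
            if not alignment.payload and rec.query_sequence:
                payload = rec.query_sequence
                if rec.is_reverse:
                    payload = reverse_complement(payload)
                alignment.payload = payload
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
            elif missing_nm == "zero":
                nm = 0
            else:
                logger.warning("record for %s lacks NM tag; dropped", name)
                continue
            if nm > max_mismatches:
                continue
            blocks = tuple(
                (s, e) for s, e in (rec.get_blocks() or [(rec.reference_start, rec.reference_end)])
            )
            alignment.mappings.append(
                Mapping(rec.reference_name, "-" if rec.is_reverse else "+", blocks, nm)
            )
    out = list(reads.values())
    for alignment in out:
        alignment.mappings.sort(key=lambda m: (m.chrom, m.pos, m.strand))
        if len(alignment.mappings) > max_hits:
            alignment.suppressed = True
            alignment.mappings = []
    out.sort(key=lambda a: a.read_id)
    return out
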