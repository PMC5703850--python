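"""5' UMI read QC and demultiplexing.

Each 45 bp cDNA read is expected to start with a 6 bp UMI, followed by three
template-switch guanosines, then 5'-proximal transcript sequence. The filter
chain, applied in order to every read:

1. drop reads flagged invalid by the instrument (the ':Y:' FASTQ flag);
2. trim the maximal 3' run of B-quality bases (Phred 2);
3. require Phred >= 17 on all six UMI bases, cut the UMI away;
4. require bases 7-9 to be G; trim the G run up to nine G total
   (template-switch derived);
5. trim a terminal poly(A) run; discard if < 25 transcript bases remain;
6. discard low-complexity payloads (fewer than six non-A bases, or a
   dinucleotide repeat with fewer than six other bases at either end);
7. demultiplex by the combined dual-index barcodes; unassignable reads are
   counted but not kept.

Every input read appears exactly once in the output with a kept/discarded
status, and per-reason discard tallies sum to the total discarded.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .plate_layout import BarcodeSet, WellAddress, address_from_indices

UMI_LENGTH = 6
N_TEMPLATE_SWITCH_G = 3

# Illumina read-segment quality indicator "B" = Phred 2, independent of the
# ASCII offset used on disk.
B_QUALITY_PHRED = 2


class DiscardReason(str, enum.Enum):
    INVALID_FLAG = "invalid_flag"
    EMPTY_AFTER_TRIM = "empty_after_trim"
    UMI_QUALITY = "umi_quality"
    MISSING_GGG = "missing_ggg"
    POLYA_SHORT = "polyA_short"
    LOW_COMPLEXITY = "low_complexity"
    UNASSIGNED_BARCODE = "unassigned_barcode"


@dataclass
class ReadParams:
    """Tunable thresholds of the read-QC chain (defaults per protocol)."""

    min_umi_phred: int = 17
    max_g_trim: int = 9
    min_remaining: int = 25
    min_polya_run: int = 5
    min_dinucleotide_repeat: int = 10  # bases, i.e. 5 repeat units
    min_non_a: int = 6
    max_flank: int = 6  # dinucleotide repeat disqualifies if both flanks < this
    max_barcode_mismatches: int = 0
    phred_offset: int = 33  # config switch: 64 for legacy Illumina encoding


@dataclass
class ProcessedRead:
    read_id: str
    umi: str = ""
    payload: str = ""
    well: WellAddress | None = None
    status: str = "kept"  # kept | discarded
    discard_reason: DiscardReason | None = None

    @property
    def kept(self) -> bool:
        return self.status == "kept"


@dataclass
class QCTally:
    """Conservation accounting for one processing run."""

    total: int = 0
    kept: int = 0
    discarded: Counter = field(default_factory=Counter)
    invalid_index_records: int = 0

    def record(self, read: ProcessedRead) -> None:
        self.total += 1
        if read.kept:
            self.kept += 1
        else:
            self.discarded[read.discard_reason.value] += 1

    @property
    def n_discarded(self) -> int:
        return sum(self.discarded.values())

    def as_dict(self) -> dict[str, int]:
        out = {"total": self.total, "kept": self.kept}
        out.update({r.value: self.discarded.get(r.value, 0) for r in DiscardReason})
        return out

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("category\tcount\n")
            for k, v in self.as_dict().items():
                fh.write(f"{k}\t{v}\n")


def trim_b_tail(
    sequence: str, qualities: list[int], b_phred: int = B_QUALITY_PHRED
) -> tuple[str, list[int]]:
    """Remove the maximal 3' run of bases at the B quality value.

    Interior B-quality bases are untouched; only the terminal run goes.
    """
    if len(sequence) != len(qualities):
        raise ValueError("sequence and qualities differ in length")
    end = len(qualities)
    while end > 0 and qualities[end - 1] == b_phred:
        end -= 1
    return sequence[:end], qualities[:end]


def extract_umi_and_trim_g(
    sequence: str,
    qualities: list[int],
    min_umi_phred: int = 17,
    max_g_trim: int = 9,
) -> tuple[str, str] | DiscardReason:
    """Split a quality-trimmed read into (UMI, payload), or a discard reason.

    The first six bases are the UMI and must all reach the Phred gate; bases
    7-9 must be template-switch G's. The G run starting at base 7 is trimmed
    up to ``max_g_trim`` G's in total — any G beyond the cap stays in the
    payload (it may be genuine transcript sequence).
    """
    if len(sequence) < UMI_LENGTH + N_TEMPLATE_SWITCH_G:
        return DiscardReason.EMPTY_AFTER_TRIM
    if any(q < min_umi_phred for q in qualities[:UMI_LENGTH]):
        return DiscardReason.UMI_QUALITY
    umi = sequence[:UMI_LENGTH]
    rest = sequence[UMI_LENGTH:]
    if rest[:N_TEMPLATE_SWITCH_G] != "G" * N_TEMPLATE_SWITCH_G:
        return DiscardReason.MISSING_GGG
    n_g = 0
    while n_g < len(rest) and n_g < max_g_trim and rest[n_g] == "G":
        n_g += 1
    return umi, rest[n_g:]


def polya_trim_filter(
    payload: str, min_remaining: int = 25, min_polya_run: int = 5
) -> str | DiscardReason:
    """Trim a terminal poly(A) run; discard if too little sequence remains.

    A terminal A-run shorter than ``min_polya_run`` does not count as
    poly(A) and is left in place. The trimmed payload is kept (the remainder
    is the alignable 5' sequence) unless it falls below ``min_remaining``.
    """
    end = len(payload)
    while end > 0 and payload[end - 1] == "A":
        end -= 1
    run = len(payload) - end
    if run < min_polya_run:
        return payload
    trimmed = payload[:end]
    if len(trimmed) < min_remaining:
        return DiscardReason.POLYA_SHORT
    return trimmed


_DINUC_RE_CACHE: dict[int, re.Pattern] = {}


def _dinuc_pattern(min_len: int) -> re.Pattern:
    # perfect repeat of a 2-base motif with two distinct bases, length >= min_len
    if min_len not in _DINUC_RE_CACHE:
        n_units = (min_len + 1) // 2
        _DINUC_RE_CACHE[min_len] = re.compile(
            r"([ACGT])(?!\1)([ACGT])(?:\1\2){%d,}\1?" % (n_units - 1)
        )
    return _DINUC_RE_CACHE[min_len]


def low_complexity_filter(
    payload: str,
    min_non_a: int = 6,
    min_dinucleotide_repeat: int = 10,
    max_flank: int = 6,
) -> bool:
    """True if the payload passes; False if it is low complexity.

    Fails when fewer than ``min_non_a`` non-A bases remain, or when a perfect
    dinucleotide repeat of at least ``min_dinucleotide_repeat`` bases sits
    with fewer than ``max_flank`` other bases at *both* ends.
    """
    non_a = sum(1 for b in payload if b != "A")
    if non_a < min_non_a:
        return False
    pat = _dinuc_pattern(min_dinucleotide_repeat)
    for m in pat.finditer(payload):
        if m.end() - m.start() < min_dinucleotide_repeat:
            continue
        left = m.start()
        right = len(payload) - m.end()
        if left < max_flank and right < max_flank:
            return False
    return True


def _is_invalid_flagged(read_id: str) -> bool:
    """Illumina CASAVA 1.8+ IDs carry ' <read>:<Y|N>:...' — Y means filtered."""
    if " " not in read_id:
        return False
    parts = read_id.split(" ", 1)[1].split(":")
    return len(parts) >= 2 and parts[1] == "Y"


def process_read(
    read_id: str,
    sequence: str,
    qualities: list[int],
    index1: str,
    index2: str,
    barcode_set: BarcodeSet,
    params: ReadParams,
    tally: QCTally | None = None,
) -> ProcessedRead:
    """Run the full filter chain on one read."""

    def discarded(reason: DiscardReason) -> ProcessedRead:
        out = ProcessedRead(read_id, status="discarded", discard_reason=reason)
        if tally is not None:
            tally.record(out)
        return out

    if _is_invalid_flagged(read_id):
        return discarded(DiscardReason.INVALID_FLAG)
    seq, quals = trim_b_tail(sequence.upper(), qualities)
    got = extract_umi_and_trim_g(seq, quals, params.min_umi_phred, params.max_g_trim)
    if isinstance(got, DiscardReason):
        return discarded(got)
    umi, payload = got
    if not payload:
        return discarded(DiscardReason.EMPTY_AFTER_TRIM)
    payload = polya_trim_filter(payload, params.min_remaining, params.min_polya_run)
    if isinstance(payload, DiscardReason):
        return discarded(payload)
    if len(payload) < params.min_remaining:
        return discarded(DiscardReason.POLYA_SHORT)
    if not low_complexity_filter(
        payload, params.min_non_a, params.min_dinucleotide_repeat, params.max_flank
    ):
        return discarded(DiscardReason.LOW_COMPLEXITY)
    try:
        well = address_from_indices(
            index1, index2, barcode_set, params.max_barcode_mismatches
        )
    except ValueError:
        if tally is not None:
            tally.invalid_index_records += 1
        well = None
    if well is None:
        return discarded(DiscardReason.UNASSIGNED_BARCODE)
    out = ProcessedRead(read_id, umi=umi, payload=payload, well=well)
    if tally is not None:
        tally.record(out)
    return out


def _fastq_records(path: str) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def process_fastq(
    r1_path: str,
    i1_path: str,
    i2_path: str,
    barcode_set: BarcodeSet,
    params: ReadParams | None = None,
    tally: QCTally | None = None,
) -> Iterator[ProcessedRead]:
    """Process three parallel FASTQ streams (cDNA read, Index 1, Index 2).

    The streams must have the same record count and order; a read-ID mismatch
    or ragged stream is a hard error. Yields one ProcessedRead per input
    record; pass a QCTally to collect conservation counts.
    """
    params = params or ReadParams()
    offset = params.phred_offset
    streams = [_fastq_records(p) for p in (r1_path, i1_path, i2_path)]
    record_no = 0
    for recs in zip(*streams, strict=True):
        record_no += 1
        (rid, seq, qual), (rid1, i1, _), (rid2, i2, _) = recs
        core = rid.split(" ")[0]
        if rid1.split(" ")[0] != core or rid2.split(" ")[0] != core:
            raise ValueError(
                f"desynchronized FASTQ streams at record {record_no}: "
                f"{core!r} vs {rid1.split(' ')[0]!r} / {rid2.split(' ')[0]!r}"
            )
        quals = [ord(c) - offset for c in qual]
        yield process_read(rid, seq, quals, i1, i2, barcode_set, params, tally)


def tag_read_id(read: ProcessedRead) -> str:
    """Encode well and UMI into the read ID: ``orig:WELL:s01w005:UMI:ACGTAC``.

    The convention round-trips through external SAM-emitting aligners.
    """
    core = read.read_id.split(" ")[0]
    return f"{core}:WELL:{read.well}:UMI:{read.umi}"


def parse_tagged_id(read_id: str) -> tuple[str, WellAddress, str]:
    """Invert :func:`tag_read_id` -> (original id, well, umi)."""
    try:
        head, umi = read_id.rsplit(":UMI:", 1)
        core, well_str = head.rsplit(":WELL:", 1)
    except ValueError as exc:
        raise ValueError(f"read id lacks :WELL:/:UMI: tags: {read_id!r}") from exc
    return core, WellAddress.parse(well_str), umi


def read_tagged_fastq(path: str) -> Iterator[ProcessedRead]:
    """Reload kept reads written by :func:`write_tagged_fastq`."""
    for rid, seq, _ in _fastq_records(path):
        core, well, umi = parse_tagged_id(rid.split(" ")[0])
        yield ProcessedRead(core, umi=umi, payload=seq, well=well)


def write_tagged_fastq(reads: Iterable[ProcessedRead], path: str) -> int:
    """Write kept reads as FASTQ with well/UMI tagged into the ID."""
    n = 0
    with open(path, "w") as fh:
        for read in reads:
            if not read.kept:
                continue
            fh.write(f"@{tag_read_id(read)}\n{read.payload}\n+\n{'I' * len(read.payload)}\n")
            n += 1
    return n
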