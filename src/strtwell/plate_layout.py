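"""Plate geometry, dual-index barcode sets, and well addressing.

The platform is an aluminium plate with 9600 nanoliter wells arranged in 96
subarrays of 100 (10 x 10) wells. Each subarray shares one 8 bp barcode read
as Index 1, and each addressed well within a subarray carries one of up to
32 5 bp barcodes read as Index 2, so a read's (Index 1, Index 2) pair jointly
addresses a single well. With 32 well barcodes, up to 32 wells per subarray
(3072 per plate) can be recovered.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

SUBARRAY_BARCODE_LENGTH = 8
WELL_BARCODE_LENGTH = 5

_BASES = "ACGT"


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well on the plate: 1-based subarray and well indices."""

    subarray: int
    well: int

    def __str__(self) -> str:
        return f"s{self.subarray:02d}w{self.well:03d}"

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        if not text.startswith("s") or "w" not in text:
            raise ValueError(f"not a well address: {text!r}")
        sub, well = text[1:].split("w")
        return cls(int(sub), int(well))


@dataclass(frozen=True)
class PlateLayout:
    """Rectangular microwell plate: ``n_subarrays`` blocks of rows x cols wells.

    Well IDs are ordered row-major within a subarray; subarrays are numbered
    1..n left-to-right, top-to-bottom. The ordering is arbitrary but fixed.
    """

    n_subarrays: int = 96
    rows_per_subarray: int = 10
    cols_per_subarray: int = 10

    def __post_init__(self) -> None:
        for name in ("n_subarrays", "rows_per_subarray", "cols_per_subarray"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")

    @property
    def wells_per_subarray(self) -> int:
        return self.rows_per_subarray * self.cols_per_subarray

    @property
    def n_wells(self) -> int:
        return self.n_subarrays * self.wells_per_subarray

    def wells(self) -> list[WellAddress]:
        """All well addresses in deterministic order."""
        return [
            WellAddress(s, w)
            for s in range(1, self.n_subarrays + 1)
            for w in range(1, self.wells_per_subarray + 1)
        ]

    def contains(self, address: WellAddress) -> bool:
        return (
            1 <= address.subarray <= self.n_subarrays
            and 1 <= address.well <= self.wells_per_subarray
        )


def build_layout(n_subarrays: int, rows: int, cols: int) -> PlateLayout:
    """Construct a plate layout; raises ``ValueError`` on non-positive dims."""
    return PlateLayout(n_subarrays, rows, cols)


def default_layout() -> PlateLayout:
    """The production plate: 96 subarrays of 100 wells = 9600 wells."""
    return PlateLayout(96, 10, 10)


def max_recoverable_cells(layout: PlateLayout, n_well_barcodes: int) -> int:
    """Cells recoverable with ``n_well_barcodes`` per-well barcodes.

    Each subarray can recover at most min(n_well_barcodes, wells per
    subarray) wells; with the default plate and 32 barcodes this is 3072.
    """
    if n_well_barcodes < 0:
        raise ValueError("n_well_barcodes must be >= 0")
    return layout.n_subarrays * min(n_well_barcodes, layout.wells_per_subarray)


def expected_singlet_wells(n_wells: int, mean_cells_per_well: float) -> float:
    """Expected number of single-cell wells under Poisson loading.

    With limiting dilution at a mean of lambda cells per well, occupancy is
    Poisson and the singlet probability is lambda * exp(-lambda), maximized
    at lambda = 1 (the Poisson limit, ~36.8% of wells).
    """
    lam = mean_cells_per_well
    if lam < 0:
        raise ValueError("mean_cells_per_well must be >= 0")
    return n_wells * lam * math.exp(-lam)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("sequences differ in length")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class BarcodeSet:
    """Subarray (8 bp) and well (5 bp) barcode sequences.

    All barcodes within a set have equal length and are unique; the minimum
    pairwise Hamming distance across both sets is recorded so callers know
    how many mismatches demultiplexing can tolerate unambiguously.
    """

    subarray_barcodes: list[str]
    well_barcodes: list[str]
    min_distance: int = field(init=False)

    def __post_init__(self) -> None:
        for name, codes, length in (
            ("subarray", self.subarray_barcodes, SUBARRAY_BARCODE_LENGTH),
            ("well", self.well_barcodes, WELL_BARCODE_LENGTH),
        ):
            if len(set(codes)) != len(codes):
                raise ValueError(f"duplicate {name} barcodes")
            if any(len(c) != length for c in codes):
                raise ValueError(f"{name} barcodes must all have length {length}")
        self.min_distance = min(
            (
                hamming(a, b)
                for codes in (self.subarray_barcodes, self.well_barcodes)
                for a, b in itertools.combinations(codes, 2)
            ),
            default=0,
        )

    def address_of(self, subarray_barcode: str, well_barcode: str) -> WellAddress:
        return WellAddress(
            self.subarray_barcodes.index(subarray_barcode) + 1,
            self.well_barcodes.index(well_barcode) + 1,
        )


def _greedy_barcodes(n: int, length: int, min_dist: int, rng: np.random.Generator) -> list[str]:
    """Seeded greedy search for n barcodes with pairwise Hamming >= min_dist."""
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        cand = "".join(_BASES[i] for i in rng.integers(0, 4, size=length))
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError(
                f"could not find {n} barcodes of length {length} at distance {min_dist}"
            )
    return chosen


def generate_barcode_set(
    n_subarray: int = 96,
    n_well: int = 32,
    min_dist: int = 3,
    seed: int = 20171127,
) -> BarcodeSet:
    """Generate default barcode sets by seeded greedy search.

    Instrument barcode sets are proprietary, so the package ships
    deterministic generated ones: 96 8-mers and 32 5-mers with minimum Hamming
    distance >= ``min_dist`` (default 3, allowing 1-mismatch correction).
    """
    rng = np.random.default_rng(seed)
    return BarcodeSet(
        _greedy_barcodes(n_subarray, SUBARRAY_BARCODE_LENGTH, min_dist, rng),
        _greedy_barcodes(n_well, WELL_BARCODE_LENGTH, min_dist, rng),
    )


def _match_barcode(seq: str, barcodes: list[str], max_mismatches: int) -> int | None:
    """Index of the unique best match within max_mismatches, else None.

    Ties at the best distance are ambiguous and return None.
    """
    best_idx: int | None = None
    best_dist = max_mismatches + 1
    tied = False
    for i, bc in enumerate(barcodes):
        d = hamming(seq, bc)
        if d < best_dist:
            best_idx, best_dist, tied = i, d, False
        elif d == best_dist:
            tied = True
    if best_idx is None or tied or best_dist > max_mismatches:
        return None
    return best_idx


def address_from_indices(
    index1_seq: str,
    index2_seq: str,
    barcode_set: BarcodeSet,
    max_mismatches: int = 0,
) -> WellAddress | None:
    """Demultiplex one (Index 1, Index 2) pair to a well address.

    Returns None (unassigned) if either index has no unique barcode within
    ``max_mismatches``. Raises ``ValueError`` for wrong index lengths so the
    caller can count the record as invalid input.
    """
    if len(index1_seq) != SUBARRAY_BARCODE_LENGTH:
        raise ValueError(f"index1 must be {SUBARRAY_BARCODE_LENGTH} bp, got {len(index1_seq)}")
    if len(index2_seq) != WELL_BARCODE_LENGTH:
        raise ValueError(f"index2 must be {WELL_BARCODE_LENGTH} bp, got {len(index2_seq)}")
    sub = _match_barcode(index1_seq.upper(), barcode_set.subarray_barcodes, max_mismatches)
    if sub is None:
        return None
    well = _match_barcode(index2_seq.upper(), barcode_set.well_barcodes, max_mismatches)
    if well is None:
        return None
    return WellAddress(sub + 1, well + 1)


def write_barcode_tsv(barcode_set: BarcodeSet, path: str) -> None:
    """Write a headered TSV (barcode_id, sequence, role in {subarray, well})."""
    with open(path, "w") as fh:
        fh.write("barcode_id\tsequence\trole\n")
        for i, bc in enumerate(barcode_set.subarray_barcodes, 1):
            fh.write(f"sub{i:03d}\t{bc}\tsubarray\n")
        for i, bc in enumerate(barcode_set.well_barcodes, 1):
            fh.write(f"well{i:03d}\t{bc}\twell\n")


def read_barcode_tsv(path: str) -> BarcodeSet:
    sub, well = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["barcode_id", "sequence", "role"]:
            raise ValueError(f"unexpected barcode TSV header in {path}: {header}")
        for line in fh:
            _, seq, role = line.rstrip("\n").split("\t")
            if role == "subarray":
                sub.append(seq)
            elif role == "well":
                well.append(seq)
            else:
                raise ValueError(f"unknown barcode role {role!r} in {path}")
    return BarcodeSet(sub, well)
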