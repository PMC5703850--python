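"""Multiread assignment, UMI molecule counting, and collision correction.

Annotation runs separately for each well. Each aligned read is assigned by a
fixed hierarchy:

1. a multiread with any mapping in a repeat outside exons is assigned
   randomly to one of those repeats and contributes to no gene;
2. otherwise, a read with any exonic mapping is assigned to the exon where
   its 5' base is closest to the (extended) transcript-model 5' end;
3. otherwise it is assigned randomly to one of its mappings, counting
   toward no gene.

Molecules per (genomic position, strand) are distinct UMIs; any UMI seen in
only a single read is excluded as a likely PCR/sequencing artifact. Raw
counts are corrected for UMI collisions — two molecules drawing the same
6-mer UMI — by inverting the expected occupancy of the 4^6 UMI space:
``n = -K * ln(1 - k/K)`` for k observed UMIs out of K.

In nuclei mode, abundant unspliced transcripts make intronic reads
informative: feature membership is tested against the whole locus
(5' extension through last exon, introns included) instead of exons.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .alignment import Mapping, ReadAlignment
from .plate_layout import WellAddress
from .reference_model import LocusModel

UMI_SPACE = 4 ** 6

MIN_READS_PER_UMI = 2  # singleton-UMI exclusion


class AnnotationIndex:
    """Interval lookups for read assignment.

    ``mode='cells'`` tests membership against the 5'-extended merged exons;
    ``mode='nuclei'`` against whole-locus intervals (introns included).
    Repeat intervals are strandless; a position counts as "repeat outside
    exons" when it falls in a repeat but in no feature on the read's strand.
    """

    def __init__(
        self,
        loci: Sequence[LocusModel],
        repeats: Iterable[tuple[str, int, int]] = (),
        mode: str = "cells",
    ):
        if mode not in ("cells", "nuclei"):
            raise ValueError("mode must be 'cells' or 'nuclei'")
        self.mode = mode
        self.five_prime: dict[str, int] = {}
        self._features: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
        self._repeats: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for locus in loci:
            self.five_prime[locus.gene_name] = locus.five_prime
            if mode == "cells":
                intervals = locus.extended_exons()
            else:
                intervals = [locus.whole_locus]
            tree = self._features[(locus.chrom, locus.strand)]
            for s, e in intervals:
                tree.addi(s, e, locus.gene_name)
        for chrom, s, e in repeats:
            if s < e:
                self._repeats[chrom].addi(s, e)

    def genes_at(self, chrom: str, pos: int, strand: str) -> list[str]:
        tree = self._features.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.at(pos)})

    def in_repeat(self, chrom: str, pos: int) -> bool:
        tree = self._repeats.get(chrom)
        return bool(tree is not None and tree.at(pos))


@dataclass
class ReadAssignment:
    """Outcome of the multiread hierarchy for one read."""

    read_id: str
    well: WellAddress
    umi: str
    kind: str  # gene | repeat | random | no_feature
    gene: str | None
    mapping: Mapping

    @property
    def counted(self) -> bool:
        return self.kind == "gene"


def assign_read(
    alignment: ReadAlignment,
    index: AnnotationIndex,
    rng: np.random.Generator,
) -> ReadAssignment | None:
    """Apply the assignment hierarchy to one aligned read.

    Returns None for unmapped/suppressed reads. Ties (equidistant exonic
    mappings, or the random-choice rules) are broken with the supplied
    per-well RNG so runs are reproducible.
    """
    if not alignment.mappings:
        return None

    exonic: list[tuple[Mapping, str, int]] = []  # (mapping, gene, 5' distance)
    repeat_hits: list[Mapping] = []
    for m in alignment.mappings:
        pos5 = m.five_prime_pos
        genes = index.genes_at(m.chrom, pos5, m.strand)
        if genes:
            for g in genes:
                exonic.append((m, g, abs(pos5 - index.five_prime[g])))
        elif index.in_repeat(m.chrom, pos5):
            repeat_hits.append(m)

    def make(kind: str, gene: str | None, mapping: Mapping) -> ReadAssignment:
        return ReadAssignment(
            alignment.read_id, alignment.well, alignment.umi, kind, gene, mapping
        )

    if repeat_hits:
        choice = repeat_hits[int(rng.integers(len(repeat_hits)))]
        return make("repeat", None, choice)
    if exonic:
        best = min(d for _, _, d in exonic)
        tied = [(m, g) for m, g, d in exonic if d == best]
        m, g = tied[int(rng.integers(len(tied)))]
        return make("gene", g, m)
    if len(alignment.mappings) > 1:
        choice = alignment.mappings[int(rng.integers(len(alignment.mappings)))]
        return make("random", None, choice)
    return make("no_feature", None, alignment.mappings[0])


MoleculeKey = tuple[str, int, str]  # (gene, 5' position, strand)


@dataclass
class MoleculeTable:
    """Per-well (gene, position, strand) -> UMI -> read count."""

    wells: dict[WellAddress, dict[MoleculeKey, Counter]] = field(default_factory=dict)

    def add(self, assignment: ReadAssignment) -> None:
        key = (
            assignment.gene,
            assignment.mapping.five_prime_pos,
            assignment.mapping.strand,
        )
        well = self.wells.setdefault(assignment.well, {})
        well.setdefault(key, Counter())[assignment.umi] += 1

    def molecules(
        self, well: WellAddress, min_reads: int = MIN_READS_PER_UMI
    ) -> dict[MoleculeKey, int]:
        """Distinct UMIs per position after singleton exclusion."""
        out: dict[MoleculeKey, int] = {}
        for key, umis in self.wells.get(well, {}).items():
            n = sum(1 for c in umis.values() if c >= min_reads)
            if n:
                out[key] = n
        return out

    def gene_counts(
        self, well: WellAddress, min_reads: int = MIN_READS_PER_UMI
    ) -> Counter:
        counts: Counter = Counter()
        for (gene, _, _), n in self.molecules(well, min_reads).items():
            counts[gene] += n
        return counts


def count_molecules(
    assignments: Iterable[ReadAssignment],
    min_reads_per_umi: int = MIN_READS_PER_UMI,
) -> MoleculeTable:
    """Tally gene-assigned reads into a per-well molecule table.

    Only hierarchy outcome "gene" contributes; repeat- and random-assigned
    reads are excluded from gene counts by construction. Singleton-UMI
    exclusion is applied downstream by the min_reads threshold (recorded
    here only for introspection).
    """
    table = MoleculeTable()
    table.min_reads_per_umi = min_reads_per_umi
    for assignment in assignments:
        if assignment is not None and assignment.counted:
            table.add(assignment)
    return table


def collision_correct(observed_distinct_umis: float, umi_length: int = 6) -> float:
    """Correct an observed distinct-UMI count for UMI collisions.

    Inverts the expected occupancy of K = 4^umi_length equiprobable UMIs:
    dropping n molecules uniformly occupies ~K(1 - e^(-n/K)) UMIs, so the
    estimated molecule count for k observed UMIs is -K * ln(1 - k/K).
    Monotone increasing in k, >= k, and diverges as k -> K.
    """
    K = 4 ** umi_length
    k = observed_distinct_umis
    if k < 0:
        raise ValueError("observed UMI count must be >= 0")
    if k >= K:
        raise ValueError(f"UMI space saturated: {k} >= {K}")
    return -K * math.log1p(-k / K)


@dataclass
class ExpressionMatrix:
    """genes x wells raw (int) and collision-corrected (float) counts."""

    raw: pd.DataFrame
    corrected: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.raw.index)

    @property
    def well_totals(self) -> pd.Series:
        return self.raw.sum(axis=0)

    def write_tsv(self, prefix: str) -> None:
        self.raw.to_csv(f"{prefix}.raw.tsv", sep="\t")
        self.corrected.to_csv(f"{prefix}.corrected.tsv", sep="\t")

    def write_mtx(self, prefix: str) -> None:
        """Matrix Market raw counts + genes.tsv + wells.tsv sidecars."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(f"{prefix}.mtx", csr_matrix(self.raw.to_numpy()))
        with open(f"{prefix}.genes.tsv", "w") as fh:
            fh.write("\n".join(self.raw.index) + "\n")
        with open(f"{prefix}.wells.tsv", "w") as fh:
            fh.write("\n".join(str(w) for w in self.raw.columns) + "\n")


def build_matrix(
    table: MoleculeTable,
    loci: Sequence[LocusModel],
    wells: Sequence[WellAddress] | None = None,
    min_reads_per_umi: int = MIN_READS_PER_UMI,
    umi_length: int = 6,
) -> ExpressionMatrix:
    """Aggregate a molecule table into a genes x wells expression matrix.

    Gene-level raw counts sum per-position molecule counts; the corrected
    value is computed per (gene, well) from its UMI count. Gene order
    follows the locus models; well order is the sorted observed wells
    unless an explicit well list is given (empty wells appear as zeros).
    """
    gene_order = [l.gene_name for l in loci]
    if wells is None:
        wells = sorted(table.wells)
    well_names = [str(w) for w in wells]
    raw = pd.DataFrame(0, index=gene_order, columns=well_names, dtype=int)
    for well in wells:
        for gene, n in table.gene_counts(well, min_reads_per_umi).items():
            if gene in raw.index:
                raw.loc[gene, str(well)] = n
    corrected = raw.astype(float).map(
        lambda k: collision_correct(k, umi_length) if k else 0.0
    )
    return ExpressionMatrix(raw=raw, corrected=corrected)


def well_rng(seed: int, well: WellAddress) -> np.random.Generator:
    """Per-well RNG so parallel and serial runs assign identically."""
    return np.random.default_rng([seed, well.subarray, well.well])


@dataclass
class WellSummary:
    well: WellAddress
    reads: int
    assigned: int
    repeat: int
    random: int
    no_feature: int
    molecules: int
    genes: int


def quantify_wells(
    alignments: Iterable[ReadAlignment],
    index: AnnotationIndex,
    loci: Sequence[LocusModel],
    seed: int = 0,
    wells: Sequence[WellAddress] | None = None,
    min_reads_per_umi: int = MIN_READS_PER_UMI,
) -> tuple[ExpressionMatrix, MoleculeTable, list[WellSummary]]:
    """Run assignment + counting well by well and assemble the matrix.

    The annotation step runs separately for each well with an RNG derived
    from (seed, well), making output independent of read order across wells
    and of serial vs parallel execution.
    """
    by_well: dict[WellAddress, list[ReadAlignment]] = defaultdict(list)
    for alignment in alignments:
        if alignment.well is not None:
            by_well[alignment.well].append(alignment)
    table = MoleculeTable()
    summaries: list[WellSummary] = []
    for well in sorted(by_well):
        rng = well_rng(seed, well)
        tally = Counter()
        n_reads = 0
        for alignment in by_well[well]:
            n_reads += 1
            assignment = assign_read(alignment, index, rng)
            if assignment is None:
                continue
            tally[assignment.kind] += 1
            if assignment.counted:
                table.add(assignment)
        per_gene = table.gene_counts(well, min_reads_per_umi)
        summaries.append(
            WellSummary(
                well=well,
                reads=n_reads,
                assigned=tally["gene"],
                repeat=tally["repeat"],
                random=tally["random"],
                no_feature=tally["no_feature"],
                molecules=sum(per_gene.values()),
                genes=len(per_gene),
            )
        )
    matrix = build_matrix(table, loci, wells=wells, min_reads_per_umi=min_reads_per_umi)
    return matrix, table, summaries


def write_well_summaries(summaries: Sequence[WellSummary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("well\treads\tassigned\trepeat\trandom\tno_feature\tmolecules\tgenes\n")
        for s in summaries:
            fh.write(
                f"{s.well}\t{s.reads}\t{s.assigned}\t{s.repeat}\t{s.random}\t"
                f"{s.no_feature}\t{s.molecules}\t{s.genes}\n"
            )
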