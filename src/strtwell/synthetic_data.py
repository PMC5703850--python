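"""Synthetic references, FASTQ trios, and ground truth for offline testing.

Emulates the platform's read structure — a 45 bp cDNA read carrying a 6 bp
UMI, three template-switch G's, and 5'-proximal transcript sequence, plus
8 bp and 5 bp index reads addressing a microwell — so the whole pipeline
(demultiplex, QC, align, junction realign, assign, count) can run end to
end with no external downloads, with every emitted read traced to exactly
one (well, gene, molecule) in the recorded truth.

The expression model is negative binomial per (well, gene) to exercise
overdispersed-Poisson CV behaviour; duplicate reads of a molecule share its
UMI and start position; read starts decay geometrically from the locus 5'
end, mirroring the 5' bias of the chemistry. Reads per molecule default to
a minimum of two so singleton-UMI exclusion does not delete true molecules;
singleton injection and per-class QC defects are explicit switches.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_layout import BarcodeSet, PlateLayout, WellAddress
from .reference_model import (
    LocusModel,
    TranscriptModel,
    extend_5prime,
    locus_spliced_sequence,
    merge_locus_models,
    write_genome_fasta,
    write_refflat,
)

_BASES = np.array(list("ACGT"))

READ_LENGTH = 45
UMI_LENGTH = 6
PAYLOAD_LENGTH = READ_LENGTH - UMI_LENGTH - 3  # after UMI and GGG

DEFECT_CLASSES = (
    "umi_quality",
    "missing_ggg",
    "polyA_short",
    "low_complexity",
    "unassigned_barcode",
    "empty_after_trim",
    "invalid_flag",
)


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    # reference
    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_genes: int = 20
    exon_count_range: tuple[int, int] = (1, 3)
    exon_length_range: tuple[int, int] = (150, 400)
    intron_length_range: tuple[int, int] = (80, 300)
    n_repeat_sites: int = 0  # duplicated exonic 45-mers, recorded in the BED
    # plate / expression
    n_wells: int = 20
    mean_molecules: float = 2.0  # NB mean per (well, gene)
    dispersion: float = 2.0  # NB size parameter r; larger = closer to Poisson
    # reads
    min_reads_per_molecule: int = 2
    extra_reads_geometric_p: float = 0.5
    error_rate: float = 0.0  # per-base substitution rate in the payload
    fraction_junction_spanning: float = 0.15
    five_prime_jitter_p: float = 0.3  # geometric decay of start offsets; 1 = none
    max_jitter: int = 50
    umi_collisions: bool = False  # False: distinct UMIs per (well, gene)
    n_singleton_molecules: int = 0  # molecules emitted with a single read
    defects: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate in (self.error_rate, self.fraction_junction_spanning):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 < self.five_prime_jitter_p <= 1:
            raise ValueError("five_prime_jitter_p must be in (0, 1]")
        unknown = set(self.defects) - set(DEFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown defect classes: {sorted(unknown)}")


@dataclass
class ToyReference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    repeats: list[tuple[str, int, int]]

    def loci(self, extension: int = 100) -> list[LocusModel]:
        lengths = {c: len(s) for c, s in self.genome.items()}
        return extend_5prime(
            merge_locus_models(self.transcripts), extension, lengths
        )

    def write(self, fasta_path: str, refflat_path: str, bed_path: str) -> None:
        write_genome_fasta(self.genome, fasta_path)
        write_refflat(self.transcripts, refflat_path)
        with open(bed_path, "w") as fh:
            for chrom, s, e in self.repeats:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_toy_reference(config: SimulationConfig) -> ToyReference:
    """Random genome + non-overlapping gene models (+ optional repeats).

    Genes are placed left to right with intergenic gaps and at least 150
    bases of headroom for the 5' extension; over-packing raises. Each
    repeat site copies a 45-mer out of a gene exon into intergenic space,
    creating a true multiread target, and is recorded in the repeat BED.
    """
    rng = np.random.default_rng(config.seed)
    chrom_len = config.genome_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: list(_random_seq(rng, chrom_len)) for c in chroms}
    transcripts: list[TranscriptModel] = []
    cursors = {c: 200 for c in chroms}
    for g in range(config.n_genes):
        chrom = chroms[g % len(chroms)]
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        pos = cursors[chrom]
        exons = []
        for i in range(n_exons):
            if i:
                pos += int(rng.integers(*config.intron_length_range))
            length = int(rng.integers(*config.exon_length_range))
            exons.append((pos, pos + length))
            pos += length
        if pos > chrom_len - 150:
            raise ValueError(
                f"cannot pack {config.n_genes} genes into a "
                f"{config.genome_length} bp genome"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        name = f"gene{g + 1:03d}"
        transcripts.append(TranscriptModel(name, f"{name}.1", chrom, strand, exons))
        cursors[chrom] = pos + int(rng.integers(150, 400))
    repeats: list[tuple[str, int, int]] = []
    for _ in range(config.n_repeat_sites):
        src = transcripts[int(rng.integers(len(transcripts)))]
        exon = src.exons[int(rng.integers(len(src.exons)))]
        if exon[1] - exon[0] < READ_LENGTH:
            continue
        start = int(rng.integers(exon[0], exon[1] - READ_LENGTH + 1))
        kmer = "".join(genome[src.chrom][start:start + READ_LENGTH])
        # paste into the tail gap of a random chromosome
        dest_chrom = chroms[int(rng.integers(len(chroms)))]
        dest = cursors[dest_chrom] + 60
        if dest + READ_LENGTH > chrom_len:
            continue
        genome[dest_chrom][dest:dest + READ_LENGTH] = list(kmer)
        cursors[dest_chrom] = dest + READ_LENGTH
        repeats.append((dest_chrom, dest, dest + READ_LENGTH))
        repeats.append((src.chrom, start, start + READ_LENGTH))
    return ToyReference(
        {c: "".join(s) for c, s in genome.items()}, transcripts, sorted(repeats)
    )


@dataclass
class ReadProvenance:
    read_id: str
    well: WellAddress
    gene: str | None
    molecule_id: int
    umi: str
    defect: str | None = None


@dataclass
class SyntheticTruth:
    """Ground truth: molecule matrix plus per-read provenance."""

    molecules: pd.DataFrame  # genes x wells, true molecule counts
    provenance: list[ReadProvenance]
    defect_counts: Counter = field(default_factory=Counter)
    well_labels: dict[WellAddress, str] = field(default_factory=dict)

    def provenance_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\twell\tgene\tmolecule_id\tumi\tdefect\n")
            for p in self.provenance:
                fh.write(
                    f"{p.read_id}\t{p.well}\t{p.gene or ''}\t{p.molecule_id}\t"
                    f"{p.umi}\t{p.defect or ''}\n"
                )


FastqRecord = tuple[str, str, str]  # (id, sequence, quality string)


@dataclass
class FastqTrio:
    r1: list[FastqRecord]
    i1: list[FastqRecord]
    i2: list[FastqRecord]

    def write(self, r1_path: str, i1_path: str, i2_path: str) -> None:
        for records, path in ((self.r1, r1_path), (self.i1, i1_path), (self.i2, i2_path)):
            with open(path, "w") as fh:
                for rid, seq, qual in records:
                    fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _all_umis(rng: np.random.Generator, n: int, with_replacement: bool) -> list[str]:
    """Sample n 6-mer UMIs, optionally without replacement (collision-free)."""
    K = 4 ** UMI_LENGTH
    if with_replacement:
        codes = rng.integers(0, K, size=n)
    else:
        if n > K:
            raise ValueError("cannot draw distinct UMIs: n exceeds 4^6")
        codes = rng.choice(K, size=n, replace=False)
    out = []
    for code in codes:
        umi = []
        for _ in range(UMI_LENGTH):
            umi.append("ACGT"[code % 4])
            code //= 4
        out.append("".join(umi))
    return out


def addressable_wells(layout: PlateLayout, barcodes: BarcodeSet, n: int) -> list[WellAddress]:
    """First n wells reachable with the available barcodes, subarray-major."""
    wells = [
        WellAddress(s, w)
        for s in range(1, min(layout.n_subarrays, len(barcodes.subarray_barcodes)) + 1)
        for w in range(1, min(layout.wells_per_subarray, len(barcodes.well_barcodes)) + 1)
    ]
    if n > len(wells):
        raise ValueError(f"only {len(wells)} addressable wells, need {n}")
    return wells[:n]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = "ACGT"[int(rng.integers(0, 4))]
    return "".join(chars)


def _transcript_layout(locus: LocusModel) -> list[tuple[int, int, int]]:
    """(transcript offset, genomic start, genomic end) per exon, 5'->3'."""
    exons = locus.merged_exons if locus.strand == "+" else locus.merged_exons[::-1]
    out = []
    offset = 0
    for s, e in exons:
        out.append((offset, s, e))
        offset += e - s
    return out


def _defect_reads(
    config: SimulationConfig,
    rng: np.random.Generator,
    wells: Sequence[WellAddress],
    barcodes: BarcodeSet,
    serial_start: int,
) -> tuple[list[FastqRecord], list[FastqRecord], list[FastqRecord], list[ReadProvenance]]:
    """Decoy reads engineered to trip exactly one QC filter each."""
    r1, i1, i2, prov = [], [], [], []
    serial = serial_start
    good_q = "I" * READ_LENGTH
    for cls, count in sorted(config.defects.items()):
        for _ in range(count):
            serial += 1
            rid = f"d{serial:07d}"
            well = wells[int(rng.integers(len(wells)))]
            umi = _all_umis(rng, 1, True)[0]
            payload = _random_seq(rng, PAYLOAD_LENGTH)
            # keep the decoy clean for every filter except the planted one
            while payload.endswith("A") or sum(b != "A" for b in payload) < 10:
                payload = _random_seq(rng, PAYLOAD_LENGTH)
            seq = umi + "GGG" + payload
            qual = good_q
            idx1 = barcodes.subarray_barcodes[well.subarray - 1]
            idx2 = barcodes.well_barcodes[well.well - 1]
            if cls == "umi_quality":
                qual = chr(33 + 16) + qual[1:]
            elif cls == "missing_ggg":
                seq = umi + "TGG" + payload
            elif cls == "polyA_short":
                seq = umi + "GGG" + payload[:10] + "A" * (PAYLOAD_LENGTH - 10)
            elif cls == "low_complexity":
                seq = umi + "GGG" + "AC" * (PAYLOAD_LENGTH // 2)
            elif cls == "unassigned_barcode":
                idx1 = "N" * len(idx1)
            elif cls == "empty_after_trim":
                qual = chr(33 + 2) * READ_LENGTH
            elif cls == "invalid_flag":
                rid = f"{rid} 1:Y:0:1"
            r1.append((rid, seq, qual))
            i1.append((rid, idx1, "I" * len(idx1)))
            i2.append((rid, idx2, "I" * len(idx2)))
            prov.append(ReadProvenance(rid, well, None, -1, umi, cls))
    return r1, i1, i2, prov


def simulate_reads(
    config: SimulationConfig,
    reference: ToyReference,
    layout: PlateLayout,
    barcodes: BarcodeSet,
) -> tuple[FastqTrio, SyntheticTruth]:
    """Simulate a FASTQ trio with full per-read ground truth.

    Per (well, gene) molecule counts are negative binomial; each molecule
    gets a UMI (distinct within the (well, gene) unless collisions are
    requested), a 5' start offset with geometric jitter, and >= 2 duplicate
    reads sharing UMI and position. A configurable fraction of molecules on
    multi-exon genes is placed to span a splice junction. Defect decoys are
    appended last and never enter the truth matrix.
    """
    from .alignment import NaiveAligner

    rng = np.random.default_rng(config.seed)
    loci = reference.loci()
    wells = addressable_wells(layout, barcodes, config.n_wells)
    gene_names = [l.gene_name for l in loci]
    truth = pd.DataFrame(0, index=gene_names, columns=[str(w) for w in wells], dtype=int)
    spliced = {l.gene_name: locus_spliced_sequence(l, reference.genome) for l in loci}
    layouts = {l.gene_name: _transcript_layout(l) for l in loci}
    # junction-spanning placements must genuinely fail ungapped genomic
    # alignment, else a chance intron match absorbs the read at a shifted
    # position; reject such placements at construction time
    genome_aligner = NaiveAligner(reference.genome)
    r1, i1, i2 = [], [], []
    prov: list[ReadProvenance] = []
    serial = 0
    molecule_id = 0
    n_singletons_left = config.n_singleton_molecules
    r = config.dispersion
    for well in wells:
        idx1 = barcodes.subarray_barcodes[well.subarray - 1]
        idx2 = barcodes.well_barcodes[well.well - 1]
        for locus in loci:
            gene = locus.gene_name
            mean = config.mean_molecules
            n_mol = int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
            if n_mol == 0:
                continue
            umis = _all_umis(rng, n_mol, config.umi_collisions)
            tx = spliced[gene]
            tx_layout = layouts[gene]
            for umi in umis:
                molecule_id += 1
                # choose the 5' start offset in transcript coordinates
                span_junction = (
                    len(tx_layout) > 1
                    and rng.random() < config.fraction_junction_spanning
                )
                offset = None
                if span_junction:
                    j = int(rng.integers(1, len(tx_layout)))
                    boundary = tx_layout[j][0]
                    lo = max(0, boundary - PAYLOAD_LENGTH + 5)
                    hi = min(boundary - 5, len(tx) - PAYLOAD_LENGTH)
                    if hi >= lo:
                        cand = int(rng.integers(lo, hi + 1))
                        seq = tx[cand:cand + PAYLOAD_LENGTH]
                        # the QC chain trims leading G (template-switch) and
                        # terminal poly(A); a spanning placement must be
                        # invariant under both so the rejection test below
                        # sees exactly what the aligner will see
                        if (
                            seq[0] != "G"
                            and seq[-1] != "A"
                            and not genome_aligner.align(seq)
                        ):
                            offset = cand
                if offset is None:
                    offset = min(
                        int(rng.geometric(config.five_prime_jitter_p)) - 1,
                        config.max_jitter,
                        max(0, len(tx) - PAYLOAD_LENGTH),
                    )
                payload = tx[offset:offset + PAYLOAD_LENGTH]
                if len(payload) < 25:
                    continue  # transcript too short at this offset; skip molecule
                if n_singletons_left > 0:
                    n_reads = 1
                    n_singletons_left -= 1
                else:
                    n_reads = config.min_reads_per_molecule + (
                        int(rng.geometric(config.extra_reads_geometric_p)) - 1
                    )
                    truth.loc[gene, str(well)] += 1
                for _ in range(n_reads):
                    serial += 1
                    rid = f"r{serial:07d}"
                    read_payload = _mutate(payload, rng, config.error_rate)
                    seq = umi + "GGG" + read_payload
                    r1.append((rid, seq, "I" * len(seq)))
                    i1.append((rid, idx1, "I" * len(idx1)))
                    i2.append((rid, idx2, "I" * len(idx2)))
                    prov.append(ReadProvenance(rid, well, gene, molecule_id, umi))
    dr1, di1, di2, dprov = _defect_reads(config, rng, wells, barcodes, serial)
    trio = FastqTrio(r1 + dr1, i1 + di1, i2 + di2)
    defect_counts = Counter(p.defect for p in dprov)
    return trio, SyntheticTruth(truth, prov + dprov, defect_counts)


def simulate_plate_loading(
    layout: PlateLayout,
    mode: str = "dilution",
    mean_cells_per_well: float = 1.0,
    error_rate: float = 0.041,
    addressed: Sequence[WellAddress] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate cell deposition: Poisson dilution or FACS addressing.

    ``dilution`` draws occupancy ~ Poisson(mean) per well; ``facs`` deposits
    one cell into each addressed well, with a deposition error rate that
    leaves the well empty. Returns a DataFrame (well, n_cells).
    """
    rng = np.random.default_rng(seed)
    wells = layout.wells()
    if mode == "dilution":
        counts = rng.poisson(mean_cells_per_well, size=len(wells))
    elif mode == "facs":
        targets = set(addressed) if addressed is not None else set(wells)
        counts = np.array(
            [
                int(w in targets and rng.random() >= error_rate)
                for w in wells
            ]
        )
    else:
        raise ValueError("mode must be 'dilution' or 'facs'")
    return pd.DataFrame({"well": [str(w) for w in wells], "n_cells": counts})


def simulate_barnyard_counts(
    n_wells: int = 1000,
    doublet_rate: float = 0.05,
    mean_molecules: float = 500.0,
    contamination_mean: float = 37.0,
    species: tuple[str, str] = ("human", "mouse"),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Molecule-count-level two-species mixture for doublet calling.

    Each well is a doublet with probability ``doublet_rate``, else a singlet
    of a random species. Own-species molecules ~ Poisson(mean); doublets get
    both; every well gains ambient other-species molecules ~
    Poisson(contamination_mean). Returns (counts frame, true labels).
    """
    rng = np.random.default_rng(seed)
    a, b = species
    rows, labels = [], []
    for i in range(n_wells):
        is_doublet = rng.random() < doublet_rate
        if is_doublet:
            na = rng.poisson(mean_molecules) + rng.poisson(contamination_mean)
            nb = rng.poisson(mean_molecules) + rng.poisson(contamination_mean)
            labels.append("doublet")
        else:
            own_a = rng.random() < 0.5
            na = rng.poisson(mean_molecules if own_a else contamination_mean)
            nb = rng.poisson(contamination_mean if own_a else mean_molecules)
            labels.append(f"singlet_{a}" if own_a else f"singlet_{b}")
        rows.append({f"molecules_{a}": na, f"molecules_{b}": nb})
    index = [f"w{i + 1:04d}" for i in range(n_wells)]
    return pd.DataFrame(rows, index=index), pd.Series(labels, index=index)


def simulate_barnyard(
    config: SimulationConfig,
    reference_a: ToyReference,
    reference_b: ToyReference,
    layout: PlateLayout,
    barcodes: BarcodeSet,
    doublet_rate: float = 0.05,
    contamination_molecules: float = 2.0,
) -> tuple[FastqTrio, SyntheticTruth]:
    """Read-level two-species mixture sharing one gene-name space.

    Wells are singlets of either species or doublets per Bernoulli
    (``doublet_rate``); ambient molecules of the other species are added at
    ``contamination_molecules`` expected per well. Reads from both species
    share the FASTQ trio; provenance genes carry a species prefix
    ("A:gene001"). The two references must use identical gene names.
    """
    rng = np.random.default_rng(config.seed)
    wells = addressable_wells(layout, barcodes, config.n_wells)
    trios: list[FastqTrio] = []
    provs: list[ReadProvenance] = []
    well_labels: dict[WellAddress, str] = {}
    frames = []
    serial_base = 0
    for tag, ref in (("A", reference_a), ("B", reference_b)):
        other = "B" if tag == "A" else "A"
        sub_rng_seed = int(rng.integers(2**31))
        means: dict[WellAddress, float] = {}
        for well in wells:
            if well not in well_labels:
                if rng.random() < doublet_rate:
                    well_labels[well] = "doublet"
                else:
                    well_labels[well] = "singlet_A" if rng.random() < 0.5 else "singlet_B"
            label = well_labels[well]
            own = label == "doublet" or label == f"singlet_{tag}"
            means[well] = config.mean_molecules if own else 0.0
        sub_cfg = replace(config, seed=sub_rng_seed, defects={})
        trio, truth = _simulate_species_reads(
            sub_cfg, ref, wells, barcodes, means,
            contamination=contamination_molecules, tag=tag, serial_base=serial_base,
        )
        serial_base += len(trio.r1)
        trios.append(trio)
        provs.extend(truth.provenance)
        frames.append(truth.molecules.rename(index=lambda g: f"{tag}:{g}"))
    combined = FastqTrio(
        trios[0].r1 + trios[1].r1,
        trios[0].i1 + trios[1].i1,
        trios[0].i2 + trios[1].i2,
    )
    molecules = pd.concat(frames)
    return combined, SyntheticTruth(molecules, provs, Counter(), well_labels)


def _simulate_species_reads(
    config: SimulationConfig,
    reference: ToyReference,
    wells: Sequence[WellAddress],
    barcodes: BarcodeSet,
    means: dict[WellAddress, float],
    contamination: float,
    tag: str,
    serial_base: int,
) -> tuple[FastqTrio, SyntheticTruth]:
    """One species' reads at per-well mean expression + ambient background."""
    rng = np.random.default_rng(config.seed)
    loci = reference.loci()
    gene_names = [l.gene_name for l in loci]
    spliced = {l.gene_name: locus_spliced_sequence(l, reference.genome) for l in loci}
    truth = pd.DataFrame(0, index=gene_names, columns=[str(w) for w in wells], dtype=int)
    r1, i1, i2 = [], [], []
    prov: list[ReadProvenance] = []
    serial = serial_base
    molecule_id = 0
    r = config.dispersion
    for well in wells:
        idx1 = barcodes.subarray_barcodes[well.subarray - 1]
        idx2 = barcodes.well_barcodes[well.well - 1]
        mean = means[well]
        for locus in loci:
            gene = locus.gene_name
            n_own = (
                int(rng.negative_binomial(r, r / (r + mean))) if mean > 0 else 0
            )
            n_ambient = (
                int(rng.poisson(contamination / max(len(loci), 1)))
                if means[well] == 0 and contamination > 0
                else 0
            )
            n_mol = n_own + n_ambient
            if n_mol == 0:
                continue
            umis = _all_umis(rng, n_mol, config.umi_collisions)
            tx = spliced[gene]
            for umi in umis:
                molecule_id += 1
                offset = min(
                    int(rng.geometric(config.five_prime_jitter_p)) - 1,
                    config.max_jitter,
                    max(0, len(tx) - PAYLOAD_LENGTH),
                )
                payload = tx[offset:offset + PAYLOAD_LENGTH]
                if len(payload) < 25:
                    continue
                truth.loc[gene, str(well)] += 1
                n_reads = config.min_reads_per_molecule + (
                    int(rng.geometric(config.extra_reads_geometric_p)) - 1
                )
                for _ in range(n_reads):
                    serial += 1
                    rid = f"{tag.lower()}{serial:07d}"
                    read_payload = _mutate(payload, rng, config.error_rate)
                    seq = umi + "GGG" + read_payload
                    r1.append((rid, seq, "I" * len(seq)))
                    i1.append((rid, idx1, "I" * len(idx1)))
                    i2.append((rid, idx2, "I" * len(idx2)))
                    prov.append(ReadProvenance(rid, well, f"{tag}:{gene}", molecule_id, umi))
    return FastqTrio(r1, i1, i2), SyntheticTruth(truth, prov)


def simulate_cv_mean_counts(
    n_genes: int = 200,
    n_cells: int = 500,
    offset: float = 0.5,
    mean_range: tuple[float, float] = (1.0, 1000.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Counts whose per-gene CV follows the offset-Poisson relation.

    Gene means sit on a log grid over ``mean_range``; counts are negative
    binomial with the size parameter chosen so that
    CV(m) = m^(-0.5) + offset, i.e. r = 1 / (2c m^(-0.5) + c^2), plus the
    sampling noise of estimating mean and CV from ``n_cells`` cells.
    """
    rng = np.random.default_rng(seed)
    means = np.logspace(np.log10(mean_range[0]), np.log10(mean_range[1]), n_genes)
    counts = np.empty((n_genes, n_cells), dtype=np.int64)
    c = offset
    for i, m in enumerate(means):
        if c == 0:
            counts[i] = rng.poisson(m, size=n_cells)
            continue
        r = 1.0 / (2 * c * m ** -0.5 + c ** 2)
        counts[i] = rng.negative_binomial(r, r / (r + m), size=n_cells)
    return pd.DataFrame(
        counts,
        index=[f"gene{i + 1:04d}" for i in range(n_genes)],
        columns=[f"cell{j + 1:04d}" for j in range(n_cells)],
    )
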