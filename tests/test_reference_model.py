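"""Locus models: refFlat parsing, exon merging, 5' extension, junctions."""

import numpy as np
import pytest

from strtwell.reference_model import (
    JunctionReference,
    LocusModel,
    TranscriptModel,
    build_junction_reference,
    extend_5prime,
    load_refflat,
    locus_spliced_sequence,
    merge_intervals,
    merge_locus_models,
    read_junction_reference,
    reverse_complement,
    translate_junction_alignment,
    whole_locus_intervals,
    write_refflat,
)


def _refflat_row(gene, name, chrom, strand, exons):
    starts = ",".join(str(s) for s, _ in exons) + ","
    ends = ",".join(str(e) for _, e in exons) + ","
    return (
        f"{gene}\t{name}\t{chrom}\t{strand}\t{exons[0][0]}\t{exons[-1][1]}\t"
        f"{exons[0][0]}\t{exons[-1][1]}\t{len(exons)}\t{starts}\t{ends}"
    )


class TestLoadRefflat:
    def test_single_exon_row(self, tmp_path):
        path = tmp_path / "a.refflat"
        path.write_text(_refflat_row("g1", "g1.1", "chr1", "+", [(100, 200)]) + "\n")
        models = load_refflat(str(path))
        assert len(models) == 1
        assert models[0].exons == [(100, 200)]

    def test_exon_count_mismatch_is_hard_error(self, tmp_path):
        row = "g1\tg1.1\tchr1\t+\t100\t300\t100\t300\t2\t100,150,250,\t120,200,300,"
        path = tmp_path / "bad.refflat"
        path.write_text(row + "\n")
        with pytest.raises(ValueError, match=":1"):
            load_refflat(str(path))

    def test_txstart_after_txend_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.refflat"
        path.write_text("g1\tg1.1\tchr1\t+\t300\t100\t300\t100\t1\t100,\t200,\n")
        with pytest.raises(ValueError, match="txStart"):
            load_refflat(str(path))

    def test_shared_gene_names(self, tmp_path):
        rows = [
            _refflat_row("g1", "g1.1", "chr1", "+", [(100, 200)]),
            _refflat_row("g1", "g1.2", "chr1", "+", [(150, 250)]),
            _refflat_row("g2", "g2.1", "chr1", "-", [(500, 600)]),
        ]
        path = tmp_path / "a.refflat"
        path.write_text("\n".join(rows) + "\n")
        models = load_refflat(str(path))
        assert len(models) == 3
        assert sum(m.gene_name == "g1" for m in models) == 2

    def test_write_read_round_trip(self, tmp_path, toy_reference):
        path = tmp_path / "rt.refflat"
        write_refflat(toy_reference.transcripts, str(path))
        loaded = load_refflat(str(path))
        assert [(m.gene_name, m.chrom, m.strand, m.exons) for m in loaded] == [
            (m.gene_name, m.chrom, m.strand, m.exons)
            for m in toy_reference.transcripts
        ]


class TestMergeLoci:
    def test_single_transcript_identity(self):
        t = TranscriptModel("g1", "g1.1", "chr1", "+", [(100, 200), (300, 400)])
        (locus,) = merge_locus_models([t])
        assert locus.merged_exons == [(100, 200), (300, 400)]

    def test_overlapping_exons_union(self):
        models = [
            TranscriptModel("g1", "g1.1", "chr1", "+", [(100, 200)]),
            TranscriptModel("g1", "g1.2", "chr1", "+", [(150, 250)]),
        ]
        (locus,) = merge_locus_models(models)
        assert locus.merged_exons == [(100, 250)]

    def test_union_matches_per_base_oracle(self):
        """Merged exons equal a brute-force boolean-array union."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            transcripts = []
            for i in range(5):
                exons, pos = [], int(rng.integers(0, 50))
                for _ in range(int(rng.integers(1, 4))):
                    pos += int(rng.integers(0, 30))
                    end = pos + int(rng.integers(1, 40))
                    exons.append((pos, end))
                    pos = end
                transcripts.append(
                    TranscriptModel("g", f"t{i}", "chr1", "+", exons)
                )
            (locus,) = merge_locus_models(transcripts)
            covered = np.zeros(500, dtype=bool)
            for t in transcripts:
                for s, e in t.exons:
                    covered[s:e] = True
            merged = np.zeros(500, dtype=bool)
            for s, e in locus.merged_exons:
                assert s < e
                assert not merged[s:e].any()  # disjoint
                merged[s:e] = True
            assert (merged == covered).all()
            total = sum(e - s for s, e in locus.merged_exons)
            assert total <= sum(e - s for t in transcripts for s, e in t.exons)

    def test_same_gene_two_chromosomes_gives_two_loci(self):
        models = [
            TranscriptModel("g1", "g1.1", "chr1", "+", [(100, 200)]),
            TranscriptModel("g1", "g1.2", "chr2", "+", [(100, 200)]),
        ]
        assert len(merge_locus_models(models)) == 2


class TestExtend5Prime:
    def test_free_upstream_extends_100(self):
        locus = LocusModel("g1", "chr1", "+", [(500, 700)])
        (ext,) = extend_5prime([locus])
        assert ext.extended_start == 400

    def test_upstream_exon_bounds_extension(self):
        a = LocusModel("g1", "chr1", "+", [(500, 700)])
        b = LocusModel("g0", "chr1", "+", [(300, 450)])
        ext = extend_5prime([a, b])
        assert ext[0].extended_start == 450  # abuts the upstream exon end

    def test_chromosome_clamp(self):
        locus = LocusModel("g1", "chr1", "+", [(40, 200)])
        (ext,) = extend_5prime([locus])
        assert ext.extended_start == 0

    def test_minus_strand_symmetric(self):
        a = LocusModel("g1", "chr1", "-", [(500, 700)])
        b = LocusModel("g2", "chr1", "-", [(760, 900)])
        ext = extend_5prime([a, b], chrom_lengths={"chr1": 1000})
        assert ext[0].extended_end == 760  # bounded by downstream-genomic exon
        assert ext[1].extended_end == 1000  # clamped at chromosome end

    def test_antisense_exon_does_not_constrain(self):
        a = LocusModel("g1", "chr1", "+", [(500, 700)])
        b = LocusModel("g0", "chr1", "-", [(300, 450)])
        ext = extend_5prime([a, b])
        assert ext[0].extended_start == 400

    def test_exon_outside_window_does_not_constrain(self):
        a = LocusModel("g1", "chr1", "+", [(500, 700)])
        b = LocusModel("g0", "chr1", "+", [(100, 350)])  # ends 150 bases upstream
        ext = extend_5prime([a, b])
        assert ext[0].extended_start == 400

    def test_extension_never_exceeds_100(self, toy_reference):
        loci = toy_reference.loci()
        for locus in loci:
            if locus.strand == "+":
                assert 0 <= locus.start - locus.extended_start <= 100
                assert locus.extended_end == locus.end
            else:
                assert 0 <= locus.extended_end - locus.end <= 100
                assert locus.extended_start == locus.start


class TestWholeLocus:
    def test_spans_extension_to_last_exon(self):
        locus = LocusModel("g1", "chr1", "+", [(400, 500), (900, 1000)])
        (ext,) = extend_5prime([locus])
        rows = whole_locus_intervals([ext])
        assert rows == [("chr1", 300, 1000, "g1", "+")]

    def test_single_exon_locus(self):
        locus = LocusModel("g1", "chr1", "+", [(400, 500)])
        (ext,) = extend_5prime([locus])
        assert ext.whole_locus == (300, 500)

    def test_overlapping_loci_preserved(self):
        a = LocusModel("g1", "chr1", "+", [(100, 400)])
        b = LocusModel("g2", "chr1", "-", [(300, 600)])
        rows = whole_locus_intervals(extend_5prime([a, b]))
        assert len(rows) == 2  # overlap allowed, never merged


def _toy_genome(length=2000, seed=3):
    rng = np.random.default_rng(seed)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, length))}


class TestJunctions:
    def test_junction_counts(self):
        genome = _toy_genome()
        two = LocusModel("g1", "chr1", "+", [(100, 300), (500, 700)])
        four = LocusModel(
            "g2", "chr1", "+", [(800, 900), (1000, 1100), (1200, 1300), (1400, 1500)]
        )
        ref = build_junction_reference([two], genome)
        assert len(ref.contigs) == 1
        ref4 = build_junction_reference([four], genome)
        assert len(ref4.contigs) == 6  # all ordered exon pairs of 4 exons

    def test_lift_round_trip_exhaustive(self):
        """Every junction base lifts to exactly one genomic base with the
        same nucleotide, and lift is injective per contig."""
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "+", [(100, 300), (500, 700), (900, 950)])
        ref = build_junction_reference([locus], genome)
        for contig in ref.contigs.values():
            lifted = [contig.lift(i) for i in range(len(contig.sequence))]
            assert len(set(lifted)) == len(lifted)
            for local, genomic in enumerate(lifted):
                assert contig.sequence[local] == genome["chr1"][genomic]

    def test_short_exon_truncates_flank(self):
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "+", [(100, 120), (500, 700)])
        ref = build_junction_reference([locus], genome, read_length=45)
        (contig,) = ref.contigs.values()
        assert contig.left == (100, 120)  # exon shorter than the 44-base flank
        assert contig.right == (500, 544)

    def test_translate_donor_only_block(self):
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "+", [(100, 300), (500, 700)])
        ref = build_junction_reference([locus], genome)
        (name,) = ref.contigs
        blocks = translate_junction_alignment(ref, name, 0, 10)
        assert blocks == [("chr1", 256, 266)]

    def test_translate_spanning_alignment(self):
        """Blocks must abut the exon boundaries and match a direct spliced
        placement of the same read on the toy genome."""
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "+", [(100, 300), (500, 700)])
        ref = build_junction_reference([locus], genome)
        (name,) = ref.contigs
        contig = ref.contigs[name]
        start = contig.joint - 15
        blocks = translate_junction_alignment(ref, name, start, 36)
        assert blocks == [("chr1", 285, 300), ("chr1", 500, 521)]
        read = contig.sequence[start:start + 36]
        spliced = genome["chr1"][285:300] + genome["chr1"][500:521]
        assert read == spliced

    def test_translate_degenerate_and_out_of_range(self):
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "+", [(100, 300), (500, 700)])
        ref = build_junction_reference([locus], genome)
        (name,) = ref.contigs
        with pytest.raises(ValueError):
            translate_junction_alignment(ref, name, 0, 0)
        with pytest.raises(ValueError):
            translate_junction_alignment(ref, name, 80, 100)
        with pytest.raises(KeyError):
            translate_junction_alignment(ref, "nope", 0, 10)

    def test_fasta_lift_table_round_trip(self, tmp_path):
        genome = _toy_genome()
        locus = LocusModel("g1", "chr1", "-", [(100, 300), (500, 700)])
        ref = build_junction_reference([locus], genome)
        ref.write_fasta(str(tmp_path / "j.fa"))
        ref.write_lift_table(str(tmp_path / "j.tsv"))
        loaded = read_junction_reference(str(tmp_path / "j.fa"), str(tmp_path / "j.tsv"))
        assert loaded.sequences() == ref.sequences()
        for name, contig in ref.contigs.items():
            other = loaded.contigs[name]
            assert (other.left, other.right, other.strand) == (
                contig.left, contig.right, contig.strand
            )


def test_spliced_sequence_strandedness():
    genome = {"chr1": "AAACCCGGGTTTAAACCCGGGTTT"}
    plus = LocusModel("g1", "chr1", "+", [(0, 3), (9, 12)])
    minus = LocusModel("g2", "chr1", "-", [(0, 3), (9, 12)])
    assert locus_spliced_sequence(plus, genome) == "AAATTT"
    assert locus_spliced_sequence(minus, genome) == reverse_complement("AAATTT")


def test_merge_intervals_touching_intervals_join():
    assert merge_intervals([(0, 5), (5, 9)]) == [(0, 9)]
    assert merge_intervals([(0, 5), (6, 9)]) == [(0, 5), (6, 9)]
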