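"""Assignment hierarchy, UMI counting, collision correction, matrices."""

import math

import numpy as np
import pytest

from strtwell.alignment import Mapping, ReadAlignment
from strtwell.molecule_counting import (
    AnnotationIndex,
    MoleculeTable,
    ReadAssignment,
    assign_read,
    build_matrix,
    collision_correct,
    count_molecules,
    quantify_wells,
    well_rng,
)
from strtwell.plate_layout import WellAddress
from strtwell.reference_model import LocusModel, extend_5prime

W = WellAddress(1, 1)


def _alignment(mappings, read_id="r1", umi="ACGTAC", well=W):
    return ReadAlignment(read_id, well, umi, payload="A" * 36, mappings=mappings)


def _m(chrom, pos, strand="+", length=36, blocks=None):
    blocks = blocks or ((pos, pos + length),)
    return Mapping(chrom, strand, tuple(blocks), 0)


@pytest.fixture()
def index():
    # gene A: exons [1000,1500) + [2000,2500), extended to 900, 5' end 900
    # gene B: exon [5000,6000), extended to 4900
    # repeat: [8000,8100) (non-exonic), plus one inside gene A's exon
    loci = extend_5prime(
        [
            LocusModel("A", "chr1", "+", [(1000, 1500), (2000, 2500)]),
            LocusModel("B", "chr1", "+", [(5000, 6000)]),
            LocusModel("C", "chr2", "-", [(1000, 2000)]),
        ]
    )
    return AnnotationIndex(loci, repeats=[("chr1", 8000, 8100), ("chr1", 1100, 1150)])


class TestAssignmentHierarchy:
    def test_unique_exonic_read(self, index):
        rng = np.random.default_rng(0)
        a = assign_read(_alignment([_m("chr1", 1200)]), index, rng)
        assert (a.kind, a.gene) == ("gene", "A")

    def test_extended_region_counts_as_exonic(self, index):
        rng = np.random.default_rng(0)
        a = assign_read(_alignment([_m("chr1", 950)]), index, rng)
        assert (a.kind, a.gene) == ("gene", "A")

    def test_repeat_outside_exons_wins_over_exon(self, index):
        rng = np.random.default_rng(0)
        a = assign_read(
            _alignment([_m("chr1", 1200), _m("chr1", 8020)]), index, rng
        )
        assert a.kind == "repeat"
        assert a.gene is None  # contributes to no gene

    def test_repeat_inside_exon_is_exonic_not_repeat(self, index):
        # the repeat at [1100,1150) overlaps gene A's exon: a read there is exonic
        rng = np.random.default_rng(0)
        a = assign_read(_alignment([_m("chr1", 1110)]), index, rng)
        assert (a.kind, a.gene) == ("gene", "A")

    def test_closest_to_five_prime_end_wins(self, index):
        rng = np.random.default_rng(0)
        # distances to extended 5' ends: gene A 940-900=40, gene B 5300-4900=400
        a = assign_read(
            _alignment([_m("chr1", 940), _m("chr1", 5300)]), index, rng
        )
        assert (a.kind, a.gene) == ("gene", "A")

    def test_no_exon_multiread_assigned_randomly(self, index):
        mappings = [_m("chr1", 9000), _m("chr1", 9500)]
        rng = np.random.default_rng(0)
        a = assign_read(_alignment(mappings), index, rng)
        assert a.kind == "random" and a.gene is None
        assert a.mapping in mappings

    def test_unique_intergenic_read_has_no_feature(self, index):
        rng = np.random.default_rng(0)
        a = assign_read(_alignment([_m("chr1", 9000)]), index, rng)
        assert a.kind == "no_feature"

    def test_unmapped_returns_none(self, index):
        assert assign_read(_alignment([]), index, np.random.default_rng(0)) is None

    def test_strandedness_respected(self, index):
        rng = np.random.default_rng(0)
        plus = assign_read(_alignment([_m("chr2", 1500, "+")]), index, rng)
        minus = assign_read(_alignment([_m("chr2", 1500, "-")]), index, rng)
        assert plus.kind == "no_feature"  # gene C is minus-strand
        assert (minus.kind, minus.gene) == ("gene", "C")

    def test_matches_brute_force_rule_evaluation(self, index):
        """Enumerate toy multireads; re-evaluate the hierarchy independently."""
        rng_pos = np.random.default_rng(3)
        candidates = [1200, 2100, 5100, 8020, 9000, 950, 4950]
        for _ in range(50):
            chosen = rng_pos.choice(candidates, size=int(rng_pos.integers(1, 4)),
                                    replace=False)
            mappings = [_m("chr1", int(p)) for p in sorted(chosen)]
            got = assign_read(_alignment(mappings), index,
                              np.random.default_rng(1))
            # independent oracle
            exonic, repeat = [], []
            for p in sorted(chosen):
                genes = index.genes_at("chr1", p, "+")
                if genes:
                    exonic += [(p, g, abs(p - index.five_prime[g])) for g in genes]
                elif index.in_repeat("chr1", p):
                    repeat.append(p)
            if repeat:
                assert got.kind == "repeat"
                assert got.mapping.pos in repeat
            elif exonic:
                best = min(d for _, _, d in exonic)
                best_genes = {g for _, g, d in exonic if d == best}
                assert got.kind == "gene" and got.gene in best_genes
            elif len(chosen) > 1:
                assert got.kind == "random"
            else:
                assert got.kind == "no_feature"

    def test_assignment_conservation(self, index):
        """Every aligned read lands in exactly one outcome class."""
        rng = np.random.default_rng(5)
        outcomes = {"gene": 0, "repeat": 0, "random": 0, "no_feature": 0}
        n = 100
        for i in range(n):
            pos = int(rng.integers(900, 9500))
            a = assign_read(_alignment([_m("chr1", pos)], read_id=f"r{i}"),
                            index, rng)
            outcomes[a.kind] += 1
        assert sum(outcomes.values()) == n


class TestNucleiMode:
    def test_intronic_read_counts_only_in_nuclei_mode(self):
        loci = extend_5prime(
            [LocusModel("A", "chr1", "+", [(1000, 1500), (2000, 2500)])]
        )
        cells = AnnotationIndex(loci, mode="cells")
        nuclei = AnnotationIndex(loci, mode="nuclei")
        intronic = _alignment([_m("chr1", 1700)])
        rng = np.random.default_rng(0)
        assert assign_read(intronic, cells, rng).kind == "no_feature"
        a = assign_read(intronic, nuclei, rng)
        assert (a.kind, a.gene) == ("gene", "A")


def _assignments(specs):
    out = []
    for i, (umi, pos, n_reads) in enumerate(specs):
        for j in range(n_reads):
            out.append(
                ReadAssignment(f"r{i}.{j}", W, umi, "gene", "A",
                               _m("chr1", pos))
            )
    return out


class TestMoleculeCounting:
    def test_duplicate_reads_collapse_to_one_molecule(self):
        table = count_molecules(_assignments([("AAAAAA", 1000, 5)]))
        assert table.molecules(W) == {("A", 1000, "+"): 1}

    def test_singleton_umis_excluded(self):
        table = count_molecules(
            _assignments([("AAAAAA", 1000, 3), ("CCCCCC", 1000, 2),
                          ("GGGGGG", 1000, 1)])
        )
        assert table.molecules(W) == {("A", 1000, "+"): 2}

    def test_positions_counted_separately(self):
        table = count_molecules(
            _assignments([("AAAAAA", 1000, 2), ("AAAAAA", 1100, 2)])
        )
        assert table.gene_counts(W)["A"] == 2


class TestCollisionCorrection:
    def test_zero_and_identity_limits(self):
        assert collision_correct(0) == 0.0
        assert collision_correct(1) == pytest.approx(1.000122, abs=1e-5)

    def test_closed_form_value_at_k_1000(self):
        # frozen from the closed form -4096 ln(1 - 1000/4096)
        assert collision_correct(1000) == pytest.approx(1146.47, abs=0.01)

    def test_monotone_and_superlinear(self):
        ks = np.arange(0, 4000, 50)
        vals = np.array([collision_correct(int(k)) for k in ks])
        assert (np.diff(vals) > 0).all()
        assert (vals >= ks - 1e-9).all()
        slopes = np.diff(vals) / np.diff(ks)
        assert (slopes >= 1.0 - 1e-12).all()  # d/dk = 1/(1 - k/K) >= 1

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            collision_correct(-1)
        with pytest.raises(ValueError):
            collision_correct(4096)

    @pytest.mark.parametrize("frac", [0.1, 0.25, 0.5, 0.9])
    def test_monte_carlo_occupancy_oracle(self, frac):
        """Dropping n = correct(k) molecules into 4^6 bins occupies ~k."""
        K = 4096
        k = int(frac * K)
        n = int(round(collision_correct(k)))
        rng = np.random.default_rng(k)
        occupied = [
            len(np.unique(rng.integers(0, K, size=n))) for _ in range(60)
        ]
        assert abs(np.mean(occupied) - k) / k < 0.01


class TestMatrix:
    def test_single_gene_single_well(self):
        loci = [LocusModel("A", "chr1", "+", [(1000, 1500)])]
        specs = [(f"UMI{i:03d}", 1000, 2) for i in range(7)]
        table = count_molecules(_assignments(specs))
        matrix = build_matrix(table, loci)
        assert matrix.raw.shape == (1, 1)
        assert matrix.raw.iloc[0, 0] == 7
        assert matrix.corrected.iloc[0, 0] == pytest.approx(
            -4096 * math.log1p(-7 / 4096)
        )

    def test_empty_table_keeps_gene_index(self):
        loci = [LocusModel("A", "chr1", "+", [(0, 100)]),
                LocusModel("B", "chr1", "+", [(200, 300)])]
        matrix = build_matrix(MoleculeTable(), loci)
        assert list(matrix.raw.index) == ["A", "B"]
        assert matrix.raw.shape == (2, 0)

    def test_corrected_at_least_raw(self):
        loci = [LocusModel("A", "chr1", "+", [(1000, 1500)])]
        specs = [(f"U{i:05d}", 1000 + (i % 3), 2) for i in range(50)]
        matrix = build_matrix(count_molecules(_assignments(specs)), loci)
        assert (matrix.corrected.to_numpy() >= matrix.raw.to_numpy() - 1e-9).all()

    def test_well_totals_are_column_sums(self):
        loci = [LocusModel("A", "chr1", "+", [(1000, 1500)])]
        matrix = build_matrix(
            count_molecules(_assignments([("AAAAAA", 1000, 2)])), loci
        )
        assert (matrix.well_totals == matrix.raw.sum(axis=0)).all()


class TestDeterminism:
    def test_identical_seed_identical_matrices(self, index):
        rng = np.random.default_rng(12)
        alignments = []
        for i in range(200):
            pos = int(rng.integers(900, 9500))
            multi = [_m("chr1", pos), _m("chr1", int(rng.integers(900, 9500)))]
            umi = "".join("ACGT"[b] for b in rng.integers(0, 4, 6))
            for j in range(2):  # duplicate reads so molecules survive
                alignments.append(
                    _alignment(multi, read_id=f"r{i}.{j}", umi=umi,
                               well=WellAddress(1, 1 + i % 3))
                )
        loci = extend_5prime(
            [LocusModel("A", "chr1", "+", [(1000, 1500), (2000, 2500)]),
             LocusModel("B", "chr1", "+", [(5000, 6000)])]
        )
        m1, _, _ = quantify_wells(alignments, index, loci, seed=77)
        m2, _, _ = quantify_wells(alignments, index, loci, seed=77)
        assert m1.raw.sum().sum() > 0
        assert m1.raw.equals(m2.raw)

    def test_well_rng_independent_of_processing_order(self):
        a = well_rng(5, WellAddress(2, 9)).integers(0, 1000, 4)
        b = well_rng(5, WellAddress(2, 9)).integers(0, 1000, 4)
        c = well_rng(5, WellAddress(2, 10)).integers(0, 1000, 4)
        assert (a == b).all()
        assert not (a == c).all()
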