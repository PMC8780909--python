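import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ttkin import (
    GenomicInterval,
    PeakSet,
    TranscriptModel,
    assign_peak_region,
    cobinding_fraction,
    genes_with_region_peaks,
    metagene_coordinate,
    metagene_profile,
    overlap_partition,
    read_transcript_models,
    write_transcript_models,
)
from ttkin.errors import ValidationError


def plus_tx(gene_id="gx", utr5=(100, 300), cds=(300, 900), utr3=(900, 1200)):
    return TranscriptModel(
        gene_id=gene_id,
        chrom="chr1",
        strand="+",
        utr5=(GenomicInterval("chr1", *utr5),),
        cds=(GenomicInterval("chr1", *cds),),
        utr3=(GenomicInterval("chr1", *utr3),),
    )


def minus_tx(gene_id="gm"):
    # genomic layout left->right: 3'UTR [0,300), CDS [300,900), 5'UTR [900,1100)
    return TranscriptModel(
        gene_id=gene_id,
        chrom="chr1",
        strand="-",
        utr5=(GenomicInterval("chr1", 900, 1100, "-"),),
        cds=(GenomicInterval("chr1", 300, 900, "-"),),
        utr3=(GenomicInterval("chr1", 0, 300, "-"),),
    )


def peak_at(mid, w=10, chrom="chr1"):
    return GenomicInterval(chrom, mid - w // 2, mid + w - w // 2)


class TestRegionAssignment:
    def test_midpoint_in_each_region(self):
        tx = plus_tx()
        assert assign_peak_region(peak_at(150), tx) == "utr5"
        assert assign_peak_region(peak_at(500), tx) == "cds"
        assert assign_peak_region(peak_at(1000), tx) == "utr3"
        assert assign_peak_region(peak_at(50), tx) == "none"

    def test_boundary_belongs_to_downstream_region(self):
        # midpoint exactly at the CDS/3'UTR junction coordinate (900)
        tx = plus_tx()
        assert assign_peak_region(GenomicInterval("chr1", 895, 905), tx) == "utr3"
        # and at the 5'UTR/CDS junction (300)
        assert assign_peak_region(GenomicInterval("chr1", 295, 305), tx) == "cds"

    def test_minus_strand_flips_regions(self):
        # genomically leftmost block of a minus-strand gene is its 3'UTR
        tx = minus_tx()
        assert assign_peak_region(peak_at(150), tx) == "utr3"
        assert assign_peak_region(peak_at(500), tx) == "cds"
        assert assign_peak_region(peak_at(1000), tx) == "utr5"

    def test_chromosome_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            assign_peak_region(peak_at(150, chrom="chr2"), plus_tx())

    def test_strand_symmetry_under_coordinate_reflection(self):
        # reflecting the locus (x -> L - x) and flipping strand must leave
        # every region assignment unchanged
        L = 1200
        tx = plus_tx()
        flipped = TranscriptModel(
            gene_id="gx_rc",
            chrom="chr1",
            strand="-",
            utr5=(GenomicInterval("chr1", L - 300, L - 100, "-"),),
            cds=(GenomicInterval("chr1", L - 900, L - 300, "-"),),
            utr3=(GenomicInterval("chr1", L - 1200, L - 900, "-"),),
        )
        for mid in range(105, 1200, 37):
            fwd = assign_peak_region(GenomicInterval("chr1", mid, mid + 1), tx)
            rev = assign_peak_region(
                GenomicInterval("chr1", L - mid - 1, L - mid), flipped
            )
            assert fwd == rev


class TestMetageneCoordinate:
    def test_region_starts_and_midpoints(self):
        tx = plus_tx(utr5=(0, 200), cds=(200, 1200), utr3=(1200, 1300))
        assert metagene_coordinate(GenomicInterval("chr1", 0, 1), tx) == 0.0
        assert metagene_coordinate(GenomicInterval("chr1", 200, 201), tx) == 1.0
        # middle base of a 100-nt 3'UTR -> 2.5
        assert metagene_coordinate(GenomicInterval("chr1", 1250, 1251), tx) == 2.5
        assert metagene_coordinate(GenomicInterval("chr1", 5000, 5001), tx) is None

    def test_agrees_with_region_assignment(self, small_sim):
        rng = np.random.default_rng(0)
        region_of = {0: "utr5", 1: "cds", 2: "utr3"}
        for tx in small_sim.transcripts[:40]:
            lo, hi = tx.span
            for mid in rng.integers(lo, hi, 5):
                peak = GenomicInterval(tx.chrom, int(mid), int(mid) + 1)
                x = metagene_coordinate(peak, tx)
                region = assign_peak_region(peak, tx)
                if x is None:
                    assert region == "none"
                else:
                    assert 0.0 <= x < 3.0
                    assert region_of[int(math.floor(x))] == region


class TestGeneSets:
    def test_empty_peak_set(self):
        assert genes_with_region_peaks(PeakSet(), [plus_tx()], "utr3") == set()

    def test_peak_shared_by_two_genes_counts_for_both(self):
        a = plus_tx("a", utr5=(0, 100), cds=(100, 800), utr3=(800, 1000))
        b = TranscriptModel(
            gene_id="b",
            chrom="chr1",
            strand="-",
            utr5=(GenomicInterval("chr1", 1500, 1600, "-"),),
            cds=(GenomicInterval("chr1", 950, 1500, "-"),),
            utr3=(GenomicInterval("chr1", 700, 950, "-"),),
        )
        peaks = PeakSet([GenomicInterval("chr1", 895, 905)])
        assert genes_with_region_peaks(peaks, [a, b], "utr3") == {"a", "b"}

    def test_cobinding_fraction(self):
        reader = {f"g{i}" for i in range(25)}
        ago2 = {f"g{i}" for i in range(23)} | {"other"}
        assert cobinding_fraction(reader, ago2) == 92.0
        assert cobinding_fraction(reader, reader | {"x"}) == 100.0
        assert cobinding_fraction(reader, {"zzz"}) == 0.0
        with pytest.raises(ValidationError):
            cobinding_fraction(set(), ago2)


def brute_force_partition(a, b, c):
    """Oracle: classify every element of the union by its membership tuple."""
    counts = dict.fromkeys(
        ["a_only", "b_only", "c_only", "ab_only", "ac_only", "bc_only", "abc"], 0
    )
    names = {
        (True, False, False): "a_only",
        (False, True, False): "b_only",
        (False, False, True): "c_only",
        (True, True, False): "ab_only",
        (True, False, True): "ac_only",
        (False, True, True): "bc_only",
        (True, True, True): "abc",
    }
    for x in a | b | c:
        counts[names[(x in a, x in b, x in c)]] += 1
    return counts


class TestOverlapPartition:
    def test_disjoint_and_identical(self):
        assert overlap_partition({"x"}, {"y"}, {"z"}) == {
            "a_only": 1, "b_only": 1, "c_only": 1,
            "ab_only": 0, "ac_only": 0, "bc_only": 0, "abc": 0,
        }
        s = set(range(7))
        part = overlap_partition(s, set(s), set(s))
        assert part["abc"] == 7 and sum(part.values()) == 7

    def test_worked_example_against_brute_force(self):
        a, b, c = set(range(1, 7)), set(range(4, 10)), set(range(6, 12))
        assert overlap_partition(a, b, c) == brute_force_partition(a, b, c)

    @given(
        st.tuples(*(st.sets(st.integers(0, 30), max_size=25) for _ in range(3)))
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_oracle_and_sums_to_union(self, sets):
        a, b, c = sets
        part = overlap_partition(a, b, c)
        assert part == brute_force_partition(a, b, c)
        assert sum(part.values()) == len(a | b | c)


class TestMetageneProfile:
    def test_single_peak_single_bin(self):
        tx = plus_tx()
        prof = metagene_profile(PeakSet([peak_at(1000)]), [tx], n_bins=30)
        occupied = prof.densities > 0
        assert occupied.sum() == 1
        width = 3.0 / 30
        assert prof.densities[occupied][0] == pytest.approx(1 / width)
        assert prof.n_peaks_mapped == 1

    def test_utr3_only_peaks_mass(self, small_sim):
        prof = metagene_profile(
            small_sim.peaks["m6A"], small_sim.transcripts, n_bins=90
        )
        assert prof.region_mass("utr3") == pytest.approx(1.0)
        assert prof.n_peaks_unmapped == 0

    def test_density_integrates_to_one(self, small_sim):
        prof = metagene_profile(
            small_sim.peaks["AGO2"], small_sim.transcripts, n_bins=30
        )
        width = prof.bin_edges[1] - prof.bin_edges[0]
        assert prof.densities.sum() * width == pytest.approx(1.0)

    def test_planted_region_mixture_recovered(self, small_sim):
        # 60/10/30% of peaks in 5'UTR/CDS/3'UTR: recovered masses within
        # 2 points at 1e4 peaks
        rng = np.random.default_rng(77)
        txs = small_sim.transcripts
        mix = {"utr5": 0.6, "cds": 0.1, "utr3": 0.3}
        peaks = []
        for region, frac in mix.items():
            for _ in range(int(frac * 10_000)):
                tx = txs[int(rng.integers(len(txs)))]
                block = tx.blocks(region)[0]
                pos = int(rng.integers(block.start, block.end))
                peaks.append(GenomicInterval(tx.chrom, pos, pos + 1))
        prof = metagene_profile(PeakSet(peaks), txs, n_bins=30)
        for region, frac in mix.items():
            assert abs(prof.region_mass(region) - frac) < 0.02

    def test_bin_count_validation(self):
        with pytest.raises(ValidationError):
            metagene_profile(PeakSet(), [plus_tx()], n_bins=20)


class TestIO:
    def test_bed_round_trip_bit_exact(self, tmp_path):
        ps = PeakSet(
            [
                GenomicInterval("chr1", 10, 60, "+", name="p1", score=3),
                GenomicInterval("chr2", 0, 5, "-", name="p2", score=0),
            ],
            name="demo",
        )
        path = tmp_path / "a.bed"
        ps.to_bed(path)
        first = path.read_bytes()
        back = PeakSet.from_bed(path)
        back.to_bed(tmp_path / "b.bed")
        assert (tmp_path / "b.bed").read_bytes() == first
        assert back.intervals == ps.intervals

    def test_transcript_tsv_round_trip(self, tmp_path):
        models = [plus_tx(), minus_tx()]
        write_transcript_models(models, tmp_path / "tx.tsv")
        back = read_transcript_models(tmp_path / "tx.tsv")
        assert [m.gene_id for m in back] == ["gx", "gm"]
        assert back[0].utr5 == models[0].utr5
        assert back[1].utr3 == models[1].utr3

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 10)
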