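"""Truncated-genome construction and peak-set algebra against brute-force
per-base / all-pairs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erna_scout.intervals import (
    GenomeAnnotation,
    Gene,
    Interval,
    RegionSet,
    TruncationParams,
    build_exclusion_zones,
    filter_intergenic_peaks,
    merge_peak_sets,
    read_annotation,
    read_bed,
    read_chrom_sizes,
)

CHROM_LEN = 100_000


def _random_annotation(rng, n_genes=20, chrom_len=CHROM_LEN, chroms=("chrA", "chrB")):
    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 2000))
        end = start + int(rng.integers(100, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(Gene(f"g{i}", chrom, start, min(end, chrom_len), strand))
    return GenomeAnnotation(genes, {c: chrom_len for c in chroms})


def _random_peaks(rng, n=50, chrom_len=CHROM_LEN, chroms=("chrA", "chrB")):
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, chrom_len - 500))
        ivs.append(Interval(chrom, start, start + int(rng.integers(50, 500)), name=f"p{i}"))
    return RegionSet(ivs).sort()


def _zone_mask(ann, p):
    """Per-base oracle: boolean exclusion mask per chromosome."""
    masks = {c: np.zeros(L, dtype=bool) for c, L in ann.chrom_sizes.items()}
    for g in ann.genes:
        if g.strand == "+":
            s, e = g.start - p.upstream_exclude, g.end + p.downstream_exclude
        else:
            s, e = g.start - p.downstream_exclude, g.end + p.upstream_exclude
        L = ann.chrom_sizes[g.chrom]
        masks[g.chrom][max(0, s):min(L, e)] = True
    return masks


class TestExclusionZones:
    def test_plus_strand_arithmetic(self):
        ann = GenomeAnnotation([Gene("g", "c", 9999, 20000, "+")], {"c": 100_000})
        (zone,) = build_exclusion_zones(ann).intervals
        assert (zone.start, zone.end) == (7999, 20500)

    def test_minus_strand_mirrors(self):
        ann = GenomeAnnotation([Gene("g", "c", 9999, 20000, "-")], {"c": 100_000})
        (zone,) = build_exclusion_zones(ann).intervals
        assert (zone.start, zone.end) == (9499, 22000)

    def test_clipped_to_chromosome(self):
        ann = GenomeAnnotation([Gene("g", "c", 500, 1000, "+")], {"c": 1200})
        (zone,) = build_exclusion_zones(ann).intervals
        assert (zone.start, zone.end) == (0, 1200)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ann = _random_annotation(rng)
        p = TruncationParams()
        zones = build_exclusion_zones(ann, p)
        oracle = _zone_mask(ann, p)
        got = {c: np.zeros(L, dtype=bool) for c, L in ann.chrom_sizes.items()}
        for iv in zones:
            got[iv.chrom][iv.start:iv.end] = True
        for c in oracle:
            assert np.array_equal(got[c], oracle[c])

    def test_covers_every_gene_body_base(self, rng):
        ann = _random_annotation(rng)
        zones = build_exclusion_zones(ann)
        cover = {c: np.zeros(L, dtype=bool) for c, L in ann.chrom_sizes.items()}
        for iv in zones:
            cover[iv.chrom][iv.start:iv.end] = True
        for g in ann.genes:
            assert cover[g.chrom][g.start:g.end].all()


class TestIntergenicFilter:
    def test_disjoint_peak_retained(self):
        excl = RegionSet([Interval("c", 7999, 20500)], sorted=True, merged=True)
        peaks = RegionSet([Interval("c", 30000, 30500)]).sort()
        assert len(filter_intergenic_peaks(peaks, excl)) == 1

    def test_single_base_overlap_drops(self):
        excl = RegionSet([Interval("c", 7999, 20500)], sorted=True, merged=True)
        peaks = RegionSet([Interval("c", 20400, 20900)]).sort()
        assert len(filter_intergenic_peaks(peaks, excl)) == 0

    def test_empty_peaks(self):
        excl = RegionSet([Interval("c", 0, 10)], sorted=True, merged=True)
        assert len(filter_intergenic_peaks(RegionSet([]), excl)) == 0

    def test_unmerged_exclusion_rejected(self):
        excl = RegionSet([Interval("c", 0, 10)])
        with pytest.raises(ValueError):
            filter_intergenic_peaks(RegionSet([]), excl)

    def test_empty_exclusion_is_identity(self, rng):
        peaks = _random_peaks(rng)
        kept = filter_intergenic_peaks(peaks, RegionSet([], sorted=True, merged=True))
        assert [iv for iv in kept] == [iv for iv in peaks]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_per_base_overlap_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ann = _random_annotation(rng)
        peaks = _random_peaks(rng, n=80)
        p = TruncationParams()
        zones = build_exclusion_zones(ann, p)
        kept = {iv.name for iv in filter_intergenic_peaks(peaks, zones)}
        masks = _zone_mask(ann, p)
        expected = {
            iv.name
            for iv in peaks
            if not masks[iv.chrom][iv.start:iv.end].any()
        }
        assert kept == expected

    def test_anti_monotone_in_exclusion(self, rng):
        ann = _random_annotation(rng)
        peaks = _random_peaks(rng, n=80)
        small = build_exclusion_zones(ann, TruncationParams(500, 100, 250))
        large = build_exclusion_zones(ann, TruncationParams(5000, 2000, 250))
        kept_small = {iv.name for iv in filter_intergenic_peaks(peaks, small)}
        kept_large = {iv.name for iv in filter_intergenic_peaks(peaks, large)}
        assert kept_large <= kept_small


def _merge_oracle(intervals, d):
    """Fixpoint oracle: repeatedly merge any pair meeting the criterion."""
    ivs = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(ivs)):
            for j in range(i + 1, len(ivs)):
                (c1, s1, e1), (c2, s2, e2) = ivs[i], ivs[j]
                if c1 != c2:
                    continue
                overlap = s1 < e2 and s2 < e1
                centres = abs((s1 + e1) // 2 - (s2 + e2) // 2) <= d
                if overlap or centres:
                    ivs[i] = (c1, min(s1, s2), max(e1, e2))
                    del ivs[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(ivs)


class TestUnionMerge:
    def test_centre_distance_merges(self):
        rs = merge_peak_sets([RegionSet([Interval("c", 900, 1100), Interval("c", 1100, 1300)])], 250)
        assert [(iv.start, iv.end) for iv in rs] == [(900, 1300)]

    def test_centres_too_far_stay_apart(self):
        rs = merge_peak_sets([RegionSet([Interval("c", 900, 1100), Interval("c", 1200, 1400)])], 250)
        assert [(iv.start, iv.end) for iv in rs] == [(900, 1100), (1200, 1400)]

    def test_idempotent(self, rng):
        peaks = _random_peaks(rng)
        once = merge_peak_sets([peaks], 250)
        twice = merge_peak_sets([once], 250)
        assert [(iv.chrom, iv.start, iv.end) for iv in once] == [
            (iv.chrom, iv.start, iv.end) for iv in twice
        ]

    def test_order_independent(self, rng):
        sets = [_random_peaks(np.random.default_rng(s), n=30) for s in range(4)]
        a = merge_peak_sets(sets, 250)
        b = merge_peak_sets(sets[::-1], 250)
        assert [(iv.chrom, iv.start, iv.end) for iv in a] == [
            (iv.chrom, iv.start, iv.end) for iv in b
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_fixpoint_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        peaks = _random_peaks(rng, n=40)
        got = merge_peak_sets([peaks], 250)
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == _merge_oracle(peaks, 250)

    @pytest.mark.parametrize("seed", range(5))
    def test_fixpoint_no_pair_mergeable(self, seed):
        rng = np.random.default_rng(300 + seed)
        got = list(merge_peak_sets([_random_peaks(rng, n=60)], 250))
        for i in range(len(got)):
            for j in range(i + 1, len(got)):
                a, b = got[i], got[j]
                if a.chrom != b.chrom:
                    continue
                assert not (a.start < b.end and b.start < a.end)
                assert abs(a.centre - b.centre) > 250


class TestReaders:
    def test_gtf_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\tgene\t10001\t20000\t.\t+\t.\tgene_id "G1";\n')
        ann = read_annotation(p, {"chr1": 50_000})
        assert (ann.genes[0].start, ann.genes[0].end) == (10000, 20000)

    def test_transcripts_collapse_to_gene_extent(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\ts\ttranscript\t100\t200\t.\t+\t.\tgene_id "G1";\n'
            'chr1\ts\ttranscript\t150\t400\t.\t+\t.\tgene_id "G1";\n'
        )
        ann = read_annotation(p, {"chr1": 1000})
        assert (ann.genes[0].start, ann.genes[0].end) == (99, 400)

    def test_empty_gtf(self, tmp_path):
        p = tmp_path / "e.gtf"
        p.write_text("")
        assert len(read_annotation(p, {"chr1": 1000})) == 0

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.gtf"
        p.write_text('chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G1";\nchr1\tonly-three\tfields\n')
        with pytest.raises(ValueError, match="line 2"):
            read_annotation(p, {"chr1": 1000})

    def test_unknown_chromosome_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chrZ\ts\tgene\t1\t100\t.\t+\t.\tgene_id "G1";\n')
        with pytest.raises(ValueError, match="chrZ"):
            read_annotation(p, {"chr1": 1000})

    def test_bed_roundtrip(self, tmp_path, rng):
        peaks = _random_peaks(rng, n=20)
        path = tmp_path / "p.bed"
        peaks.write_bed(path)
        back = read_bed(path)
        assert [(iv.chrom, iv.start, iv.end, iv.name) for iv in back] == [
            (iv.chrom, iv.start, iv.end, iv.name) for iv in peaks
        ]

    def test_chrom_sizes(self, tmp_path):
        p = tmp_path / "cs.tsv"
        p.write_text("chr1\t1000\nchr2\t2000\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 2000}


@given(
    start=st.integers(0, 10_000),
    length=st.integers(1, 5_000),
    up=st.integers(0, 3_000),
    down=st.integers(0, 3_000),
)
@settings(max_examples=50, deadline=None)
def test_zone_always_contains_gene_body(start, length, up, down):
    ann = GenomeAnnotation([Gene("g", "c", start, start + length, "+")], {"c": 20_000})
    (zone,) = build_exclusion_zones(ann, TruncationParams(up, down, 250)).intervals
    assert zone.start <= start and zone.end >= min(20_000, start + length)
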