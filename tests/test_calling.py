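import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1peak import calling
from l1peak.calling import (
    INTERGENIC,
    INTRAGENIC,
    KNR,
    KR,
    NEW_PROFILE,
    NOVEL,
    ORIGINAL_PROFILE,
    FilterProfile,
    Peak,
    annotate_genic_context,
    annotate_mappability,
    apply_filter,
    build_peaks,
    classify_peak,
    compute_mappability,
    read_peak_report,
    write_peak_report,
)
from l1peak.core import GenomicInterval, ReferenceGenome
from l1peak.reads import AlignedRead
from l1peak.synth import GeneModel, L1CatalogEntry, generate_genome


def aln(start, strand="+", contig="chrS", mapq=60, matchpct=1.0, n_best=1, rid=None):
    return AlignedRead(
        rid or f"r{start}.{strand}",
        GenomicInterval(contig, start, start + 64, strand),
        mapq,
        matchpct,
        n_best,
    )


def make_peak(**overrides):
    defaults = dict(
        interval=GenomicInterval("chrS", 1000, 1100, "+"),
        insertion_point=1000,
        per_pool_reads={"p1": 6, "p2": 4},
        per_pool_unique={"p1": 3, "p2": 2},
        unique_alignments=5,
        mean_mapq=45.0,
        mean_matchpct=0.999,
        mapscore=0.9,
        mappability=1.0,
    )
    defaults.update(overrides)
    return Peak(**defaults)


class TestBuildPeaks:
    def test_contiguous_starts_one_peak(self):
        alns = [aln(1000 + i, rid=f"r{i}") for i in range(6)] + [
            aln(1000, rid=f"d{i}") for i in range(4)
        ]
        peaks = build_peaks({"p1": alns})
        assert len(peaks) == 1
        peak = peaks[0]
        assert peak.unique_alignments == 6
        assert peak.insertion_point == 1000
        assert peak.total_reads == 10
        assert peak.per_pool_unique["p1"] == 6

    def test_distant_groups_two_peaks(self):
        alns = [aln(1000), aln(1010, rid="a")] + [aln(11_000), aln(11_005, rid="b")]
        peaks = build_peaks({"p1": alns})
        assert len(peaks) == 2

    def test_identical_starts_single_unique(self):
        alns = [aln(2000, rid=f"r{i}") for i in range(8)]
        peaks = build_peaks({"p1": alns})
        assert len(peaks) == 1
        assert peaks[0].unique_alignments == 1
        assert peaks[0].maxuniq == 1
        assert not ORIGINAL_PROFILE.accepts(
            make_peak(
                per_pool_reads={"p1": 8}, per_pool_unique={"p1": 1}, unique_alignments=1
            )
        )

    def test_cross_strand_never_merges(self):
        peaks = build_peaks({"p1": [aln(1000, "+"), aln(1001, "-")]})
        assert len(peaks) == 2

    def test_minus_strand_insertion_point(self):
        alns = [aln(3000, "-"), aln(3010, "-")]
        peaks = build_peaks({"p1": alns})
        assert peaks[0].insertion_point == 3010 + 64

    def test_per_pool_counts(self):
        peaks = build_peaks({"p1": [aln(100), aln(101, rid="x")], "p2": [aln(102, rid="y")]})
        assert len(peaks) == 1
        assert peaks[0].per_pool_reads == {"p1": 2, "p2": 1}
        assert peaks[0].maxcount == 2

    def test_empty_input(self):
        assert build_peaks({}) == []
        assert build_peaks({"p1": []}) == []

    def test_mapscore_is_unique_fraction(self):
        alns = [aln(100, n_best=1), aln(101, n_best=2, mapq=0), aln(102, n_best=1, rid="z")]
        peaks = build_peaks({"p1": alns})
        assert peaks[0].mapscore == pytest.approx(2 / 3)

    def test_mean_metrics(self):
        alns = [aln(100, mapq=60, matchpct=1.0), aln(101, mapq=30, matchpct=0.9)]
        peak = build_peaks({"p1": alns})[0]
        assert peak.mean_mapq == 45.0
        assert peak.mean_matchpct == pytest.approx(0.95)

    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=2000), min_size=1, max_size=30),
        st.integers(min_value=1, max_value=128),
    )
    def test_matches_bruteforce_single_linkage(self, starts, window):
        """Oracle: brute-force single-linkage clustering of starts."""
        starts = sorted(starts)
        clusters = [[starts[0]]]
        for s in starts[1:]:
            if s - clusters[-1][-1] <= window:
                clusters[-1].append(s)
            else:
                clusters.append([s])
        alns = [aln(s, rid=f"r{i}") for i, s in enumerate(starts)]
        peaks = build_peaks({"p1": alns}, window=window)
        assert len(peaks) == len(clusters)
        for peak, members in zip(peaks, clusters):
            assert peak.total_reads == len(members)
            assert peak.interval.start == min(members)


class TestMappability:
    def test_unique_genome_all_ones(self):
        genome = generate_genome(5000, 0.5, seed=3)
        track = compute_mappability(genome, k=64)
        assert np.all(track.scores["chrS"] == 1.0)

    def test_duplicated_64mer_scores_half(self):
        base = generate_genome(4000, 0.5, seed=4)["chrS"]
        dup = base[1000:1064]
        genome = ReferenceGenome({"c": base + dup + base[2000:2500]})
        track = compute_mappability(genome, k=64)
        assert track.scores["c"][1000] == 0.5
        assert track.scores["c"][4000] == 0.5
        assert track.scores["c"][500] == 1.0

    def test_peak_mean_unique_region(self):
        genome = generate_genome(5000, 0.5, seed=5)
        track = compute_mappability(genome, k=64)
        peak = make_peak(interval=GenomicInterval("chrS", 1000, 1100, "+"))
        annotate_mappability(peak, track)
        assert peak.mappability == 1.0

    def test_k_exceeds_contig_errors(self):
        genome = ReferenceGenome({"c": "ACGT" * 10})
        with pytest.raises(ValueError):
            compute_mappability(genome, k=64)


def catalog_entry(pos, cls, strand="+"):
    return L1CatalogEntry(GenomicInterval("chrS", pos, pos + 1, strand), cls, f"{cls}@{pos}")


class TestClassify:
    def test_near_kr(self):
        peak = make_peak(insertion_point=1000)
        assert classify_peak(peak, [catalog_entry(1100, KR)]) == KR
        assert peak.catalog_class == KR

    def test_near_knr(self):
        peak = make_peak(insertion_point=1000)
        assert classify_peak(peak, [catalog_entry(1100, KNR)]) == KNR

    def test_kr_precedence_on_double_match(self):
        peak = make_peak(insertion_point=1000)
        catalog = [catalog_entry(1100, KNR), catalog_entry(1200, KR)]
        assert classify_peak(peak, catalog) == KR

    def test_window_boundary(self):
        entry = catalog_entry(2000, KR)
        at_edge = make_peak(insertion_point=1500)  # distance exactly 500
        assert classify_peak(at_edge, [entry]) == KR
        outside = make_peak(insertion_point=1499)  # distance 501
        assert classify_peak(outside, [entry]) == NOVEL

    def test_no_catalog_novel(self):
        assert classify_peak(make_peak(), []) == NOVEL

    def test_partition_property(self):
        catalog = [catalog_entry(5000, KR), catalog_entry(9000, KNR)]
        peaks = [make_peak(insertion_point=p) for p in range(0, 20_000, 500)]
        labels = [classify_peak(p, catalog) for p in peaks]
        assert all(l in (KR, KNR, NOVEL) for l in labels)
        assert labels.count(KR) + labels.count(KNR) + labels.count(NOVEL) == len(peaks)


class TestApplyFilter:
    def test_original_pass_example(self):
        peak = make_peak(
            per_pool_reads={"p1": 6},
            per_pool_unique={"p1": 2},
            mean_mapq=35.0,
            mapscore=0.6,
        )
        assert apply_filter([peak], ORIGINAL_PROFILE) == [peak]

    def test_new_total_reads_strict(self):
        peak = make_peak(per_pool_reads={"p1": 5}, per_pool_unique={"p1": 3})
        assert peak.total_reads == 5
        assert apply_filter([peak], NEW_PROFILE) == []

    def test_new_matchpct_strict(self):
        peak = make_peak(mean_matchpct=0.98)
        assert apply_filter([peak], NEW_PROFILE) == []

    def test_new_pass(self):
        assert apply_filter([make_peak()], NEW_PROFILE) == [make_peak()]

    def test_missing_metric_errors(self):
        peak = make_peak(mappability=None)
        with pytest.raises(ValueError):
            apply_filter([peak], NEW_PROFILE)
        bad_profile = FilterProfile("bad", (("no_such_metric", ">", 1),))
        with pytest.raises(AttributeError):
            apply_filter([make_peak()], bad_profile)

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=20),  # total reads
                st.integers(min_value=1, max_value=10),  # unique
                st.floats(min_value=0, max_value=60),  # mean mapq
                st.floats(min_value=0.9, max_value=1.0),  # matchpct
            ),
            max_size=15,
        )
    )
    def test_monotonicity(self, rows):
        peaks = [
            make_peak(
                per_pool_reads={"p1": max(1, t)},
                per_pool_unique={"p1": min(u, max(1, t))},
                unique_alignments=min(u, max(1, t)),
                mean_mapq=q,
                mean_matchpct=m,
            )
            for t, u, q, m in rows
        ]
        stricter = FilterProfile(
            "stricter",
            tuple(
                (metric, op, value + (2 if metric != "mean_matchpct" else 0.005))
                for metric, op, value in NEW_PROFILE.thresholds
            ),
        )
        loose = {id(p) for p in apply_filter(peaks, NEW_PROFILE)}
        strict = {id(p) for p in apply_filter(peaks, stricter)}
        assert strict <= loose


def gene(gene_id, start, end, strand="+", contig="chrS"):
    mid = (start + end) // 2
    return GeneModel(
        gene_id,
        GenomicInterval(contig, start, end, strand),
        (
            GenomicInterval(contig, start, start + 100, strand),
            GenomicInterval(contig, mid, mid + 100, strand),
        ),
    )


class TestGenicContext:
    def test_intron_is_intragenic(self):
        g = gene("g1", 10_000, 20_000)
        peak = make_peak(insertion_point=12_000)  # between the two exons
        assert annotate_genic_context(peak, [g]) == INTRAGENIC
        assert peak.gene_id == "g1"

    def test_exon_is_intragenic(self):
        g = gene("g1", 10_000, 20_000)
        assert annotate_genic_context(make_peak(insertion_point=10_050), [g]) == INTRAGENIC

    def test_tss_window_boundaries(self):
        g = gene("g1", 10_000, 20_000, strand="+")
        assert annotate_genic_context(make_peak(insertion_point=10_000 - 499), [g]) == INTRAGENIC
        assert annotate_genic_context(make_peak(insertion_point=10_000 - 500), [g]) == INTRAGENIC
        assert annotate_genic_context(make_peak(insertion_point=10_000 - 501), [g]) == INTERGENIC

    def test_utr3_window_minus_strand(self):
        g = gene("g1", 10_000, 20_000, strand="-")
        # 3'UTR end of a minus-strand gene is its span start
        assert annotate_genic_context(make_peak(insertion_point=9_600), [g]) == INTRAGENIC

    def test_empty_gene_set_intergenic(self):
        peak = make_peak()
        assert annotate_genic_context(peak, []) == INTERGENIC
        assert peak.gene_id is None

    def test_nearest_gene_tie_lexicographic(self):
        a = gene("geneB", 10_000, 11_000)
        b = gene("geneA", 12_000, 13_000)
        peak = make_peak(insertion_point=11_500)  # 500 from both
        annotate_genic_context(peak, [a, b])
        assert peak.gene_id == "geneA"


class TestPeakReport:
    def test_report_roundtrip(self, tmp_path):
        peaks = [
            make_peak(catalog_class=NOVEL, genic_context=INTRAGENIC, gene_id="g1"),
            make_peak(
                interval=GenomicInterval("chrS", 5000, 5100, "-"),
                insertion_point=5100,
                catalog_class=KR,
                genic_context=INTERGENIC,
            ),
        ]
        path = str(tmp_path / "peaks.tsv")
        write_peak_report(peaks, path)
        back = read_peak_report(path, pool_id="all")
        assert len(back) == 2
        for orig, rec in zip(peaks, back):
            assert rec.interval == orig.interval
            assert rec.insertion_point == orig.insertion_point
            assert rec.catalog_class == orig.catalog_class
            assert rec.genic_context == orig.genic_context
            assert rec.total_reads == orig.total_reads
            assert rec.mean_mapq == pytest.approx(orig.mean_mapq)
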