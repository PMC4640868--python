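import numpy as np
import pytest
from hypothesis import given, strategies as st

from triotarget import (
    InputError,
    annotate_peaks,
    extract_peak_windows,
    load_gene_models,
    load_peaks,
    motif_enrichment,
    scan_motif,
    tss_distance_profile,
)
from triotarget.cistrome import GeneModel, Peak, reverse_complement


def make_peak(chrom, start, end, rank=1, score=10.0, summit=None):
    return Peak(chrom, start, end, score, rank, summit)


def gene(gid, chrom, tss, strand="+"):
    if strand == "+":
        return GeneModel(gid, chrom, strand, tss, tss, tss + 1000)
    return GeneModel(gid, chrom, strand, tss, tss - 999, tss + 1)


class TestLoadPeaks:
    def test_round_trip_and_rank_ties(self, tmp_path):
        p = tmp_path / "peaks.bed"
        p.write_text(
            "chr2\t100\t200\tp1\t9\nchr1\t500\t700\tp2\t7\nchr1\t100\t300\tp3\t7\n"
        )
        peaks = load_peaks(p)
        assert [(pk.chrom, pk.start, pk.end) for pk in peaks] == [
            ("chr2", 100, 200), ("chr1", 500, 700), ("chr1", 100, 300)]
        # equal scores tie-broken by (chrom, start): chr1:100 before chr1:500
        assert [pk.rank for pk in peaks] == [1, 3, 2]

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(InputError, match="bad.bed:1"):
            load_peaks(p)


class TestGeneModels:
    def test_bed_and_gtf_agree_on_tss(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t600\tfwd\t0\t+\nchr1\t1000\t1500\trev\t0\t-\n")
        gtf = tmp_path / "genes.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t600\t.\t+\t.\tgene_id "fwd";\n'
            'chr1\tsrc\tgene\t1001\t1500\t.\t-\t.\tgene_id "rev";\n'
        )
        for models in (load_gene_models(bed), load_gene_models(gtf)):
            by_id = {g.gene: g for g in models}
            assert by_id["fwd"].tss == 100
            assert by_id["rev"].tss == 1499  # last base of the half-open span


class TestAnnotation:
    def test_nearest_tss_chosen(self):
        genes = [gene("far", "chr1", 80_000), gene("near", "chr1", 60_000)]
        peak = make_peak("chr1", 49_900, 50_100)  # midpoint 50 kb
        result = annotate_peaks([peak], genes)
        (ann,) = result.annotations
        assert ann.gene == "near"
        assert ann.distance == -10_000  # peak upstream of + strand TSS
        assert result.gene_best_rank == {"near": 1}

    def test_outside_window_unassigned(self):
        genes = [gene("g", "chr1", 200_000)]
        result = annotate_peaks([make_peak("chr1", 49_900, 50_100)], genes, window=100_000)
        assert result.annotations[0].gene is None

    def test_minus_strand_distance_is_strand_oriented(self):
        genes = [gene("g", "chr1", 50_000, strand="-")]
        # midpoint 10 kb to the right of a minus-strand TSS = 10 kb upstream
        result = annotate_peaks([make_peak("chr1", 59_900, 60_100)], genes)
        assert result.annotations[0].distance == -10_000

    def test_matches_brute_force_on_random_layouts(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            genes = [gene(f"g{i:02d}", "chr1", int(rng.integers(0, 500_000)),
                          "+" if rng.random() < 0.5 else "-")
                     for i in range(rng.integers(1, 20))]
            starts = rng.integers(0, 500_000, rng.integers(1, 20))
            peaks = [make_peak("chr1", int(s), int(s) + 200, rank=r + 1)
                     for r, s in enumerate(starts)]
            window = 60_000
            result = annotate_peaks(peaks, genes, window=window)
            for ann in result.annotations:
                ref = (ann.peak.start + ann.peak.end) // 2
                dists = sorted((abs(g.tss - ref), g.gene) for g in genes)
                best_d, best_g = dists[0]
                if best_d > window:
                    assert ann.gene is None
                else:
                    assert ann.gene == best_g
                    assert abs(ann.distance) == best_d

    def test_shrinking_window_never_adds_assignments(self):
        rng = np.random.default_rng(7)
        genes = [gene(f"g{i}", "chr1", int(rng.integers(0, 300_000))) for i in range(10)]
        peaks = [make_peak("chr1", int(s), int(s) + 100, rank=i + 1)
                 for i, s in enumerate(rng.integers(0, 300_000, 15))]
        counts = [len(annotate_peaks(peaks, genes, window=w).assigned)
                  for w in (100_000, 30_000, 5_000)]
        assert counts == sorted(counts, reverse=True)


class TestDistanceProfile:
    def test_enumerated_bins(self):
        genes = [gene("g", "chr1", 10_000)]
        peaks = [make_peak("chr1", 9_400, 9_600, 1), make_peak("chr1", 10_400, 10_600, 2),
                 make_peak("chr1", 11_400, 11_600, 3)]
        result = annotate_peaks(peaks, genes)
        hist = tss_distance_profile(result.annotations, 1000)
        assert hist == {-1000: 1, 0: 1, 1000: 1}
        assert sum(hist.values()) == len(result.assigned)

    def test_unassigned_peaks_not_counted(self):
        result = annotate_peaks([make_peak("chrX", 0, 100)], [gene("g", "chr1", 0)])
        assert tss_distance_profile(result.annotations, 500) == {}

    def test_invalid_bin_width(self):
        with pytest.raises(InputError):
            tss_distance_profile([], 0)


class TestWindows:
    def write_fasta(self, tmp_path, contigs):
        p = tmp_path / "genome.fa"
        p.write_text("".join(f">{name}\n{seq}\n" for name, seq in contigs.items()))
        return p

    def test_window_clipped_at_contig_ends(self, tmp_path):
        seq = "ACGT" * 25  # 100 bp contig
        fasta = self.write_fasta(tmp_path, {"chr1": seq})
        genes = [gene("g", "chr1", 50)]
        result = annotate_peaks([make_peak("chr1", 40, 60)], genes, window=1000)
        windows = extract_peak_windows(result.annotations, fasta, width=100)
        assert windows == [("chr1:0-100|rank1", seq)]

    def test_content_matches_direct_slice(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 5000))
        fasta = self.write_fasta(tmp_path, {"chr1": seq})
        genes = [gene("g", "chr1", 2500)]
        result = annotate_peaks([make_peak("chr1", 2400, 2601)], genes)
        ((_, window),) = extract_peak_windows(result.annotations, fasta, width=100)
        assert window == seq[2450:2550]

    def test_missing_chromosome_named(self, tmp_path):
        fasta = self.write_fasta(tmp_path, {"chr1": "ACGT" * 30})
        genes = [gene("g", "chr9", 50)]
        result = annotate_peaks([make_peak("chr9", 40, 60)], genes)
        with pytest.raises(InputError, match="chr9"):
            extract_peak_windows(result.annotations, fasta)

    def test_top_limits_selection_by_rank(self, tmp_path):
        fasta = self.write_fasta(tmp_path, {"chr1": "A" * 2000})
        genes = [gene("g", "chr1", 1000)]
        peaks = [make_peak("chr1", 100 * i, 100 * i + 50, rank=i) for i in range(1, 6)]
        result = annotate_peaks(peaks, genes)
        windows = extract_peak_windows(result.annotations, fasta, width=50, top=2)
        assert [w[0].split("rank")[1] for w in windows] == ["1", "2"]


class TestMotifScan:
    def test_plus_strand_hit(self):
        hits, counts = scan_motif([("s", "AACACTCAA")], "CACTY", both_strands=False)
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(2, "+", "CACTC")]
        assert counts == {"s": 1}

    def test_no_hit(self):
        hits, counts = scan_motif([("s", "GGGGG")], "CACTY")
        assert hits == [] and counts == {"s": 0}

    def test_minus_strand_offset_convention(self):
        hits, _ = scan_motif([("s", "GAGTG")], "CACTY")
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(0, "-", "CACTC")]

    def test_overlapping_matches_all_reported(self):
        hits, counts = scan_motif([("s", "CACTCACTC")], "CACTY", both_strands=False)
        assert [h.offset for h in hits] == [0, 4]

    def test_invalid_iupac_code_rejected(self):
        with pytest.raises(InputError, match="IUPAC"):
            scan_motif([("s", "ACGT")], "CAXTY")

    @given(st.text(alphabet="ACGT", min_size=0, max_size=60))
    def test_scan_commutes_with_reverse_complement(self, seq):
        fwd, _ = scan_motif([("s", seq)], "CHCTY")
        rev, _ = scan_motif([("s", reverse_complement(seq))], "CHCTY")
        flipped = sorted((len(seq) - h.offset - 5, {"+": "-", "-": "+"}[h.strand]) for h in fwd)
        assert flipped == sorted((h.offset, h.strand) for h in rev)


class TestMotifEnrichment:
    def test_absent_pattern_gives_zero_fold(self):
        fold, p = motif_enrichment([("s", "GGGGGGGGGG")], "CACTY", n_shuffles=20, seed=0)
        assert fold == 0.0
        assert p == pytest.approx(1.0)

    def test_motif_rich_sequences_enriched_over_shuffles(self):
        seqs = [("s%d" % i, "CACTC" * 10) for i in range(5)]
        fold, p = motif_enrichment(seqs, "CACTY", n_shuffles=50, seed=1)
        _, counts = scan_motif(seqs, "CACTY")
        assert sum(counts.values()) >= 50  # direct-count oracle: 10 tandem sites each
        assert fold > 1.0
        assert p >= 1.0 / 51.0  # formula lower bound

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            motif_enrichment([], "CACTY", n_shuffles=5, seed=0)
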