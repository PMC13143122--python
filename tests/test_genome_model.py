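"""Interval algebra, windows, coverage, random sampling and I/O round-trips."""

import numpy as np
import pytest
from scipy import stats

import paraloci as pl
from paraloci.genome_model import (
    read_bed_tes,
    read_gff3_genes,
    revcomp,
    write_bed_tes,
    write_gff3_genes,
)

from conftest import brute_force_coverage


def _te(contig, start, end, family="fam", orient="+"):
    return pl.TEAnnotation(pl.GenomicInterval(contig, start, end), family, "e", orient)


def _gene(contig="c", start=60_000, end=62_000, strand="+"):
    iv = pl.GenomicInterval(contig, start, end, strand)
    return pl.GeneModel("g1", iv, strand, (iv,))


class TestTypes:
    def test_interval_invariants(self):
        with pytest.raises(ValueError):
            pl.GenomicInterval("c", 10, 10)
        with pytest.raises(ValueError):
            pl.GenomicInterval("c", -1, 5)
        assert pl.GenomicInterval("c", 2, 7).width == 5

    def test_contig_sequence_must_match_length(self):
        with pytest.raises(ValueError):
            pl.Contig("c", 5, "ACGT")
        with pytest.raises(ValueError):
            pl.Contig("c", 4, "ACGX")

    def test_gene_exons_sorted_and_contained(self):
        iv = pl.GenomicInterval("c", 0, 1000, "+")
        e2 = pl.GenomicInterval("c", 500, 600, "+")
        e1 = pl.GenomicInterval("c", 100, 200, "+")
        g = pl.GeneModel("g", iv, "+", (e2, e1))
        assert [e.start for e in g.exons] == [100, 500]
        with pytest.raises(ValueError):
            pl.GeneModel("g", iv, "+", (pl.GenomicInterval("c", 900, 1100, "+"),))

    def test_windowspec_divisibility(self):
        with pytest.raises(ValueError):
            pl.WindowSpec(width_bp=100_000, bin_bp=3_000)


class TestExpandToWindow:
    def test_gene_span_pad(self):
        contig = pl.Contig("c", 1_000_000)
        w, clipped = pl.expand_to_window(_gene(), pl.WindowSpec(), contig)
        assert (w.start, w.end) == (10_000, 112_000) and not clipped

    def test_clipping_at_contig_start(self):
        contig = pl.Contig("c", 1_000_000)
        w, clipped = pl.expand_to_window(
            _gene(start=10_000, end=12_000), pl.WindowSpec(), contig
        )
        assert (w.start, w.end) == (0, 62_000) and clipped

    def test_fixed_center(self):
        contig = pl.Contig("c", 1_000_000)
        w, clipped = pl.expand_to_window(
            _gene(start=499_000, end=501_000),
            pl.WindowSpec(mode="fixed_center"),
            contig,
        )
        assert (w.start, w.end) == (450_000, 550_000) and not clipped

    def test_wrong_contig_errors(self):
        with pytest.raises(ValueError):
            pl.expand_to_window(_gene(), pl.WindowSpec(), pl.Contig("other", 10**6))


class TestCoverageFraction:
    def test_half_covered(self):
        w = pl.GenomicInterval("c", 0, 100)
        assert pl.coverage_fraction(w, [_te("c", 0, 50)]) == 0.5

    def test_overlapping_tes_merge_to_full(self):
        w = pl.GenomicInterval("c", 0, 100)
        assert pl.coverage_fraction(w, [_te("c", 0, 60), _te("c", 40, 100)]) == 1.0

    def test_other_contig_ignored(self):
        w = pl.GenomicInterval("c", 0, 100)
        assert pl.coverage_fraction(w, [_te("d", 0, 100)]) == 0.0

    def test_matches_per_base_oracle_on_random_instances(self, rng):
        for _ in range(200):
            width = int(rng.integers(100, 10_000))
            start = int(rng.integers(0, 5_000))
            w = pl.GenomicInterval("c", start, start + width)
            tes = []
            for _ in range(int(rng.integers(0, 50))):
                s = int(rng.integers(0, 15_000))
                e = s + int(rng.integers(1, 800))
                tes.append(_te("c", s, e))
            assert pl.coverage_fraction(w, tes) == pytest.approx(
                brute_force_coverage(w, tes), abs=1e-12
            )

    def test_invariant_to_order_and_splitting(self, rng):
        w = pl.GenomicInterval("c", 0, 10_000)
        tes = [_te("c", int(s), int(s) + 300) for s in rng.integers(0, 9_700, size=20)]
        base = pl.coverage_fraction(w, tes)
        shuffled = list(tes)
        rng.shuffle(shuffled)
        assert pl.coverage_fraction(w, shuffled) == base
        split = []
        for te in tes:  # split each element into two abutting pieces
            mid = (te.interval.start + te.interval.end) // 2
            split.append(_te("c", te.interval.start, mid))
            split.append(_te("c", mid, te.interval.end))
        assert pl.coverage_fraction(w, split) == base


class TestBinnedCoverage:
    def test_bin_count(self):
        w = pl.GenomicInterval("c", 0, 100_000)
        vals = pl.binned_coverage(w, _gene(start=49_000, end=51_000), [], pl.WindowSpec())
        assert len(vals) == 100

    def test_strand_flip_symmetry_is_exact(self, rng):
        spec = pl.WindowSpec(width_bp=20_000)
        w = pl.GenomicInterval("c", 0, 20_000)
        tes = [_te("c", int(s), int(s) + int(l))
               for s, l in zip(rng.integers(0, 19_000, 30), rng.integers(50, 900, 30))]
        mirror = [_te("c", 20_000 - t.interval.end, 20_000 - t.interval.start) for t in tes]
        plus = pl.binned_coverage(w, _gene(start=9_000, end=11_000, strand="+"), tes, spec)
        minus = pl.binned_coverage(w, _gene(start=9_000, end=11_000, strand="-"), mirror, spec)
        assert np.array_equal(plus, minus)

    def test_each_bin_equals_independent_coverage(self, rng):
        spec = pl.WindowSpec(width_bp=10_000, bin_bp=500)
        w = pl.GenomicInterval("c", 5_000, 15_000)
        tes = [_te("c", int(s), int(s) + 200) for s in rng.integers(0, 15_000, 40)]
        vals = pl.binned_coverage(w, _gene(start=9_000, end=11_000), tes, spec)
        for i, v in enumerate(vals):
            b = pl.GenomicInterval("c", 5_000 + i * 500, 5_000 + (i + 1) * 500)
            assert v == pytest.approx(pl.coverage_fraction(b, tes), abs=1e-12)

    def test_bin_sum_equals_window_coverage(self, rng):
        spec = pl.WindowSpec(width_bp=10_000, bin_bp=1_000)
        w = pl.GenomicInterval("c", 0, 10_000)
        tes = [_te("c", int(s), int(s) + 400) for s in rng.integers(0, 9_600, 25)]
        vals = pl.binned_coverage(w, _gene(start=4_000, end=6_000), tes, spec)
        assert vals.sum() * spec.bin_bp == pytest.approx(
            pl.coverage_fraction(w, tes) * w.width, abs=1e-9
        )

    def test_indivisible_width_errors(self):
        w = pl.GenomicInterval("c", 0, 1_500)
        with pytest.raises(ValueError):
            pl.binned_coverage(w, _gene(start=500, end=700), [], pl.WindowSpec())


class TestSampleRandomWindows:
    def test_forced_single_position(self):
        wins = pl.sample_random_windows([pl.Contig("c", 5_000)], 5_000, 10, seed=0)
        assert all((w.start, w.end) == (0, 5_000) for w in wins)

    def test_n_zero(self):
        assert pl.sample_random_windows([pl.Contig("c", 10_000)], 1_000, 0, seed=0) == []

    def test_no_eligible_contig_errors(self):
        with pytest.raises(ValueError, match="width"):
            pl.sample_random_windows([pl.Contig("c", 500)], 1_000, 1, seed=0)

    def test_seed_reproducibility(self):
        contigs = [pl.Contig("a", 50_000), pl.Contig("b", 80_000)]
        w1 = pl.sample_random_windows(contigs, 2_000, 50, seed=7)
        w2 = pl.sample_random_windows(contigs, 2_000, 50, seed=7)
        assert w1 == w2
        assert w1 != pl.sample_random_windows(contigs, 2_000, 50, seed=8)

    def test_contig_choice_proportional_to_eligible_positions(self):
        l1, l2, w = 30_000, 90_000, 1_000
        contigs = [pl.Contig("a", l1), pl.Contig("b", l2)]
        wins = pl.sample_random_windows(contigs, w, 10_000, seed=3)
        n_a = sum(win.contig_id == "a" for win in wins)
        p = (l1 - w + 1) / ((l1 - w + 1) + (l2 - w + 1))
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, p)
        assert lo <= n_a <= hi

    def test_start_positions_uniform(self):
        contigs = [pl.Contig("a", 21_000)]
        wins = pl.sample_random_windows(contigs, 1_000, 10_000, seed=5)
        starts = np.array([w.start for w in wins])
        counts, _ = np.histogram(starts, bins=20, range=(0, 20_001))
        assert stats.chisquare(counts).pvalue > 0.01


class TestIO:
    def test_gff3_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "genes.gff3"
        write_gff3_genes(path, small_dataset.genes)
        back = read_gff3_genes(str(path))
        orig = sorted(small_dataset.genes, key=lambda g: g.id)
        back = sorted(back, key=lambda g: g.id)
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert (a.id, a.strand, a.interval.start, a.interval.end) == (
                b.id, b.strand, b.interval.start, b.interval.end)
            assert [(e.start, e.end) for e in a.exons] == [(e.start, e.end) for e in b.exons]

    def test_te_bed_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "tes.bed"
        write_bed_tes(path, small_dataset.tes)
        back = read_bed_tes(str(path))
        assert len(back) == len(small_dataset.tes)
        orig = sorted((t.interval.contig_id, t.interval.start, t.interval.end, t.family)
                      for t in small_dataset.tes)
        got = sorted((t.interval.contig_id, t.interval.start, t.interval.end, t.family)
                     for t in back)
        assert got == orig

    def test_fasta_round_trip(self, tmp_path, small_dataset):
        from paraloci.genome_model import read_fasta, write_fasta

        path = tmp_path / "genome.fa"
        write_fasta(path, small_dataset.contigs)
        back = {c.id: c for c in read_fasta(str(path))}
        for c in small_dataset.contigs:
            assert back[c.id].sequence == c.sequence

    def test_revcomp(self):
        assert revcomp("ACGTN") == "NACGT"
        assert revcomp(revcomp("GATTACA")) == "GATTACA"

    def test_bed12_genes(self, tmp_path):
        from paraloci.genome_model import read_bed12_genes

        path = tmp_path / "genes.bed"
        path.write_text(
            "c1\t1000\t5000\tgA\t0\t+\t1000\t5000\t0\t3\t200,300,150\t0,1500,3850\n"
            "c1\t9000\t12000\tgB\t0\t-\t9000\t12000\t0\t2\t400,200\t0,2800\n"
        )
        genes = {g.id: g for g in read_bed12_genes(str(path))}
        assert [(e.start, e.end) for e in genes["gA"].exons] == [
            (1000, 1200), (2500, 2800), (4850, 5000)]
        assert genes["gB"].strand == "-"
        assert genes["gB"].exons_5to3[0].start == 11800  # first exon 5'->3'

    def test_gff3_tes_with_family_attribute(self, tmp_path):
        from paraloci.genome_model import read_gff3_tes

        path = tmp_path / "tes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "c1\tEDTA\trepeat_region\t101\t600\t.\t+\t.\t"
            "ID=TE_1;Classification=CACTA_TIR\n"
            "c1\tEDTA\trepeat_region\t901\t1200\t.\t-\t.\t"
            "ID=TE_2;Classification=LTR_Gypsy\n"
        )
        tes = read_gff3_tes(str(path))
        assert [(t.interval.start, t.interval.end) for t in tes] == [(100, 600), (900, 1200)]
        assert [t.family for t in tes] == ["CACTA_TIR", "LTR_Gypsy"]
        assert [t.orientation for t in tes] == ["+", "-"]


class TestCoverageProperties:
    """Hypothesis property: coverage is exact and invariant to representation."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    intervals = st.lists(
        st.tuples(st.integers(0, 9_000), st.integers(1, 2_000)),
        min_size=0, max_size=40,
    )

    @given(tes=intervals, win_start=st.integers(0, 4_000), width=st.integers(1, 6_000))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_coverage_equals_oracle_and_is_order_free(self, tes, win_start, width):
        w = pl.GenomicInterval("c", win_start, win_start + width)
        annots = [_te("c", s, s + l) for s, l in tes]
        got = pl.coverage_fraction(w, annots)
        assert got == pytest.approx(brute_force_coverage(w, annots), abs=1e-12)
        assert pl.coverage_fraction(w, annots[::-1]) == got
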