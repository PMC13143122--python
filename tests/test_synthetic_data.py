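"""Generator ground truth: determinism, densities, spacing, lesions, TEs."""

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats

import paraloci as pl
from paraloci.synthetic_data import Lesion, _apply_lesions, make_reference_gene


class TestConfigValidation:
    def test_lesion_spec_length_mismatch(self):
        with pytest.raises(ValueError, match="lesion_spec"):
            pl.SimConfig(n_pseudogenes=2, lesion_spec=((Lesion("exon_deletion", 2),),))

    def test_frameshift_length_must_not_be_multiple_of_3(self):
        with pytest.raises(ValueError):
            Lesion("frameshift_indel", 2, detail=3)
        with pytest.raises(ValueError):
            Lesion("frameshift_indel", 2, detail=0)

    def test_bad_weights(self):
        with pytest.raises(ValueError):
            pl.SimConfig(te_family_mix={"a": 0.0})

    def test_contig_too_short_for_cluster(self):
        cfg = pl.SimConfig(seed=0, contig_lengths=(200_000,), n_genes=8,
                           n_pseudogenes=0, genes_per_cluster=8,
                           generate_sequence=False)
        with pytest.raises(ValueError, match="too short"):
            pl.simulate_genome(cfg)


class TestDeterminism:
    def test_same_seed_byte_identical_files(self, tmp_path):
        cfg = pl.SimConfig(seed=4, contig_lengths=(400_000,), n_genes=2,
                           n_pseudogenes=1, genes_per_cluster=3,
                           background_te_density=0.2, placement_margin_bp=30_000)
        a = tmp_path / "a"
        b = tmp_path / "b"
        pl.simulate_genome(cfg).write(str(a))
        pl.simulate_genome(cfg).write(str(b))
        for name in ("genome.fa", "genes.gff3", "tes.bed", "proteins.faa",
                     "truth.tsv", "truth.json"):
            assert (a / name).read_bytes() == (b / name).read_bytes(), name


class TestGenomeStructure:
    def test_zero_density_emits_no_tes(self):
        cfg = pl.SimConfig(seed=1, contig_lengths=(300_000,), n_genes=1,
                           n_pseudogenes=0, background_te_density=0.0,
                           signature_te=None, generate_sequence=False,
                           placement_margin_bp=30_000)
        assert pl.simulate_genome(cfg).tes == []

    def test_truth_table_lists_every_planted_locus(self, small_dataset):
        truth = small_dataset.truth.loci
        assert len(truth) == 6
        assert (truth.label == "gene").sum() == 3
        assert (truth.label == "pseudogene").sum() == 3
        assert truth.feature_id.is_unique

    def test_annotations_internally_consistent(self, small_dataset):
        clen = {c.id: c.length for c in small_dataset.contigs}
        for g in small_dataset.genes:
            assert 0 <= g.interval.start < g.interval.end <= clen[g.interval.contig_id]
            for e in g.exons:
                assert g.interval.start <= e.start < e.end <= g.interval.end
        for te in small_dataset.tes:
            iv = te.interval
            assert 0 <= iv.start < iv.end <= clen[iv.contig_id]

    def test_realized_background_density_within_10pct(self):
        cfg = pl.SimConfig(seed=6, contig_lengths=(2_000_000,), n_genes=0,
                           n_pseudogenes=0, background_te_density=0.43,
                           signature_te=None, generate_sequence=False)
        real = pl.simulate_genome(cfg).truth.realized["background_coverage"]
        assert abs(real - 0.43) / 0.43 < 0.10

    def test_focal_enrichment_15x_regime(self):
        # mirrors the observed 0.65-vs-0.43 regime: factor 1.5 on background 0.43
        focals = []
        for i in range(20):
            cfg = pl.SimConfig(seed=40_000 + i, contig_lengths=(5_000_000,),
                               n_genes=10, n_pseudogenes=0, genes_per_cluster=5,
                               focal_enrichment_factor=1.5, background_te_density=0.43,
                               signature_te=None, generate_sequence=False)
            focals.append(pl.simulate_genome(cfg).truth.realized["focal_coverage"])
        assert np.mean(focals) == pytest.approx(0.645, abs=0.02)


class TestGeneFamily:
    def test_zero_divergence_copies_identical_to_reference(self):
        cfg = pl.SimConfig(seed=2, contig_lengths=(600_000,), n_genes=3,
                           n_pseudogenes=0, genes_per_cluster=3, divergence=0.0,
                           background_te_density=0.0, signature_te=None)
        ds = pl.simulate_genome(cfg)
        contig = {c.id: c for c in ds.contigs}
        ref_exons = ds.reference.exon_seqs
        for g in ds.genes:
            seqs = []
            for e in g.exons_5to3:
                s = contig[g.interval.contig_id].sequence[e.start:e.end]
                seqs.append(s if g.strand == "+" else pl.genome_model.revcomp(s))
            assert tuple(seqs) == ref_exons

    def test_gene_copies_translate_cleanly_at_divergence(self):
        cfg = pl.SimConfig(seed=3, contig_lengths=(600_000,), n_genes=4,
                           n_pseudogenes=0, genes_per_cluster=4, divergence=0.05,
                           background_te_density=0.0, signature_te=None)
        ds = pl.simulate_genome(cfg)
        ref_len = len(ds.reference.protein)
        for pid, aa in ds.proteins.items():
            assert len(aa) == ref_len - 1  # stored without terminal stop
            assert aa.startswith("M") and "*" not in aa

    def test_spacing_statistics(self):
        cfg = pl.SimConfig(seed=5, contig_lengths=(3_000_000,) * 2, n_genes=20,
                           n_pseudogenes=0, genes_per_cluster=10,
                           paralog_spacing_bp=(23_000, 1_000), generate_sequence=False)
        ds = pl.simulate_genome(cfg)
        spacings = []
        for cid in ds.truth.loci.cluster_id.unique():
            sub = ds.truth.loci[ds.truth.loci.cluster_id == cid].sort_values("start")
            centers = ((sub.start + sub.end) / 2).values
            spacings.extend(np.diff(centers))
        assert np.mean(spacings) == pytest.approx(23_000, abs=1_000)
        assert min(spacings) >= 1_000


@pytest.fixture(scope="module")
def ref():
    return make_reference_gene(np.random.default_rng(0))


class TestLesions:
    def test_frameshift_breaks_conceptual_translation(self, ref):
        rng = np.random.default_rng(1)
        exons, kinds = _apply_lesions(
            list(ref.exon_seqs), (Lesion("frameshift_indel", 3, -1),), rng, ref
        )
        assert kinds == ["frameshift_indel"]
        cds = "".join(e for e in exons if e is not None)
        assert len(cds) == len(ref.cds) - 1
        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
        assert "*" in aa[:-1] or not aa.endswith("*")

    def test_nonsense_plants_inframe_stop(self, ref):
        rng = np.random.default_rng(1)
        exons, _ = _apply_lesions(
            list(ref.exon_seqs), (Lesion("nonsense_substitution", 2),), rng, ref
        )
        cds = "".join(exons)
        assert len(cds) == len(ref.cds)  # substitution only
        aa = str(Seq(cds).translate())
        assert "*" in aa[:-1]
        assert len(aa) == len(ref.protein)

    def test_exon_deletion_drops_exon(self, ref):
        rng = np.random.default_rng(1)
        exons, _ = _apply_lesions(
            list(ref.exon_seqs), (Lesion("exon_deletion", 4),), rng, ref
        )
        assert exons[3] is None and all(e is not None for i, e in enumerate(exons) if i != 3)


class TestTEPlanting:
    def test_signature_antisense_probability_one(self, small_dataset):
        sig = small_dataset.truth.signature_tes
        genes = {g.id: g for g in small_dataset.genes}
        assert len(sig) == 6
        for row in sig.itertuples(index=False):
            assert row.antisense
            assert row.orientation != genes[row.gene_id].strand

    def test_single_family_mix(self):
        cfg = pl.SimConfig(seed=8, contig_lengths=(1_000_000,), n_genes=0,
                           n_pseudogenes=0, te_family_mix={"solo": 1.0},
                           signature_te=None, generate_sequence=False)
        ds = pl.simulate_genome(cfg)
        assert ds.tes and all(te.family == "solo" for te in ds.tes)

    def test_family_mix_frequencies_within_multinomial_ci(self):
        mix = {"A": 0.5, "B": 0.3, "C": 0.2}
        cfg = pl.SimConfig(seed=9, contig_lengths=(10_000_000,), n_genes=0,
                           n_pseudogenes=0, te_family_mix=mix, signature_te=None,
                           generate_sequence=False)
        ds = pl.simulate_genome(cfg)
        counts = {}
        for te in ds.tes:
            counts[te.family] = counts.get(te.family, 0) + 1
        n = sum(counts.values())
        assert n > 5_000
        for fam, p in mix.items():
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= counts[fam] <= hi, fam


class TestProteinPanel:
    def test_labels_verified_against_scanner(self):
        from paraloci.motif_classifier import builtin_motifs, classify_ids_family

        panel = pl.make_protein_panel(n_per_class=5, seed=3)
        assert len(panel) == 15
        motifs = builtin_motifs()
        for pid, seq, label in panel:
            assert classify_ids_family(seq, motifs).call == label
            assert len(seq) >= 150

    def test_noise_degrades_detection_monotonically(self):
        from paraloci.motif_classifier import DDXXD, scan_motif

        rates = []
        for noise in (0.0, 0.05, 0.1, 0.2):
            panel = pl.make_protein_panel(n_per_class=15, seed=6, noise=noise)
            canon = [s for _, s, lab in panel if lab == "canonical"]
            rates.append(np.mean([bool(scan_motif(s, DDXXD)) for s in canon]))
        assert rates[0] == 1.0
        assert all(a >= b for a, b in zip(rates, rates[1:]))
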