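# paraloci

Analysis of expanded gene families in transposable-element-rich genomes:
locus discovery and gene/pseudogene classification for a focal multi-copy
family, permutation-based TE co-localization enrichment with binned
meta-locus profiles and TE-family composition, and motif-based
classification of isoprenyl diphosphate synthase (IDS) proteins into
canonical versus divergent clades — with a synthetic-genome simulator that
provides exact ground truth for every stage.

## The problem

Tandem gene-family expansions — such as the GGPPS-like IDS family that
underlies terpene biosynthesis in higher termites — leave a characteristic
genomic footprint: a cluster of highly similar paralogs, a mix of intact
genes and pseudogenes broken by frameshifts, nonsense mutations or exon
loss, and an unusually dense transposable-element (TE) neighbourhood.
Quantifying that footprint needs three things done carefully:

1. **Finding and classifying family copies.** Candidate loci are found by
   scanning each reference exon against both strands of the assembly
   (Smith–Waterman, match +1 / mismatch −1 / gap open −2 / gap extend −1,
   behind a fast banded-edit-distance prefilter); hits with identity ≥ 80 %
   are chained into loci containing ≥ 2 consecutive exon-like regions. Each
   locus is then a **gene** iff all six reference exons are present, no exon
   carries a net frame-shifting indel, and the spliced conceptual
   translation runs to its terminal stop with no premature stop — otherwise
   a **pseudogene**, with the violated rules as machine-readable reasons.

2. **Testing TE enrichment.** The mean TE density (base-pair coverage
   fraction of the merged TE union) over windows around the family loci
   (gene span ± 50 kb) is compared against the mean over sets of random
   100 kb windows in `n` permutations; the empirical p-value is plus-one
   corrected, `p = (1 + #{null ≥ obs}) / (n + 1)`. Strand-oriented 1 kb
   binned profiles around gene centres expose *satellite peaks* at the
   inter-paralog spacing, and TE-family composition is compared between the
   focal windows and the whole genome.

3. **Classifying the proteins.** IDS proteins carry two aspartate-rich
   DDxxD motifs (FARM and SARM) plus a set of insect-GGPPS motifs (IGMs).
   Proteins with FARM, SARM and all IGMs are **canonical**; proteins
   retaining only FARM and IGM3 with other IGMs lost are **divergent-like**
   (the conservation pattern of the divergent termite clade); anything else
   is **indeterminate**. Motif definitions can be trained from aligned
   panels by per-column residue frequency thresholds, and sequence-logo
   matrices (frequencies + information content) are computed for motif
   instances.

A small extra utility computes enantiomer ratios from chiral-chromatography
peak areas, `area_R / (area_R + area_S)`, and compares groups with a
two-tailed Welch t test.

See `docs/methods.md` for the full model description, parameter defaults,
and known limitations.

## Worked example

```python
import numpy as np
import paraloci as pl

cfg = pl.SimConfig(seed=1)          # defaults: 15 genes + 13 pseudogenes in
ds = pl.simulate_genome(cfg)        # ~23 kb tandem clusters, TE background
                                    # coverage 0.43, 1.5x enrichment at loci

calls = pl.annotate_genome(ds.contigs, list(ds.reference.exon_seqs))
n_genes = sum(c.classification == "gene" for c in calls)
print(f"{len(calls)} family loci: {n_genes} genes, {len(calls) - n_genes} pseudogenes")

windows, _ = pl.focal_windows_for_genes(ds.genes, ds.contigs, pl.WindowSpec())
res = pl.permutation_test(windows, ds.tes, ds.contigs, n_perm=1000, seed=1)
print(f"focal TE density {res.observed_mean:.3f} = "
      f"{res.percent_of_null:.0f}% of the permutation null "
      f"({np.mean(res.null_means):.3f}), p = {res.empirical_p:.2g}")
```

prints

```
28 family loci: 15 genes, 13 pseudogenes
focal TE density 0.686 = 149% of the permutation null (0.460), p = 0.001
```

— every planted copy is recovered with its planted label, and the planted
1.5× TE enrichment is estimated at 149 % of the null with the smallest
p-value 1,000 permutations can produce (1/1001). The null mean (0.460) sits
slightly above the 0.43 background because on a 9 Mb toy genome the enriched
focal regions occupy a noticeable fraction of the random-window space.

The enantiomer utility:

```python
from paraloci import EnantiomerAssay, enantiomer_ratio_test
assay = EnantiomerAssay({"wild_type": [(65, 35), (64, 36), (66, 34)],
                         "mutant":    [(91, 9), (90, 10), (92, 8)]})
t = enantiomer_ratio_test(assay)
print(f"R-enantiomer: wild type {t['groups']['wild_type']['mean_ratio_percent']:.0f}%, "
      f"mutant {t['groups']['mutant']['mean_ratio_percent']:.0f}%, "
      f"Welch t = {t['t_statistic']:.1f}, p = {t['p_value']:.2g}")
# R-enantiomer: wild type 65%, mutant 91%, Welch t = -31.8, p = 5.8e-06
```

## Command line

The same stages are exposed as subcommands of a single executable:

```bash
paraloci simulate --config sim.yaml --seed 1 --out simdir/
paraloci annotate --genome genome.fa --ref-cds ref_exons.fa --out calls.tsv
paraloci enrich --genes genes.gff3 --tes tes.bed --genome genome.fa \
         --n-perm 1000 --seed 1 --out enrich.json
paraloci classify --proteins proteins.faa --out motif_calls.tsv
paraloci run --config pipeline.yaml --seed 1 --out outdir/
paraloci stats-enantiomer --areas areas.tsv
```

`run` chains annotate → enrich → classify over real input files or a
simulated dataset and writes a single `report.json` (stable schema, explicit
nulls for skipped analyses) plus per-stage TSVs; re-running the same config
and seed reproduces the report byte for byte.

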