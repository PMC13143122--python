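# Methods

`paraloci` analyses the genomic neighbourhood of an expanded multi-copy gene
family — the motivating case is the GGPPS-like isoprenyl diphosphate synthase
(IDS) family of higher termites, which expanded into a tandem array of genes
and pseudogenes embedded in a transposable-element (TE) rich landscape. The
package has four analysis stages plus a synthetic-genome generator that
provides ground truth for all of them.

## Coordinates and interval algebra

All coordinates are 0-based half-open internally. GFF3 is converted at the
I/O boundary (1-based inclusive); BED is read and written natively. Gene
models carry an ordered, non-overlapping exon chain; `exons_5to3` orders
exons in transcriptional direction.

**TE density** is defined as the base-pair coverage fraction of the *merged*
union of TE annotations within a window. Merging overlapping and nested
elements before measuring means no base is counted twice regardless of how
the annotation track was produced (EDTA/RepeatMasker-style annotators emit
heavily nested calls). An element-count mode (midpoint elements per kb) is
available on `coverage_fraction(mode="count")` but is never the default.
Coverage queries run on a prefix-summed merged index
(`TECoverageIndex`), so permutation tests cost O(log n) per window.

Runs of `N` are not masked by default — windows and null positions treat
them like any other base; callers that need masking can pre-filter the
contig list.

## Windows

Two window modes exist:

* `gene_span_pad` (default; pad 50 kb per side) — the window used for the
  focal-family density measurements. Window width therefore exceeds the
  nominal 100 kb by the gene-span length (a few kb for six-exon loci);
  realized widths are reported alongside results.
* `fixed_center` (width 100 kb) — a window centred on the gene-span
  midpoint; used for the null windows and the meta-locus profile, where
  all loci must share a common bin grid.

Windows clipped at contig edges are kept and their true width is the
coverage denominator; the profile stage is the one exception (below).

## Permutation enrichment test

The observed statistic is the unweighted mean TE coverage over the focal
windows. Each of `n_perm` (default 1,000) permutations draws the same
*number* of windows of fixed width (default 100 kb), uniformly over all
eligible start positions pooled across contigs (a contig is chosen with
probability proportional to `length − width + 1`), and records the mean
coverage of the drawn set. The null statistic is a mean over a window *set*
of matching cardinality — the comparison is mean-vs-mean, not
window-vs-window. The empirical p-value is plus-one corrected,

    p = (1 + #{null_mean >= observed_mean}) / (n_perm + 1),

one-sided for enrichment by default (`alternative="two-sided"` doubles the
smaller tail). `fold` is observed mean over the mean of null means;
`percent_of_null` is `fold × 100`.

**Independence caveat.** The null resamples *independent* windows. When
focal loci sit in tight tandem clusters, their padded windows overlap
heavily and the observed mean is built from positively correlated values;
under no enrichment its distribution is then wider than the null's, and the
p-value is not uniform. This is a property of the statistic (shared with any
window-resampling null) and applies equally to real clustered families; the
calibration test therefore uses dispersed single-gene loci, and results on
clustered families should be read as enrichment of the *locus neighbourhood*
rather than of independent windows.

## Meta-locus density profile and satellite peaks

For each focal gene a `fixed_center` window is cut into 1 kb bins whose
order follows the gene's transcriptional direction (minus-strand genes are
reversed, so bin index increases 5′→3′; unstranded genes are treated as
plus-strand with a warning). The profile is the per-bin mean over loci.
Genes whose fixed window would be clipped at a contig edge are skipped with
a warning — a clipped window cannot be aligned to the common bin grid.

Peak detection is deliberately simple and fully declared: the profile is
smoothed with a moving average (`smoothing_bins`, default 3) and local
maxima exceeding `mean + peak_z × sd` of the smoothed profile (default
`peak_z = 2`) are reported with signed offsets from the gene centre
(negative = upstream). In tandem families, neighbouring paralogs carry their
own TE-dense surroundings, so the profile shows *satellite peaks* at the
inter-paralog spacing (±23 kb in the motivating family).

For wide TE blankets (the enriched region around each locus spans several
kb) the satellite is a plateau rather than a spike; the satellite-recovery
analysis therefore uses a wider smoothing window (9 bins) and a lower
threshold (`peak_z = 1`), which centres the detected maximum on the plateau.
Both values are exposed parameters, not defaults.

TE-family representation counts *elements* (midpoint containment) inside the
focal windows versus genome-wide and normalises each universe to frequencies;
it never mixes with the base-pair coverage measure. No per-family test is
run by default — the output is descriptive, mirroring how family composition
is usually reported.

## Locus discovery (exon-homology scan)

Each reference exon is searched against both strands of every contig in two
stages:

1. **Prefilter** — banded edit-distance infix search (edlib, `HW` mode)
   for the full exon at `k = 0.30 × L` and for each exon half at
   `k = 0.30 × L/2`, with iterative masking so multiple hits per contig are
   found. For random nucleotide sequence the best infix edit distance sits
   near `0.44 × L`, so the prefilter almost never fires on background.
2. **Smith–Waterman refinement** — local alignment (match +1, mismatch −1,
   gap open −2, gap extend −1) inside each candidate region; a hit is
   reported when identity ≥ 0.80 and aligned length ≥ 50 % of the exon.
   Identity is defined as matches / aligned columns *including gaps* — the
   denominator must be pinned for the 0.80 threshold to be meaningful.
   Within a region, non-overlapping hits are extracted best-first with
   masking.

Sensitivity envelope: full-length and end-truncated copies down to ~50 % of
the exon length are reachable through the half-exon prefilter; a truncated
remnant that straddles the exon midpoint at well under full length can fall
below the prefilter's edit-distance budget and be missed. At the divergence
levels the family analyses target (≤ 15 % per base) this envelope is not
binding.

Hits are chained into candidate loci when they share a strand, their exon
indices ascend in gene orientation (descend genomically for minus-strand
chains), and consecutive hits are ≤ 20 kb apart (`max_gap_bp`, matching the
multi-kb intron scale of the family's loci). A chain qualifies as a locus iff
it contains at least `min_consecutive = 2` hits with consecutive exon
indices. An index repeat or reset starts a new chain, so tandem neighbours
and chimeric duplicates are reported separately, never merged.

## Gene/pseudogene classification

A locus is classified from four integrity rules; it is a gene iff none fire:

* `missing_exon` — any of the six reference exons lacks a qualifying hit;
* `frameshift_indel` — the aligned segment of any exon differs from the
  reference exon length by a non-multiple of 3 (net per exon, so
  compensating indels within one exon restore the frame and do not fire);
* `premature_stop` — conceptual translation of the spliced candidate CDS
  (hit segments concatenated in exon order, gene orientation) contains a
  stop before its final codon;
* `no_terminal_stop` — the translation does not end in a stop.

**Frame assessment.** Per-exon segments are *not* taken from the discovery
alignment. Instead each exon is re-examined in a padded region around its
hit with two safeguards. First, a parsimony rule: the best ungapped
placement of the reference exon is preferred (substitutions only, net indel
0) unless a glocal alignment — full exon against an infix of the region,
free end gaps on the region side — scores more than 2 points better.
Second, that glocal aligner uses heavier gap penalties (open −4, extend −2)
than the discovery scan: under these scores an isolated spurious gap at a
mutated exon edge (rescued by coincidental flank agreement) is strictly
unprofitable, while a genuine internal indel still wins by the margin of the
entire rescued downstream register. Without these safeguards, roughly 1 % of
intact copies at 5 % divergence acquire phantom 1-bp indels from co-optimal
alignment ambiguity. The residual blind spot is an indel within the last
base or two of an exon, which is mathematically indistinguishable from a
substitution at that position; such damage still surfaces through the
translation checks when it matters.

In-frame indels do not, by themselves, mark a locus as a pseudogene: the
integrity rules target frame- and stop-disrupting lesions, and an intact
reading frame with one residue more or less is reported as a gene.

## Motif classification

Motif definitions are ordered per-column residue classes (a column may be a
wildcard). A definition can be trained from an aligned panel: per column the
allowed class is the set of residues at frequency ≥ `min_residue_freq`
(default 0.05 — admits rare-but-real residues while excluding singleton
noise in panels of ≥ 20 sequences) among non-gap characters; a column whose
allowed class equals all observed residues with ≥ 15 distinct residues
becomes a wildcard; a gap-majority column inside a motif is an error.

The aspartate-rich motifs share the DDxxD consensus; the scanner reports all
matches and FARM/SARM are disambiguated by a declared convention: FARM is
the first DDxxD-class hit, SARM the next hit starting at least 80 residues
downstream of the FARM start (the FARM–SARM separation in IDS enzymes is
well above this). "Disrupted" aspartate-rich motifs are operationalised as
fewer than two intact DDxxD hits.

Family calls from the motif complement: **canonical** iff FARM, SARM and all
insect-GGPPS motifs (IGMs) are present; **divergent_like** iff FARM and IGM3
are present and at least one other IGM is absent (the conservation pattern
of the divergent termite clade); **indeterminate** otherwise. The full
status map is always reported so callers can apply other rules. The built-in
IGM definitions are synthetic placeholder consensus classes — real analyses
should train IGMs from their own alignment boundaries, which are a published
convention the package takes as input rather than rederiving.

The phylogeny inclusion filter keeps exactly the sequences with ≥ 150
residues and both FARM and SARM. Logo matrices report per-column residue
frequencies and information content `log2(20) − H` in bits.

## Synthetic data generator

The generator emulates the inputs of the genomic analyses with exact ground
truth:

* **Background sequence** — i.i.d. nucleotides at configurable GC (default
  0.38). No repeat landscape beyond the planted TEs, no mutational
  heterogeneity: sufficient contrast for the statistics under test.
* **Reference gene** — six coding exons (default lengths 190/160/205/175/
  140/150 bp, CDS 1,020 bp = 340 codons, ATG…TAA), introns 400–900 bp.
* **Paralogs** — planted in tandem clusters (default 5 copies per cluster)
  with centre-to-centre spacing drawn from Normal(23,000, 1,000) bp
  truncated at ≥ 1 kb, random strand per copy. Exons diverge by per-base
  substitution (default 0.02); copies labelled *gene* are rejected and
  resampled until the CDS still translates cleanly, so truth labels are
  exact. Introns are re-randomised per copy except 10 bp of conserved
  splice-boundary context, giving the homology scan realistic exon/intron
  contrast. Pseudogene copies carry exactly their configured lesions:
  frameshift indel (length not divisible by 3, planted mid-exon), nonsense
  substitution (an in-frame TAA), or whole-exon deletion.
* **TE track** — annotations laid *over* the sequence (no insertion), so
  planted exons are never disrupted and the field is spatially homogeneous.
  Element lengths are log-normal (median 500 bp, σ = 0.7). Placement
  intensity is solved from the target *merged coverage*: for a Poisson
  segment field, coverage = 1 − exp(−λ·E[len]), so λ = −ln(1 − c)/E[len].
  Inside focal regions (gene span ± `focal_pad_bp`) the intensity is solved
  for `focal_enrichment_factor × background` coverage — the enrichment
  factor acts on the coverage scale, matching how fold-enrichment is
  reported (0.645 ≈ 1.5 × 0.43), not linearly on intensity (coverage is
  concave in intensity, so a 1.5× intensity would realize only ≈1.33×
  coverage at this density). With factor 1 the field is placed in a single
  homogeneous stream. An optional *signature element* (default a 2 kb
  CACTA-family TIR) is planted once per locus at a fixed offset downstream
  of the last exon, antisense to the gene with configurable probability —
  emulating the recurrent antisense element observed next to the motivating
  family's terminal exons.
* **Protein panel** — labelled canonical / divergent-like / indeterminate
  proteins assembled from motif consensus strings with random linkers;
  construction is verified against the scanner (and scrambled segments
  re-verified not to match), so labels are exact at zero noise.

Determinism: one `numpy` generator seeded from `SimConfig.seed` drives
everything; identical configs give byte-identical output files.

What the generator does **not** model — and hence what passing tests do not
show about real data: phylogenetic sequence evolution (no codon models, no
indel evolution along a tree, divergence is star-shaped from one reference),
real repeat landscapes and nested TE sequence, GC/chromatin covariates of TE
insertion, splice-site evolution, and assembly artefacts. The statistics are
validated for their own correctness and calibration, not for robustness to
those confounders.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
genomes of 1–12 Mb, 5–500 planted loci, 200–1,000 permutations, 50–200
simulation replicates. The study-condition run behind the headline numbers
simulates 28 loci (15 genes + 13 pseudogenes) in clusters of five on six
1.5 Mb contigs at background coverage 0.43 and focal factor 1.5 — at that
genome size the focal regions occupy ~13 % of the genome, so random null
windows partially overlap them and the realized percent-of-null lands a few
points under the asymptotic 150 %.

## Enantiomer-ratio statistic

For chiral assays, each replicate's ratio is `area_R / (area_R + area_S)`;
group means are reported as percentages and compared with a two-sample
two-tailed t test — Welch's unequal-variance form by default (the safer
default when nothing is known about the variances), pooled-variance
Student's t behind a flag. A replicate with both areas zero is an error
naming the replicate.

## Known limitations

* The permutation null assumes independent windows (see caveat above).
* No GC- or chromatin-matched null; no circular permutation of tracks.
* Exon-edge indels (last 1–2 bp) are resolved as substitutions.
* Built-in IGM definitions are placeholders; train real ones.
* The generator's TE field is annotation-only; analyses that need TE
  *sequence* (e.g. element dating) are out of scope.
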