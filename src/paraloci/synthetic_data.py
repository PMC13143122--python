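"""Synthetic genomes with planted paralog families and TE landscapes.

The generator emits a multi-contig genome carrying tandem clusters of a
six-exon focal gene family (intact copies plus pseudogenized copies with
known lesions), a transposable-element annotation track with a configurable
background coverage density and a focal enrichment factor around the family
loci, and the proteins of the intact copies — together with a truth table, so
every downstream stage (locus discovery, integrity classification, TE
enrichment, motif calls) can be validated against known ground truth.

Defaults mirror the regime the analyses are designed for: background TE
coverage 0.43 with 1.5x enrichment inside family windows (gene span +/-50 kb),
tandem paralogs spaced ~23 kb apart, six coding exons per copy, and lesions
drawn from {frameshift indel, nonsense substitution, exon loss}.

TE annotations are laid *over* the background sequence (no sequence is
inserted), so planted exons are never disrupted by a TE interval and the TE
field stays spatially homogeneous outside the configured focal enrichment.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_model import (
    Contig,
    GeneModel,
    GenomicInterval,
    TEAnnotation,
    revcomp,
    write_bed_tes,
    write_fasta,
    write_gff3_genes,
)

__all__ = [
    "Lesion",
    "SimConfig",
    "ReferenceGene",
    "TruthTable",
    "SimulatedDataset",
    "make_reference_gene",
    "simulate_genome",
    "make_protein_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}

LESION_KINDS = ("frameshift_indel", "nonsense_substitution", "exon_deletion")

#: the integrity-rule reason each planted lesion kind must trigger
LESION_EXPECTED_REASON = {
    "frameshift_indel": "frameshift_indel",
    "nonsense_substitution": "premature_stop",
    "exon_deletion": "missing_exon",
}


@dataclass(frozen=True)
class Lesion:
    """A pseudogenizing lesion planted into one exon of a family copy.

    ``detail`` is the indel length in bp for ``frameshift_indel`` (positive =
    insertion, negative = deletion, |detail| not divisible by 3) or the
    1-based codon position within the exon for ``nonsense_substitution``
    (None = middle codon); ignored for ``exon_deletion``.
    """

    kind: str
    exon_index: int  # 1-based among the reference exons
    detail: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in LESION_KINDS:
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.kind == "frameshift_indel":
            if self.detail is None or self.detail == 0 or abs(self.detail) % 3 == 0:
                raise ValueError("frameshift indel length must be nonzero and not divisible by 3")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset."""

    seed: int = 0
    contig_lengths: tuple[int, ...] = (1_500_000,) * 6
    gc_content: float = 0.38
    background_te_density: float = 0.43
    te_family_mix: dict = field(
        default_factory=lambda: {
            "CACTA_TIR": 0.25,
            "LTR_Gypsy": 0.20,
            "LINE_L2": 0.20,
            "hAT_TIR": 0.15,
            "Helitron": 0.10,
            "Mutator_TIR": 0.10,
        }
    )
    focal_enrichment_factor: float = 1.5
    focal_pad_bp: int = 50_000  # half-width of the enriched region around each copy
    n_genes: int = 15
    n_pseudogenes: int = 13
    lesion_spec: tuple[tuple[Lesion, ...], ...] | None = None  # one tuple per pseudogene
    paralog_spacing_bp: tuple[float, float] = (23_000.0, 1_000.0)  # mean, sd (center-to-center)
    genes_per_cluster: int = 5
    divergence: float = 0.02  # per-base substitution probability among paralogs
    te_length_median: float = 500.0
    te_length_sigma: float = 0.7
    signature_te: tuple[str, int, float] | None = ("CACTA_TIR", 500, 1.0)
    # (family, offset downstream of the last exon in bp, antisense probability)
    intron_length_range: tuple[int, int] = (400, 900)
    placement_margin_bp: int = 60_000  # keeps default 100 kb windows unclipped
    generate_sequence: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0,1]")
        if not 0.0 <= self.background_te_density < 1.0:
            raise ValueError("background_te_density must be in [0,1)")
        if self.focal_enrichment_factor < 0:
            raise ValueError("focal_enrichment_factor must be >= 0")
        if self.n_genes < 0 or self.n_pseudogenes < 0:
            raise ValueError("counts must be >= 0")
        weights = list(self.te_family_mix.values())
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("TE family weights must be >= 0 and not all zero")
        if self.genes_per_cluster < 1:
            raise ValueError("genes_per_cluster must be >= 1")
        if self.lesion_spec is not None and len(self.lesion_spec) != self.n_pseudogenes:
            raise ValueError(
                f"lesion_spec has {len(self.lesion_spec)} entries for "
                f"{self.n_pseudogenes} pseudogenes"
            )


@dataclass(frozen=True)
class ReferenceGene:
    """The intact six-exon reference model all paralogs are copied from."""

    exon_seqs: tuple[str, ...]
    intron_context: tuple[tuple[str, str], ...]  # conserved (donor, acceptor) 5 bp each

    @property
    def cds(self) -> str:
        return "".join(self.exon_seqs)

    @property
    def protein(self) -> str:
        from Bio.Seq import Seq

        return str(Seq(self.cds).translate())

    @property
    def n_exons(self) -> int:
        return len(self.exon_seqs)


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset."""

    loci: pd.DataFrame  # one row per planted family copy
    signature_tes: pd.DataFrame  # one row per planted signature element
    realized: dict  # realized background / focal coverage etc.

    def write(self, tsv_path: str, json_path: str) -> None:
        self.loci.to_csv(tsv_path, sep="\t", index=False)
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "realized": self.realized,
                    "signature_tes": self.signature_tes.to_dict(orient="records"),
                },
                fh, indent=2, sort_keys=True,
            )
            fh.write("\n")


@dataclass
class SimulatedDataset:
    config: SimConfig
    contigs: list[Contig]
    genes: list[GeneModel]
    tes: list[TEAnnotation]
    proteins: dict[str, str]
    reference: ReferenceGene
    truth: TruthTable

    def write(self, outdir: str) -> dict[str, str]:
        """Write FASTA/GFF3/BED/protein-FASTA/truth files; returns the paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "genes": os.path.join(outdir, "genes.gff3"),
            "tes": os.path.join(outdir, "tes.bed"),
            "proteins": os.path.join(outdir, "proteins.faa"),
            "truth_tsv": os.path.join(outdir, "truth.tsv"),
            "truth_json": os.path.join(outdir, "truth.json"),
        }
        if self.config.generate_sequence:
            write_fasta(paths["genome"], self.contigs)
        else:
            paths.pop("genome")
            # emit contig lengths so coordinate-only runs stay self-describing
            with open(os.path.join(outdir, "contigs.tsv"), "w") as fh:
                for c in self.contigs:
                    fh.write(f"{c.id}\t{c.length}\n")
        write_gff3_genes(paths["genes"], self.genes)
        write_bed_tes(paths["tes"], self.tes)
        with open(paths["proteins"], "w") as fh:
            for pid in sorted(self.proteins):
                fh.write(f">{pid}\n{self.proteins[pid]}\n")
        self.truth.write(paths["truth_tsv"], paths["truth_json"])
        return paths


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    if hit.any():
        # shift each hit base to one of the 3 other bases
        lut = np.zeros(256, dtype=np.int64)
        for i, b in enumerate(_BASES):
            lut[b] = i
        cur_idx = lut[arr[hit]]
        new_idx = (cur_idx + rng.integers(1, 4, size=hit.sum())) % 4
        arr[hit] = _BASES[new_idx]
    return arr.tobytes().decode()


def make_reference_gene(
    rng: np.random.Generator,
    exon_lengths: tuple[int, ...] = (190, 160, 205, 175, 140, 150),
    gc: float = 0.42,
) -> ReferenceGene:
    """Build a clean six-exon reference gene (ATG ... sense codons ... TAA)."""
    total = sum(exon_lengths)
    if total % 3 != 0:
        raise ValueError("exon lengths must sum to a multiple of 3")
    n_codons = total // 3
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    cds = "".join(codons)
    exon_seqs, pos = [], 0
    for L in exon_lengths:
        exon_seqs.append(cds[pos : pos + L])
        pos += L
    # conserved splice-boundary context: 5 bp donor + 5 bp acceptor per intron
    intron_context = tuple(
        ("GT" + _random_seq(rng, 3, gc), _random_seq(rng, 3, gc) + "AG")
        for _ in range(len(exon_lengths) - 1)
    )
    return ReferenceGene(tuple(exon_seqs), intron_context)


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate())


def _clean_orf(exon_seqs: list[str], ref: ReferenceGene) -> bool:
    aa = _translate("".join(exon_seqs))
    return (
        len(aa) == len(ref.protein)
        and aa.startswith("M")
        and aa.endswith("*")
        and "*" not in aa[:-1]
    )


# ---------------------------------------------------------------------------
# Planting the gene family
# ---------------------------------------------------------------------------


def _apply_lesions(
    exon_seqs: list[str], lesions: tuple[Lesion, ...], rng: np.random.Generator,
    ref: ReferenceGene,
) -> tuple[list[str | None], list[str]]:
    """Apply lesions; a deleted exon becomes None.  Returns (exons, kinds)."""
    out: list[str | None] = list(exon_seqs)
    kinds: list[str] = []
    # CDS offset of each exon start in the reference frame
    offsets = np.concatenate([[0], np.cumsum([len(e) for e in ref.exon_seqs])])
    for les in lesions:
        i = les.exon_index - 1
        if not 0 <= i < len(out):
            raise ValueError(f"lesion exon_index {les.exon_index} out of range")
        if out[i] is None:
            raise ValueError(f"exon {les.exon_index} already deleted")
        if les.kind == "exon_deletion":
            out[i] = None
        elif les.kind == "frameshift_indel":
            seq = out[i]
            pos = len(seq) // 2
            if les.detail > 0:
                ins = _random_seq(rng, les.detail, 0.5)
                out[i] = seq[:pos] + ins + seq[pos:]
            else:
                k = -les.detail
                if k >= len(seq):
                    raise ValueError("deletion longer than exon")
                out[i] = seq[:pos] + seq[pos + k :]
        else:  # nonsense_substitution
            seq = out[i]
            off = int(offsets[i])
            # codons fully inside this exon, in the reference frame
            first = math.ceil(off / 3)
            last = (off + len(seq)) // 3 - 1
            first = max(first, 1)  # never the start codon
            last = min(last, len(ref.protein) - 2)  # never the terminal stop
            if first > last:
                raise ValueError(f"exon {les.exon_index} has no internal codon")
            if les.detail is None:
                codon_idx = (first + last) // 2
            else:
                codon_idx = first + les.detail - 1
                if not first <= codon_idx <= last:
                    raise ValueError("nonsense codon position outside exon")
            p = codon_idx * 3 - off
            out[i] = seq[:p] + "TAA" + seq[p + 3 :]
        kinds.append(les.kind)
    return out, kinds


def _default_lesion_spec(n: int) -> tuple[tuple[Lesion, ...], ...]:
    """One lesion per pseudogene, cycling kind and target exon."""
    spec = []
    for k in range(n):
        kind = LESION_KINDS[k % 3]
        exon = 2 + (k % 4)  # exons 2..5
        detail = -1 if kind == "frameshift_indel" else None
        spec.append((Lesion(kind, exon, detail),))
    return tuple(spec)


def _build_copy_seq(
    exons: list[str | None],
    ref: ReferenceGene,
    rng: np.random.Generator,
    gc: float,
    intron_range: tuple[int, int],
) -> tuple[str, list[tuple[int, int]]]:
    """Assemble exons with fresh random introns (conserved 10 bp boundary
    context); returns (sequence, exon spans relative to the copy, 5'->3')."""
    parts: list[str] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    present = [(k, e) for k, e in enumerate(exons) if e is not None]
    for j, (k, exon_seq) in enumerate(present):
        parts.append(exon_seq)
        spans.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        if j < len(present) - 1:
            donor, acceptor = ref.intron_context[min(k, len(ref.intron_context) - 1)]
            ilen = int(rng.integers(intron_range[0], intron_range[1] + 1))
            intron = donor + _random_seq(rng, max(ilen - 10, 0), gc) + acceptor
            parts.append(intron)
            pos += len(intron)
    return "".join(parts), spans


def simulate_genome(config: SimConfig) -> SimulatedDataset:
    """Generate a full dataset (genome, genes, TEs, proteins, truth).

    Deterministic under ``config.seed``.  Raises when a contig cannot host
    the requested family clusters.
    """
    rng = np.random.default_rng(config.seed)
    ref = make_reference_gene(rng)
    n_total = config.n_genes + config.n_pseudogenes
    lesion_spec = (
        config.lesion_spec
        if config.lesion_spec is not None
        else _default_lesion_spec(config.n_pseudogenes)
    )

    # --- build the planted copies (sequence + class label) -----------------
    labels = ["gene"] * config.n_genes + ["pseudogene"] * config.n_pseudogenes
    copies = []  # (label, exon list possibly with None, lesion kinds)
    pseudo_i = 0
    for label in labels:
        if label == "gene":
            for _ in range(1000):
                exons = [_mutate(e, config.divergence, rng) for e in ref.exon_seqs]
                if _clean_orf(exons, ref):
                    break
            else:  # pragma: no cover - astronomically unlikely at sane divergence
                raise RuntimeError("could not generate a clean diverged gene copy")
            copies.append((label, exons, []))
        else:
            exons = [_mutate(e, config.divergence, rng) for e in ref.exon_seqs]
            lesioned, kinds = _apply_lesions(exons, lesion_spec[pseudo_i], rng, ref)
            copies.append((label, lesioned, kinds))
            pseudo_i += 1
    # interleave genes and pseudogenes deterministically across clusters
    order = rng.permutation(n_total)
    copies = [copies[i] for i in order]

    # --- realize copy sequences and lay out clusters ------------------------
    built = []
    for label, exons, kinds in copies:
        seq, spans = _build_copy_seq(
            exons, ref, rng, config.gc_content, config.intron_length_range
        )
        built.append((label, kinds, seq, spans))
    mean_sp, sd_sp = config.paralog_spacing_bp
    clusters = [
        built[i : i + config.genes_per_cluster]
        for i in range(0, n_total, config.genes_per_cluster)
    ]
    margin = config.placement_margin_bp

    # footprint of each cluster: spacings are center-to-center
    placements: list[tuple[int, int, int]] = []  # (contig index, copy index in built, start)
    contig_assign: list[list[int]] = [[] for _ in config.contig_lengths]
    for ci, _ in enumerate(clusters):
        contig_assign[ci % len(config.contig_lengths)].append(ci)

    gene_rows = []  # (id, contig_idx, start, strand, spans, label, kinds, seq)
    copy_counter = 0
    for tig_idx, cluster_ids in enumerate(contig_assign):
        L = config.contig_lengths[tig_idx]
        if not cluster_ids:
            continue
        usable = L - 2 * margin
        seg = usable // len(cluster_ids)
        for slot, ci in enumerate(cluster_ids):
            cluster = clusters[ci]
            spacings = []
            for _ in range(len(cluster) - 1):
                d = rng.normal(mean_sp, sd_sp)
                while d < 1000:
                    d = rng.normal(mean_sp, sd_sp)
                spacings.append(int(round(d)))
            footprint = sum(spacings) + max(len(c[2]) for c in cluster) + 2000
            if footprint > seg:
                raise ValueError(
                    f"contig {tig_idx} too short to host cluster {ci} "
                    f"(footprint {footprint} > segment {seg}); use longer contigs"
                )
            jitter = int(rng.integers(0, seg - footprint + 1))
            center = margin + slot * seg + jitter + len(cluster[0][2]) // 2
            for k, (label, kinds, seq, spans) in enumerate(cluster):
                strand = "+" if rng.random() < 0.5 else "-"
                start = center - len(seq) // 2
                cid = f"locus_{copy_counter:04d}"
                gene_rows.append(
                    (cid, tig_idx, start, strand, spans, label, kinds, seq, ci)
                )
                copy_counter += 1
                if k < len(cluster) - 1:
                    center += spacings[k]

    # --- genome sequences ----------------------------------------------------
    contig_names = [f"contig_{i:03d}" for i in range(len(config.contig_lengths))]
    contigs: list[Contig] = []
    if config.generate_sequence:
        for i, L in enumerate(config.contig_lengths):
            p = np.array(
                [(1 - config.gc_content) / 2, config.gc_content / 2,
                 config.gc_content / 2, (1 - config.gc_content) / 2]
            )
            arr = _BASES[rng.choice(4, size=L, p=p)].copy()
            for cid, tig_idx, start, strand, spans, label, kinds, seq, ci in gene_rows:
                if tig_idx != i:
                    continue
                placed = seq if strand == "+" else revcomp(seq)
                arr[start : start + len(seq)] = np.frombuffer(
                    placed.encode(), dtype=np.uint8
                )
            contigs.append(Contig(contig_names[i], L, arr.tobytes().decode()))
    else:
        contigs = [Contig(contig_names[i], L) for i, L in enumerate(config.contig_lengths)]

    # --- gene models, proteins, truth rows ----------------------------------
    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    truth_rows = []
    for cid, tig_idx, start, strand, spans, label, kinds, seq, ci in gene_rows:
        tig = contig_names[tig_idx]
        glen = len(seq)
        if strand == "+":
            exon_ivs = [
                GenomicInterval(tig, start + a, start + b, strand) for a, b in spans
            ]
        else:
            exon_ivs = [
                GenomicInterval(tig, start + glen - b, start + glen - a, strand)
                for a, b in spans
            ]
        gene = GeneModel(
            id=cid,
            interval=GenomicInterval(tig, start, start + glen, strand),
            strand=strand,
            exons=tuple(exon_ivs),
            family_label="focal",
        )
        genes.append(gene)
        if label == "gene":
            aa = _translate("".join(seq[a:b] for a, b in spans))
            proteins[cid] = aa.rstrip("*")
        truth_rows.append(
            {
                "feature_id": cid,
                "contig": tig,
                "start": start,
                "end": start + glen,
                "strand": strand,
                "label": label,
                "lesion_kinds": ",".join(kinds),
                "expected_reasons": ",".join(
                    sorted({LESION_EXPECTED_REASON[k] for k in kinds})
                ),
                "cluster_id": ci,
                "n_exons": len(spans),
            }
        )
    truth_loci = pd.DataFrame(truth_rows)

    # --- TE landscape --------------------------------------------------------
    tes, sig_rows, realized = _plant_tes(contigs, genes, config, rng)
    truth = TruthTable(
        loci=truth_loci,
        signature_tes=pd.DataFrame(
            sig_rows, columns=["element_id", "gene_id", "contig", "start", "end",
                               "family", "orientation", "antisense"],
        ),
        realized=realized,
    )
    return SimulatedDataset(config, contigs, genes, tes, proteins, ref, truth)


# ---------------------------------------------------------------------------
# TE planting
# ---------------------------------------------------------------------------


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not spans:
        return []
    spans = sorted(spans)
    out = [list(spans[0])]
    for s, e in spans[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _plant_tes(
    contigs: list[Contig],
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[list[TEAnnotation], list[dict], dict]:
    """Place TE annotations: homogeneous background plus focal enrichment.

    Element placement intensity is chosen so that the *expected merged
    coverage* equals ``background_te_density`` genome-wide and
    ``focal_enrichment_factor x background_te_density`` inside the focal
    regions (gene span +/- focal_pad_bp): merged coverage of a Poisson
    segment field is c = 1 - exp(-lambda * E[len]), so the intensity is
    solved from the target coverage rather than scaled linearly.
    """
    d = config.background_te_density
    f = config.focal_enrichment_factor
    mean_len = config.te_length_median * math.exp(config.te_length_sigma**2 / 2)
    families = sorted(config.te_family_mix)
    weights = np.array([config.te_family_mix[k] for k in families], dtype=float)
    weights = weights / weights.sum()

    def intensity(target_cov: float) -> float:
        target_cov = min(target_cov, 0.98)
        return -math.log(1.0 - target_cov) / mean_len if target_cov > 0 else 0.0

    lam_bg = intensity(d)
    lam_focal = intensity(min(f * d, 0.98)) if d > 0 else 0.0

    focal_by_contig: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}
    clen = {c.id: c.length for c in contigs}
    for g in genes:
        lo = max(0, g.interval.start - config.focal_pad_bp)
        hi = min(clen[g.interval.contig_id], g.interval.end + config.focal_pad_bp)
        focal_by_contig[g.interval.contig_id].append((lo, hi))
    focal_by_contig = {k: _merge_spans(v) for k, v in focal_by_contig.items()}

    tes: list[TEAnnotation] = []
    counter = 0

    def place(contig: Contig, lo: int, hi: int, lam: float) -> None:
        nonlocal counter
        n = int(round(lam * (hi - lo)))
        if n <= 0:
            return
        starts = rng.integers(lo, hi, size=n)
        lengths = np.maximum(
            50,
            rng.lognormal(math.log(config.te_length_median), config.te_length_sigma, size=n),
        ).astype(np.int64)
        fams = rng.choice(len(families), size=n, p=weights)
        orients = rng.choice(np.array(["+", "-"]), size=n)
        for s, L, fi, o in zip(starts, lengths, fams, orients):
            e = min(int(s) + int(L), contig.length)
            if e <= int(s):
                continue
            tes.append(
                TEAnnotation(
                    GenomicInterval(contig.id, int(s), e),
                    family=families[int(fi)],
                    element_id=f"TE_{counter:08d}",
                    orientation=str(o),
                )
            )
            counter += 1

    for contig in contigs:
        if d <= 0:
            break
        focal = focal_by_contig.get(contig.id, [])
        if abs(f - 1.0) < 1e-12 or not focal:
            place(contig, 0, contig.length, lam_bg)
            continue
        cursor = 0
        for lo, hi in focal:
            if lo > cursor:
                place(contig, cursor, lo, lam_bg)
            place(contig, lo, hi, lam_focal)
            cursor = hi
        if cursor < contig.length:
            place(contig, cursor, contig.length, lam_bg)

    # signature element near the last exon, antisense with given probability
    sig_rows: list[dict] = []
    if config.signature_te is not None:
        fam, offset, anti_p = config.signature_te
        sig_len = 2000
        for g in genes:
            last = g.exons_5to3[-1]
            if g.strand == "+":
                s = last.end + offset
            else:
                s = last.start - offset - sig_len
            s = max(0, min(s, clen[g.interval.contig_id] - sig_len))
            antisense = bool(rng.random() < anti_p)
            orient = ("-" if g.strand == "+" else "+") if antisense else g.strand
            eid = f"TE_{counter:08d}"
            counter += 1
            tes.append(
                TEAnnotation(
                    GenomicInterval(g.interval.contig_id, s, s + sig_len),
                    family=fam, element_id=eid, orientation=orient,
                )
            )
            sig_rows.append(
                {
                    "element_id": eid, "gene_id": g.id,
                    "contig": g.interval.contig_id, "start": s, "end": s + sig_len,
                    "family": fam, "orientation": orient, "antisense": antisense,
                }
            )

    # realized densities (coverage of merged union, background vs focal)
    from .genome_model import TECoverageIndex

    realized: dict = {"target_background": d, "target_focal": min(f * d, 0.98) if d else 0.0}
    if tes:
        index = TECoverageIndex(tes)
        tot_focal = tot_focal_cov = 0
        tot_bg = tot_bg_cov = 0
        for contig in contigs:
            focal = focal_by_contig.get(contig.id, [])
            cursor = 0
            for lo, hi in focal:
                tot_focal += hi - lo
                tot_focal_cov += index.covered_bases(contig.id, lo, hi)
                if lo > cursor:
                    tot_bg += lo - cursor
                    tot_bg_cov += index.covered_bases(contig.id, cursor, lo)
                cursor = hi
            if cursor < contig.length:
                tot_bg += contig.length - cursor
                tot_bg_cov += index.covered_bases(contig.id, cursor, contig.length)
        realized["background_coverage"] = tot_bg_cov / tot_bg if tot_bg else 0.0
        realized["focal_coverage"] = tot_focal_cov / tot_focal if tot_focal else 0.0
    else:
        realized["background_coverage"] = 0.0
        realized["focal_coverage"] = 0.0
    return tes, sig_rows, realized


# ---------------------------------------------------------------------------
# Protein panel for the motif classifier
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_protein_panel(
    motifs: dict | None = None,
    n_per_class: int = 20,
    seed: int = 0,
    linker_len: int = 14,
    noise: float = 0.0,
) -> list[tuple[str, str, str]]:
    """Build a labelled protein panel for motif-classification tests.

    Returns ``(id, sequence, true_label)`` triples with labels ``canonical``
    (FARM, SARM and all insect-GGPPS motifs present in canonical order),
    ``divergent_like`` (FARM and IGM3 intact, the other IGMs scrambled,
    SARM lost) and ``indeterminate`` (FARM scrambled).  Construction is
    verified against the scanner, so labels are exact at ``noise=0``;
    ``noise`` then applies per-residue substitutions *after* labelling.
    """
    from . import motif_classifier as mc

    motifs = dict(motifs) if motifs is not None else dict(mc.builtin_motifs())
    rng = np.random.default_rng(seed)
    order = ["IGM1", "IGM2", "FARM", "IGM3", "IGM4", "IGM5", "IGM6", "SARM"]
    missing = [k for k in order if k not in motifs]
    if missing:
        raise ValueError(f"panel needs motif definitions for {missing}")

    def consensus(name: str) -> str:
        return mc.motif_consensus(motifs[name], rng)

    def scrambled(name: str) -> str:
        """Same-length segment guaranteed not to match the motif."""
        width = len(motifs[name].column_classes)
        for _ in range(200):
            cand = "".join(rng.choice(list(_AA), size=width))
            if not mc.scan_motif(cand, motifs[name]):
                return cand
        raise RuntimeError(f"could not scramble motif {name}")

    def linker(n: int) -> str:
        return "".join(rng.choice(list(_AA), size=n))

    def build(parts_for: dict[str, str], label: str, idx: int) -> tuple[str, str, str]:
        for _ in range(200):
            segs = [linker(linker_len)]
            for name in order:
                segs.append(parts_for[name])
                segs.append(linker(linker_len))
            seq = "".join(segs)
            # pad to >= 150 aa so the phylogeny length filter is exercised
            if len(seq) < 160:
                seq += linker(160 - len(seq))
            call = mc.classify_ids_family(seq, motifs)
            if call.call == label:
                return (f"{label}_{idx:03d}", seq, label)
        raise RuntimeError(f"could not construct a clean {label} panel member")

    panel: list[tuple[str, str, str]] = []
    for i in range(n_per_class):
        canonical_parts = {name: consensus(name) for name in order}
        panel.append(build(canonical_parts, "canonical", i))
        divergent_parts = dict(canonical_parts)
        for name in ("IGM1", "IGM2", "IGM4", "IGM5", "IGM6", "SARM"):
            divergent_parts[name] = scrambled(name)
        panel.append(build(divergent_parts, "divergent_like", i))
        indet_parts = dict(canonical_parts)
        indet_parts["FARM"] = scrambled("FARM")
        indet_parts["SARM"] = scrambled("SARM")
        panel.append(build(indet_parts, "indeterminate", i))
    if noise > 0:
        noisy = []
        for pid, seq, label in panel:
            arr = list(seq)
            hit = rng.random(len(arr)) < noise
            for j in np.flatnonzero(hit):
                arr[j] = rng.choice(list(_AA))
            noisy.append((pid, "".join(arr), label))
        panel = noisy
    return panel
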