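"""Coordinate conventions, interval algebra, windows, and annotation I/O.

All coordinates are 0-based half-open internally.  GFF3 is read and written
as 1-based inclusive with conversion at the boundary; BED is native 0-based
half-open.  Everything downstream (simulation, enrichment, locus annotation)
builds on the types and operations defined here.

TE "density" throughout the package means the base-pair coverage fraction of
the merged union of TE annotations inside a window, not an element count
(an element-count mode is available on :func:`coverage_fraction`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Contig",
    "GenomicInterval",
    "GeneModel",
    "TEAnnotation",
    "WindowSpec",
    "TECoverageIndex",
    "expand_to_window",
    "coverage_fraction",
    "sample_random_windows",
    "binned_coverage",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bed12_genes",
    "read_gff3_tes",
    "read_bed_tes",
    "write_bed_tes",
    "write_bed6",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    """A sequence in the assembly; ``sequence`` may be omitted when only
    coordinates are analysed (e.g. enrichment statistics)."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"contig {self.id}: sequence length {len(self.sequence)} "
                    f"!= declared length {self.length}"
                )
            bad = set(self.sequence.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"contig {self.id}: invalid characters {sorted(bad)}")


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."  # '+', '-', or '.' (unstranded)

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.contig_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig_id == other.contig_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with an ordered exon chain.

    Exons are stored sorted by genomic start, pairwise non-overlapping and
    contained in ``interval``.  ``family_label`` distinguishes the focal
    family (e.g. the expanded GGPPS-like paralogs) from background genes.
    """

    id: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...]
    family_label: str = "focal"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if len(self.exons) < 1:
            raise ValueError(f"gene {self.id}: needs >= 1 exon")
        object.__setattr__(
            self, "exons", tuple(sorted(self.exons, key=lambda e: e.start))
        )
        prev_end = None
        for ex in self.exons:
            if ex.contig_id != self.interval.contig_id:
                raise ValueError(f"gene {self.id}: exon on wrong contig")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"gene {self.id}: exon outside gene interval")
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            prev_end = ex.end

    @property
    def exons_5to3(self) -> tuple[GenomicInterval, ...]:
        """Exons ordered in transcriptional direction."""
        return self.exons if self.strand == "+" else self.exons[::-1]


@dataclass(frozen=True)
class TEAnnotation:
    """A transposable-element interval with a family label."""

    interval: GenomicInterval
    family: str
    element_id: str = ""
    orientation: str = "."  # '+', '-', '.' (unknown)

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-", "."):
            raise ValueError(f"invalid orientation {self.orientation!r}")


@dataclass(frozen=True)
class WindowSpec:
    """How to build analysis windows around genes.

    ``gene_span_pad`` expands the gene span by ``pad_bp`` on each side
    (default 50 kb); ``fixed_center`` centers a ``width_bp`` window (default
    100 kb) on the gene midpoint.  ``bin_bp`` is the bin size for profiles.
    """

    mode: str = "gene_span_pad"
    pad_bp: int = 50_000
    width_bp: int = 100_000
    bin_bp: int = 1_000

    def __post_init__(self) -> None:
        if self.mode not in ("gene_span_pad", "fixed_center"):
            raise ValueError(f"unknown window mode {self.mode!r}")
        if min(self.pad_bp, self.width_bp, self.bin_bp) <= 0:
            raise ValueError("pad_bp, width_bp and bin_bp must be positive")
        if self.width_bp % self.bin_bp != 0:
            raise ValueError("width_bp must be divisible by bin_bp")


# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


def expand_to_window(
    gene: GeneModel, spec: WindowSpec, contig: Contig
) -> tuple[GenomicInterval, bool]:
    """Build the analysis window around a gene.

    Returns ``(window, clipped)``; ``clipped`` is True when the window was
    truncated at a contig edge.  Clipped windows are kept (their true width
    is used as the coverage denominator downstream).
    """
    if gene.interval.contig_id != contig.id:
        raise ValueError(
            f"gene {gene.id} is on {gene.interval.contig_id}, not {contig.id}"
        )
    if spec.mode == "gene_span_pad":
        lo = gene.interval.start - spec.pad_bp
        hi = gene.interval.end + spec.pad_bp
    else:  # fixed_center
        center = gene.interval.center
        lo = center - spec.width_bp // 2
        hi = lo + spec.width_bp
    clipped = lo < 0 or hi > contig.length
    lo = max(lo, 0)
    hi = min(hi, contig.length)
    return GenomicInterval(contig.id, lo, hi, gene.strand), clipped


# ---------------------------------------------------------------------------
# Coverage
# ---------------------------------------------------------------------------


class TECoverageIndex:
    """Merged, prefix-summed TE intervals for O(log n) coverage queries.

    Overlapping and nested annotations are merged per contig before any
    measurement, so no base is counted twice regardless of how the input
    track was produced.
    """

    def __init__(self, tes: list[TEAnnotation] | list[GenomicInterval]):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for te in tes:
            iv = te.interval if isinstance(te, TEAnnotation) else te
            by_contig.setdefault(iv.contig_id, []).append((iv.start, iv.end))
        self._merged: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for cid, pairs in by_contig.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            starts, ends = arr[:, 0], arr[:, 1]
            # merge overlapping/abutting-with-overlap intervals
            keep_start: list[int] = []
            keep_end: list[int] = []
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e:
                    cur_e = max(cur_e, int(e))
                else:
                    keep_start.append(cur_s)
                    keep_end.append(cur_e)
                    cur_s, cur_e = int(s), int(e)
            keep_start.append(cur_s)
            keep_end.append(cur_e)
            ms = np.array(keep_start, dtype=np.int64)
            me = np.array(keep_end, dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(me - ms)])
            self._merged[cid] = (ms, me, cum)

    def covered_bases(self, contig_id: str, start: int, end: int) -> int:
        """Number of bases in [start, end) covered by the merged TE union."""
        entry = self._merged.get(contig_id)
        if entry is None:
            return 0
        ms, me, cum = entry
        i = int(np.searchsorted(me, start, side="right"))
        j = int(np.searchsorted(ms, end, side="left"))
        if i >= j:
            return 0
        total = int(cum[j] - cum[i])
        total -= max(0, start - int(ms[i]))
        total -= max(0, int(me[j - 1]) - end)
        return total

    def covered_bases_many(self, contig_id: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`covered_bases` for many windows on one contig."""
        entry = self._merged.get(contig_id)
        if entry is None:
            return np.zeros(len(starts), dtype=np.int64)
        ms, me, cum = entry
        i = np.searchsorted(me, starts, side="right")
        j = np.searchsorted(ms, ends, side="left")
        total = cum[j] - cum[i]
        valid = i < j
        left_clip = np.where(valid, np.maximum(0, starts - ms[np.minimum(i, len(ms) - 1)]), 0)
        right_clip = np.where(valid, np.maximum(0, me[np.maximum(j - 1, 0)] - ends), 0)
        return np.where(valid, total - left_clip - right_clip, 0)


def coverage_fraction(
    window: GenomicInterval,
    tes: list[TEAnnotation] | TECoverageIndex,
    mode: str = "coverage",
) -> float:
    """Fraction of window bases covered by the merged TE union.

    ``mode='count'`` instead returns the number of TE elements whose midpoint
    falls in the window, divided by window width in kb (elements per kb) —
    provided for comparison, never the default.
    """
    if mode == "count":
        if isinstance(tes, TECoverageIndex):
            raise TypeError("count mode requires the raw TE list")
        n = sum(
            1
            for te in tes
            if te.interval.contig_id == window.contig_id
            and window.start <= (te.interval.start + te.interval.end) // 2 < window.end
        )
        return n / (window.width / 1000.0)
    index = tes if isinstance(tes, TECoverageIndex) else TECoverageIndex(tes)
    return index.covered_bases(window.contig_id, window.start, window.end) / window.width


def binned_coverage(
    window: GenomicInterval,
    gene: GeneModel,
    tes: list[TEAnnotation] | TECoverageIndex,
    spec: WindowSpec,
) -> np.ndarray:
    """Per-bin TE coverage fractions across a window, oriented 5'->3'.

    The window is cut into ``spec.bin_bp`` bins in genomic order; for a
    minus-strand gene the order is reversed so that bin index increases in
    the gene's transcriptional direction.  Unstranded genes are treated as
    plus strand with a warning.
    """
    if window.width % spec.bin_bp != 0:
        raise ValueError(
            f"window width {window.width} not divisible by bin size {spec.bin_bp}"
        )
    index = tes if isinstance(tes, TECoverageIndex) else TECoverageIndex(tes)
    n_bins = window.width // spec.bin_bp
    starts = window.start + np.arange(n_bins, dtype=np.int64) * spec.bin_bp
    ends = starts + spec.bin_bp
    covered = index.covered_bases_many(window.contig_id, starts, ends)
    vals = covered / float(spec.bin_bp)
    strand = gene.strand
    if strand not in ("+", "-"):
        warnings.warn(f"gene {gene.id} unstranded; orienting bins as plus strand")
        strand = "+"
    return vals[::-1].copy() if strand == "-" else vals


# ---------------------------------------------------------------------------
# Random window sampling
# ---------------------------------------------------------------------------


def sample_random_windows(
    contigs: list[Contig],
    width: int,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[GenomicInterval]:
    """Draw ``n`` windows of exactly ``width`` uniformly over the genome.

    A contig is eligible when ``length >= width``; start positions are
    uniform over all eligible positions pooled across contigs (each contig
    is chosen with probability proportional to ``length - width + 1``).
    Windows may overlap one another.  Deterministic under ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible = [c for c in contigs if c.length >= width]
    if not eligible:
        raise ValueError(f"no contig is long enough for window width {width}")
    if n == 0:
        return []
    n_pos = np.array([c.length - width + 1 for c in eligible], dtype=np.float64)
    probs = n_pos / n_pos.sum()
    idx = rng.choice(len(eligible), size=n, p=probs)
    out: list[GenomicInterval] = []
    for i in idx:
        c = eligible[int(i)]
        start = int(rng.integers(0, c.length - width + 1))
        out.append(GenomicInterval(c.id, start, start + width))
    return out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_fasta(path: str) -> list[Contig]:
    """Read a genome FASTA (indexed with pyfaidx) into Contig objects."""
    import pyfaidx

    fa = pyfaidx.Fasta(str(path), as_raw=True)
    return [Contig(name, len(fa[name]), str(fa[name][:]).upper()) for name in fa.keys()]


def write_fasta(path: str, contigs: list[Contig], line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            if c.sequence is None:
                raise ValueError(f"contig {c.id} has no sequence to write")
            fh.write(f">{c.id}\n")
            for i in range(0, c.length, line_width):
                fh.write(c.sequence[i : i + line_width] + "\n")


def read_gff3_genes(path: str, family_attribute: str = "family") -> list[GeneModel]:
    """Read gene models (gene/mRNA/exon hierarchy) from GFF3 via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = [
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(g, featuretype="exon")
        ]
        if not exons:  # allow exon-less records to mean single-exon genes
            exons = [GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)]
        fam = g.attributes.get(family_attribute, ["focal"])[0]
        genes.append(
            GeneModel(
                id=g.id,
                interval=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
                strand=g.strand,
                exons=tuple(exons),
                family_label=fam,
            )
        )
    return genes


def write_gff3_genes(path: str, genes: list[GeneModel]) -> None:
    """Write gene/mRNA/exon(+CDS) records; coordinates converted to 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.interval.contig_id, x.interval.start)):
            cid = g.interval.contig_id
            base = (
                f"{cid}\tparaloci\t{{ftype}}\t{{s}}\t{{e}}\t.\t{g.strand}\t.\t{{attrs}}\n"
            )
            fh.write(
                base.format(
                    ftype="gene", s=g.interval.start + 1, e=g.interval.end,
                    attrs=f"ID={g.id};family={g.family_label}",
                )
            )
            fh.write(
                base.format(
                    ftype="mRNA", s=g.interval.start + 1, e=g.interval.end,
                    attrs=f"ID={g.id}.t1;Parent={g.id}",
                )
            )
            for k, ex in enumerate(g.exons, start=1):
                fh.write(
                    base.format(
                        ftype="exon", s=ex.start + 1, e=ex.end,
                        attrs=f"ID={g.id}.exon{k};Parent={g.id}.t1",
                    )
                )
                fh.write(
                    base.format(
                        ftype="CDS", s=ex.start + 1, e=ex.end,
                        attrs=f"ID={g.id}.cds{k};Parent={g.id}.t1",
                    )
                )


def read_bed12_genes(path: str, family_label: str = "focal") -> list[GeneModel]:
    """Read gene models from BED12 (exons from the block definitions)."""
    names = ["chrom", "start", "end", "name", "score", "strand", "thickStart",
             "thickEnd", "itemRgb", "blockCount", "blockSizes", "blockStarts"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", names=names)
    genes: list[GeneModel] = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        exons = tuple(
            GenomicInterval(str(row.chrom), start + o, start + o + s, row.strand)
            for o, s in zip(offs, sizes)
        )
        genes.append(
            GeneModel(
                id=str(row.name),
                interval=GenomicInterval(str(row.chrom), start, int(row.end), row.strand),
                strand=str(row.strand),
                exons=exons,
                family_label=family_label,
            )
        )
    return genes


def read_gff3_tes(path: str, family_attribute: str = "Classification") -> list[TEAnnotation]:
    """Read a TE track from GFF3; the family label comes from
    ``family_attribute`` (falling back to the feature type)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[TEAnnotation] = []
    for i, feat in enumerate(db.all_features()):
        fam = feat.attributes.get(family_attribute, [feat.featuretype])[0]
        out.append(
            TEAnnotation(
                interval=GenomicInterval(feat.seqid, feat.start - 1, feat.end),
                family=str(fam),
                element_id=feat.id or f"TE_{i:08d}",
                orientation=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return out


def read_bed_tes(path: str) -> list[TEAnnotation]:
    """Read a TE track from BED6 (name = family label, strand = orientation)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        out.append(
            TEAnnotation(
                interval=GenomicInterval(str(row.chrom), int(row.start), int(row.end)),
                family=str(row.name),
                element_id=f"TE_{i:08d}",
                orientation=row.strand if row.strand in ("+", "-") else ".",
            )
        )
    return out


def write_bed_tes(path: str, tes: list[TEAnnotation]) -> None:
    with open(path, "w") as fh:
        for te in sorted(tes, key=lambda t: (t.interval.contig_id, t.interval.start)):
            iv = te.interval
            fh.write(
                f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{te.family}\t0\t"
                f"{te.orientation if te.orientation != '.' else '.'}\n"
            )


def write_bed6(path: str, intervals: list[GenomicInterval], names: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for k, iv in enumerate(intervals):
            name = names[k] if names else f"iv{k}"
            fh.write(f"{iv.contig_id}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")
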