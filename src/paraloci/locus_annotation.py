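"""Family-locus discovery and gene/pseudogene integrity classification.

Candidate loci are found by an exon-level homology scan: each reference exon
is aligned against both strands of every contig and local alignments with
identity >= 80% (over aligned columns, gaps included) and aligned length
>= 50% of the exon are reported.  Hits are chained into candidate loci when
they lie on one strand with exon indices ascending in gene orientation
within a configurable gap, and a chain qualifies when it contains at least
two hits with consecutive exon indices.  Each locus is then classified as
gene or pseudogene from integrity rules: all six reference exons present, no
frame-shifting indel, no premature stop, and an intact terminal stop.

The scan is a two-stage search: a banded edit-distance prefilter (edlib,
infix mode) bounds the candidate regions, and Smith-Waterman alignment
(match +1, mismatch -1, gap open -2, gap extend -1) inside each region
produces the reported hits, identities and coordinates.  The prefilter scans
the full exon and its two halves, so end-truncated copies down to about half
the exon length remain detectable; severely truncated copies whose remnant
straddles the exon midpoint may fall below the prefilter's reach.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import edlib
import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .genome_model import Contig, GenomicInterval, revcomp

__all__ = [
    "ExonHit",
    "CandidateLocus",
    "LocusCall",
    "scan_exon_homology",
    "select_candidate_loci",
    "classify_locus",
    "annotate_genome",
]

REASONS = ("missing_exon", "frameshift_indel", "premature_stop", "no_terminal_stop")


@dataclass(frozen=True)
class ExonHit:
    """A local-alignment hit of one reference exon on a contig."""

    ref_exon_index: int  # 1-based
    locus_interval: GenomicInterval  # forward-strand coordinates
    strand: str
    percent_identity: float  # matches / aligned columns (gaps included)
    aligned_columns: int
    score: float = 0.0


@dataclass(frozen=True)
class CandidateLocus:
    contig_id: str
    strand: str
    hits: tuple[ExonHit, ...]  # sorted by ref_exon_index
    span: GenomicInterval


@dataclass(frozen=True)
class LocusCall:
    locus_id: str
    span: GenomicInterval
    strand: str
    exon_hits: tuple[ExonHit, ...]
    classification: str  # gene | pseudogene
    reasons: tuple[str, ...]
    spliced_cds: str
    translation: str


# ---------------------------------------------------------------------------
# Alignment machinery
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _local_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


@lru_cache(maxsize=None)
def _glocal_aligner() -> Align.PairwiseAligner:
    """Full query (exon) against an infix of the target (region).

    Gap penalties here are deliberately heavier than in the discovery scan:
    with gap open -4 / extend -2 a gap can only win when it rescues more
    matches than any run of coincidental flank agreement can supply, so
    substitution noise at mutated exon edges never masquerades as an indel,
    while a genuine internal indel (which rescues the entire downstream
    register) still wins by a wide margin.
    """
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -4
    a.extend_gap_score = -2
    a.end_deletion_score = 0.0  # unaligned target flanks are free
    return a


def _alignment_stats(aln) -> tuple[int, int, int, int]:
    """(matches, columns, target_start, target_end) of a pairwise alignment."""
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return 0, 0, 0, 0
    target, query = aln.target, aln.query
    matches = 0
    block_len = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        block_len += te - ts
        seg_t = target[ts:te]
        seg_q = query[qs:qe]
        matches += sum(a == b for a, b in zip(seg_t, seg_q))
    t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
    q_start, q_end = int(q_blocks[0][0]), int(q_blocks[-1][1])
    columns = (t_end - t_start) + (q_end - q_start) - block_len
    return matches, columns, t_start, t_end


def _prefilter_regions(query: str, target: str, max_hits: int = 500) -> list[tuple[int, int]]:
    """Candidate regions via iterative edlib infix search with masking.

    Scans the full query at k = 0.30 * len and each half at k = 0.30 * len/2;
    the random-sequence noise floor for DNA sits near 0.44 * len, so the
    prefilter rarely fires on background.
    """
    queries = [query]
    if len(query) >= 100:
        mid = len(query) // 2
        queries += [query[:mid], query[mid:]]
    regions: list[tuple[int, int]] = []
    pad = len(query)
    buf = bytearray(target.encode())
    for q in queries:
        k = int(math.floor(0.30 * len(q)))
        qb = q.encode()
        for _ in range(max_hits):
            res = edlib.align(qb, bytes(buf), mode="HW", task="locations", k=k)
            if res["editDistance"] < 0:
                break
            for s, e in res["locations"]:
                regions.append((max(0, s - pad), min(len(target), e + 1 + pad)))
                buf[s : e + 1] = b"#" * (e + 1 - s)
    if not regions:
        return []
    regions.sort()
    merged = [list(regions[0])]
    for s, e in regions[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _sw_hits_in_region(
    region: str,
    exon_seq: str,
    min_identity: float,
    min_len_frac: float,
    max_iter: int = 50,
) -> list[tuple[int, int, float, int, float]]:
    """Non-overlapping qualifying SW hits inside a region, best first.

    Returns (start, end, identity, columns, score) in region coordinates.
    """
    aligner = _local_aligner()
    min_cols = min_len_frac * len(exon_seq)
    # lowest score a qualifying alignment can have (all non-matches mismatches)
    min_score = (2 * min_identity - 1) * min_cols
    buf = region
    out = []
    for _ in range(max_iter):
        alns = aligner.align(buf, exon_seq)
        if alns.score < min_score:
            break
        aln = alns[0]
        matches, columns, t_start, t_end = _alignment_stats(aln)
        if columns == 0 or t_end <= t_start:
            break
        identity = matches / columns
        if identity >= min_identity and columns >= min_cols:
            out.append((t_start, t_end, identity, columns, float(alns.score)))
        buf = buf[:t_start] + "#" * (t_end - t_start) + buf[t_end:]
    return out


def scan_exon_homology(
    contig: Contig | str,
    ref_exons: list[str],
    min_identity: float = 0.80,
    min_len_frac: float = 0.50,
) -> list[ExonHit]:
    """Scan one contig (both strands) for homologs of each reference exon.

    Hits are sorted by contig position.  A contig shorter than the shortest
    exon yields an empty result.
    """
    if isinstance(contig, Contig):
        if contig.sequence is None:
            raise ValueError(f"contig {contig.id} carries no sequence")
        seq, contig_id = contig.sequence, contig.id
    else:
        seq, contig_id = contig, "contig"
    for ex in ref_exons:
        if len(ex) < 20:
            raise ValueError("reference exons must be >= 20 bp")
    L = len(seq)
    hits: list[ExonHit] = []
    for strand, target in (("+", seq), ("-", revcomp(seq))):
        for idx, exon_seq in enumerate(ref_exons, start=1):
            if L < len(exon_seq):
                continue
            for rs, re_ in _prefilter_regions(exon_seq, target):
                region = target[rs:re_]
                for s, e, ident, cols, score in _sw_hits_in_region(
                    region, exon_seq, min_identity, min_len_frac
                ):
                    a, b = rs + s, rs + e
                    if strand == "-":
                        a, b = L - (rs + e), L - (rs + s)
                    hits.append(
                        ExonHit(
                            ref_exon_index=idx,
                            locus_interval=GenomicInterval(contig_id, a, b, strand),
                            strand=strand,
                            percent_identity=ident,
                            aligned_columns=cols,
                            score=score,
                        )
                    )
    hits.sort(key=lambda h: (h.locus_interval.start, h.locus_interval.end))
    return hits


# ---------------------------------------------------------------------------
# Chaining hits into candidate loci
# ---------------------------------------------------------------------------


def select_candidate_loci(
    hits: list[ExonHit],
    min_consecutive: int = 2,
    max_gap_bp: int = 20_000,
) -> list[CandidateLocus]:
    """Chain same-strand hits with exon indices ascending in gene orientation
    and inter-hit gaps <= ``max_gap_bp``; keep chains containing at least
    ``min_consecutive`` hits with consecutive exon indices.

    Index order resets (e.g. a fresh exon 1 after exon 6, or a repeated
    index) start a new chain, so tandem neighbors and chimeric duplicates are
    reported as separate loci rather than merged.
    """
    contigs = {h.locus_interval.contig_id for h in hits}
    if len(contigs) > 1:
        raise ValueError("hits must come from a single contig")
    loci: list[CandidateLocus] = []
    for strand in ("+", "-"):
        sh = sorted(
            (h for h in hits if h.strand == strand),
            key=lambda h: h.locus_interval.start,
        )
        if not sh:
            continue
        chains: list[list[ExonHit]] = [[sh[0]]]
        for h in sh[1:]:
            prev = chains[-1][-1]
            gap = h.locus_interval.start - prev.locus_interval.end
            ascending = (
                h.ref_exon_index > prev.ref_exon_index
                if strand == "+"
                else h.ref_exon_index < prev.ref_exon_index
            )
            if ascending and gap <= max_gap_bp:
                chains[-1].append(h)
            else:
                chains.append([h])
        for chain in chains:
            idxs = sorted(h.ref_exon_index for h in chain)
            run = best = 1
            for a, b in zip(idxs, idxs[1:]):
                run = run + 1 if b == a + 1 else 1
                best = max(best, run)
            if best >= min_consecutive:
                start = min(h.locus_interval.start for h in chain)
                end = max(h.locus_interval.end for h in chain)
                loci.append(
                    CandidateLocus(
                        contig_id=chain[0].locus_interval.contig_id,
                        strand=strand,
                        hits=tuple(sorted(chain, key=lambda h: h.ref_exon_index)),
                        span=GenomicInterval(
                            chain[0].locus_interval.contig_id, start, end, strand
                        ),
                    )
                )
    loci.sort(key=lambda l: l.span.start)
    return loci


# ---------------------------------------------------------------------------
# Integrity classification
# ---------------------------------------------------------------------------


def _extract_exon_segment(
    region: str, ref_exon: str, margin: float = 2.0
) -> tuple[str, int]:
    """Candidate-exon segment within a region, with its net indel length.

    Parsimony rule: the best *ungapped* placement of the reference exon is
    preferred (net indel 0, substitutions only) unless the gapped glocal
    alignment scores more than ``margin`` points better under the
    heavy-gap scoring of :func:`_glocal_aligner` — a genuine internal indel
    rescues the entire downstream register and wins by a wide margin, while
    substitution runs never do.  An indel in the last base or two of an exon
    is inherently indistinguishable from a substitution and resolves to the
    ungapped reading; planted or real frame damage elsewhere still surfaces
    through the translation check.
    """
    L = len(ref_exon)
    ref_arr = np.frombuffer(ref_exon.encode(), dtype=np.uint8)
    reg_arr = np.frombuffer(region.encode(), dtype=np.uint8)
    best_off, best_matches = 0, -1
    for off in range(len(region) - L + 1):
        m = int((reg_arr[off : off + L] == ref_arr).sum())
        if m > best_matches:
            best_off, best_matches = off, m
    score_ungapped = 2 * best_matches - L
    alns = _glocal_aligner().align(region, ref_exon)
    if alns.score <= score_ungapped + margin:
        return region[best_off : best_off + L], 0
    t_blocks, q_blocks = alns[0].aligned
    parts: list[str] = []
    net = 0
    if len(q_blocks) and q_blocks[0][0] > 0:  # rare unaligned query start
        parts.append(ref_exon[: q_blocks[0][0]])
    for i, ((ts, te), (qs, qe)) in enumerate(zip(t_blocks, q_blocks)):
        if i > 0:
            pt, pq = int(t_blocks[i - 1][1]), int(q_blocks[i - 1][1])
            net += (int(ts) - pt) - (int(qs) - pq)
            if int(ts) > pt:  # insertion: keep the extra target bases
                parts.append(region[pt:ts])
        parts.append(region[ts:te])
    if len(q_blocks) and q_blocks[-1][1] < L:  # rare unaligned query end
        parts.append(ref_exon[q_blocks[-1][1] :])
    return "".join(parts), net


def classify_locus(
    locus: CandidateLocus,
    ref_exons: list[str],
    contig_seq: str,
    locus_id: str = "locus",
    flank_pad: int = 30,
) -> LocusCall:
    """Classify a candidate locus as gene or pseudogene.

    Reasons: ``missing_exon`` when any reference exon lacks a qualifying hit;
    ``frameshift_indel`` when the aligned segment of any exon differs from
    the reference exon length by a non-multiple of 3 (compensating indels
    within an exon restore the frame and are not flagged); ``premature_stop``
    when the conceptual translation of the spliced candidate CDS stops before
    its final codon; ``no_terminal_stop`` when the translation lacks a final
    stop.  A locus is a gene iff no reason fires.
    """
    n_ref = len(ref_exons)
    best: dict[int, ExonHit] = {}
    for h in locus.hits:
        if h.ref_exon_index not in best or h.percent_identity > best[h.ref_exon_index].percent_identity:
            best[h.ref_exon_index] = h
    reasons: set[str] = set()
    if any(i not in best for i in range(1, n_ref + 1)):
        reasons.add("missing_exon")
    segments: list[tuple[int, str]] = []
    for idx in range(1, n_ref + 1):
        if idx not in best:
            continue
        h = best[idx]
        lo = max(0, h.locus_interval.start - flank_pad)
        hi = min(len(contig_seq), h.locus_interval.end + flank_pad)
        region = contig_seq[lo:hi]
        if locus.strand == "-":
            region = revcomp(region)
        segment, net_indel = _extract_exon_segment(region, ref_exons[idx - 1])
        if net_indel % 3 != 0:
            reasons.add("frameshift_indel")
        segments.append((idx, segment))
    spliced = "".join(seg for _, seg in sorted(segments))
    aa = ""
    if spliced:
        trimmed = spliced[: len(spliced) - len(spliced) % 3]
        aa = str(Seq(trimmed).translate())
    if "*" in aa[:-1]:
        reasons.add("premature_stop")
    if not aa.endswith("*"):
        reasons.add("no_terminal_stop")
    ordered = tuple(r for r in REASONS if r in reasons)
    return LocusCall(
        locus_id=locus_id,
        span=locus.span,
        strand=locus.strand,
        exon_hits=locus.hits,
        classification="gene" if not ordered else "pseudogene",
        reasons=ordered,
        spliced_cds=spliced,
        translation=aa,
    )


def annotate_genome(
    contigs: list[Contig],
    ref_exons: list[str],
    min_identity: float = 0.80,
    min_consecutive: int = 2,
    max_gap_bp: int = 20_000,
) -> list[LocusCall]:
    """Scan every contig, chain hits into candidate loci, classify each."""
    calls: list[LocusCall] = []
    k = 0
    for contig in contigs:
        hits = scan_exon_homology(contig, ref_exons, min_identity)
        for locus in select_candidate_loci(hits, min_consecutive, max_gap_bp):
            calls.append(
                classify_locus(locus, ref_exons, contig.sequence, f"call_{k:04d}")
            )
            k += 1
    return calls
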