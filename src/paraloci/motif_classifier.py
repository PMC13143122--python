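"""Motif regexes, scanning and canonical/divergent IDS classification.

Isoprenyl diphosphate synthases (IDSs: FPPS, GGPPS and their divergent
paralogs) carry two aspartate-rich motifs (FARM and SARM, consensus DDxxD)
that coordinate the Mg2+ ions of the active site, plus a set of insect-GGPPS
motifs (IGM 1-6) characteristic of canonical insect GGPPS proteins.  This
module builds per-column residue-class definitions ("motif regexes") from
aligned training sequences, scans proteins for them, and classifies each
protein as canonical, divergent-like (FARM and IGM3 retained, other IGMs
lost) or indeterminate.

A built-in motif set ships with the package: the DDxxD definition for
FARM/SARM, and a synthetic placeholder consensus for each IGM (the real IGM
column boundaries are taken from the user's own training alignments, since
they are a published convention rather than something this package derives).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "FamilyCall",
    "LogoMatrix",
    "builtin_motifs",
    "build_motif_regex",
    "scan_motif",
    "find_farm_sarm",
    "classify_ids_family",
    "is_ddxxd_disrupted",
    "filter_phylogeny_set",
    "logo_matrix",
    "motif_consensus",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)


@dataclass(frozen=True)
class MotifDefinition:
    """An ordered list of allowed residue sets; ``None`` marks a wildcard."""

    name: str
    column_classes: tuple[frozenset | None, ...]
    source: str = "built_in"  # or "trained"

    def __post_init__(self) -> None:
        if len(self.column_classes) < 3:
            raise ValueError(f"motif {self.name}: needs >= 3 columns")
        for k, cls in enumerate(self.column_classes):
            if cls is not None and (not cls or not set(cls) <= _AA_SET):
                raise ValueError(f"motif {self.name}: bad residue class at column {k}")

    @property
    def width(self) -> int:
        return len(self.column_classes)

    def matches_at(self, protein: str, pos: int) -> bool:
        if pos < 0 or pos + self.width > len(protein):
            return False
        for k, cls in enumerate(self.column_classes):
            aa = protein[pos + k]
            if cls is None:
                continue  # wildcard: matches anything, including X
            if aa not in cls:  # X matches only wildcards
                return False
        return True

    def to_json(self) -> dict:
        return {
            "name": self.name,
            "columns": ["*" if c is None else "".join(sorted(c)) for c in self.column_classes],
            "source": self.source,
        }

    @classmethod
    def from_json(cls, d: dict) -> "MotifDefinition":
        cols = tuple(None if c == "*" else frozenset(c) for c in d["columns"])
        return cls(d["name"], cols, d.get("source", "trained"))


@dataclass(frozen=True)
class MotifHit:
    motif_name: str
    start: int  # 0-based on the protein
    span: str
    exact: bool  # True when every column is a single-residue class match


@dataclass(frozen=True)
class FamilyCall:
    """Per-protein motif status and canonical/divergent assignment."""

    sequence_id: str
    status: dict  # motif name -> bool (present)
    call: str  # canonical | divergent_like | indeterminate
    length_ok: bool  # >= 150 aa


@dataclass(frozen=True)
class LogoMatrix:
    """Column residue frequencies and information content (bits)."""

    frequencies: np.ndarray  # (n_columns, 20), rows sum to 1
    information_bits: np.ndarray  # log2(20) - Shannon entropy per column
    alphabet: str = AMINO_ACIDS


# ---------------------------------------------------------------------------
# Built-in definitions
# ---------------------------------------------------------------------------

def _cls(spec: str) -> frozenset | None:
    return None if spec == "*" else frozenset(spec)


#: DDxxD — the aspartate-rich motif shared by FARM and SARM.
DDXXD = MotifDefinition("DDxxD", tuple(_cls(c) for c in ("D", "D", "*", "*", "D")))


def builtin_motifs() -> dict[str, MotifDefinition]:
    """Default motif set: DDxxD for FARM/SARM plus synthetic placeholder
    consensus classes for IGM1-6 (stand-ins for user-trained definitions;
    real analyses should train IGMs from their own alignment boundaries)."""
    igms = {
        "IGM1": ("KL", "Q", "*", "Y", "N", "VI"),
        "IGM2": ("G", "Q", "*", "LM", "D", "LIV"),
        "IGM3": ("G", "K", "*", "FY", "R", "P"),
        "IGM4": ("K", "T", "A", "*", "LIV", "F"),
        "IGM5": ("E", "M", "*", "H", "T", "A"),
        "IGM6": ("W", "C", "*", "E", "R", "G"),
    }
    out = {
        "FARM": MotifDefinition("FARM", DDXXD.column_classes),
        "SARM": MotifDefinition("SARM", DDXXD.column_classes),
    }
    for name, cols in igms.items():
        out[name] = MotifDefinition(name, tuple(_cls(c) for c in cols))
    return out


def motif_consensus(motif: MotifDefinition, rng: np.random.Generator | None = None) -> str:
    """A representative string matching the motif (wildcards filled randomly)."""
    rng = rng or np.random.default_rng(0)
    out = []
    for cls in motif.column_classes:
        if cls is None:
            out.append(str(rng.choice(list(AMINO_ACIDS))))
        else:
            out.append(sorted(cls)[0])
    return "".join(out)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def build_motif_regex(
    alignment: list[str],
    boundaries: tuple[int, int],
    name: str = "trained",
    min_residue_freq: float = 0.05,
    wildcard_min_residues: int = 15,
) -> MotifDefinition:
    """Derive a motif definition from aligned training sequences.

    Per column, the allowed class is the set of residues with frequency
    >= ``min_residue_freq`` among non-gap characters; a column whose allowed
    class equals all observed residues and spans >= ``wildcard_min_residues``
    distinct residues becomes a wildcard.  A gap-majority column inside the
    motif is rejected.
    """
    if len(alignment) < 5:
        raise ValueError("need >= 5 training sequences")
    width = len(alignment[0])
    if any(len(s) != width for s in alignment):
        raise ValueError("training sequences must be aligned (equal length)")
    lo, hi = boundaries
    if not 0 <= lo < hi <= width:
        raise ValueError(f"boundaries {boundaries} outside alignment width {width}")
    classes: list[frozenset | None] = []
    for col in range(lo, hi):
        chars = [s[col].upper() for s in alignment]
        residues = [c for c in chars if c in _AA_SET]
        if len(residues) * 2 <= len(chars):
            raise ValueError(f"gap-majority column {col} inside motif {name!r}")
        counts: dict[str, int] = {}
        for c in residues:
            counts[c] = counts.get(c, 0) + 1
        n = len(residues)
        allowed = frozenset(c for c, k in counts.items() if k / n >= min_residue_freq)
        observed = frozenset(counts)
        if allowed == observed and len(allowed) >= wildcard_min_residues:
            classes.append(None)
        else:
            classes.append(allowed)
    return MotifDefinition(name, tuple(classes), source="trained")


# ---------------------------------------------------------------------------
# Scanning and classification
# ---------------------------------------------------------------------------


def scan_motif(protein: str, motif: MotifDefinition) -> list[MotifHit]:
    """All match positions of a motif in a protein, left to right."""
    protein = protein.upper()
    hits = []
    exact = all(cls is not None and len(cls) == 1 for cls in motif.column_classes)
    for pos in range(len(protein) - motif.width + 1):
        if motif.matches_at(protein, pos):
            hits.append(
                MotifHit(motif.name, pos, protein[pos : pos + motif.width], exact)
            )
    return hits


def find_farm_sarm(
    protein: str,
    ddxxd: MotifDefinition = DDXXD,
    min_separation: int = 80,
) -> tuple[MotifHit | None, MotifHit | None]:
    """FARM = first DDxxD-class hit; SARM = next hit starting at least
    ``min_separation`` residues downstream of the FARM start."""
    hits = scan_motif(protein, ddxxd)
    if not hits:
        return None, None
    farm = hits[0]
    sarm = next((h for h in hits[1:] if h.start >= farm.start + min_separation), None)
    return farm, sarm


def is_ddxxd_disrupted(protein: str, ddxxd: MotifDefinition = DDXXD) -> bool:
    """Aspartate-rich motifs disrupted: fewer than two intact DDxxD hits
    (a testable proxy for loss of Mg2+ coordination)."""
    farm, sarm = find_farm_sarm(protein, ddxxd)
    return farm is None or sarm is None


def classify_ids_family(
    protein: str,
    motifs: dict[str, MotifDefinition] | None = None,
    sequence_id: str = "",
    min_separation: int = 80,
) -> FamilyCall:
    """Classify a protein as canonical GGPPS-like, divergent-like or
    indeterminate from its motif complement.

    canonical: FARM, SARM and every IGM present.
    divergent_like: FARM and IGM3 present, at least one other IGM absent.
    indeterminate: anything else.  The full status map is reported so
    callers can apply their own rules.
    """
    motifs = dict(motifs) if motifs is not None else builtin_motifs()
    igm_names = sorted(n for n in motifs if n.upper().startswith("IGM"))
    farm_def = motifs.get("FARM", DDXXD)
    farm, sarm = find_farm_sarm(protein, farm_def, min_separation)
    status: dict[str, bool] = {"FARM": farm is not None, "SARM": sarm is not None}
    for name in igm_names:
        status[name] = bool(scan_motif(protein, motifs[name]))
    igm_present = [status[n] for n in igm_names]
    if status["FARM"] and status["SARM"] and all(igm_present):
        call = "canonical"
    elif (
        status["FARM"]
        and status.get("IGM3", False)
        and any(not status[n] for n in igm_names if n != "IGM3")
    ):
        call = "divergent_like"
    else:
        call = "indeterminate"
    return FamilyCall(sequence_id, status, call, length_ok=len(protein) >= 150)


def filter_phylogeny_set(
    proteins: dict[str, str],
    min_length: int = 150,
    ddxxd: MotifDefinition = DDXXD,
    min_separation: int = 80,
) -> dict[str, str]:
    """Keep exactly the sequences with length >= ``min_length`` and both
    FARM and SARM hits (the inclusion rule for phylogenetic analysis)."""
    out = {}
    for pid, seq in proteins.items():
        if len(seq) < min_length:
            continue
        farm, sarm = find_farm_sarm(seq, ddxxd, min_separation)
        if farm is not None and sarm is not None:
            out[pid] = seq
    return out


# ---------------------------------------------------------------------------
# Logos
# ---------------------------------------------------------------------------


def logo_matrix(instances: list[str]) -> LogoMatrix:
    """Column residue frequencies and information content from equal-length,
    ungapped motif instances.  IC per column = log2(20) - H(column)."""
    if not instances:
        raise ValueError("need >= 1 motif instance")
    width = len(instances[0])
    if any(len(s) != width for s in instances):
        raise ValueError("motif instances must have equal length")
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    freqs = np.zeros((width, 20))
    for s in instances:
        for k, aa in enumerate(s.upper()):
            if aa not in idx:
                raise ValueError(f"non-standard residue {aa!r} in motif instance")
            freqs[k, idx[aa]] += 1
    freqs /= len(instances)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logp).sum(axis=1)
    ic = math.log2(20) - entropy
    return LogoMatrix(frequencies=freqs, information_bits=ic)


def save_motifs_json(path: str, motifs: dict[str, MotifDefinition]) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_json() for k, m in sorted(motifs.items())}, fh, indent=2)
        fh.write("\n")


def load_motifs_json(path: str) -> dict[str, MotifDefinition]:
    with open(path) as fh:
        data = json.load(fh)
    return {k: MotifDefinition.from_json(v) for k, v in data.items()}
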