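"""IUPAC degenerate motif scanning on circular sequences.

Semantics: a pattern symbol matches a subject base iff the base is in the
symbol's IUPAC set.  ``N`` in a pattern matches any concrete base, but an ``N``
in the *subject* matches nothing — ambiguity in the data must not create
annotations.  A non-matching position costs one mismatch regardless of the
pattern symbol's degeneracy.  Scans cover both strands and origin-spanning
positions; minus-strand hits are reported as forward-strand intervals with the
matched subsequence given in its forward projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .circgenome import CircularSequence, Feature, Interval, reverse_complement

__all__ = [
    "IUPAC",
    "DegenerateMotif",
    "MotifHit",
    "scan",
    "build_consensus",
    "dedupe",
    "default_panel",
    "parse_panel",
    "write_panel",
    "hamming",
    "hits_to_features",
]

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC.items()}


def hamming(a: str, b: str) -> int:
    """Plain Hamming distance between equal-length concrete DNA strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class DegenerateMotif:
    name: str
    pattern: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise ValueError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) in pattern: {sorted(bad)}")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    location: Interval
    mismatches: int
    matched: str  # forward-strand projection of the matched subsequence


# uint8 base codes used for vectorized scanning
_BASE_ORD = {b: ord(b) for b in "ACGTN"}


def _allowed_table(symbol: str) -> np.ndarray:
    """Boolean lookup over byte values: which subject bases match the symbol."""
    table = np.zeros(256, dtype=bool)
    for base in IUPAC[symbol]:
        table[_BASE_ORD[base]] = True
    # subject N never matches
    return table


_TABLES = {sym: _allowed_table(sym) for sym in IUPAC}


def _scan_strand(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """(start, mismatches) for every position on one strand of a circle."""
    L, m = len(seq), len(pattern)
    ext = seq + seq[: m - 1]
    x = np.frombuffer(ext.encode(), dtype=np.uint8)
    mism = np.zeros(L, dtype=np.int32)
    for j, sym in enumerate(pattern):
        mism += ~_TABLES[sym][x[j : j + L]]
    idx = np.nonzero(mism <= max_mm)[0]
    return [(int(i), int(mism[i])) for i in idx]


def scan(s: CircularSequence, m: DegenerateMotif) -> list[MotifHit]:
    """All hits of a degenerate motif on both strands of a circular sequence.

    Hits are sorted by (forward position, strand); overlapping hits are all
    reported.  Raises ``ValueError`` if the pattern is longer than the genome.
    """
    L = s.length
    pat = m.pattern
    if len(pat) > L:
        raise ValueError(f"pattern {m.name!r} longer than genome {s.id!r}")
    hits: list[MotifHit] = []
    for start, mm in _scan_strand(s.seq, pat, m.max_mismatch):
        iv = Interval(start, start + len(pat), "+")
        hits.append(MotifHit(m.name, iv, mm, s.fetch(start, start + len(pat))))
    rc = reverse_complement(s.seq)
    for start, mm in _scan_strand(rc, pat, m.max_mismatch):
        fwd_start = (L - start - len(pat)) % L
        iv = Interval(fwd_start, fwd_start + len(pat), "-")
        hits.append(MotifHit(m.name, iv, mm, s.fetch(fwd_start, fwd_start + len(pat))))
    hits.sort(key=lambda h: (h.location.start, h.location.strand == "-"))
    return hits


def build_consensus(motifs: Sequence[str], name: str = "consensus") -> DegenerateMotif:
    """Minimal IUPAC consensus covering all observed bases per column.

    Every input motif matches the returned pattern with zero mismatches.
    Inputs must be equal-length concrete (A/C/G/T) strings.
    """
    if not motifs:
        raise ValueError("need at least one motif")
    cleaned = [m.upper() for m in motifs]
    n = len(cleaned[0])
    for m in cleaned:
        if len(m) != n:
            raise ValueError("motifs must have equal lengths")
        bad = set(m) - set("ACGT")
        if bad:
            raise ValueError(f"consensus input must be concrete bases, got {sorted(bad)}")
    pattern = "".join(
        _SET_TO_CODE[frozenset({m[i] for m in cleaned})] for i in range(n)
    )
    return DegenerateMotif(name, pattern, 0)


def dedupe(motifs: Iterable[str]) -> list[str]:
    """Order-preserving case-normalized unique list."""
    seen: set[str] = set()
    out: list[str] = []
    for m in motifs:
        u = str(m).upper()
        if u not in seen:
            seen.add(u)
            out.append(u)
    return out


def default_panel() -> list[DegenerateMotif]:
    """The default origin-element motif panel.

    DnaA-box 8-mer, oriT 12-mer (1 mismatch allowed), dso nick heptamer,
    CS-6 hexamer, the CRESS-viral nonanucleotide, and the 12-bp inverted
    motif characteristic of group-1 genomes.
    """
    return [
        DegenerateMotif("DnaA-box", "ATTTTCAT", 0),
        DegenerateMotif("oriT", "TAAGTGCGCCCT", 1),
        DegenerateMotif("dso-nick", "CTTGATA", 0),
        DegenerateMotif("CS-6", "TAGCGW", 0),
        DegenerateMotif("viral-nona", "WADTTATAC", 0),
        DegenerateMotif("inv12", "TAAATGCTTTTA", 0),
    ]


def parse_panel(path: str | Path) -> list[DegenerateMotif]:
    """Read a plain-text panel: one ``name pattern max_mismatch`` per line."""
    panel = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(
                f"{path}: line {lineno}: expected 'name pattern max_mismatch'"
            )
        panel.append(DegenerateMotif(parts[0], parts[1], int(parts[2])))
    return panel


def write_panel(panel: Sequence[DegenerateMotif], path: str | Path) -> None:
    lines = [f"{m.name} {m.pattern} {m.max_mismatch}" for m in panel]
    Path(path).write_text("\n".join(lines) + "\n")


def hits_to_features(seq_id: str, hits: Sequence[MotifHit]) -> list[Feature]:
    return [
        Feature(
            seq_id,
            "motif",
            h.location,
            attributes={"Name": h.motif, "mismatches": h.mismatches, "match": h.matched},
        )
        for h in hits
    ]


def write_bed(seq_id: str, hits: Sequence[MotifHit], path: str | Path, genome_length: int) -> None:
    """BED6 export (0-based half-open); wrapped hits are clipped at the origin."""
    lines = []
    for h in hits:
        iv = h.location
        parts = [(iv.start, min(iv.end, genome_length))]
        if iv.end > genome_length:
            parts.append((0, iv.end - genome_length))
        for st, en in parts:
            lines.append(
                f"{seq_id}\t{st}\t{en}\t{h.motif}\t{h.mismatches}\t{iv.strand}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
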