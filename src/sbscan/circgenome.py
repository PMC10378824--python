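"""Circular-sequence data model and standard-format I/O.

Everything downstream operates on :class:`CircularSequence`, a normalized
(uppercase, T-only) DNA record whose coordinates are understood modulo the
genome length.  Intervals are 0-based half-open internally; an interval whose
``end`` exceeds the genome length denotes an origin-spanning feature and is
interpreted modulo the length.  GFF3 output follows the GFF3 convention
(1-based inclusive), with origin-spanning features split into two part lines
sharing an ``ID`` attribute, since GFF3 has no native circular-wrap encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "CircularSequence",
    "Interval",
    "Feature",
    "FastaError",
    "normalize_sequence",
    "read_fasta",
    "write_fasta",
    "gc_content",
    "reverse_complement",
    "write_features",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
VALID_BASES = frozenset("ACGTN")


class FastaError(ValueError):
    """Raised for malformed FASTA input or invalid sequence content."""


def normalize_sequence(raw: str, record_id: str = "<anonymous>") -> str:
    """Uppercase, convert U->T, and validate the {A,C,G,T,N} alphabet."""
    seq = str(raw).upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FastaError(
            f"record {record_id!r}: invalid character(s) {sorted(bad)} "
            "(allowed: A, C, G, T, N; U is converted to T)"
        )
    return seq


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N."""
    seq = str(seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid character(s) for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval; ``end > genome length`` means origin-spanning.

    ``start`` must lie in ``[0, length)`` of its genome; ``end - start`` may not
    exceed the genome length.  Those genome-dependent rules are checked where a
    genome is in scope (:func:`write_features`, feature constructors).
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length

    def positions(self, genome_length: int) -> list[int]:
        """Genome positions covered, reduced modulo the genome length."""
        return [p % genome_length for p in range(self.start, self.end)]

    def overlap(self, other: "Interval", genome_length: int) -> int:
        """Number of shared genome positions (circular-aware)."""
        return len(
            set(self.positions(genome_length)) & set(other.positions(genome_length))
        )

    def shift(self, offset: int, genome_length: int) -> "Interval":
        """Interval after rotating the genome so old position ``offset`` is 0."""
        start = (self.start - offset) % genome_length
        return Interval(start, start + self.length, self.strand)


@dataclass
class CircularSequence:
    """A circular DNA record with rotation-aware, strand-aware access."""

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.seq = normalize_sequence(self.seq, self.id)
        if not self.seq:
            raise FastaError(f"record {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence [start, end) with circular wrap; span may not exceed length."""
        L = self.length
        span = end - start
        if span > L:
            raise ValueError(f"span {span} exceeds genome length {L}")
        if span <= 0:
            return ""
        start %= L
        return (self.seq + self.seq)[start : start + span]

    def fetch_interval(self, iv: Interval) -> str:
        """Sequence of an interval, reverse-complemented for '-' strand."""
        s = self.fetch(iv.start, iv.end)
        return reverse_complement(s) if iv.strand == "-" else s

    def rotate_to(self, p: int) -> "CircularSequence":
        """New record with old position ``p`` as position 0 (same circle)."""
        p %= self.length
        return CircularSequence(self.id, self.seq[p:] + self.seq[:p])


def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read FASTA records as circular sequences (normalized, order preserved).

    Raises :class:`FastaError` for a file whose first non-blank line is not a
    header (naming the offending line), for empty records (naming the id), and
    for invalid sequence characters.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaError(
                    f"{path}: line {lineno}: expected FASTA header starting "
                    f"with '>', got {line.strip()[:30]!r}"
                )
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaError(f"record {rec.id!r} is empty")
        records.append(CircularSequence(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[CircularSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def gc_content(s: CircularSequence, window: Interval | None = None) -> float:
    """(G+C)/(A+C+G+T) over the window (whole genome if None); N excluded.

    Raises ``ValueError`` if the window contains no unambiguous base.
    """
    seq = s.seq if window is None else s.fetch(window.start, window.end)
    gc = sum(seq.count(b) for b in "GC")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("GC content undefined: window contains only N")
    return gc / denom


@dataclass
class Feature:
    """A typed interval with attributes, for GFF3/BED export."""

    seq_id: str
    type: str
    interval: Interval
    score: float | None = None
    attributes: dict = field(default_factory=dict)
    source: str = "sbscan"


def _gff3_attr(attrs: dict) -> str:
    if not attrs:
        return "."
    enc = lambda v: str(v).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")
    return ";".join(f"{k}={enc(v)}" for k, v in attrs.items())


def write_features(
    features: Sequence[Feature],
    path: str | Path,
    sequence_lengths: dict[str, int],
) -> None:
    """Write features as GFF3 (1-based inclusive coordinates).

    Origin-spanning features (interval end beyond the genome length) are
    emitted as two part lines sharing an ``ID`` attribute.
    """
    lines = ["##gff-version 3"]
    for n, f in enumerate(features, start=1):
        if f.seq_id not in sequence_lengths:
            raise ValueError(f"feature references unknown sequence id {f.seq_id!r}")
        L = sequence_lengths[f.seq_id]
        iv = f.interval
        if iv.start >= L or iv.length > L:
            raise ValueError(
                f"feature {n} interval ({iv.start}, {iv.end}) outside coordinate "
                f"rules for genome of length {L}"
            )
        score = "." if f.score is None else f"{f.score:g}"
        attrs = dict(f.attributes)
        if iv.wraps(L):
            attrs.setdefault("ID", f"feature{n}")
            parts = [(iv.start, L), (0, iv.end - L)]
        else:
            parts = [(iv.start, iv.end)]
        attr_s = _gff3_attr(attrs)
        for p_start, p_end in parts:
            lines.append(
                "\t".join(
                    [
                        f.seq_id,
                        f.source,
                        f.type,
                        str(p_start + 1),
                        str(p_end),
                        score,
                        iv.strand,
                        ".",
                        attr_s,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
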