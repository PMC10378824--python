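"""Open reading frame prediction on circular genomes.

Both strands are scanned, including ORFs spanning the sequence origin, by
reading a tripled copy of the genome and deduplicating stop positions modulo
the genome length.  Per stop codon the reported ORF begins at the most
upstream in-frame start after the previous in-frame stop (longest-ORF rule).

Length convention: ``nt_length`` *includes* the stop codon, so a 906-nt ORF
encodes a 301-aa protein (aa_length = nt_length/3 - 1).  This makes the usual
paired nt/aa size ranges for these genomes (e.g. 894-987 nt <-> 297-328 aa)
self-consistent.  Alternative initiation codons default to the bacterial
standard-code set {ATG, GTG, TTG}; every start codon is translated as Met.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left
from dataclasses import dataclass

from Bio.Seq import Seq

from .circgenome import CircularSequence, Feature, Interval, reverse_complement

__all__ = ["OrfFeature", "find_orfs", "orfs_to_features", "write_protein_fasta"]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_STARTS = ("ATG", "GTG", "TTG")


@dataclass(frozen=True)
class OrfFeature:
    location: Interval
    start_codon: str
    nt_length: int  # includes the stop codon
    aa_length: int
    protein: str
    rank: int = 0

    @property
    def strand(self) -> str:
        return self.location.strand


def _translate(cds: str) -> str:
    """Translate a CDS (with stop), forcing the initiator to Met."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # partial-codon warnings cannot occur here
        aa = str(Seq(cds).translate())
    return "M" + aa[1:].rstrip("*")


def find_orfs(
    s: CircularSequence,
    min_nt: int = 75,
    min_aa_report: int = 95,
    starts: tuple[str, ...] = DEFAULT_STARTS,
) -> list[OrfFeature]:
    """All maximal ORFs on both strands of a circular genome.

    Results are sorted by nt_length descending (ties: '+' strand first, then
    smaller start) and rank-annotated (1 = longest).  Only ORFs of at least
    ``min_aa_report`` amino acids are reported.  A genome shorter than
    ``min_nt`` yields an empty list.  An ORF candidate longer than the genome
    (no in-frame stop within one full turn) is rejected with a warning.
    """
    if min_nt < 6:
        raise ValueError("min_nt must be >= 6 (start + stop codon)")
    if not starts:
        raise ValueError("starts must be non-empty")
    starts = tuple(c.upper() for c in starts)
    L = s.length
    if L < min_nt:
        return []

    found: dict[tuple[str, int], OrfFeature] = {}
    for strand in "+-":
        template = s.seq if strand == "+" else reverse_complement(s.seq)
        d = template * 3
        for frame in range(3):
            stop_pos = [
                i for i in range(frame, len(d) - 2, 3) if d[i : i + 3] in STOP_CODONS
            ]
            if not stop_pos:
                warnings.warn(
                    f"{s.id}: reading frame with no stop codon anywhere; "
                    "wrap-around ORF rejected",
                    stacklevel=2,
                )
                continue
            for p in stop_pos:
                if p < L or p >= 2 * L:
                    continue  # consider each circular stop once, with full context
                key = (strand, p % L)
                if key in found:
                    continue
                i = bisect_left(stop_pos, p)
                prev = stop_pos[i - 1] if i > 0 else None
                # ORF may not exceed one full genome turn; align the bound to
                # this reading frame (L need not be a multiple of 3)
                lower = p + 3 - L
                lower += (p - lower) % 3
                if prev is not None and prev + 3 > lower:
                    lower = prev + 3
                # first in-frame start codon at or after `lower`
                start_at = None
                for j in range(lower, p, 3):
                    if d[j : j + 3] in starts:
                        start_at = j
                        break
                if start_at is None:
                    continue
                nt = p + 3 - start_at
                if nt < min_nt:
                    continue
                cds = d[start_at : p + 3]
                if strand == "+":
                    g_start = start_at % L
                    iv = Interval(g_start, g_start + nt, "+")
                else:
                    g_start = (L - (start_at % L) - nt) % L
                    iv = Interval(g_start, g_start + nt, "-")
                found[key] = OrfFeature(
                    location=iv,
                    start_codon=cds[:3],
                    nt_length=nt,
                    aa_length=nt // 3 - 1,
                    protein=_translate(cds),
                )

    reported = [o for o in found.values() if o.aa_length >= min_aa_report]
    reported.sort(key=lambda o: (-o.nt_length, o.strand == "-", o.location.start))
    return [
        OrfFeature(o.location, o.start_codon, o.nt_length, o.aa_length, o.protein, r)
        for r, o in enumerate(reported, start=1)
    ]


def orfs_to_features(seq_id: str, orfs: list[OrfFeature]) -> list[Feature]:
    return [
        Feature(
            seq_id,
            "ORF",
            o.location,
            attributes={
                "ID": f"{seq_id}_orf{o.rank}",
                "start_codon": o.start_codon,
                "aa_length": o.aa_length,
            },
        )
        for o in orfs
    ]


def write_protein_fasta(seq_id: str, orfs: list[OrfFeature], path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f">{seq_id}_orf{o.rank} strand={o.strand} "
                f"start={o.location.start} nt={o.nt_length}\n{o.protein}\n"
            )
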