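"""Tandem-repeat (iteron-like) arrays, repeat typing, and inverted repeats.

The tandem detector is a seed-and-extend scan over a tripled copy of the
genome: for every unit length in the search range, positions where one unit is
followed by a near-identical unit seed a candidate array; copies are then
chained by comparison against the *first* copy (each full copy may differ from
it by at most ``max_mismatch_per_copy`` substitutions).  Arrays are maximal
(not extendable by a full copy on the left), and overlapping candidates are
resolved by (more full copies, then longer unit, then fewer total mismatches,
then smaller start) — the mismatch term prevents a chance frame-shifted
candidate from displacing a cleaner array with the same copy count.  A
partial terminal repeat is reported when at least 6 nt continue the consensus
within a length-prorated mismatch budget; the tail always ends on a matching
base (trailing mismatches are trimmed).

Hairpin folding treats stems as perfect Watson-Crick DNA pairs by default
(no G.U wobble): the fold maximizing stem length with a loop of at least
``min_loop`` nucleotides wins; ties prefer the smaller loop, then the
leftmost fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circgenome import CircularSequence, Feature, Interval, reverse_complement
from .motif_scan import hamming

__all__ = [
    "RepeatArray",
    "ItrMotif",
    "Hairpin",
    "find_tandem_arrays",
    "type_itr",
    "fold_hairpin",
    "find_inverted_repeats",
    "arrays_to_features",
]

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class RepeatArray:
    location: Interval
    unit_length: int
    full_copies: int
    partial_tail_nt: int
    consensus: str
    copy_mismatches: tuple[int, ...]


@dataclass
class ItrMotif:
    """A catalog entry: a 22-bp (or other fixed-length) iteron-like consensus."""

    motif_id: str
    consensus: str
    members: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Hairpin:
    location: Interval
    stem_length: int
    loop_length: int
    mismatches_in_stem: int = 0

    @property
    def span(self) -> int:
        return 2 * self.stem_length + self.loop_length


def _consensus_of(copies: list[str]) -> str:
    """Column-wise majority; ties broken by the first copy's base."""
    out = []
    for col in range(len(copies[0])):
        counts: dict[str, int] = {}
        for c in copies:
            counts[c[col]] = counts.get(c[col], 0) + 1
        best = max(counts.values())
        winners = {b for b, n in counts.items() if n == best}
        first = copies[0][col]
        out.append(first if first in winners else sorted(winners)[0])
    return "".join(out)


def find_tandem_arrays(
    s: CircularSequence,
    unit_range: tuple[int, int] = (15, 30),
    min_copies: int = 2,
    max_mismatch_per_copy: int = 3,
    min_partial: int = 6,
) -> list[RepeatArray]:
    """Maximal tandem repeat arrays with units in ``unit_range`` (inclusive)."""
    L = s.length
    lo, hi = unit_range
    if lo < 4 or hi > L // 2 or lo > hi:
        raise ValueError(f"unit_range {unit_range} outside [4, length/2] for length {L}")
    d = s.seq * 3
    x = np.frombuffer(d.encode(), dtype=np.uint8)
    candidates = []
    for u in range(lo, hi + 1):
        neq = (x[:-u] != x[u:]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(neq)])
        n_pos = len(x) - 2 * u + 1
        mm = cs[u : u + n_pos] - cs[:n_pos]  # mismatches between unit at p and p+u
        seeds = np.nonzero(mm[: 2 * L] <= max_mismatch_per_copy)[0]
        for p in seeds:
            p = int(p)
            if p < L or p >= 2 * L:
                continue
            first = d[p : p + u]
            # left-maximality: the preceding unit must not be another full copy
            if hamming(d[p - u : p], first) <= max_mismatch_per_copy:
                continue
            copies = [first]
            mism = [0]
            while True:
                q = p + len(copies) * u
                nxt = d[q : q + u]
                if len(nxt) < u or (len(copies) + 1) * u > L:
                    break
                hm = hamming(nxt, first)
                if hm > max_mismatch_per_copy:
                    break
                copies.append(nxt)
                mism.append(hm)
            if len(copies) < min_copies:
                continue
            consensus = _consensus_of(copies)
            end = p + len(copies) * u
            tail = 0
            for t in range(u - 1, min_partial - 1, -1):
                if end + t - p > L:
                    continue
                if d[end + t - 1] != consensus[t - 1]:
                    continue  # tails end on a matching base
                budget = (max_mismatch_per_copy * t) // u
                if hamming(d[end : end + t], consensus[:t]) <= budget:
                    tail = t
                    break
            candidates.append(
                (len(copies), u, p % L, tail, consensus, tuple(mism))
            )
    # resolution order: copies, unit length, total mismatches, start
    candidates.sort(key=lambda c: (-c[0], -c[1], sum(c[5]), c[2]))
    taken: set[int] = set()
    arrays: list[RepeatArray] = []
    for copies_n, u, start, tail, consensus, mism in candidates:
        span = copies_n * u + tail
        pos = {(start + k) % L for k in range(span)}
        if pos & taken:
            continue
        taken |= pos
        arrays.append(
            RepeatArray(
                location=Interval(start, start + span),
                unit_length=u,
                full_copies=copies_n,
                partial_tail_nt=tail,
                consensus=consensus,
                copy_mismatches=mism,
            )
        )
    arrays.sort(key=lambda a: a.location.start)
    return arrays


def type_itr(
    consensus: str,
    catalog: list[ItrMotif],
    max_mismatch: int = 3,
    member: str | None = None,
) -> str:
    """Assign a repeat-unit consensus to a catalog motif, or mint a new one.

    The nearest catalog motif within ``max_mismatch`` substitutions wins (ties
    go to the lowest catalog index); otherwise a fresh motif id is appended to
    the catalog.  Raises ``ValueError`` on a length mismatch with the catalog.
    """
    consensus = consensus.upper()
    for entry in catalog:
        if len(entry.consensus) != len(consensus):
            raise ValueError(
                f"consensus length {len(consensus)} does not match catalog "
                f"unit length {len(entry.consensus)}"
            )
    best_id, best_d = None, None
    for entry in catalog:
        dist = hamming(consensus, entry.consensus)
        if best_d is None or dist < best_d:
            best_id, best_d = entry.motif_id, dist
    if best_d is not None and best_d <= max_mismatch:
        if member is not None:
            next(e for e in catalog if e.motif_id == best_id).members.append(member)
        return best_id  # type: ignore[return-value]
    new_id = f"ITR-{len(catalog) + 1}"
    catalog.append(ItrMotif(new_id, consensus, [member] if member else []))
    return new_id


def fold_hairpin(
    motif: str,
    min_stem: int = 3,
    min_loop: int = 3,
    max_mismatch: int = 0,
) -> Hairpin | None:
    """Best stem-loop fold of a short motif, or None if no stem >= min_stem.

    Considers every (offset, stem, loop) decomposition within the motif and
    returns the fold with the longest perfect (or <=max_mismatch) stem;
    ties prefer smaller loops, then smaller offsets.
    """
    motif = motif.upper()
    n = len(motif)
    if n < 2 * min_stem + min_loop:
        return None  # too short to fold at all
    max_stem = (n - min_loop) // 2
    for stem in range(max_stem, min_stem - 1, -1):
        for loop in range(min_loop, n - 2 * stem + 1):
            for a in range(0, n - 2 * stem - loop + 1):
                arm1 = motif[a : a + stem]
                arm2 = motif[a + stem + loop : a + 2 * stem + loop]
                if hamming(arm1, reverse_complement(arm2)) <= max_mismatch:
                    return Hairpin(
                        Interval(a, a + 2 * stem + loop),
                        stem,
                        loop,
                        hamming(arm1, reverse_complement(arm2)),
                    )
    return None


def find_inverted_repeats(
    s: CircularSequence,
    min_arm: int = 5,
    max_spacer: int = 50,
    max_mismatch: int = 1,
) -> list[Hairpin]:
    """Maximal inverted repeats genome-wide (circular-aware).

    For each putative loop (spacer) the arms are grown outward while the total
    number of non-complementary pairs stays within ``max_mismatch``; the
    outermost pair of a reported arm always matches.  Repeats whose span is
    contained in a reported repeat with the same loop centre are suppressed.
    """
    L = s.length
    d = s.seq * 3
    raw: list[Hairpin] = []
    for c0 in range(L):
        c = c0 + L  # loop start, with full context on both sides in d
        for gap in range(0, max_spacer + 1):
            m = 0
            mm = 0
            best = None  # (arm, mismatches) at last matching outer pair
            while True:
                left = d[c - m - 1]
                right = d[c + gap + m]
                pair_ok = _PAIR.get(left) == right  # N never pairs
                if not pair_ok:
                    mm += 1
                    if mm > max_mismatch:
                        break
                m += 1
                if m + (m + gap) > L:
                    break
                if pair_ok:
                    best = (m, mm)
            if best is None:
                continue
            arm, mism = best
            if arm < min_arm:
                continue
            start = (c0 - arm) % L
            raw.append(Hairpin(Interval(start, start + 2 * arm + gap), arm, gap, mism))
    # deduplicate: keep maximal spans per loop centre
    raw.sort(key=lambda h: (-h.stem_length, h.loop_length, h.location.start))
    kept: list[Hairpin] = []
    for h in raw:
        centre = (2 * h.location.start + 2 * h.stem_length + h.loop_length) % (2 * L)
        contained = False
        for k in kept:
            k_centre = (2 * k.location.start + 2 * k.stem_length + k.loop_length) % (2 * L)
            if centre == k_centre and h.location.start >= k.location.start and h.location.end <= k.location.end:
                contained = True
                break
            # same physical fold found one period later
            if (
                h.stem_length == k.stem_length
                and h.loop_length == k.loop_length
                and h.location.start % L == k.location.start % L
            ):
                contained = True
                break
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: h.location.start)
    return kept


def arrays_to_features(seq_id: str, arrays: list[RepeatArray]) -> list[Feature]:
    return [
        Feature(
            seq_id,
            "tandem_repeat",
            a.location,
            attributes={
                "unit_length": a.unit_length,
                "full_copies": a.full_copies,
                "partial_tail_nt": a.partial_tail_nt,
                "consensus": a.consensus,
            },
        )
        for a in arrays
    ]
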