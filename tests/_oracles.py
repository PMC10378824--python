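"""Independent brute-force oracles for scanner equality tests.

These deliberately use the slowest, most literal formulation of each
operation (start-driven ORF walking, exhaustive triple enumeration for
repeats, naive sliding-window search for motifs) so they share no code path
with the package implementations they check.
"""

from __future__ import annotations

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
_STOPS = {"TAA", "TAG", "TGA"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def ham(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def orf_triples(seq: str, starts=("ATG", "GTG", "TTG"), min_nt: int = 6):
    """All maximal ORFs as (strand, start_pos, nt_length) in the forward
    interval convention, by walking forward from every start codon."""
    L = len(seq)
    out = {}
    for strand in "+-":
        t = seq if strand == "+" else rc(seq)
        dd = t + t
        for sp in range(L):
            if dd[sp : sp + 3] not in starts:
                continue
            q = sp
            while q + 3 <= sp + L:
                codon = dd[q : q + 3]
                if codon in _STOPS:
                    break
                q += 3
            else:
                continue  # no stop within one turn: wrap-around ORF rejected
            if dd[q : q + 3] not in _STOPS:
                continue
            nt = q + 3 - sp
            if nt < min_nt:
                continue
            key = (strand, q % L)  # one ORF per stop: keep the longest
            if key not in out or nt > out[key][1]:
                out[key] = (sp % L, nt)
    triples = set()
    for (strand, _), (sp, nt) in out.items():
        if strand == "+":
            g_start = sp
        else:
            g_start = (L - sp - nt) % L
        triples.add((strand, g_start, nt))
    return triples


def exact_motif_positions(seq: str, pattern: str):
    """(start, strand) of every exact occurrence on both strands, circular."""
    L, m = len(seq), len(pattern)
    hits = set()
    dd = seq + seq
    for p in range(L):
        if dd[p : p + m] == pattern:
            hits.add((p, "+"))
    rpat = rc(pattern)
    for p in range(L):
        if dd[p : p + m] == rpat:
            hits.add((p, "-"))
    return hits


def tandem_arrays(seq: str, unit_range=(15, 30), min_copies=2, max_mm=3, min_partial=6):
    """Exhaustive (start, unit, copies) enumeration with the package's
    maximality, tail, and overlap-resolution rules, written naively."""
    L = len(seq)
    dd = seq * 3
    cands = []
    for u in range(unit_range[0], unit_range[1] + 1):
        for p0 in range(L):
            p = p0 + L
            first = dd[p : p + u]
            if ham(dd[p - u : p], first) <= max_mm:
                continue  # extendable left: not a chain start
            copies = [first]
            mism = [0]
            while True:
                q = p + len(copies) * u
                nxt = dd[q : q + u]
                if len(nxt) < u or (len(copies) + 1) * u > L:
                    break
                d = ham(nxt, first)
                if d > max_mm:
                    break
                copies.append(nxt)
                mism.append(d)
            if len(copies) < min_copies:
                continue
            cons = []
            for col in range(u):
                counts = {}
                for c in copies:
                    counts[c[col]] = counts.get(c[col], 0) + 1
                best = max(counts.values())
                winners = {b for b, n in counts.items() if n == best}
                cons.append(copies[0][col] if copies[0][col] in winners else sorted(winners)[0])
            cons = "".join(cons)
            end = p + len(copies) * u
            tail = 0
            for t in range(u - 1, min_partial - 1, -1):
                if end + t - p > L:
                    continue
                if dd[end + t - 1] != cons[t - 1]:
                    continue
                if ham(dd[end : end + t], cons[:t]) <= (max_mm * t) // u:
                    tail = t
                    break
            cands.append((len(copies), u, p0, tail, cons, tuple(mism)))
    cands.sort(key=lambda c: (-c[0], -c[1], sum(c[5]), c[2]))
    taken = set()
    arrays = []
    for copies_n, u, start, tail, cons, mism in cands:
        span = copies_n * u + tail
        pos = {(start + k) % L for k in range(span)}
        if pos & taken:
            continue
        taken |= pos
        arrays.append((start, u, copies_n, tail, cons))
    return sorted(arrays)


def best_fold(motif: str, min_stem=3, min_loop=3):
    """Exhaustive best (stem, loop) over all decompositions of a motif."""
    n = len(motif)
    best = None
    for a in range(n):
        for stem in range(min_stem, n):
            for loop in range(min_loop, n):
                if a + 2 * stem + loop > n:
                    continue
                arm1 = motif[a : a + stem]
                arm2 = motif[a + stem + loop : a + 2 * stem + loop]
                if arm1 == rc(arm2):
                    key = (-stem, loop, a)
                    if best is None or key < best[0]:
                        best = (key, stem, loop)
    if best is None:
        return None
    return best[1], best[2]


def inverted_repeats(seq: str, min_arm=5, max_spacer=50, max_mm=1):
    """All maximal inverted repeats as (start, stem, loop) triples, naive."""
    L = len(seq)
    dd = seq * 3
    raw = []
    for c0 in range(L):
        c = c0 + L
        for gap in range(0, max_spacer + 1):
            m = mm = 0
            best = None
            while True:
                ok = _COMP.get(dd[c - m - 1]) == dd[c + gap + m] and dd[c - m - 1] != "N"
                if not ok:
                    mm += 1
                    if mm > max_mm:
                        break
                m += 1
                if m + m + gap > L:
                    break
                if ok:
                    best = (m, mm)
            if best is None or best[0] < min_arm:
                continue
            arm = best[0]
            raw.append(((c0 - arm) % L, arm, gap))
    # keep maximal spans per loop centre (same rule as the package)
    raw.sort(key=lambda h: (-h[1], h[2], h[0]))
    kept = []
    for start, arm, gap in raw:
        centre = (2 * start + 2 * arm + gap) % (2 * L)
        end = start + 2 * arm + gap
        contained = False
        for ks, ka, kg in kept:
            kc = (2 * ks + 2 * ka + kg) % (2 * L)
            kend = ks + 2 * ka + kg
            if centre == kc and start >= ks and end <= kend:
                contained = True
                break
            if arm == ka and gap == kg and start % L == ks % L:
                contained = True
                break
        if not contained:
            kept.append((start, arm, gap))
    return sorted(kept)
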