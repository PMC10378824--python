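"""Composite replication-origin annotations.

Combines motif hits, hairpins and repeat arrays into the higher-level origin
elements that distinguish theta-like from rolling-circle-like replicons:

* ``AT_RICH``   — a long run of low-GC sequence (candidate origin region);
* ``DNAA_PAIR`` — two DnaA-box hits on opposite strands with overlapping
  intervals, inside (or within 10 nt of) an AT-rich region;
* ``ORIT``      — the conserved 12-mer of a transfer origin (<=1 mismatch),
  with nearby inverted repeats attached as supporting evidence;
* ``DSO``       — the exact double-strand-origin nick heptamer, with flanks;
* ``SSO``       — a CS-6 hexamer presented in the loop of a hairpin
  (single-strand origin); ranked by upstream proximity to a dso if given;
* ``VIRAL_NONA`` — the CRESS-viral nonanucleotide inside the 10-13 nt loop of
  a ~32-nt stem-loop element.

"Upstream" on a circle is the arc ending at the reference feature's start.
An SSO *requires* its structural context (the hairpin loop); an oriT does not
require the adjacent inverted repeats — they are recorded as evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circgenome import CircularSequence, Feature, Interval, gc_content
from .motif_scan import DegenerateMotif, MotifHit, scan
from .repeat_scan import Hairpin, find_inverted_repeats

__all__ = [
    "AT_RICH",
    "DNAA_PAIR",
    "ORIT",
    "DSO",
    "SSO",
    "VIRAL_NONA",
    "OriginLocus",
    "find_at_rich",
    "find_dnaa_pair",
    "find_dso",
    "find_sso",
    "find_orit",
    "find_viral_nona",
    "loci_to_features",
]

AT_RICH = "AT_RICH"
DNAA_PAIR = "DNAA_PAIR"
ORIT = "ORIT"
DSO = "DSO"
SSO = "SSO"
VIRAL_NONA = "VIRAL_NONA"

DNAA_MOTIF = DegenerateMotif("DnaA-box", "ATTTTCAT", 0)
ORIT_MOTIF = DegenerateMotif("oriT", "TAAGTGCGCCCT", 1)
DSO_MOTIF = DegenerateMotif("dso-nick", "CTTGATA", 0)
CS6_MOTIF = DegenerateMotif("CS-6", "TAGCGW", 0)
NONA_MOTIF = DegenerateMotif("viral-nona", "WADTTATAC", 0)


@dataclass
class OriginLocus:
    kind: str
    location: Interval
    evidence: list = field(default_factory=list)
    attributes: dict = field(default_factory=dict)


def find_at_rich(
    s: CircularSequence,
    window: int = 20,
    gc_max: float = 0.30,
    min_len: int = 40,
) -> list[OriginLocus]:
    """Maximal merged runs of low-GC windows, circular-aware.

    Every ``window``-nt sliding window whose GC fraction (N excluded from
    numerator and denominator) is at most ``gc_max`` qualifies; overlapping
    qualifying windows are merged into runs.  Because a window straddling the
    boundary of a low-GC region qualifies on the strength of its low-GC half,
    the full union span overstates the region by about half a window on each
    side; reported locus boundaries are therefore the *centres* of the
    outermost qualifying windows.  Trimmed runs of at least ``min_len`` bases
    are reported with their mean GC.
    """
    L = s.length
    if window > L:
        raise ValueError(f"window {window} exceeds genome length {L}")
    arr = np.frombuffer(s.seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_base = arr != ord("N")

    def _winsum(a: np.ndarray) -> np.ndarray:
        ext = np.concatenate([a, a[: window - 1]])
        cs = np.concatenate([[0], np.cumsum(ext.astype(np.int64))])
        return cs[window : window + L] - cs[:L]

    gc_sum = _winsum(is_gc)
    base_sum = _winsum(is_base)
    win_ok = (base_sum > 0) & (gc_sum <= gc_max * base_sum)
    if win_ok.all():
        mean = gc_content(s)
        return [OriginLocus(AT_RICH, Interval(0, L), attributes={"mean_gc": mean})]
    if not win_ok.any():
        return []
    # merge qualifying window *starts* whose coverage overlaps (gap < window),
    # then trim each merged run to the outermost window centres
    half = window // 2
    tiled = np.concatenate([win_ok, win_ok])
    loci = []
    for i in np.nonzero(win_ok)[0]:
        i = int(i)
        # run starts at i iff no qualifying window begins within `window`
        # positions before it (circularly)
        if any(win_ok[(i - k) % L] for k in range(1, window)):
            continue
        last = i
        j = i + 1
        while j < i + L and j - last < window:
            if tiled[j]:
                last = j
            j += 1
        # the min_len filter applies to the full merged coverage (the
        # detection rule); the reported boundaries are the trimmed ones
        if last + window - i >= min_len and last > i:
            run_start = i + half
            run_end = last + window - half
            start = run_start % L
            iv = Interval(start, start + (run_end - run_start))
            mean = gc_content(s, iv)
            loci.append(OriginLocus(AT_RICH, iv, attributes={"mean_gc": mean}))
    loci.sort(key=lambda lc: lc.location.start)
    return loci


def _within(iv: Interval, region: Interval, L: int) -> bool:
    return iv.overlap(region, L) == iv.length


def find_dnaa_pair(
    s: CircularSequence,
    at_rich: OriginLocus,
    motif: DegenerateMotif = DNAA_MOTIF,
    margin: int = 10,
) -> OriginLocus | None:
    """Closest opposite-strand DnaA hit pair overlapping by >=1 nt in a region."""
    L = s.length
    region = at_rich.location
    # expand on both sides (shift start back by margin, circularly)
    exp_start = (region.start - margin) % L
    exp_len = min(region.length + 2 * margin, L)
    expanded = Interval(exp_start, exp_start + exp_len)
    hits = [h for h in scan(s, motif) if _within(h.location, expanded, L)]
    fwd = [h for h in hits if h.location.strand == "+"]
    rev = [h for h in hits if h.location.strand == "-"]
    best = None
    for hf in fwd:
        for hr in rev:
            ov = hf.location.overlap(hr.location, L)
            if ov < 1:
                continue
            dist = min(
                (hf.location.start - hr.location.start) % L,
                (hr.location.start - hf.location.start) % L,
            )
            key = (dist, min(hf.location.start, hr.location.start))
            if best is None or key < best[0]:
                best = (key, hf, hr, ov)
    if best is None:
        return None
    _, hf, hr, ov = best
    start = min(hf.location.start, hr.location.start)
    end = max(hf.location.end, hr.location.end)
    return OriginLocus(
        DNAA_PAIR,
        Interval(start, end),
        evidence=[hf, hr],
        attributes={"overlap_nt": ov},
    )


def find_dso(s: CircularSequence, motif: DegenerateMotif = DSO_MOTIF, flank: int = 30) -> list[OriginLocus]:
    """One DSO locus per exact nick-site hit, with flanks kept for reporting."""
    loci = []
    for h in scan(s, motif):
        iv = h.location
        loci.append(
            OriginLocus(
                DSO,
                iv,
                evidence=[h],
                attributes={
                    "flank_up": s.fetch(iv.start - flank, iv.start),
                    "flank_down": s.fetch(iv.end, iv.end + flank),
                },
            )
        )
    return loci


def _enclosing_hairpin(
    s: CircularSequence,
    hit: Interval,
    min_arm: int,
    max_arm: int,
    loop_range: tuple[int, int],
) -> Hairpin | None:
    """Best hairpin (max perfect stem) whose loop fully contains ``hit``."""
    L = s.length
    d = s.seq * 3
    best: Hairpin | None = None
    h_start = hit.start + L  # anchor in the middle copy of d
    h_end = h_start + hit.length
    for loop in range(loop_range[0], loop_range[1] + 1):
        if loop < hit.length:
            continue
        for loop_start in range(h_end - loop, h_start + 1):
            for arm in range(max_arm, min_arm - 1, -1):
                if best is not None and arm <= best.stem_length:
                    break
                if 2 * arm + loop > L:
                    continue
                ok = all(
                    _b_pair(d[loop_start - 1 - k], d[loop_start + loop + k])
                    for k in range(arm)
                )
                if ok:
                    start = (loop_start - arm) % L
                    best = Hairpin(Interval(start, start + 2 * arm + loop), arm, loop)
                    break
    return best


def _b_pair(a: str, b: str) -> bool:
    return {"A": "T", "T": "A", "C": "G", "G": "C"}.get(a) == b


def find_sso(
    s: CircularSequence,
    search_upstream_of: Interval | None = None,
    min_arm: int = 5,
    max_arm: int = 15,
    loop_range: tuple[int, int] = (6, 30),
    motif: DegenerateMotif = CS6_MOTIF,
) -> list[OriginLocus]:
    """CS-6 hits presented in a hairpin loop; optionally ranked by upstream
    proximity to a reference (dso) interval on the circle."""
    L = s.length
    loci = []
    for h in scan(s, motif):
        hp = _enclosing_hairpin(s, h.location, min_arm, max_arm, loop_range)
        if hp is None:
            continue
        loci.append(
            OriginLocus(
                SSO,
                hp.location,
                evidence=[h, hp],
                attributes={"stem": hp.stem_length, "loop": hp.loop_length},
            )
        )
    if search_upstream_of is not None:
        ref = search_upstream_of.start
        loci.sort(key=lambda lc: (ref - lc.location.end) % L)
    else:
        loci.sort(key=lambda lc: lc.location.start)
    return loci


def find_orit(
    s: CircularSequence,
    motif: DegenerateMotif = ORIT_MOTIF,
    ir_window: int = 100,
    ir_min_arm: int = 5,
) -> list[OriginLocus]:
    """oriT 12-mer hits (<=1 mismatch); nearby inverted repeats attached as
    evidence but not required."""
    L = s.length
    loci = []
    for h in scan(s, motif):
        iv = h.location
        # look for inverted repeats within ir_window of the hit
        ctx_start = iv.start - ir_window
        ctx_len = min(iv.length + 2 * ir_window, L)
        ctx_seq = s.fetch(ctx_start, ctx_start + ctx_len)
        irs: list[Hairpin] = []
        if ctx_len >= 2 * ir_min_arm:
            ctx = CircularSequence(f"{s.id}:orit_ctx", ctx_seq)
            for hp in find_inverted_repeats(ctx, min_arm=ir_min_arm, max_spacer=30, max_mismatch=0):
                if hp.location.end <= ctx_len:  # ignore folds wrapping the context
                    g_start = (ctx_start + hp.location.start) % L
                    irs.append(
                        Hairpin(
                            Interval(g_start, g_start + hp.span),
                            hp.stem_length,
                            hp.loop_length,
                            hp.mismatches_in_stem,
                        )
                    )
        loci.append(
            OriginLocus(
                ORIT,
                iv,
                evidence=[h, *irs],
                attributes={"mismatches": h.mismatches, "n_inverted_repeats": len(irs)},
            )
        )
    return loci


def find_viral_nona(
    s: CircularSequence,
    motif: DegenerateMotif = NONA_MOTIF,
    loop_range: tuple[int, int] = (10, 13),
    min_arm: int = 6,
    max_arm: int = 15,
    element_span: tuple[int, int] = (25, 40),
) -> list[OriginLocus]:
    """Nonanucleotide hits inside the loop of a ~32-nt stem-loop element."""
    loci = []
    for h in scan(s, motif):
        hp = _enclosing_hairpin(s, h.location, min_arm, max_arm, loop_range)
        if hp is None:
            continue
        if not (element_span[0] <= hp.span <= element_span[1]):
            continue
        loci.append(
            OriginLocus(
                VIRAL_NONA,
                hp.location,
                evidence=[h, hp],
                attributes={"stem": hp.stem_length, "loop": hp.loop_length},
            )
        )
    return loci


def loci_to_features(seq_id: str, loci: list[OriginLocus]) -> list[Feature]:
    feats = []
    for lc in loci:
        attrs = {k: v for k, v in lc.attributes.items() if not isinstance(v, (list, tuple))}
        feats.append(Feature(seq_id, lc.kind, lc.location, attributes=attrs))
    return feats
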