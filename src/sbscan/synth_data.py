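"""Seeded synthetic circular genomes with planted, ground-truthed features.

The generator emulates the two architectures of small circular Rep-encoding
(SPHINX/BMMF-like) genomes plus a CRESS-virus-like control:

* ``GROUP1`` — in order around the circle: a 55-bp AT-rich segment (~23 mol%
  GC) containing an overlapping DnaA-box pair, the 12-bp inverted motif
  TAAATGCTTTTA, an iteron-like tandem array (3 full copies of a random 22-mer
  plus a 10-nt partial copy), the conserved oriT 12-mer, one Rep ORF of
  894-987 nt, and (with probability 0.25) a second ORF of 303-660 nt.
  Genome length 1665-2522 bp, background GC 0.36-0.40.
* ``GROUP2`` — an sso hairpin (8-bp arms, 12-nt loop presenting a CS-6 site)
  upstream of the dso nick site CTTGATA, a Rep ORF of 1017-1317 nt
  (338-438 aa), and two small ORFs (111-145 aa and 96-107 aa) in close
  proximity, overlapping by one nucleotide with probability 0.5.
  Genome length 2299-2442 bp, background GC 0.38-0.42.
* ``VIRAL``  — a ~32-nt stem-loop whose 11-nt loop carries a nonanucleotide
  matching [T/A]A[A/T/G]TTATAC, and a single Rep ORF.
* ``RANDOM`` — background only; the truth record is empty.

Background is i.i.d. at the requested GC (no dinucleotide structure).  Each
planted ORF is written as random sense codons drawn with base-composition
weights at the background GC, and is preceded by an in-frame stop codon so
that the ORF finder's longest-ORF rule recovers exactly the planted start.  The whole construction
is deterministic per seed; the genome is finally rotated by a random offset
so features regularly span the sequence origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .circgenome import CircularSequence, Interval, reverse_complement

__all__ = [
    "GROUP1",
    "GROUP2",
    "VIRAL",
    "RANDOM",
    "GenomeSpec",
    "GenomeSpecError",
    "PlantedFeature",
    "TruthRecord",
    "generate",
    "generate_batch",
    "mutate_features",
]

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
VIRAL = "VIRAL"
RANDOM = "RANDOM"

_LENGTH_RANGES = {GROUP1: (1665, 2522), GROUP2: (2299, 2442), VIRAL: (1800, 2200), RANDOM: (1665, 2522)}
_GC_RANGES = {GROUP1: (0.36, 0.40), GROUP2: (0.38, 0.42), VIRAL: (0.36, 0.42), RANDOM: (0.36, 0.42)}

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)

DNAA_CONSTRUCT = "ATTTTCATGAAAAT"  # one DnaA 8-mer per strand, 2-nt overlap
INV12 = "TAAATGCTTTTA"
ORIT_12MER = "TAAGTGCGCCCT"
DSO_SITE = "CTTGATA"


class GenomeSpecError(ValueError):
    """Planted features do not fit the requested genome length."""


@dataclass(frozen=True)
class GenomeSpec:
    mode: str = GROUP1
    length: int | None = None  # drawn from the mode's range when None
    background_gc: float | None = None
    seed: int = 0
    include_orf2: bool | None = None  # GROUP1: drawn w.p. 0.25 when None
    overlap_small_orfs: bool | None = None  # GROUP2: drawn w.p. 0.5 when None
    itr_copies: int = 3
    itr_unit_length: int = 22
    itr_partial_nt: int = 10

    def __post_init__(self) -> None:
        if self.mode not in (GROUP1, GROUP2, VIRAL, RANDOM):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PlantedFeature:
    kind: str
    interval: Interval
    sequence: str
    mutations: tuple[tuple[int, str, str], ...] = ()  # (position, old, new)


@dataclass(frozen=True)
class TruthRecord:
    spec: GenomeSpec
    features: tuple[PlantedFeature, ...]

    def get(self, kind: str) -> PlantedFeature | None:
        for f in self.features:
            if f.kind == kind:
                return f
        return None

    def all(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]


def _other_base(rng: np.random.Generator, base: str) -> str:
    """A uniformly drawn base different from ``base``."""
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _codon_weights(gc: float) -> np.ndarray:
    """Sense-codon probabilities from i.i.d. base frequencies at ``gc``."""
    p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in _SENSE_CODONS])
    return w / w.sum()


def _random_orf(
    rng: np.random.Generator,
    nt_length: int,
    start_codon: str = "ATG",
    gc: float = 0.39,
) -> str:
    """A CDS of nt_length (including stop): start + random sense codons + stop.

    Codons are drawn with probabilities derived from i.i.d. bases at the
    background GC (conditioned on not being a stop), so coding regions do not
    distort the genome-wide base composition.
    """
    if nt_length % 3 or nt_length < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    n_body = nt_length // 3 - 2
    idx = rng.choice(len(_SENSE_CODONS), size=n_body, p=_codon_weights(gc))
    body = "".join(_SENSE_CODONS[i] for i in idx)
    stop = _STOPS[rng.integers(0, 3)]
    return start_codon + body + stop


def _at_rich_segment(rng: np.random.Generator, length: int = 55, gc: float = 0.23) -> tuple[str, int]:
    """AT-rich segment containing the DnaA pair construct; returns (seq, offset
    of the construct within the segment).

    The segment realizes the requested composition exactly (GC count rounded
    to the nearest base, including the construct's contribution) rather than
    in expectation: an i.i.d. draw would miss the target by several points a
    few percent of the time, which would make the planted region undetectable
    as an AT-rich locus in those genomes.
    """
    n_free = length - len(DNAA_CONSTRUCT)
    construct_gc = sum(b in "GC" for b in DNAA_CONSTRUCT)
    n_gc_free = max(0, round(gc * length) - construct_gc)
    bases = np.empty(n_free, dtype="<U1")
    gc_pos = rng.permutation(n_free)[:n_gc_free]
    is_gc = np.zeros(n_free, dtype=bool)
    is_gc[gc_pos] = True
    bases[is_gc] = np.where(rng.random(n_gc_free) < 0.5, "G", "C")
    bases[~is_gc] = np.where(rng.random(n_free - n_gc_free) < 0.5, "A", "T")
    free = "".join(bases)
    offset = int(rng.integers(1, n_free))  # keep construct off the segment edges
    seq = free[:offset] + DNAA_CONSTRUCT + free[offset:]
    return seq, offset


def _hairpin_with_loop_site(
    rng: np.random.Generator, site: str, arm: int, loop_len: int, gc: float
) -> tuple[str, int]:
    """arm + loop(containing site) + revcomp(arm); returns (seq, site offset).

    The loop's terminal bases are kept non-complementary so the stem cannot
    grow inward past the intended loop boundary: the planted (arm, loop)
    geometry is then the hairpin's true maximal fold.
    """
    if loop_len < len(site):
        raise ValueError("loop shorter than the site it must present")
    if loop_len - len(site) < 1:
        raise ValueError("loop needs at least one free base beside the site")
    arm_seq = _random_dna(rng, arm, gc)
    pad = loop_len - len(site)
    off = int(rng.integers(0, pad + 1))
    loop = _random_dna(rng, pad, gc)
    loop = loop[:off] + site + loop[off:]
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if pair[loop[0]] == loop[-1]:
        if off < pad:  # last base is free pad: re-draw it
            loop = loop[:-1] + _other_base(rng, loop[-1])
        else:  # site sits at the loop end: re-draw the first base instead
            loop = _other_base(rng, loop[0]) + loop[1:]
        # _other_base may still complement; walk until it does not
        while pair[loop[0]] == loop[-1]:
            if off < pad:
                loop = loop[:-1] + _other_base(rng, loop[-1])
            else:
                loop = _other_base(rng, loop[0]) + loop[1:]
    return arm_seq + loop + reverse_complement(arm_seq), arm + off


def _layout(
    rng: np.random.Generator,
    mode: str,
    cassettes: list[tuple[str, list[tuple[str, int, int]]]],
    spec: GenomeSpec,
    background_gc: float,
) -> tuple[str, list[PlantedFeature]]:
    """Place cassettes in order with random spacers on an i.i.d. background.

    Each cassette is ``(sequence, annotations)`` where every annotation
    (kind, truth_offset, truth_length) marks a planted feature within the
    cassette (guard stops and hairpin arms may sit outside truth intervals;
    one cassette may carry several features, e.g. overlapping ORFs).
    """
    total_feature_nt = sum(len(seq) for seq, _ in cassettes)
    lo, hi = _LENGTH_RANGES[mode]
    min_needed = total_feature_nt + 4 * (len(cassettes) + 1)  # >=4 nt spacers
    length = spec.length
    if length is None:
        if max(lo, min_needed) > hi:
            raise GenomeSpecError(
                f"features ({total_feature_nt} nt) do not fit any genome length "
                f"in [{lo}, {hi}]"
            )
        length = int(rng.integers(max(lo, min_needed), hi + 1))
    if length < min_needed:
        raise GenomeSpecError(
            f"features require at least {min_needed} nt but genome length is {length}"
        )
    slack = length - total_feature_nt - 4 * (len(cassettes) + 1)
    cuts = np.sort(rng.integers(0, slack + 1, size=len(cassettes)))
    gaps = np.diff(np.concatenate([[0], cuts, [slack]])) + 4

    parts: list[str] = []
    features: list[PlantedFeature] = []
    pos = 0
    for gap, (seq, annots) in zip(gaps, cassettes):
        parts.append(_random_dna(rng, int(gap), background_gc))
        pos += int(gap)
        for kind, t_off, t_len in annots:
            features.append(
                PlantedFeature(
                    kind,
                    Interval(pos + t_off, pos + t_off + t_len),
                    seq[t_off : t_off + t_len],
                )
            )
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_dna(rng, int(gaps[-1]), background_gc))
    genome = "".join(parts)
    assert len(genome) == length, (len(genome), length)

    # rotate so that features may span the sequence origin
    rot = int(rng.integers(0, length))
    genome = genome[rot:] + genome[:rot]
    features = [
        replace(f, interval=f.interval.shift(rot, length)) for f in features
    ]
    return genome, features


def generate(spec: GenomeSpec) -> tuple[CircularSequence, TruthRecord]:
    """Generate one synthetic circular genome and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    mode = spec.mode
    gc_lo, gc_hi = _GC_RANGES[mode]
    bg = spec.background_gc
    if bg is None:
        bg = float(rng.uniform(gc_lo, gc_hi))
    cassettes: list[tuple[str, list[tuple[str, int, int]]]] = []

    if mode == GROUP1:
        at_seq, _ = _at_rich_segment(rng)
        cassettes.append((at_seq, [("AT_RICH", 0, len(at_seq))]))
        cassettes.append((INV12, [("INV12", 0, len(INV12))]))
        unit = _random_dna(rng, spec.itr_unit_length, bg)
        itr = unit * spec.itr_copies + unit[: spec.itr_partial_nt]
        # guard bases break accidental continuation of the repeat period into
        # the flanks, so the planted (unit, copies, tail) triple is the unique
        # maximal description of the array
        gl = _other_base(rng, unit[-1])
        gr = "".join(
            _other_base(rng, unit[(spec.itr_partial_nt + k) % len(unit)])
            for k in range(3)
        )
        cassettes.append((gl + itr + gr, [("ITR_ARRAY", 1, len(itr))]))
        cassettes.append((ORIT_12MER, [("ORIT", 0, len(ORIT_12MER))]))
        rep_nt = 3 * int(rng.integers(298, 330))  # 894..987 nt incl. stop
        rep = "TAA" + _random_orf(rng, rep_nt, gc=bg)
        cassettes.append((rep, [("ORF_REP", 3, rep_nt)]))
        include2 = spec.include_orf2
        if include2 is None:
            include2 = bool(rng.random() < 0.25)
        if include2:
            orf2_nt = 3 * int(rng.integers(101, 221))  # 303..660 nt
            orf2 = "TAA" + _random_orf(rng, orf2_nt, gc=bg)
            cassettes.append((orf2, [("ORF2", 3, orf2_nt)]))
    elif mode == GROUP2:
        site = "TAGCGA" if rng.random() < 0.5 else "TAGCGT"
        sso_seq, _ = _hairpin_with_loop_site(rng, site, arm=8, loop_len=12, gc=bg)
        cassettes.append((sso_seq, [("SSO", 0, len(sso_seq))]))
        cassettes.append((DSO_SITE, [("DSO", 0, len(DSO_SITE))]))
        rep_nt = 3 * int(rng.integers(339, 440))  # 1017..1317 nt (338-438 aa)
        rep = "TAA" + _random_orf(rng, rep_nt, gc=bg)
        cassettes.append((rep, [("ORF_REP", 3, rep_nt)]))
        small1_nt = 3 * int(rng.integers(112, 147))  # 111-145 aa
        small2_nt = 3 * int(rng.integers(97, 109))  # 96-107 aa
        overlap = spec.overlap_small_orfs
        if overlap is None:
            overlap = bool(rng.random() < 0.5)
        if overlap:
            # small2 begins on the final A of small1's TAA stop (1-nt overlap):
            # cassette = guard TAA + small1 (forced TAA stop) + "TG" + rest of
            # small2, so that cassette[3+small1_nt-1:] starts A|TG...
            s1 = _random_orf(rng, small1_nt, "ATG", gc=bg)[:-3] + "TAA"
            s2 = _random_orf(rng, small2_nt, "ATG", gc=bg)
            cassette = "TAA" + s1 + "TG" + s2[3:]
            cassettes.append(
                (
                    cassette,
                    [
                        ("ORF_SMALL1", 3, small1_nt),
                        ("ORF_SMALL2", 3 + small1_nt - 1, small2_nt),
                    ],
                )
            )
        else:
            s1 = "TAA" + _random_orf(rng, small1_nt, gc=bg)
            cassettes.append((s1, [("ORF_SMALL1", 3, small1_nt)]))
            s2 = "TAA" + _random_orf(rng, small2_nt, gc=bg)
            cassettes.append((s2, [("ORF_SMALL2", 3, small2_nt)]))
    elif mode == VIRAL:
        w = "TA"[int(rng.integers(0, 2))]
        dd = "ATG"[int(rng.integers(0, 3))]
        nona = w + "A" + dd + "TTATAC"
        hp_seq, _ = _hairpin_with_loop_site(rng, nona, arm=10, loop_len=11, gc=bg)
        cassettes.append((hp_seq, [("VIRAL_NONA", 0, len(hp_seq))]))
        rep_nt = 3 * int(rng.integers(298, 330))
        rep = "TAA" + _random_orf(rng, rep_nt, gc=bg)
        cassettes.append((rep, [("ORF_REP", 3, rep_nt)]))

    if mode == RANDOM:
        lo, hi = _LENGTH_RANGES[mode]
        length = spec.length or int(rng.integers(lo, hi + 1))
        genome = _random_dna(rng, length, bg)
        features: list[PlantedFeature] = []
    else:
        genome, features = _layout(rng, mode, cassettes, spec, bg)

    seq_id = f"{mode.lower()}_{spec.seed}"
    return CircularSequence(seq_id, genome), TruthRecord(spec, tuple(features))


def generate_batch(
    mode: str, n: int, seed: int, **kwargs
) -> list[tuple[CircularSequence, TruthRecord]]:
    """n genomes with per-genome seeds seed, seed+1, ..."""
    out = []
    for i in range(n):
        spec = GenomeSpec(mode=mode, seed=seed + i, **kwargs)
        out.append(generate(spec))
    return out


def mutate_features(
    genome: CircularSequence,
    truth: TruthRecord,
    rate: float,
    seed: int,
) -> tuple[CircularSequence, TruthRecord]:
    """Apply per-base substitutions inside planted features only.

    Every substitution replaces a base by a uniformly drawn *different* base
    and is recorded in the returned truth record.  ``rate=0`` is the identity.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = genome.length
    seq = list(genome.seq)
    new_features = []
    mutated_positions: set[int] = set()
    for f in truth.features:
        muts = []
        for p in f.interval.positions(L):
            if rng.random() >= rate or p in mutated_positions:
                continue
            old = seq[p]
            choices = [b for b in "ACGT" if b != old]
            new = choices[rng.integers(0, 3)]
            seq[p] = new
            muts.append((p, old, new))
            mutated_positions.add(p)
        new_features.append(replace(f, mutations=tuple(muts)))
    return (
        CircularSequence(genome.id, "".join(seq)),
        TruthRecord(truth.spec, tuple(new_features)),
    )
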