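"""Group-1 / group-2 classification and replication-mechanism verdict.

The call is a pure, deterministic function of the annotated feature set:

* ``GROUP1`` requires exactly one Rep-sized ORF (270-332 aa), an iteron-like
  tandem array, and either the 12-bp inverted motif or an AT-rich region.
* ``GROUP2`` requires a Rep-sized ORF (333-460 aa), a dso nick locus, and an
  sso (CS-6-in-hairpin) locus; the two small ORFs add evidence only.

The outer aa bounds are the observed ranges for each group widened by ~10% so
that boundary genomes do not flip on a single codon; between the two groups
the observed ranges are disjoint (up to 328 aa vs at least 338 aa), so the
decision boundary is placed at their midpoint (333 aa) rather than letting
the windows overlap — overlapping windows would let a short-ORF genome with a
chance nick-site heptamer satisfy both groups at once.  When both minimal
feature sets are nevertheless met the genome stays ``UNCLASSIFIED`` with both
evidence sets: the evidence is contradictory and no group is forced.

Mechanism verdict: ``RCR_LIKE`` iff dso and sso are both present;
``THETA_LIKE`` iff iterons, an AT-rich region, and a DnaA pair are present
without a dso; ``VIRAL_LIKE`` iff a viral nonanucleotide stem-loop is present;
anything else (including conflicts) is ``INCONCLUSIVE``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .circgenome import CircularSequence, gc_content
from .motif_scan import DegenerateMotif, scan
from .orf_scan import OrfFeature
from .origin_annot import AT_RICH, DNAA_PAIR, DSO, ORIT, SSO, VIRAL_NONA, OriginLocus
from .repeat_scan import RepeatArray

__all__ = ["GroupCall", "ClassifierConfig", "classify_genome", "batch_report"]

GROUP1 = "GROUP1"
GROUP2 = "GROUP2"
UNCLASSIFIED = "UNCLASSIFIED"

THETA_LIKE = "THETA_LIKE"
RCR_LIKE = "RCR_LIKE"
VIRAL_LIKE = "VIRAL_LIKE"
INCONCLUSIVE = "INCONCLUSIVE"

INV12_MOTIF = DegenerateMotif("inv12", "TAAATGCTTTTA", 0)


@dataclass(frozen=True)
class ClassifierConfig:
    g1_rep_aa: tuple[int, int] = (270, 332)  # 297-328 aa, widened below, midpoint above
    g2_rep_aa: tuple[int, int] = (333, 460)  # 338-438 aa, midpoint below, widened above
    small_orf_aa: tuple[int, int] = (90, 160)  # 96-145 aa widened


@dataclass
class GroupCall:
    seq_id: str
    length: int
    gc_mol_percent: float
    group: str
    mechanism_verdict: str
    feature_checklist: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)


def _in_range(x: int, rng: tuple[int, int]) -> bool:
    return rng[0] <= x <= rng[1]


def classify_genome(
    s: CircularSequence,
    orfs: list[OrfFeature],
    arrays: list[RepeatArray],
    origins: list[OriginLocus],
    config: ClassifierConfig = ClassifierConfig(),
) -> GroupCall:
    """Aggregate ORF/repeat/origin evidence into a deterministic group call."""
    kinds = {k: [o for o in origins if o.kind == k] for k in
             (AT_RICH, DNAA_PAIR, ORIT, DSO, SSO, VIRAL_NONA)}
    inv12_hits = scan(s, INV12_MOTIF)

    g1_reps = [o for o in orfs if _in_range(o.aa_length, config.g1_rep_aa)]
    g2_reps = [o for o in orfs if _in_range(o.aa_length, config.g2_rep_aa)]
    smalls = [o for o in orfs if _in_range(o.aa_length, config.small_orf_aa)]
    itr_arrays = [a for a in arrays if a.full_copies >= 2]

    checklist = {
        "rep_orf_group1_size": {
            "present": len(g1_reps) == 1,
            "count": len(g1_reps),
            "locations": [o.location for o in g1_reps],
        },
        "rep_orf_group2_size": {
            "present": bool(g2_reps),
            "count": len(g2_reps),
            "locations": [o.location for o in g2_reps],
        },
        "small_orfs": {
            "present": len(smalls) >= 2,
            "count": len(smalls),
            "locations": [o.location for o in smalls],
        },
        "itr_array": {
            "present": bool(itr_arrays),
            "locations": [a.location for a in itr_arrays],
        },
        "inverted_12bp_motif": {
            "present": bool(inv12_hits),
            "locations": [h.location for h in inv12_hits],
        },
        "at_rich_region": {
            "present": bool(kinds[AT_RICH]),
            "locations": [o.location for o in kinds[AT_RICH]],
        },
        "dnaa_pair": {
            "present": bool(kinds[DNAA_PAIR]),
            "locations": [o.location for o in kinds[DNAA_PAIR]],
        },
        "oriT": {
            "present": bool(kinds[ORIT]),
            "locations": [o.location for o in kinds[ORIT]],
        },
        "dso": {
            "present": bool(kinds[DSO]),
            "locations": [o.location for o in kinds[DSO]],
        },
        "sso": {
            "present": bool(kinds[SSO]),
            "locations": [o.location for o in kinds[SSO]],
        },
        "viral_nonanucleotide": {
            "present": bool(kinds[VIRAL_NONA]),
            "locations": [o.location for o in kinds[VIRAL_NONA]],
        },
        "pfam_family": {"present": None, "note": "not assessed (no homology search)"},
    }

    g1_ok = (
        len(g1_reps) == 1
        and bool(itr_arrays)
        and (bool(inv12_hits) or bool(kinds[AT_RICH]))
    )
    g2_ok = bool(g2_reps) and bool(kinds[DSO]) and bool(kinds[SSO])
    if g1_ok and not g2_ok:
        group = GROUP1
    elif g2_ok and not g1_ok:
        group = GROUP2
    else:
        group = UNCLASSIFIED

    rcr = bool(kinds[DSO]) and bool(kinds[SSO])
    theta = (
        bool(itr_arrays)
        and bool(kinds[AT_RICH])
        and bool(kinds[DNAA_PAIR])
        and not kinds[DSO]
    )
    viral = bool(kinds[VIRAL_NONA])
    verdicts = [v for v, on in ((RCR_LIKE, rcr), (THETA_LIKE, theta), (VIRAL_LIKE, viral)) if on]
    verdict = verdicts[0] if len(verdicts) == 1 else INCONCLUSIVE

    score = {
        GROUP1: sum(
            [
                len(g1_reps) == 1,
                bool(itr_arrays),
                bool(inv12_hits),
                bool(kinds[AT_RICH]),
                bool(kinds[DNAA_PAIR]),
                bool(kinds[ORIT]),
            ]
        ),
        GROUP2: sum(
            [
                bool(g2_reps),
                bool(kinds[DSO]),
                bool(kinds[SSO]),
                len(smalls) >= 2,
            ]
        ),
    }

    return GroupCall(
        seq_id=s.id,
        length=s.length,
        gc_mol_percent=round(100 * gc_content(s), 1),
        group=group,
        mechanism_verdict=verdict,
        feature_checklist=checklist,
        score=score,
    )


def batch_report(calls: list[GroupCall]) -> pd.DataFrame:
    """Per-genome summary table; group counts in ``df.attrs['group_counts']``."""
    rows = []
    for c in calls:
        row = {
            "id": c.seq_id,
            "length": c.length,
            "gc_mol_percent": c.gc_mol_percent,
            "group": c.group,
            "verdict": c.mechanism_verdict,
        }
        for feat, info in c.feature_checklist.items():
            if info.get("present") is not None:
                row[feat] = bool(info["present"])
        rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["group_counts"] = dict(Counter(c.group for c in calls))
    return df
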