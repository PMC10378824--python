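"""End-to-end per-genome annotation shared by the CLI and the test suite."""

from __future__ import annotations

from dataclasses import dataclass, field

from .circgenome import CircularSequence, Feature
from .classify import ClassifierConfig, GroupCall, classify_genome
from .config import RunConfig
from .motif_scan import MotifHit, scan
from .orf_scan import OrfFeature, find_orfs, orfs_to_features
from .origin_annot import (
    OriginLocus,
    find_at_rich,
    find_dnaa_pair,
    find_dso,
    find_orit,
    find_sso,
    find_viral_nona,
    loci_to_features,
)
from .repeat_scan import RepeatArray, arrays_to_features, find_tandem_arrays

__all__ = ["Annotation", "annotate_genome", "classify_genomes"]


@dataclass
class Annotation:
    seq: CircularSequence
    orfs: list[OrfFeature]
    arrays: list[RepeatArray]
    origins: list[OriginLocus]
    motif_hits: dict[str, list[MotifHit]] = field(default_factory=dict)

    def features(self) -> list[Feature]:
        return (
            orfs_to_features(self.seq.id, self.orfs)
            + arrays_to_features(self.seq.id, self.arrays)
            + loci_to_features(self.seq.id, self.origins)
        )


def annotate_genome(s: CircularSequence, config: RunConfig | None = None) -> Annotation:
    """Run every detector on one genome and collect the evidence."""
    cfg = config or RunConfig()
    orfs = find_orfs(s, min_nt=cfg.orf_min_nt, min_aa_report=cfg.orf_min_aa,
                     starts=tuple(cfg.orf_starts))
    arrays = find_tandem_arrays(
        s,
        unit_range=cfg.itr_unit_range,
        min_copies=cfg.itr_min_copies,
        max_mismatch_per_copy=cfg.itr_max_mismatch,
    )
    origins: list[OriginLocus] = []
    at_loci = find_at_rich(s, window=cfg.at_window, gc_max=cfg.at_gc_max,
                           min_len=cfg.at_min_len)
    origins.extend(at_loci)
    for at in at_loci:
        pair = find_dnaa_pair(s, at)
        if pair is not None:
            origins.append(pair)
    dso_loci = find_dso(s)
    origins.extend(dso_loci)
    ref = dso_loci[0].location if dso_loci else None
    origins.extend(find_sso(s, search_upstream_of=ref))
    origins.extend(find_orit(s))
    origins.extend(find_viral_nona(s))
    motif_hits = {m.name: scan(s, m) for m in cfg.motifs}
    return Annotation(s, orfs, arrays, origins, motif_hits)


def classify_genomes(
    seqs: list[CircularSequence], config: RunConfig | None = None
) -> list[GroupCall]:
    cfg = config or RunConfig()
    calls = []
    for s in seqs:
        ann = annotate_genome(s, cfg)
        calls.append(
            classify_genome(
                s,
                ann.orfs,
                ann.arrays,
                ann.origins,
                ClassifierConfig(
                    g1_rep_aa=cfg.g1_rep_aa,
                    g2_rep_aa=cfg.g2_rep_aa,
                    small_orf_aa=cfg.small_orf_aa,
                ),
            )
        )
    return calls
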