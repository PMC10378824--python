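"""Tandem arrays, ITR typing, hairpin folding and inverted repeats."""

import numpy as np
import pytest

import _oracles as oracle
from sbscan.circgenome import CircularSequence, reverse_complement
from sbscan.repeat_scan import (
    ItrMotif,
    find_inverted_repeats,
    find_tandem_arrays,
    fold_hairpin,
    type_itr,
)
from sbscan.synth_data import GenomeSpec, generate


class TestTandemArrays:
    def test_planted_triple_recovered_exactly(self):
        g, truth = generate(GenomeSpec(mode="GROUP1", seed=7))
        itr = truth.get("ITR_ARRAY")
        unit = itr.sequence[:22]
        arrays = [
            a
            for a in find_tandem_arrays(g)
            if a.location.overlap(itr.interval, g.length) > 30
        ]
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.unit_length, a.full_copies, a.partial_tail_nt) == (22, 3, 10)
        assert a.consensus == unit
        assert a.location.start == itr.interval.start % g.length

    def test_planted_triples_exact_across_100_seeds(self):
        for seed in range(1, 101):
            g, truth = generate(GenomeSpec(mode="GROUP1", seed=seed))
            itr = truth.get("ITR_ARRAY")
            arrays = [
                a
                for a in find_tandem_arrays(g)
                if a.location.overlap(itr.interval, g.length) > 30
            ]
            assert arrays, seed
            a = arrays[0]
            assert (a.unit_length, a.full_copies, a.partial_tail_nt) == (22, 3, 10), seed
            assert a.consensus == itr.sequence[:22], seed

    def test_homopolymer_has_no_array_in_unit_range(self):
        s = CircularSequence("x", "A" * 200)
        # period collapses to 1; every candidate is left-extendable, so no
        # chain start exists in the 15-30 unit range
        assert find_tandem_arrays(s, unit_range=(15, 30)) == []

    def test_rotation_invariance_of_planted_array(self):
        g, truth = generate(GenomeSpec(mode="GROUP1", seed=13))
        itr = truth.get("ITR_ARRAY")
        for offset in (5, 500, 1500):
            rot = g.rotate_to((itr.interval.start - offset) % g.length)
            arrays = find_tandem_arrays(rot)
            match = [
                a
                for a in arrays
                if (a.unit_length, a.full_copies, a.partial_tail_nt) == (22, 3, 10)
            ]
            assert any(a.consensus == itr.sequence[:22] for a in match)

    def test_matches_exhaustive_oracle_on_short_sequences(self, rng):
        for trial in range(6):
            n = int(rng.integers(120, 260))
            seq = list("".join(rng.choice(list("ACGT"), size=n)))
            if trial % 2 == 0:  # plant an array so the comparison is non-trivial
                u = int(rng.integers(15, 25))
                unit = "".join(rng.choice(list("ACGT"), size=u))
                arr = unit * 2 + unit[:8]
                pos = int(rng.integers(0, n - len(arr)))
                seq[pos : pos + len(arr)] = arr
            seq = "".join(seq)
            got = [
                (a.location.start, a.unit_length, a.full_copies, a.partial_tail_nt, a.consensus)
                for a in find_tandem_arrays(CircularSequence("x", seq), unit_range=(15, 30))
            ]
            want = oracle.tandem_arrays(seq, unit_range=(15, 30))
            assert sorted(got) == want, trial

    def test_unit_range_validated(self):
        s = CircularSequence("x", "ACGT" * 20)
        with pytest.raises(ValueError):
            find_tandem_arrays(s, unit_range=(2, 30))


class TestTypeItr:
    def test_exact_catalog_match(self):
        catalog = [ItrMotif("ITR-1", "A" * 22), ItrMotif("ITR-2", "C" * 22)]
        assert type_itr("A" * 22, catalog) == "ITR-1"
        assert len(catalog) == 2

    def test_beyond_threshold_mints_new_id(self):
        catalog = [ItrMotif("ITR-1", "A" * 22)]
        query = "TTTT" + "A" * 18  # Hamming distance 4
        new_id = type_itr(query, catalog, max_mismatch=3)
        assert new_id == "ITR-2"
        assert len(catalog) == 2
        assert catalog[1].consensus == query

    def test_tie_goes_to_lowest_catalog_index(self):
        catalog = [ItrMotif("ITR-1", "A" * 22), ItrMotif("ITR-2", "A" * 21 + "C")]
        query = "A" * 21 + "G"  # distance 1 from both
        assert type_itr(query, catalog) == "ITR-1"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            type_itr("ACGT", [ItrMotif("ITR-1", "A" * 22)])

    def test_fourteen_planted_motifs_recovered_from_noisy_copies(self, rng):
        # noisy copies (<=1 substitution) of 14 well-separated 22-mers
        planted = []
        while len(planted) < 14:
            cand = "".join(rng.choice(list("ACGT"), size=22))
            if all(oracle.ham(cand, p) > 8 for p in planted):
                planted.append(cand)
        consensi = []
        for _ in range(56):
            base = list(planted[int(rng.integers(0, 14))])
            if rng.random() < 0.7:
                pos = int(rng.integers(0, 22))
                base[pos] = [b for b in "ACGT" if b != base[pos]][int(rng.integers(0, 3))]
            consensi.append("".join(base))
        consensi.extend(planted)  # ensure every motif is observed
        catalog: list[ItrMotif] = []
        for c in consensi:
            type_itr(c, catalog, max_mismatch=3)
        assert len(catalog) == 14

    def test_deterministic_under_input_permutation_with_fixed_catalog(self, rng):
        start = [ItrMotif(f"ITR-{i+1}", "".join(rng.choice(list("ACGT"), 22))) for i in range(5)]
        queries = ["".join(rng.choice(list("ACGT"), 22)) for _ in range(20)]
        import copy

        def run(qs):
            cat = copy.deepcopy(start)
            return {q: type_itr(q, cat) for q in qs if True}

        a = run(queries)
        b = run(list(reversed(queries)))
        # assignments to *existing* catalog entries must agree regardless of order
        for q in queries:
            if a[q].startswith("ITR-") and int(a[q][4:]) <= 5:
                assert b[q] == a[q]


class TestFoldHairpin:
    def test_twelve_bp_inverted_motif_folds_with_four_nt_loop(self):
        hp = fold_hairpin("TAAATGCTTTTA")
        assert (hp.stem_length, hp.loop_length) == (4, 4)

    def test_homopolymer_cannot_fold(self):
        assert fold_hairpin("AAAAAAAA") is None

    def test_motif_too_short_cannot_fold(self):
        assert fold_hairpin("ACGT") is None

    def test_matches_exhaustive_oracle_on_random_40mers(self, rng):
        for _ in range(40):
            motif = "".join(rng.choice(list("ACGT"), size=40))
            got = fold_hairpin(motif)
            want = oracle.best_fold(motif)
            if want is None:
                assert got is None
            else:
                assert (got.stem_length, got.loop_length) == want

    def test_fold_invariant_under_reverse_complement(self, rng):
        for _ in range(30):
            motif = "".join(rng.choice(list("ACGT"), size=24))
            a = fold_hairpin(motif)
            b = fold_hairpin(reverse_complement(motif))
            if a is None:
                assert b is None
            else:
                assert (a.stem_length, a.loop_length) == (b.stem_length, b.loop_length)


class TestInvertedRepeats:
    def test_planted_perfect_arm_pair_found_exactly(self, rng):
        arm = "GATTACAG"
        spacer = "".join(rng.choice(list("ACGT"), size=10))
        insert = arm + spacer + reverse_complement(arm)
        bg = "".join(rng.choice(list("AC"), size=200))  # AC-only background cannot pair
        seq = bg[:90] + insert + bg[90:]
        hits = find_inverted_repeats(CircularSequence("x", seq), min_arm=5, max_mismatch=0)
        match = [h for h in hits if h.stem_length >= 8 and h.loop_length == 10]
        assert any(h.location.start == 90 for h in match)

    def test_mirrored_on_reverse_complemented_genome(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        L = len(seq)
        a = find_inverted_repeats(CircularSequence("x", seq), max_mismatch=0)
        b = find_inverted_repeats(CircularSequence("x", reverse_complement(seq)), max_mismatch=0)
        mirror = sorted(((L - h.location.end) % L, h.stem_length, h.loop_length) for h in a)
        got = sorted((h.location.start % L, h.stem_length, h.loop_length) for h in b)
        assert mirror == got

    def test_matches_exhaustive_oracle_on_short_sequences(self, rng):
        for trial in range(5):
            n = int(rng.integers(80, 200))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            got = sorted(
                (h.location.start, h.stem_length, h.loop_length)
                for h in find_inverted_repeats(
                    CircularSequence("x", seq), min_arm=5, max_spacer=30, max_mismatch=1
                )
            )
            want = oracle.inverted_repeats(seq, min_arm=5, max_spacer=30, max_mm=1)
            assert got == want, trial
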