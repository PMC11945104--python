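"""Homology search, folding, star derivation and hairpin validation."""

import numpy as np
import pandas as pd
import pytest

from curesmir import discovery, preprocess
from curesmir._utils import pair_table, revcomp, to_rna
from curesmir.preprocess import UniqueReadTable

# mature sequences of two conserved miR398 family members that differ by a
# single 5'-terminal base, a classic within-family relationship
MIR398A = "CGUGUUCUCAGGUCGCCCCUG"
MIR398B = "UGUGUUCUCAGGUCGCCCCUG"
MIR168A = "UCGCUUGGUACAGGUCGGGAA"
MIR168B = "UCGCUUGGUGCAGGUCGGGAA"


def brute_force_distance(a: str, b: str) -> int:
    """Independent oracle: minimum over all offsets of Hamming-over-overlap
    plus unmatched footprint positions."""
    a, b = to_rna(a), to_rna(b)
    la, lb = len(a), len(b)
    span = max(la, lb)
    best = span
    for off in range(-lb + 1, la):
        s, e = max(0, off), min(la, off + lb)
        if e <= s:
            continue
        ham = sum(a[i] != b[i - off] for i in range(s, e))
        best = min(best, ham + span - (e - s))
    return best


def _random_read(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


def _as_table(seqs, lib="lib"):
    return UniqueReadTable(pd.DataFrame({lib: 1}, index=pd.Index(sorted(set(seqs)))))


class TestHomologySearch:
    def test_identical_read_scores_zero(self):
        table = _as_table([MIR398A])
        hits = discovery.homology_search(table, {"ref-miR398a": MIR398A})
        assert len(hits) == 1 and hits[0].reference_mismatches == 0

    def test_single_base_family_differences(self):
        """Within-family matures differing by one base score one mismatch."""
        assert discovery.sliding_distance(MIR398A, MIR398B) == 1
        assert discovery.sliding_distance(MIR168A, MIR168B) == 1

    def test_ties_break_lexicographically(self):
        table = _as_table([MIR398A])
        hits = discovery.homology_search(
            table, {"zzz-miR398": MIR398A, "aaa-miR398": MIR398A})
        assert hits[0].best_reference == "aaa-miR398"

    def test_empty_reference_warns(self):
        with pytest.warns(UserWarning, match="empty reference"):
            assert discovery.homology_search(_as_table([MIR398A]), {}) == []

    def test_matches_brute_force_on_random_instances(self):
        """The vectorized search equals an all-pairs brute-force scan."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            reads = [_random_read(rng, int(rng.integers(18, 26))) for _ in range(30)]
            refs = {f"r{j}": _random_read(rng, int(rng.integers(19, 23)))
                    for j in range(4)}
            # make some reads near-misses of references
            for j, r in enumerate(list(refs.values())[:3]):
                mutated = list(r)
                for pos in rng.choice(len(r), size=int(rng.integers(0, 4)), replace=False):
                    mutated[pos] = "ACGU"[int(rng.integers(0, 4))]
                reads.append("".join(mutated))
            table = _as_table(reads)
            hits = {c.sequence: c.reference_mismatches
                    for c in discovery.homology_search(table, refs)}
            expected = {}
            for s in table.sequences():
                d = min(brute_force_distance(s, r) for r in refs.values())
                if d <= 3:
                    expected[s] = d
            assert hits == expected


class TestTranscriptPlacement:
    def test_planted_mature_found_at_truth_span(self, dataset):
        for m in dataset.truth.planted_mirnas:
            hits = discovery.locate_on_transcripts(m.mature, dataset.transcripts)
            assert (m.transcript_id, m.mature_span, "+") in hits

    def test_absent_candidate_yields_empty(self, dataset):
        assert discovery.locate_on_transcripts("ACGU" * 6, {"t": "AAAAAAAA"}) == []

    def test_repeated_occurrences_ascending(self):
        motif = "ACGUGGCAUCGAUCGAUGCA"
        tx = "AAA" + motif + "CCCC" + motif + "GG"
        hits = discovery.locate_on_transcripts(motif, {"t": tx})
        spans = [span for _, span, _ in hits]
        assert spans == [(4, 23), (28, 47)]

    def test_window_arithmetic_and_clip(self):
        tx = "A" * 1000
        win, off = discovery.extract_precursor_window(tx, (400, 420), 300)
        assert (off + 1, off + len(win)) == (100, 720)
        win2, off2 = discovery.extract_precursor_window(tx, (10, 30), 300)
        assert (off2 + 1, off2 + len(win2)) == (1, 330)
        # round trip: window coordinate of the mature maps back to its span
        assert (400 - off, 420 - off) == (301, 321)
        with pytest.raises(ValueError):
            discovery.extract_precursor_window(tx, (990, 1010), 5)


class TestFolding:
    def test_forced_hairpin(self):
        stem = "GCGACUGCAUGGAUCCAGUCAGUCAGGCAU"
        seq = stem + "AACAACAACA" + revcomp(stem)
        structure, mfe = discovery.fold_rna(seq)
        pt = pair_table(structure)
        paired = sum(1 for i in range(1, 31) if 31 <= pt[i] if pt[i])
        assert structure.count("(") >= 25
        assert mfe < -20

    def test_homopolymer_is_unstructured(self):
        structure, mfe = discovery.fold_rna("A" * 100)
        assert set(structure) == {"."}
        assert mfe >= 0

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            discovery.fold_rna("ACGU" * 5)
        with pytest.raises(ValueError):
            discovery.fold_rna("ACGU" * 2000)

    def test_planted_matures_pair_to_star_arm(self, dataset):
        """At least 60% of mature bases pair into the opposite arm."""
        for m in dataset.truth.planted_mirnas:
            tx = to_rna(dataset.transcripts[m.transcript_id])
            flank = discovery.FLANK_LONG if m.is_long else discovery.FLANK_DEFAULT
            win, off = discovery.extract_precursor_window(tx, m.mature_span, flank)
            structure, _ = discovery.fold_rna(win)
            pt = pair_table(structure)
            ms, me = m.mature_span[0] - off, m.mature_span[1] - off
            ss, se = m.star_span[0] - off, m.star_span[1] - off
            arm = range(min(ss, se) - 3, max(ss, se) + 4)
            paired = sum(1 for i in range(ms, me + 1) if pt[i] in arm)
            assert paired >= 0.6 * (me - ms + 1)


class TestStarDerivation:
    def test_perfect_duplex_geometry(self):
        """A fully paired 21-bp stem yields a 21-nt star offset by +2."""
        structure = "(" * 21 + "." * 10 + ")" * 21 + ".."
        star = discovery.derive_star(structure, (1, 21))
        assert star == (34, 54)
        assert star[1] - star[0] + 1 == 21

    def test_symmetric_internal_loop_keeps_length(self):
        # 10 pairs, 1x1 loop, 10 pairs on each arm
        structure = ("(" * 10 + "." + "(" * 10 + "." * 8
                     + ")" * 10 + "." + ")" * 10 + "..")
        star = discovery.derive_star(structure, (1, 21))
        assert star[1] - star[0] + 1 == 21

    def test_unpaired_arm_rejected(self):
        structure = "." * 30 + "((((......))))" + "." * 10
        with pytest.raises(ValueError, match="insufficient pairing"):
            discovery.derive_star(structure, (1, 21))

    def test_planted_stars_recovered_exactly(self, dataset):
        for m in dataset.truth.planted_mirnas:
            tx = to_rna(dataset.transcripts[m.transcript_id])
            flank = discovery.FLANK_LONG if m.is_long else discovery.FLANK_DEFAULT
            win, off = discovery.extract_precursor_window(tx, m.mature_span, flank)
            structure, _ = discovery.fold_rna(win)
            ss, se = discovery.derive_star(
                structure, (m.mature_span[0] - off, m.mature_span[1] - off))
            assert win[ss - 1:se] == m.star


class TestValidateHairpin:
    def test_planted_hairpins_accepted_with_designed_mismatches(self, dataset):
        for m in dataset.truth.planted_mirnas:
            tx = to_rna(dataset.transcripts[m.transcript_id])
            flank = discovery.FLANK_LONG if m.is_long else discovery.FLANK_DEFAULT
            win, off = discovery.extract_precursor_window(tx, m.mature_span, flank)
            structure, mfe = discovery.fold_rna(win)
            res = discovery.validate_hairpin(
                win, structure, (m.mature_span[0] - off, m.mature_span[1] - off),
                srna_reads={m.star})
            assert res.accepted
            assert res.annotation.duplex_mismatches == m.duplex_mismatches
            assert res.annotation.star_detected == "this_experiment"
            pre_len = (res.annotation.precursor_span[1]
                       - res.annotation.precursor_span[0] + 1)
            assert pre_len >= 2 * len(m.mature) + 3

    def test_mature_spanning_terminal_loop_rejected(self):
        stem = "GCGACUGCAUGGAUCCAGUCAGUCAGGCAU"
        seq = stem + "AACAACAACA" + revcomp(stem)
        structure, _ = discovery.fold_rna(seq)
        res = discovery.validate_hairpin(seq, structure, (25, 45))
        assert not res.accepted
        assert res.reason == "loop overlap"

    def test_structure_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="lengths differ"):
            discovery.validate_hairpin("ACGU" * 20, "." * 10, (1, 10))

    def test_dinucleotide_shuffled_precursors_rejected(self, dataset):
        """Shuffling destroys the stem-loop in >90% of trials."""
        m = next(x for x in dataset.truth.planted_mirnas if not x.is_long)
        tx = to_rna(dataset.transcripts[m.transcript_id])
        ps, pe = m.precursor_span
        precursor = tx[ps - 1:pe]
        ms = m.mature_span[0] - ps + 1
        me = m.mature_span[1] - ps + 1
        rng = np.random.default_rng(7)
        rejected = 0
        n_trials = 100
        for _ in range(n_trials):
            shuffled = discovery.dinucleotide_shuffle(precursor, rng)
            structure, _ = discovery.fold_rna(shuffled)
            if not discovery.validate_hairpin(shuffled, structure, (ms, me)).accepted:
                rejected += 1
        assert rejected > 0.9 * n_trials


class TestIsoforms:
    def test_canonical_only_when_no_shifts(self, dataset):
        m = dataset.truth.planted_mirnas[1]
        table = _as_table([m.mature])
        iso = discovery.collect_isoforms(m.mature, table,
                                         dataset.transcripts[m.transcript_id])
        assert [(r.sequence, r.offset) for r in iso] == [(m.mature, 0)]

    def test_planted_shift_recovered_and_far_shifts_excluded(self, dataset):
        m = dataset.truth.planted_mirnas[1]
        tx = to_rna(dataset.transcripts[m.transcript_id])
        s, e = m.mature_span
        plus1 = tx[s:e + 1]       # +1 shift, same length
        plus5 = tx[s + 4:e + 5]   # beyond the +-2 window
        table = _as_table([m.mature, plus1, plus5])
        iso = discovery.collect_isoforms(m.mature, table, tx)
        offsets = {r.sequence: r.offset for r in iso}
        assert offsets[plus1] == 1
        assert plus5 not in offsets

    def test_pipeline_recovery_on_clean_data(self, dataset, discovered):
        """No planted miRNA is lost by the full discovery pass."""
        candidates, hairpins = discovered
        found = {c.sequence for c in candidates}
        stars = {h.star_seq for h in hairpins}
        for m in dataset.truth.planted_mirnas:
            assert m.mature in found
            assert m.star in stars
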