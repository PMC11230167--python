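import pytest

from mave_anchor import (
    TranscriptRecord,
    TranscriptSelectionError,
    compute_offset,
    reconcile_offset,
    select_transcript,
    translate_dna,
)
from oracles import shift_scan_oracle


class TestTranslateDna:
    @pytest.mark.parametrize(
        "dna,protein",
        [
            ("ATGGCT", "MA"),
            ("ATGGC", "M"),          # trailing partial codon dropped
            ("TGA", "*"),            # stop renders * and translation continues
            ("TGAATG", "*M"),
            ("atggct", "MA"),        # case-insensitive
        ],
    )
    def test_standard_table(self, dna, protein):
        assert translate_dna(dna) == protein

    def test_ambiguous_base_names_codon(self):
        with pytest.raises(TranscriptSelectionError, match="codon 1"):
            translate_dna("ATGGNT")

    def test_too_short(self):
        with pytest.raises(TranscriptSelectionError):
            translate_dna("AT")


def _rec(acc, mane="none", length=400, pub=1, coding=True):
    return TranscriptRecord(
        tx_accession=acc,
        protein_accession=f"NP_{acc}" if coding else None,
        is_coding=coding,
        mane_status=mane,
        length=length,
        pub_order=pub,
        chromosome="chrT",
        gene="G",
    )


class TestSelectTranscript:
    # every ordering of the ranking rules: MANE Select > MANE Plus Clinical
    # > longest > first published
    @pytest.mark.parametrize(
        "records,winner",
        [
            ([_rec("T1", "MANE Select"), _rec("T2")], "T1"),
            ([_rec("T1"), _rec("T2", "MANE Select")], "T2"),
            ([_rec("T1", "MANE Plus Clinical"), _rec("T2")], "T1"),
            ([_rec("T1", "MANE Select"), _rec("T2", "MANE Plus Clinical")], "T1"),
            ([_rec("T1", "MANE Plus Clinical"), _rec("T2", "MANE Select")], "T2"),
            ([_rec("T1", length=500), _rec("T2", length=300)], "T1"),
            ([_rec("T1", length=300), _rec("T2", length=500)], "T2"),
            ([_rec("T1", length=400, pub=2), _rec("T2", length=400, pub=1)], "T2"),
            ([_rec("T1", length=400, pub=1), _rec("T2", length=400, pub=2)], "T1"),
            ([_rec("T1", "MANE Plus Clinical", length=100), _rec("T2", length=900)], "T1"),
            ([_rec("T1", "MANE Select", length=100), _rec("T2", length=900, pub=0)], "T1"),
            ([_rec("T1", length=200, pub=3), _rec("T2", length=200, pub=2),
              _rec("T3", length=100, pub=1)], "T2"),
        ],
    )
    def test_ranking_table(self, records, winner):
        assert select_transcript([records]).tx_accession == winner

    def test_noncoding_dropped_before_intersection(self):
        lists = [[_rec("T1"), _rec("NR1", coding=False)], [_rec("T1"), _rec("NR1", coding=False)]]
        assert select_transcript(lists).tx_accession == "T1"

    def test_intersection_across_blocks(self):
        lists = [[_rec("T1"), _rec("T2")], [_rec("T1")]]
        assert select_transcript(lists).tx_accession == "T1"

    def test_empty_intersection_raises(self):
        with pytest.raises(TranscriptSelectionError, match="no compatible transcript"):
            select_transcript([[_rec("T1")], [_rec("T2")]])

    def test_invariant_under_within_list_permutation(self):
        records = [_rec("T1", length=300, pub=2), _rec("T2", "MANE Plus Clinical"),
                   _rec("T3", length=900, pub=1)]
        a = select_transcript([records]).tx_accession
        b = select_transcript([list(reversed(records))]).tx_accession
        assert a == b == "T2"


class TestComputeOffset:
    REF = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

    def test_identity(self):
        assert compute_offset(self.REF, self.REF) == (0, True)

    def test_suffix_target(self):
        assert compute_offset(self.REF[5:], self.REF) == (5, True)

    def test_seed_matches_then_diverges(self):
        target = self.REF[4:14] + "WWWWW"
        assert compute_offset(target, self.REF) == (4, False)

    def test_seed_not_found(self):
        with pytest.raises(TranscriptSelectionError, match="seed"):
            compute_offset("WWWWWWWWWW", self.REF)

    def test_short_target_uses_whole_string(self):
        assert compute_offset("AYIA", self.REF) == (3, True)


class TestReconcileOffset:
    def test_consistent_map_keeps_offset(self):
        target = "MKTAYIAKQR"
        assert reconcile_offset(target, {1: "M", 2: "K"}, offset=7) == 7

    def test_leucine_vs_reported_arginine_discordance_shift(self):
        """A matrix reporting p.Arg100His over a target with Leu at position
        100 and Arg two residues later reconciles with shift 2."""
        target = ["A"] * 105
        target[99] = "L"    # 1-based position 100
        target[100] = "G"
        target[101] = "R"   # 1-based position 102 == 100 + shift 2
        target = "".join(target)
        expected = {100: "R"}
        assert reconcile_offset(target, expected, offset=10) == 12
        assert shift_scan_oracle(target, expected)[0] == 2

    def test_met_start_shift(self):
        # expected {1: 'M'} on a target starting 'GSM...'
        target = "GSMKTAYIAK"
        expected = {1: "M"}
        assert reconcile_offset(target, expected, offset=0) == 2
        assert shift_scan_oracle(target, expected)[0] == 2

    def test_after_reconcile_every_claim_matches(self):
        target = "XXMKTAYIAK"
        expected = {1: "M", 2: "K", 5: "Y"}
        shift = reconcile_offset(target, expected, offset=0)
        assert all(target[pos - 1 + shift] == res for pos, res in expected.items())

    def test_irreconcilable(self):
        with pytest.raises(TranscriptSelectionError, match="discordance"):
            reconcile_offset("AAAA", {1: "W"}, offset=0)

    def test_agrees_with_bruteforce_scan(self):
        target = "QQQMKTAYIAKMKT"
        expected = {1: "M", 2: "K", 3: "T"}
        got = reconcile_offset(target, expected, offset=5) - 5
        assert got == shift_scan_oracle(target, expected)[0]
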