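import random
import re

import pytest
from hypothesis import given, strategies as st

from slqscan.io import SequenceRecord
from slqscan.scanner import (
    LONG_LOOP_CANDIDATE,
    PQS_L7,
    ScanParams,
    chromosome_code,
    enumerate_pqs,
    find_g_runs,
    make_id,
    revcomp,
    scan_both_strands,
)


def grammar_oracle(seq, params=ScanParams()):
    """Independent brute force: every 4-interval placement tested directly
    against the G_3-6 N_1-20 grammar (tracts all-G, gaps within loop bounds)."""
    n = len(seq)
    tracts = [
        (s, s + k)
        for k in range(params.min_tract, params.max_tract + 1)
        for s in range(n - k + 1)
        if set(seq[s:s + k]) == {"G"}
    ]
    tracts.sort()
    quads = set()

    def rec(chosen):
        if len(chosen) == 4:
            quads.add(tuple(chosen))
            return
        prev_end = chosen[-1][1]
        for t in tracts:
            gap = t[0] - prev_end
            if params.min_loop <= gap <= params.max_loop:
                rec(chosen + [t])

    for t in tracts:
        rec([t])
    return quads


class TestFindGRuns:
    def test_two_maximal_runs(self):
        runs = find_g_runs(SequenceRecord("s", "GGGATGGG"))
        assert [(r.start, r.end) for r in runs] == [(0, 3), (5, 8)]
        assert not any(r.flagged for r in runs)

    def test_myt1l_has_four_runs_of_three(self, oligos):
        runs = find_g_runs(oligos["G4ST02001786748"])
        assert len(runs) == 4
        assert all(r.length == 3 for r in runs)

    def test_long_run_flagged_with_true_length(self):
        (run,) = find_g_runs(SequenceRecord("s", "GGGGGGG"))
        assert run.length == 7 and run.flagged

    def test_minus_strand_runs_are_c_runs(self):
        runs = find_g_runs(SequenceRecord("s", "AACCCAA"), strand="-")
        assert [(r.start, r.end, r.strand) for r in runs] == [(2, 5, "-")]


class TestEnumeratePqs:
    def test_myt1l_single_hit_loop_lengths(self, oligos):
        rec = oligos["G4ST02001786748"]
        hits = enumerate_pqs(find_g_runs(rec), rec)
        assert len(hits) == 1
        assert hits[0].loop_lengths == (13, 2, 1)
        assert hits[0].class_label == LONG_LOOP_CANDIDATE

    def test_five_runs_give_five_overlapping_hits(self):
        # 4-of-5 quadruples; a skipped run leaves a 5-nt loop (<= 20)
        rec = SequenceRecord("s", "GGGAGGGAGGGAGGGAGGG")
        hits = enumerate_pqs(find_g_runs(rec), rec)
        assert len(hits) == 5

    def test_deletion_mutant_yields_no_hits(self, oligos):
        rec = oligos["G4ST19017166594del"]
        assert len(enumerate_pqs(find_g_runs(rec), rec)) == 0

    def test_hit_spanning_n_is_discarded(self):
        rec = SequenceRecord("s", "GGGANGGGAGGGAGGG")
        hits = enumerate_pqs(find_g_runs(rec), rec)
        assert hits == []

    def test_quadruple_cap_warns_and_flags(self):
        rec = SequenceRecord("s", "GGGA" * 40)
        params = ScanParams(max_quadruples_per_window=5)
        with pytest.warns(UserWarning, match="cap"):
            hits = enumerate_pqs(find_g_runs(rec, "+", params), rec, params)
        assert hits.truncated
        assert len(hits) <= 5

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_grammar_oracle_on_random_g_rich(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choices("ACGT", weights=[1, 1, 3, 1], k=200))
        rec = SequenceRecord("s", seq)
        params = ScanParams(max_quadruples_per_window=10**7)  # uncapped comparison
        hits = enumerate_pqs(find_g_runs(rec, "+", params), rec, params)
        assert not hits.truncated
        assert {h.tracts for h in hits} == grammar_oracle(seq, params)


class TestScanBothStrands:
    def test_c_strand_motif_found_on_minus(self):
        rec = SequenceRecord("s", "CCCTCCCTCCCTCCC")
        (hit,) = scan_both_strands(rec)
        assert hit.strand == "-"
        assert hit.loop_lengths == (1, 1, 1)
        assert hit.span == (0, 15)

    def test_all_a_yields_nothing(self):
        assert len(scan_both_strands(SequenceRecord("s", "A" * 100))) == 0

    def test_class_partition(self, small_synthetic):
        _, record, _, _ = small_synthetic
        hits = scan_both_strands(record)
        assert all(h.class_label in (PQS_L7, LONG_LOOP_CANDIDATE) for h in hits)
        short = [h for h in hits if max(h.loop_lengths) <= 7]
        assert all(h.class_label == PQS_L7 for h in short)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=80))
    def test_revcomp_symmetry(self, seq):
        fwd = scan_both_strands(SequenceRecord("s", seq))
        rev = scan_both_strands(SequenceRecord("s", revcomp(seq)))
        n = len(seq)
        mirrored = {
            ((n - h.span[1], n - h.span[0]), "+" if h.strand == "-" else "-")
            for h in rev
        }
        assert {(h.span, h.strand) for h in fwd} == mirrored

    def test_n_separator_blocks_cross_hits(self):
        left = "GGGAGGGAGGGAGGG"
        right = "GGGTGGGTGGGTGGG"
        joined = SequenceRecord("s", left + "N" * 21 + right)
        n_joined = len(scan_both_strands(joined))
        n_split = len(scan_both_strands(SequenceRecord("l", left))) + len(
            scan_both_strands(SequenceRecord("r", right))
        )
        assert n_joined == n_split


class TestMakeId:
    @pytest.mark.parametrize(
        "code,pos,expected",
        [
            ("02", 1786748, "G4ST02001786748"),
            ("05", 39110287, "G4ST05039110287"),
            ("01", 1, "G4ST01000000001"),
        ],
    )
    def test_formats(self, code, pos, expected):
        assert make_id(None, code, pos) == expected

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            make_id(None, "01", 10**9)
        with pytest.raises(ValueError):
            make_id(None, "26", 5)

    def test_chromosome_codes(self):
        assert chromosome_code("chr1") == "01"
        assert chromosome_code("chrX") == "23"
        assert chromosome_code("chrY") == "24"
        assert chromosome_code("chrM") == "25"
        with pytest.raises(ValueError):
            chromosome_code("scaffold_12")


def test_flagged_seven_g_run_still_yields_hits(oligos):
    """The HIC1 oligo's tracts live inside maximal runs of 7 and 6 G."""
    rec = oligos["G4ST17001906030"]
    runs = find_g_runs(rec)
    assert any(r.flagged for r in runs)
    hits = enumerate_pqs(runs, rec)
    assert len(hits) > 0
    assert re.fullmatch(r"G{7}", rec.seq[2:9])
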