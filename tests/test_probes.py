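"""Orientation inference, composition metrics, enumeration and selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from satarray import probes
from satarray.probes import (ProbeCriteria, TranscriptRecord, assign_orientation,
                             enumerate_candidates, passes_criteria, probe_metrics,
                             revcomp, select_probe_set, total_probe_features)

DNA = st.text(alphabet="ACGT", min_size=60, max_size=60)


class TestOrientation:
    @pytest.mark.parametrize("frames,est,expected", [
        ((1, 2, 1), (0, 0), "forward"),          # majority frame sign
        ((-1, -2, -3), (0, 0), "reverse"),
        ((1, -1), (0, 0), "unknown"),            # tie, no EST tiebreaker
        ((1, -1), (2, 9), "reverse"),            # tie broken by EST majority
        ((), (7, 2), "forward"),                 # EST-only path
        ((), (3, 3), "unknown"),                 # exact EST tie
        ((), (0, 0), "unknown"),                 # no evidence at all
    ])
    def test_decision_table(self, frames, est, expected):
        assert assign_orientation("t", frames, *est) == expected

    def test_more_than_three_hits_rejected(self):
        with pytest.raises(ValueError):
            assign_orientation("t", (1, 1, 1, 1))

    def test_frame_zero_rejected(self):
        with pytest.raises(ValueError):
            assign_orientation("t", (0,))


class TestMetrics:
    def test_periodic_sequence(self):
        m = probe_metrics("ACGT" * 15)
        assert m["pct_g"] == 25.0
        assert m["pct_gc"] == 50.0
        assert m["max_run"] == 1

    def test_constructed_homopolymer(self):
        m = probe_metrics("A" * 7 + "C" * 53)
        assert m["max_run"] == 53
        m = probe_metrics("A" * 7 + ("CT" * 27)[:53])
        assert m["max_run"] == 7

    def test_salt_adjusted_tm(self):
        # 27 G+C of 60 -> 45% GC -> 54.9 + 0.41*45 at 0.1 M Na+
        seq = "G" * 13 + "C" * 14 + "A" * 17 + "T" * 16
        assert len(seq) == 60
        m = probe_metrics(seq)
        assert m["pct_gc"] == 45.0
        assert m["tm"] == pytest.approx(54.9 + 0.41 * 45, abs=1e-9)
        assert m["tm"] == pytest.approx(73.35, abs=0.005)

    def test_non_acgt_names_position(self):
        with pytest.raises(probes.MetricsError, match="position 31"):
            probe_metrics("A" * 30 + "N" + "C" * 29)

    @given(DNA)
    def test_metrics_invariant_under_reverse_complement(self, seq):
        m = probe_metrics(seq)
        r = probe_metrics(revcomp(seq))
        assert r["pct_gc"] == m["pct_gc"]
        assert r["tm"] == m["tm"]
        assert r["max_run"] == m["max_run"]
        # %G of the reverse complement equals %C of the original
        assert r["pct_g"] == pytest.approx(m["pct_gc"] - m["pct_g"])


class TestCriteria:
    def test_pct_g_bound_is_strict(self):
        m = {"pct_g": 50.0, "pct_gc": 50.0, "tm": 73.0, "max_run": 1}
        ok, reasons = passes_criteria(m, ProbeCriteria())
        assert not ok and any("pct_g" in r for r in reasons)

    def test_inclusive_bounds_pass_at_edges(self):
        m = {"pct_g": 10.0, "pct_gc": 35.0, "tm": 68.0, "max_run": 6}
        ok, reasons = passes_criteria(m, ProbeCriteria())
        assert ok and reasons == []

    def test_non_acgt_fails_alphabet_rule(self):
        ok, reasons = passes_criteria({}, ProbeCriteria(), has_non_acgt=True)
        assert not ok and reasons == ["non-ACGT base"]


class TestEnumeration:
    def test_single_window_transcript(self):
        t = TranscriptRecord(id="t", sequence="ACGT" * 15, orientation="forward")
        c = enumerate_candidates(t)
        sense = c[c["strand"] == "sense"]
        assert len(sense) == 1
        assert sense["pos3"].iloc[0] == 1
        # |1 - 50| = 49 > 40: not in the P50 window
        assert sense["position_class"].iloc[0] == "none"

    def test_window_count(self):
        t = TranscriptRecord(id="t", sequence="ACGT" * 125, orientation="forward")
        c = enumerate_candidates(t)
        assert (c["strand"] == "sense").sum() == 500 - 60 + 1
        assert (c["strand"] == "antisense").sum() == 441

    def test_reverse_orientation_symmetry(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 300))
        fwd = enumerate_candidates(
            TranscriptRecord(id="t", sequence=revcomp(seq), orientation="reverse"))
        ref = enumerate_candidates(
            TranscriptRecord(id="t", sequence=seq, orientation="forward"))
        pd.testing.assert_frame_equal(
            fwd.reset_index(drop=True), ref.reset_index(drop=True))

    def test_antisense_is_reverse_complement_of_window(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 200))
        t = TranscriptRecord(id="t", sequence=seq, orientation="forward")
        c = enumerate_candidates(t)
        for pos3, grp in c.groupby("pos3"):
            s = grp[grp["strand"] == "sense"]["sequence"].iloc[0]
            a = grp[grp["strand"] == "antisense"]["sequence"].iloc[0]
            assert a == revcomp(s)

    def test_short_transcript_yields_empty(self):
        t = TranscriptRecord(id="t", sequence="ACGT" * 10, orientation="forward")
        assert enumerate_candidates(t).empty

    def test_unknown_orientation_excluded(self):
        t = TranscriptRecord(id="t", sequence="ACGT" * 30, orientation="unknown")
        with pytest.raises(ValueError, match="unknown orientation"):
            enumerate_candidates(t)

    def test_metrics_agree_with_scalar_path(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 250))
        t = TranscriptRecord(id="t", sequence=seq, orientation="forward")
        c = enumerate_candidates(t)
        sample = c.sample(20, random_state=0)
        for row in sample.itertuples(index=False):
            m = probe_metrics(row.sequence)
            assert m["pct_g"] == pytest.approx(row.pct_g)
            assert m["pct_gc"] == pytest.approx(row.pct_gc)
            assert m["tm"] == pytest.approx(row.tm)
            assert m["max_run"] == row.max_run


def _candidate_frame(rows):
    df = pd.DataFrame(rows)
    df["passes"] = True
    df["probe_id"] = df["transcript_id"] + "|" + df["strand"] + "|" + df["pos3"].astype(str)
    return df


class TestSelection:
    def test_closest_to_center_wins(self):
        df = _candidate_frame([
            {"transcript_id": "t", "strand": "sense", "pos3": p, "position_class": "P50"}
            for p in (12, 49, 88)
        ])
        sel = select_probe_set(df)
        assert list(sel["pos3"]) == [49]

    def test_equidistant_tie_prefers_smaller_pos3(self):
        df = _candidate_frame([
            {"transcript_id": "t", "strand": "sense", "pos3": p, "position_class": "P50"}
            for p in (45, 55)
        ])
        sel = select_probe_set(df)
        assert list(sel["pos3"]) == [45]

    def test_antisense_only_not_paired_but_selected(self):
        df = _candidate_frame([
            {"transcript_id": "t", "strand": "antisense", "pos3": 50, "position_class": "P50"},
        ])
        sel = select_probe_set(df)
        assert len(sel) == 1
        assert sel["role"].iloc[0] == "antisense_P50"
        assert not sel["paired"].iloc[0]

    def test_full_complement_flags_paired(self):
        df = _candidate_frame([
            {"transcript_id": "t", "strand": "sense", "pos3": 50, "position_class": "P50"},
            {"transcript_id": "t", "strand": "sense", "pos3": 350, "position_class": "P350"},
            {"transcript_id": "t", "strand": "antisense", "pos3": 52, "position_class": "P50"},
        ])
        sel = select_probe_set(df)
        assert set(sel["role"]) == {"sense_P50", "sense_P350", "antisense_P50"}
        assert sel["paired"].all()


class TestDesignArray:
    def test_identical_transcripts_fail_specificity(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 400, p=[0.275, 0.225, 0.225, 0.275]))
        recs = [probes.TranscriptRecord(id=f"t{i}", sequence=seq) for i in (1, 2)]
        hits = pd.DataFrame([{"transcript_id": f"t{i}", "rank": r, "frame": 1}
                             for i in (1, 2) for r in (1, 2, 3)])
        db = {r.id: r.sequence for r in recs}
        design = probes.design_array(recs, hits, None, db)
        assert design.probes.empty
        spec_fail = design.audit[design.audit["stage"] == "specificity"]
        assert len(spec_fail) > 0

    def test_deterministic_and_order_invariant(self, small_design):
        recs, db, hits, ests, d1 = small_design
        d2 = probes.design_array(list(reversed(recs)), hits, ests, db)
        pd.testing.assert_frame_equal(d1.probes, d2.probes)

    def test_unique_pool_keeps_positional_selection(self, small_design):
        """With unique random sequences the specificity screen never fires:
        accepted probes equal the positional selection."""
        recs, db, hits, ests, design = small_design
        probes.assign_orientations(recs, hits, ests)
        expected = []
        for t in recs:
            if t.orientation == "unknown":
                continue
            sel = select_probe_set(enumerate_candidates(t))
            expected.append(sel)
        expected = pd.concat(expected, ignore_index=True)
        assert set(design.probes["probe_id"]) == set(expected["probe_id"])

    def test_accepted_probes_satisfy_all_bounds(self, small_design):
        recs, db, hits, ests, design = small_design
        crit = ProbeCriteria()
        for row in design.probes.itertuples(index=False):
            m = probe_metrics(row.sequence)
            ok, reasons = passes_criteria(m, crit, length=len(row.sequence))
            assert ok, reasons


def test_duplicate_spot_accounting():
    assert total_probe_features(21901, 1, duplicates=2) == 43803
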