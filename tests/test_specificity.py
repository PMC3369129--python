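"""Ungapped specificity screen: scoring, thresholds, oracle agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from satarray import specificity
from satarray.probes import revcomp
from satarray.specificity import (bit_score, specificity_pass, specificity_scan)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def brute_force_best(probe: str, subject: str) -> tuple[int, int]:
    """Independent oracle: enumerate every diagonal offset and every segment
    with a plain quadratic scan.  Returns (best raw score, longest exact run)."""
    m, n = len(probe), len(subject)
    best = 0
    best_run = 0
    for off in range(-(m - 1), n):
        cur = 0
        run = 0
        for k in range(m):
            j = off + k
            if j < 0 or j >= n:
                continue
            s = 1 if probe[k] == subject[j] else -3
            cur = max(0, cur + s)
            best = max(best, cur)
            run = run + 1 if probe[k] == subject[j] else 0
            best_run = max(best_run, run)
    return best, best_run


class TestBitScore:
    def test_threshold_identity(self):
        # a 21-bp perfect ungapped match sits exactly at the 42.1-bit cutoff
        assert round(bit_score(21), 1) == 42.1

    def test_zero_raw_score(self):
        assert bit_score(0) == pytest.approx(0.49, abs=0.005)

    def test_strictly_increasing_in_raw(self):
        assert bit_score(42) > bit_score(21)
        raws = np.arange(0, 80)
        assert np.all(np.diff(bit_score(raws)) > 0)

    def test_invalid_parameters(self):
        with pytest.raises(specificity.SpecificityError):
            bit_score(10, lambda_=0.0)
        with pytest.raises(specificity.SpecificityError):
            bit_score(10, K=-1.0)


class TestScan:
    def test_self_hit_is_perfect(self):
        rng = np.random.default_rng(0)
        t = _random_seq(rng, 300)
        probe = t[100:160]
        hits = specificity_scan(probe, {"t": t}, "p")
        top = hits.iloc[0]
        assert top["identity_pct"] == 100.0
        assert top["matched_bp"] == 60
        assert top["full_length_identical"]

    def test_antisense_probe_hits_minus_strand(self):
        rng = np.random.default_rng(1)
        t = _random_seq(rng, 300)
        probe = revcomp(t[100:160])
        hits = specificity_scan(probe, {"t": t}, "p")
        top = hits.iloc[0]
        assert top["subject_strand"] == "-"
        assert top["full_length_identical"]

    def test_planted_21bp_block_crosses_threshold(self):
        rng = np.random.default_rng(2)
        probe = _random_seq(rng, 60)
        other = _random_seq(rng, 200)
        other = other[:90] + probe[10:31] + other[111:]   # 21-bp exact block
        hits = specificity_scan(probe, {"o": other}, "p")
        top = hits.iloc[0]
        assert top["raw_score"] >= 21
        assert top["bit_score"] >= 42.1
        assert top["matched_bp"] >= 21

    def test_short_shared_stretch_stays_below_threshold(self):
        rng = np.random.default_rng(3)
        probe = _random_seq(rng, 60)
        other = _random_seq(rng, 200)
        other = other[:90] + probe[10:21] + other[101:]   # 11-bp block only
        hits = specificity_scan(probe, {"o": other}, "p")
        raw, run = max(
            brute_force_best(probe, s) for s in (other, revcomp(other))
        )
        assert hits["raw_score"].max() == raw
        if raw < 21:
            assert (hits["bit_score"] < 42.1).all()

    def test_bulk_scan_matches_single_probe_scan(self):
        rng = np.random.default_rng(9)
        db = {f"s{i}": _random_seq(rng, 150) for i in range(4)}
        probes = {f"p{i}": _random_seq(rng, 60) for i in range(6)}
        probes["p0"] = db["s0"][10:70]   # one planted perfect hit
        bulk = specificity.scan_probes(probes, db)
        for pid, seq in probes.items():
            single = specificity_scan(seq, db, pid)
            b = bulk[bulk["probe_id"] == pid].sort_values(
                ["subject_id", "subject_strand"]).reset_index(drop=True)
            s = single.sort_values(
                ["subject_id", "subject_strand"]).reset_index(drop=True)
            pd.testing.assert_frame_equal(
                b[["raw_score", "matched_bp"]],
                s[["raw_score", "matched_bp"]])
            assert (b["full_length_identical"] == s["full_length_identical"]).all()

    def test_empty_db_rejected(self):
        with pytest.raises(specificity.SpecificityError):
            specificity_scan("ACGT" * 15, {})

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        probe = _random_seq(rng, 30)
        subject = _random_seq(rng, 80)
        if seed % 2:
            # plant a shared fragment to exercise the high-score path
            frag = probe[5:20]
            subject = subject[:30] + frag + subject[45:]
        hits = specificity_scan(probe, {"s": subject}, "p")
        for strand, subj in (("+", subject), ("-", revcomp(subject))):
            want_raw, want_run = brute_force_best(probe, subj)
            row = hits[hits["subject_strand"] == strand].iloc[0]
            assert row["raw_score"] == want_raw
            assert row["matched_bp"] == want_run


class TestPass:
    def _self_hits(self):
        rng = np.random.default_rng(4)
        t = _random_seq(rng, 250)
        return t, t[50:110]

    def test_accepts_clean_probe(self):
        t, probe = self._self_hits()
        rng = np.random.default_rng(5)
        hits = specificity_scan(probe, {"t": t, "o": _random_seq(rng, 250)}, "p")
        ok, why = specificity_pass(hits, "t")
        assert ok, why

    def test_boundary_bit_score_fails(self):
        hits = pd.DataFrame([
            {"subject_id": "t", "subject_strand": "+", "raw_score": 60,
             "bit_score": bit_score(60), "aln_len": 60, "identity_pct": 100.0,
             "matched_bp": 60, "full_length_identical": True},
            {"subject_id": "o", "subject_strand": "+", "raw_score": 21,
             "bit_score": 42.1, "aln_len": 21, "identity_pct": 100.0,
             "matched_bp": 21, "full_length_identical": False},
        ])
        ok, why = specificity_pass(hits, "t")
        assert not ok and "42.1" in why

    def test_just_below_threshold_passes(self):
        hits = pd.DataFrame([
            {"subject_id": "t", "subject_strand": "+", "raw_score": 60,
             "bit_score": bit_score(60), "aln_len": 60, "identity_pct": 100.0,
             "matched_bp": 60, "full_length_identical": True},
            {"subject_id": "o", "subject_strand": "+", "raw_score": 20,
             "bit_score": 41.9, "aln_len": 20, "identity_pct": 100.0,
             "matched_bp": 20, "full_length_identical": False},
        ])
        ok, _ = specificity_pass(hits, "t")
        assert ok

    def test_imperfect_self_hit_fails(self):
        t, probe = self._self_hits()
        mutated = probe[:30] + ("A" if probe[30] != "A" else "C") + probe[31:]
        hits = specificity_scan(mutated, {"t": t}, "p")
        ok, why = specificity_pass(hits, "t")
        assert not ok and "100%" in why

    def test_missing_target_is_an_error(self):
        t, probe = self._self_hits()
        rng = np.random.default_rng(6)
        hits = specificity_scan(probe, {"o": _random_seq(rng, 250)}, "p")
        with pytest.raises(specificity.SpecificityError):
            specificity_pass(hits, "t")
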