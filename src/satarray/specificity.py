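"""Probe specificity screening by ungapped local alignment.

A candidate probe is compared against every sequence of an EST/transcript
database on both subject strands under blastn-like ungapped scoring
(match +1, mismatch -3).  Raw scores are converted to bits with the
Karlin-Altschul rescaling (lambda = 1.374, K = 0.711, the classic ungapped
blastn parameters), under which a 21-bp perfect match scores 42.1 bits —
the acceptance threshold: a probe is specific when its only strong hit is a
full-length, 100%-identity match to its own source transcript and every
other hit stays below 42.1 bits.

The scan is exact: every diagonal of the probe x subject comparison is
evaluated with a reset-at-zero maximum-segment recurrence (Kadane), carried
out as numpy array sweeps across all diagonals at once.  No seeding
heuristic is involved, so the scan is identical to brute-force enumeration
of all offsets by construction.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .probes import revcomp

MATCH_SCORE = 1
MISMATCH_SCORE = -3
DEFAULT_LAMBDA = 1.374
DEFAULT_K = 0.711
DEFAULT_THRESHOLD_BITS = 42.1

_NEG = -(10 ** 9)

_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class SpecificityError(ValueError):
    pass


def bit_score(raw: int | float | np.ndarray,
              lambda_: float = DEFAULT_LAMBDA,
              K: float = DEFAULT_K) -> float | np.ndarray:
    """Karlin-Altschul bit score: (lambda * raw - ln K) / ln 2."""
    if lambda_ <= 0 or K <= 0:
        raise SpecificityError("lambda and K must be positive")
    return (lambda_ * np.asarray(raw, dtype=float) - math.log(K)) / math.log(2)


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _best_ungapped(probe: np.ndarray, subject: np.ndarray) -> tuple[int, int, int, int]:
    """Best ungapped local alignment of probe vs one subject strand.

    Returns ``(raw_score, aln_len, n_match, longest_exact_run)`` for the
    highest-scoring segment over all diagonals (all offsets, including
    partial overlaps at the subject ends).
    """
    m = len(probe)
    n = len(subject)
    pad = np.full(m - 1, -2, dtype=subject.dtype)  # sentinel never matches
    padded = np.concatenate([pad, subject, pad])
    W = np.lib.stride_tricks.sliding_window_view(padded, m)  # (n+m-1, m)
    valid = W != -2
    match = (W == probe[None, :]) & (probe[None, :] >= 0) & (W >= 0)
    score = np.where(match, MATCH_SCORE, MISMATCH_SCORE).astype(np.int64)
    score[~valid] = _NEG

    d = W.shape[0]
    cur = np.zeros(d, dtype=np.int64)
    cur_len = np.zeros(d, dtype=np.int64)
    cur_match = np.zeros(d, dtype=np.int64)
    best = np.zeros(d, dtype=np.int64)
    best_len = np.zeros(d, dtype=np.int64)
    best_match = np.zeros(d, dtype=np.int64)
    runm = np.zeros(d, dtype=np.int64)
    best_run = np.zeros(d, dtype=np.int64)

    for k in range(m):
        s = score[:, k]
        mt = match[:, k]
        cur = cur + s
        cur_len = cur_len + 1
        cur_match = cur_match + mt
        improved = cur > best
        best = np.where(improved, cur, best)
        best_len = np.where(improved, cur_len, best_len)
        best_match = np.where(improved, cur_match, best_match)
        reset = cur < 0
        cur[reset] = 0
        cur_len[reset] = 0
        cur_match[reset] = 0
        runm = np.where(mt, runm + 1, 0)
        best_run = np.maximum(best_run, runm)

    i = int(np.argmax(best))
    return int(best[i]), int(best_len[i]), int(best_match[i]), int(best_run.max())


_NEG32 = np.int32(-(10 ** 6))


def _best_ungapped_bulk(pcodes: np.ndarray, subject: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised form of :func:`_best_ungapped` over many probes at once.

    ``pcodes`` is (P, m); returns per-probe ``(raw_score, longest_exact_run)``
    arrays of shape (P,).  Same reset-at-zero recurrence, carried over a
    (P, diagonals) plane per probe column; segment length/identity tracking
    is left to the single-probe path, since a full-length perfect hit is
    recognisable here as ``raw_score == m``.
    """
    P, m = pcodes.shape
    pad = np.full(m - 1, -2, dtype=subject.dtype)
    padded = np.concatenate([pad, subject, pad])
    W = np.lib.stride_tricks.sliding_window_view(padded, m)  # (D, m)
    D = W.shape[0]

    cur = np.zeros((P, D), dtype=np.int32)
    best = np.zeros((P, D), dtype=np.int32)
    runm = np.zeros((P, D), dtype=np.int32)
    best_run = np.zeros((P, D), dtype=np.int32)
    s = np.empty((P, D), dtype=np.int32)

    for k in range(m):
        col = W[:, k]                       # (D,)
        invalid = col == -2
        mt = (col[None, :] == pcodes[:, k][:, None]) & (pcodes[:, k][:, None] >= 0)
        np.copyto(s, np.int32(MISMATCH_SCORE))
        s[mt] = MATCH_SCORE
        s[:, invalid] = _NEG32
        cur += s
        np.maximum(best, cur, out=best)
        np.maximum(cur, 0, out=cur)
        runm += 1
        runm[~mt] = 0
        np.maximum(best_run, runm, out=best_run)

    return best.max(axis=1).astype(np.int64), best_run.max(axis=1).astype(np.int64)


def scan_probes(
    probe_seqs: Mapping[str, str],
    db: Mapping[str, str],
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
    chunk: int = 256,
) -> pd.DataFrame:
    """Scan many equal-length probes against a database in one pass.

    Returns the same hit schema as :func:`specificity_scan`, one row per
    (probe, subject, strand), unsorted.  Probes are batched so the
    intermediate (probe x diagonal) planes stay small.
    """
    if not db:
        raise SpecificityError("specificity database is empty")
    if not probe_seqs:
        return pd.DataFrame(columns=["probe_id", "subject_id", "subject_strand",
                                     "raw_score", "matched_bp", "bit_score",
                                     "full_length_identical"])
    pids = list(probe_seqs)
    lengths = {len(probe_seqs[p]) for p in pids}
    if len(lengths) != 1:
        raise SpecificityError("bulk scan requires equal-length probes")
    m = lengths.pop()
    pcodes = np.stack([_encode(probe_seqs[p]) for p in pids])
    subjects = [(sid, strand, _encode(s if strand == "+" else revcomp(s)))
                for sid, s in db.items() for strand in ("+", "-")]
    frames = []
    for lo in range(0, len(pids), chunk):
        sl = slice(lo, lo + chunk)
        batch = pcodes[sl]
        for sid, strand, scode in subjects:
            raw, run = _best_ungapped_bulk(batch, scode)
            frames.append(pd.DataFrame({
                "probe_id": pids[sl],
                "subject_id": sid,
                "subject_strand": strand,
                "raw_score": raw,
                "matched_bp": run,
            }))
    out = pd.concat(frames, ignore_index=True)
    out["bit_score"] = bit_score(out["raw_score"].to_numpy(), lambda_, K)
    # +1/-3 scoring: only an all-match, full-length segment can reach m
    out["full_length_identical"] = out["raw_score"] == m
    return out


def specificity_scan(
    probe_seq: str,
    db: Mapping[str, str],
    probe_id: str = "",
    lambda_: float = DEFAULT_LAMBDA,
    K: float = DEFAULT_K,
) -> pd.DataFrame:
    """Scan a probe against a sequence database, both subject strands.

    One row per (subject, strand) with the best ungapped local raw score,
    its bit score, the identity of the optimal segment and the longest
    contiguous exact-match stretch, sorted by bit score descending.
    """
    if not db:
        raise SpecificityError("specificity database is empty")
    pcode = _encode(probe_seq)
    rows = []
    for sid in db:
        sseq = db[sid]
        for strand, s in (("+", sseq), ("-", revcomp(sseq))):
            raw, aln_len, n_match, run = _best_ungapped(pcode, _encode(s))
            rows.append({
                "probe_id": probe_id,
                "subject_id": sid,
                "subject_strand": strand,
                "raw_score": raw,
                "aln_len": aln_len,
                "identity_pct": (100.0 * n_match / aln_len) if aln_len else 0.0,
                "matched_bp": run,
            })
    out = pd.DataFrame(rows)
    out["bit_score"] = bit_score(out["raw_score"].to_numpy(), lambda_, K)
    out["full_length_identical"] = (
        (out["aln_len"] == len(probe_seq)) & (out["identity_pct"] == 100.0)
    )
    return out.sort_values(
        ["bit_score", "subject_id", "subject_strand"],
        ascending=[False, True, True], kind="mergesort",
    ).reset_index(drop=True)


def specificity_pass(
    hits: pd.DataFrame,
    target_id: str,
    threshold_bits: float = DEFAULT_THRESHOLD_BITS,
    probe_length: int = 60,
) -> tuple[bool, str]:
    """Accept a probe iff its own target gives a perfect full-length hit and
    every other subject stays strictly below the bit-score threshold."""
    subjects = set(hits["subject_id"])
    if target_id not in subjects:
        raise SpecificityError(
            f"target {target_id!r} absent from the specificity database"
        )
    self_hits = hits[hits["subject_id"] == target_id]
    if not bool(self_hits["full_length_identical"].any()):
        return False, "no 100% identity full-length hit to its own target"
    others = hits[hits["subject_id"] != target_id]
    offending = others[others["bit_score"] >= threshold_bits]
    if len(offending):
        worst = offending.iloc[0]
        return False, (
            f"cross-hybridisation risk: {worst['subject_id']} "
            f"bit {worst['bit_score']:.1f} >= {threshold_bits}"
        )
    return True, ""
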