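"""Strand-specific 60-mer probe design.

The design pipeline mirrors custom oligo-array practice for EST-derived
transcript assemblies: infer each transcript's strand from protein-hit
reading frames (coding) or EST orientation counts (non-coding), enumerate
every 60-bp window on both strands, filter on composition (%G, %GC, Tm,
homopolymer run), and pick probes anchored near fixed distances from the
transcript 3' end — two sense probes (near 50 bp and 350 bp) plus one
antisense probe (near 50 bp) per transcript.  Candidates that survive the
composition filter go on to the specificity screen (:mod:`satarray.specificity`).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MetricsError(ValueError):
    pass


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TranscriptRecord:
    """An assembled transcript, the unit probes are designed for."""

    id: str
    sequence: str
    orientation: str = "unknown"  # forward | reverse | unknown
    coding: bool = False
    source_pool: str = "primary"  # primary | priority
    category: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()

    @property
    def oriented_sequence(self) -> str:
        """The mRNA-sense sequence (5'->3'): reverse-complemented when the
        assembly is recorded on the reverse strand."""
        if self.orientation == "reverse":
            return revcomp(self.sequence)
        return self.sequence


@dataclasses.dataclass(frozen=True)
class ProbeCriteria:
    """Composition bounds a candidate must satisfy.

    %G is a strict upper bound; %GC, Tm and the homopolymer limit are
    inclusive.  ``anchor`` records that window positions are measured from
    the transcript 3' end.
    """

    length: int = 60
    max_pct_g: float = 50.0          # strict <
    gc_range: tuple[float, float] = (35.0, 55.0)
    tm_range: tuple[float, float] = (68.0, 76.0)
    max_homopolymer: int = 6
    na_molar: float = 0.1
    anchor: str = "3prime"
    position_centers: tuple[int, ...] = (50, 350)
    position_halfwidth: int = 40

    def __post_init__(self) -> None:
        if self.length <= 0 or self.max_homopolymer <= 0:
            raise ConfigError("length and max_homopolymer must be positive")
        lo, hi = self.gc_range
        if not (0 <= lo <= hi <= 100):
            raise ConfigError("gc_range must lie within [0, 100]")


@dataclasses.dataclass
class ArrayDesign:
    """Accepted probes plus spot replication on the physical array."""

    probes: pd.DataFrame          # one row per accepted probe
    duplicates: int = 2
    controls: int = 0
    audit: pd.DataFrame | None = None

    @property
    def n_spots(self) -> int:
        return len(self.probes) * self.duplicates + self.controls

    def spot_table(self) -> pd.DataFrame:
        """One row per physical spot (probe duplicates expanded)."""
        reps = self.probes.loc[self.probes.index.repeat(self.duplicates)].copy()
        reps["spot"] = np.tile(np.arange(1, self.duplicates + 1), len(self.probes))
        return reps.reset_index(drop=True)


def total_probe_features(n_duplicated: int, n_single: int = 0, duplicates: int = 2) -> int:
    """Number of probe features printed on the slide: duplicated probes each
    occupy ``duplicates`` spots, singles one spot each."""
    return n_duplicated * duplicates + n_single


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------

def assign_orientation(
    transcript_id: str,
    hit_frames: Sequence[int] = (),
    est_forward: int = 0,
    est_reverse: int = 0,
) -> str:
    """Infer transcript strand from protein-hit frames and/or EST counts.

    Coding path: the majority sign among the (up to three) top protein-hit
    reading frames decides; a sign tie falls back to the EST majority.
    Non-coding / no-hit path: the EST orientation majority decides.  Exact
    ties or no evidence at all yield ``"unknown"``.
    """
    if len(hit_frames) > 3:
        raise ValueError(f"{transcript_id}: at most 3 hit frames expected")
    if any(f == 0 for f in hit_frames):
        raise ValueError(f"{transcript_id}: reading frame 0 is invalid")

    if hit_frames:
        pos = sum(1 for f in hit_frames if f > 0)
        neg = len(hit_frames) - pos
        if pos > neg:
            return "forward"
        if neg > pos:
            return "reverse"
        # frame-sign tie: fall through to EST evidence

    if est_forward > est_reverse:
        return "forward"
    if est_reverse > est_forward:
        return "reverse"
    if not hit_frames and est_forward == 0 and est_reverse == 0:
        logger.warning("transcript %s has neither protein hits nor EST counts; "
                       "orientation unknown", transcript_id)
    return "unknown"


def assign_orientations(
    transcripts: Iterable[TranscriptRecord],
    hits: pd.DataFrame | None = None,
    ests: pd.DataFrame | None = None,
) -> None:
    """Set ``orientation`` in place for every transcript.

    ``hits`` columns: transcript_id, rank, frame.  ``ests`` columns:
    transcript_id, n_forward, n_reverse.
    """
    frames_by_id: dict[str, list[int]] = {}
    if hits is not None and len(hits):
        for tid, grp in hits.sort_values("rank").groupby("transcript_id"):
            frames_by_id[tid] = [int(f) for f in grp["frame"]]
    est_by_id: dict[str, tuple[int, int]] = {}
    if ests is not None and len(ests):
        for row in ests.itertuples(index=False):
            est_by_id[row.transcript_id] = (int(row.n_forward), int(row.n_reverse))
    for t in transcripts:
        fwd, rev = est_by_id.get(t.id, (0, 0))
        t.orientation = assign_orientation(t.id, frames_by_id.get(t.id, ()), fwd, rev)


# ---------------------------------------------------------------------------
# composition metrics
# ---------------------------------------------------------------------------

def melting_temperature(pct_gc: float, length: int = 60, na_molar: float = 0.1) -> float:
    """Salt-adjusted empirical Tm (degrees C).

    Tm = 81.5 + 16.6*log10([Na+]) + 0.41*%GC - 600/L.  Parameter-light and
    deterministic; adequate for bounding long oligos rather than predicting
    exact duplex stability.
    """
    return 81.5 + 16.6 * math.log10(na_molar) + 0.41 * pct_gc - 600.0 / length


def probe_metrics(seq: str, na_molar: float = 0.1) -> dict[str, float]:
    """Composition metrics of a probe sequence.

    Returns ``pct_g``, ``pct_gc``, ``tm`` and ``max_run`` (longest
    single-base run).  A character outside {A,C,G,T} raises
    :class:`MetricsError` naming its (1-based) position.
    """
    seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in "ACGT":
            raise MetricsError(f"non-ACGT character {ch!r} at position {i}")
    n = len(seq)
    g = seq.count("G")
    gc = g + seq.count("C")
    run = best = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return {
        "pct_g": 100.0 * g / n,
        "pct_gc": 100.0 * gc / n,
        "tm": melting_temperature(100.0 * gc / n, n, na_molar),
        "max_run": best,
    }


def passes_criteria(metrics: Mapping[str, float], crit: ProbeCriteria,
                    length: int | None = None, has_non_acgt: bool = False) -> tuple[bool, list[str]]:
    """Apply the composition filter; returns (pass, named failure reasons)."""
    reasons: list[str] = []
    if length is not None and length != crit.length:
        reasons.append(f"length != {crit.length}")
    if has_non_acgt:
        reasons.append("non-ACGT base")
    else:
        if not metrics["pct_g"] < crit.max_pct_g:
            reasons.append(f"pct_g >= {crit.max_pct_g}")
        if not (crit.gc_range[0] <= metrics["pct_gc"] <= crit.gc_range[1]):
            reasons.append(f"pct_gc outside [{crit.gc_range[0]}, {crit.gc_range[1]}]")
        if not (crit.tm_range[0] <= metrics["tm"] <= crit.tm_range[1]):
            reasons.append(f"tm outside [{crit.tm_range[0]}, {crit.tm_range[1]}]")
        if not metrics["max_run"] <= crit.max_homopolymer:
            reasons.append(f"homopolymer > {crit.max_homopolymer}")
    return (not reasons, reasons)


# ---------------------------------------------------------------------------
# candidate enumeration (vectorised)
# ---------------------------------------------------------------------------

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _position_class(pos3: np.ndarray, crit: ProbeCriteria) -> np.ndarray:
    cls = np.full(pos3.shape, "none", dtype=object)
    for c in crit.position_centers:
        cls[np.abs(pos3 - c) <= crit.position_halfwidth] = f"P{c}"
    return cls


def enumerate_candidates(t: TranscriptRecord, crit: ProbeCriteria = ProbeCriteria()) -> pd.DataFrame:
    """Enumerate every 60-bp window on both strands of an oriented transcript.

    Windows are indexed by ``pos3``: the 1-based distance from the transcript
    3' end to the window's 3'-terminal base (the window nearest the 3' end has
    pos3 = 1).  The sense candidate is the window itself; the antisense
    candidate is its reverse complement.  All candidates carry composition
    metrics and the criteria verdict with named failure reasons.
    """
    if t.orientation == "unknown":
        raise ValueError(f"transcript {t.id!r} has unknown orientation; excluded from design")
    L = len(t.sequence)
    w = crit.length
    if L < w:
        logger.warning("transcript %s shorter than probe length (%d < %d)", t.id, L, w)
        return _empty_candidates()

    seq = t.oriented_sequence
    code = _encode(seq)
    nwin = L - w + 1
    starts = np.arange(nwin)
    # pos3 of window starting at i (0-based): distance from 3' end to base i+w-1
    pos3 = L - starts - (w - 1)

    ok = code >= 0
    is_g = (code == 2) & ok
    is_c = (code == 1) & ok

    def wsum(x: np.ndarray) -> np.ndarray:
        cs = np.concatenate([[0], np.cumsum(x)])
        return cs[w:] - cs[:-w]

    g_cnt = wsum(is_g)
    c_cnt = wsum(is_c)
    bad_cnt = wsum(~ok)

    # longest single-base run inside each window: run length ending at each
    # position, truncated at the window start
    idx = np.arange(L)
    change = np.ones(L, dtype=bool)
    change[1:] = code[1:] != code[:-1]
    last_start = np.maximum.accumulate(np.where(change, idx, 0))
    run = idx - last_start + 1
    Wr = np.lib.stride_tricks.sliding_window_view(run, w)
    max_run = np.minimum(Wr, np.arange(1, w + 1)).max(axis=1)

    pct_g_sense = 100.0 * g_cnt / w
    pct_c_sense = 100.0 * c_cnt / w
    pct_gc = pct_g_sense + pct_c_sense
    tm = 81.5 + 16.6 * math.log10(crit.na_molar) + 0.41 * pct_gc - 600.0 / w

    frames = []
    for strand in ("sense", "antisense"):
        pct_g = pct_g_sense if strand == "sense" else pct_c_sense
        df = pd.DataFrame({
            "transcript_id": t.id,
            "strand": strand,
            "start": starts,
            "pos3": pos3,
            "pct_g": pct_g,
            "pct_gc": pct_gc,
            "tm": tm,
            "max_run": max_run,
            "has_non_acgt": bad_cnt > 0,
        })
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["position_class"] = _position_class(out["pos3"].to_numpy(), crit)

    # verdicts (vectorised mirror of passes_criteria)
    fail = pd.DataFrame({
        "non-ACGT base": out["has_non_acgt"],
        f"pct_g >= {crit.max_pct_g}": ~out["has_non_acgt"] & ~(out["pct_g"] < crit.max_pct_g),
        f"pct_gc outside [{crit.gc_range[0]}, {crit.gc_range[1]}]":
            ~out["has_non_acgt"] & ~out["pct_gc"].between(*crit.gc_range),
        f"tm outside [{crit.tm_range[0]}, {crit.tm_range[1]}]":
            ~out["has_non_acgt"] & ~out["tm"].between(*crit.tm_range),
        f"homopolymer > {crit.max_homopolymer}":
            ~out["has_non_acgt"] & (out["max_run"] > crit.max_homopolymer),
    })
    out["passes"] = ~fail.any(axis=1)
    reason_names = np.array(fail.columns, dtype=object)
    out["fail_reasons"] = [
        ";".join(reason_names[row]) for row in fail.to_numpy()
    ]

    # materialise sequences: sense rows take the window itself, antisense
    # rows its reverse complement
    sense_windows = [seq[i:i + w] for i in starts]
    seqs = np.empty(len(out), dtype=object)
    half = len(starts)
    seqs[:half] = sense_windows
    seqs[half:] = [revcomp(s) for s in sense_windows]
    out["sequence"] = seqs
    out["probe_id"] = (
        out["transcript_id"] + "|" + out["strand"] + "|" + out["pos3"].astype(str)
    )
    return out


def _empty_candidates() -> pd.DataFrame:
    cols = ["transcript_id", "strand", "start", "pos3", "pct_g", "pct_gc", "tm",
            "max_run", "has_non_acgt", "position_class", "passes", "fail_reasons",
            "sequence", "probe_id"]
    return pd.DataFrame(columns=cols)


# ---------------------------------------------------------------------------
# positional selection
# ---------------------------------------------------------------------------

def select_probe_set(candidates: pd.DataFrame, crit: ProbeCriteria = ProbeCriteria()) -> pd.DataFrame:
    """Pick the positional probe complement per transcript.

    Among criteria-passing candidates: at most one sense probe in the P50
    window, one sense probe in the P350 window and one antisense probe in the
    P50 window, each chosen closest to the window centre with ties broken
    toward the smaller pos3.  Transcripts holding both members of a sense +
    antisense P50 pair are flagged ``paired``.
    """
    passing = candidates[candidates["passes"]].copy()
    if passing.empty:
        out = passing.copy()
        out["role"] = pd.Series(dtype=object)
        out["paired"] = pd.Series(dtype=bool)
        return out
    roles = {
        "sense_P50": ("sense", "P50", 50),
        "sense_P350": ("sense", "P350", 350),
        "antisense_P50": ("antisense", "P50", 50),
    }
    chosen = []
    for role, (strand, pclass, center) in roles.items():
        pool = passing[(passing["strand"] == strand) & (passing["position_class"] == pclass)].copy()
        if pool.empty:
            continue
        pool["_dist"] = (pool["pos3"] - center).abs()
        pool = pool.sort_values(["transcript_id", "_dist", "pos3"], kind="mergesort")
        best = pool.groupby("transcript_id", sort=True).head(1).drop(columns="_dist")
        best["role"] = role
        chosen.append(best)
    if not chosen:
        out = passing.iloc[0:0].copy()
        out["role"] = pd.Series(dtype=object)
        out["paired"] = pd.Series(dtype=bool)
        return out
    sel = pd.concat(chosen, ignore_index=True)
    have = sel.groupby("transcript_id")["role"].agg(set)
    paired_ids = set(have[have.map(lambda s: {"sense_P50", "antisense_P50"} <= s)].index)
    sel["paired"] = sel["transcript_id"].isin(paired_ids)
    return sel.sort_values(["transcript_id", "role"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def design_array(
    transcripts: Sequence[TranscriptRecord],
    hits: pd.DataFrame | None,
    ests: pd.DataFrame | None,
    est_db: Mapping[str, str],
    crit: ProbeCriteria = ProbeCriteria(),
    duplicates: int = 2,
    threshold_bits: float = 42.1,
    screen_all_sense: bool = True,
) -> ArrayDesign:
    """Run the design pipeline end to end.

    Steps: orientation assignment, candidate enumeration on both strands,
    composition filtering, positional selection, specificity screening of the
    selected probes (and, when ``screen_all_sense``, of every passing sense
    candidate — their verdicts land in the audit trail).  Deterministic for
    fixed inputs and invariant to input transcript order apart from id order.
    """
    from . import specificity

    transcripts = sorted(transcripts, key=lambda t: t.id)
    assign_orientations(transcripts, hits, ests)

    audit_rows: list[pd.DataFrame] = []
    selected_frames: list[pd.DataFrame] = []
    extra_sense_frames: list[pd.DataFrame] = []
    for t in transcripts:
        if t.orientation == "unknown":
            audit_rows.append(pd.DataFrame([{
                "transcript_id": t.id, "probe_id": "", "stage": "orientation",
                "accepted": False, "reason": "orientation unknown",
            }]))
            continue
        cands = enumerate_candidates(t, crit)
        if cands.empty:
            audit_rows.append(pd.DataFrame([{
                "transcript_id": t.id, "probe_id": "", "stage": "enumeration",
                "accepted": False, "reason": "shorter than probe length",
            }]))
            continue
        failed = cands[~cands["passes"]]
        if len(failed):
            audit_rows.append(pd.DataFrame({
                "transcript_id": failed["transcript_id"],
                "probe_id": failed["probe_id"],
                "stage": "criteria",
                "accepted": False,
                "reason": failed["fail_reasons"],
            }))
        sel = select_probe_set(cands, crit)
        if len(sel):
            selected_frames.append(sel)
        if screen_all_sense:
            extra = cands[cands["passes"] & (cands["strand"] == "sense")]
            extra = extra[~extra["probe_id"].isin(sel["probe_id"] if len(sel) else [])]
            if len(extra):
                extra_sense_frames.append(extra)

    if not selected_frames:
        return ArrayDesign(probes=_empty_candidates().assign(role=None, paired=None),
                           duplicates=duplicates,
                           audit=pd.concat(audit_rows, ignore_index=True) if audit_rows else pd.DataFrame())

    selected = pd.concat(selected_frames, ignore_index=True)
    to_screen = [selected]
    if extra_sense_frames:
        extra = pd.concat(extra_sense_frames, ignore_index=True)
        extra["role"] = "sense_extra"
        extra["paired"] = False
        to_screen.append(extra)
    screen = pd.concat(to_screen, ignore_index=True)

    all_hits = specificity.scan_probes(
        dict(zip(screen["probe_id"], screen["sequence"])), est_db)
    hits_by_probe = dict(tuple(all_hits.groupby("probe_id", sort=False)))
    spec_ok = np.zeros(len(screen), dtype=bool)
    spec_reason = np.empty(len(screen), dtype=object)
    for i, row in enumerate(screen.itertuples(index=False)):
        ok, why = specificity.specificity_pass(
            hits_by_probe[row.probe_id], target_id=row.transcript_id,
            threshold_bits=threshold_bits, probe_length=crit.length,
        )
        spec_ok[i] = ok
        spec_reason[i] = "" if ok else why
    screen = screen.assign(specificity_pass=spec_ok, specificity_reason=spec_reason)

    rejected = screen[~screen["specificity_pass"]]
    if len(rejected):
        audit_rows.append(pd.DataFrame({
            "transcript_id": rejected["transcript_id"],
            "probe_id": rejected["probe_id"],
            "stage": "specificity",
            "accepted": False,
            "reason": rejected["specificity_reason"],
        }))

    accepted = screen[screen["specificity_pass"] & (screen["role"] != "sense_extra")].copy()
    # recompute the paired flag on the post-screen survivors
    have = accepted.groupby("transcript_id")["role"].agg(set)
    paired_ids = set(have[have.map(lambda s: {"sense_P50", "antisense_P50"} <= s)].index)
    accepted["paired"] = accepted["transcript_id"].isin(paired_ids)
    if len(accepted):
        audit_rows.append(pd.DataFrame({
            "transcript_id": accepted["transcript_id"],
            "probe_id": accepted["probe_id"],
            "stage": "accepted",
            "accepted": True,
            "reason": "",
        }))
    audit = pd.concat(audit_rows, ignore_index=True) if audit_rows else pd.DataFrame()
    accepted = accepted.sort_values(["transcript_id", "role"], kind="mergesort").reset_index(drop=True)
    return ArrayDesign(probes=accepted, duplicates=duplicates, audit=audit)
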