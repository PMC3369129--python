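"""Sense/antisense probe-pair matching and pattern tabulation.

For every transcript carrying both an accepted sense and an accepted
antisense probe, the pair's expression pattern at each timepoint is the
pair of three-way statuses: *inside* when the member's signal is not above
background, otherwise *up* (M > 0) or *down* (M < 0); M exactly zero maps
to inside.  Patterns are tabulated as a 3x3 contingency table per
timepoint.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .probes import ArrayDesign

STATUSES = ("up", "down", "inside")


def match_pairs(design: ArrayDesign) -> pd.DataFrame:
    """One (sense probe, antisense probe) pair per transcript that has both.

    When a transcript carries several accepted sense probes the P50 probe is
    preferred, matching the antisense probe's location near the 3' end.
    """
    probes = design.probes
    rows = []
    for tid, grp in probes.groupby("transcript_id", sort=True):
        sense = grp[grp["strand"] == "sense"]
        anti = grp[grp["strand"] == "antisense"]
        if sense.empty or anti.empty:
            continue
        p50 = sense[sense["position_class"] == "P50"]
        s = (p50 if len(p50) else sense).iloc[0]
        a = anti.iloc[0]
        rows.append({"transcript_id": tid,
                     "sense_probe_id": s["probe_id"],
                     "antisense_probe_id": a["probe_id"]})
    return pd.DataFrame(rows, columns=["transcript_id", "sense_probe_id", "antisense_probe_id"])


def classify_member(m: float | None, above_bg: bool) -> str:
    """Three-way status of one pair member at one timepoint."""
    if not above_bg or m is None:
        return "inside"
    if m > 0:
        return "up"
    if m < 0:
        return "down"
    return "inside"  # M exactly zero carries no direction


def classify_pairs(
    pairs: pd.DataFrame,
    normalized: pd.DataFrame,
    above_bg: Mapping[str, set[str]] | set[str],
    timepoint: str,
) -> pd.DataFrame:
    """Classify every pair at one timepoint.

    ``above_bg`` is the set of probes counted as above background at this
    timepoint (or a mapping timepoint -> set).  The member's M is the mean
    normalized log ratio over its spots and arrays at the timepoint.
    """
    if isinstance(above_bg, Mapping):
        above = above_bg.get(timepoint, set())
    else:
        above = above_bg
    sub = normalized[normalized["timepoint"] == timepoint]
    mean_m = sub.groupby("probe_id")["M"].mean()
    rows = []
    for r in pairs.itertuples(index=False):
        statuses = {}
        for side, pid in (("sense", r.sense_probe_id), ("antisense", r.antisense_probe_id)):
            m = mean_m.get(pid)
            statuses[side] = classify_member(None if pd.isna(m) else m, pid in above)
        rows.append({"transcript_id": r.transcript_id, "timepoint": timepoint,
                     "sense_status": statuses["sense"],
                     "antisense_status": statuses["antisense"]})
    return pd.DataFrame(rows, columns=["transcript_id", "timepoint",
                                       "sense_status", "antisense_status"])


def tabulate_patterns(patterns: pd.DataFrame) -> pd.DataFrame:
    """3x3 contingency of (sense_status x antisense_status) per timepoint.

    Returns a long-format table with every cell present (zeros included);
    cells sum to the number of pairs at each timepoint.
    """
    rows = []
    for tp, grp in patterns.groupby("timepoint", sort=True):
        counts = grp.groupby(["sense_status", "antisense_status"]).size()
        for s in STATUSES:
            for a in STATUSES:
                rows.append({"timepoint": tp, "sense_status": s,
                             "antisense_status": a,
                             "n": int(counts.get((s, a), 0))})
    return pd.DataFrame(rows, columns=["timepoint", "sense_status", "antisense_status", "n"])


def concordant_fraction(table: pd.DataFrame) -> float:
    """Fraction of direction-called pairs that agree in direction
    ((up,up) + (down,down)) over all pairs where both members have a
    direction."""
    both = table[table["sense_status"].isin(("up", "down"))
                 & table["antisense_status"].isin(("up", "down"))]
    total = both["n"].sum()
    if total == 0:
        return float("nan")
    agree = both[both["sense_status"] == both["antisense_status"]]["n"].sum()
    return agree / total
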