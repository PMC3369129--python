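"""Intensity-dependent outlier calling (modified HTself) and gene calls.

A credibility window is built from null (A, M) points — self-self spots
when available, otherwise all spots of the comparison under the
most-genes-unchanged assumption.  At each point of a regular A grid the
window bounds are the empirical symmetric quantiles (default 90%
confidence) of M among null points within a sliding A window; windows too
sparse are widened symmetrically until they hold enough points.  A spot is
called up/down when its M exits the interpolated bounds; a gene (probe) is
called per replicate when at least 70% of its usable spots agree; a
differential call requires both biological replicates to agree.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExperimentConfig

logger = logging.getLogger(__name__)


class WindowError(ValueError):
    pass


@dataclasses.dataclass
class HTselfWindow:
    """Lower/upper credibility bounds for M, indexed by A."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence: float
    window_width: float

    def bounds_at(self, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation between grid points; nearest-bound
        extrapolation (with a warning) outside the grid range."""
        A = np.asarray(A, dtype=float)
        if np.any(A < self.grid[0]) or np.any(A > self.grid[-1]):
            logger.warning("A values outside the window grid; using nearest bounds")
        lo = np.interp(A, self.grid, self.lower)
        hi = np.interp(A, self.grid, self.upper)
        return lo, hi


def build_htself_window(
    null_A: Sequence[float],
    null_M: Sequence[float],
    confidence: float = 0.90,
    window_width: float = 1.0,
    min_points: int = 30,
    grid_step: float = 0.1,
) -> HTselfWindow:
    """Build the credibility window from null (A, M) points.

    At each grid point the bounds are the ((1-c)/2, 1-(1-c)/2) empirical
    quantiles of M among null points within +/- window_width/2 in A; a
    window holding fewer than ``min_points`` is widened symmetrically until
    it qualifies.
    """
    A = np.asarray(null_A, dtype=float)
    M = np.asarray(null_M, dtype=float)
    keep = np.isfinite(A) & np.isfinite(M)
    A, M = A[keep], M[keep]
    if len(A) < min_points:
        raise WindowError(f"need at least {min_points} null points, got {len(A)}")
    order = np.argsort(A, kind="mergesort")
    A, M = A[order], M[order]

    lo_q = (1.0 - confidence) / 2.0
    hi_q = 1.0 - lo_q
    grid = np.arange(A[0], A[-1] + grid_step / 2, grid_step)
    lower = np.empty(len(grid))
    upper = np.empty(len(grid))
    half0 = window_width / 2.0
    for i, g in enumerate(grid):
        half = half0
        left, right = np.searchsorted(A, [g - half, g + half], side="left")
        right = np.searchsorted(A, g + half, side="right")
        while right - left < min_points:
            half *= 1.5
            left = np.searchsorted(A, g - half, side="left")
            right = np.searchsorted(A, g + half, side="right")
        m = M[left:right]
        if confidence >= 1.0:
            lower[i], upper[i] = m.min(), m.max()
        else:
            lower[i], upper[i] = np.quantile(m, [lo_q, hi_q])
    return HTselfWindow(grid=grid, lower=lower, upper=upper,
                        confidence=confidence, window_width=window_width)


def call_spot(M, A, window: HTselfWindow):
    """Classify spots: 'up' if M strictly above the upper bound at A,
    'down' if strictly below the lower bound, else 'within'."""
    M = np.asarray(M, dtype=float)
    scalar = M.ndim == 0
    M = np.atleast_1d(M)
    lo, hi = window.bounds_at(np.atleast_1d(np.asarray(A, dtype=float)))
    out = np.full(M.shape, "within", dtype=object)
    out[M > hi] = "up"
    out[M < lo] = "down"
    return out[0] if scalar else out


def call_gene(statuses: Sequence[str], majority: float = 0.70) -> tuple[str, float]:
    """Majority vote over a probe's usable spots within one replicate.

    Returns ``(status, support)``; ``not_called`` unless one of up/down/within
    reaches the majority fraction.  Missing spots must already be excluded.
    """
    statuses = [s for s in statuses if s]
    n = len(statuses)
    if n == 0:
        return "not_called", 0.0
    counts = pd.Series(statuses).value_counts()
    top, top_n = counts.index[0], int(counts.iloc[0])
    support = top_n / n
    if support >= majority:
        return top, support
    return "not_called", support


@dataclasses.dataclass
class DECall:
    unit_id: str
    timepoint: str
    status: str                  # up | down | not_called
    support: float
    replicate_consistent: bool


def call_differential(rep1: tuple[str, float], rep2: tuple[str, float],
                      unit_id: str = "", timepoint: str = "") -> DECall:
    """Combine the two biological replicates: a direction is called only
    when both replicates independently called the same direction."""
    s1, p1 = rep1
    s2, p2 = rep2
    consistent = s1 == s2
    status = s1 if (consistent and s1 in ("up", "down")) else "not_called"
    support = min(p1, p2) if status != "not_called" else 0.0
    return DECall(unit_id=unit_id, timepoint=timepoint, status=status,
                  support=support, replicate_consistent=consistent)


# ---------------------------------------------------------------------------
# experiment-level drivers
# ---------------------------------------------------------------------------

def call_experiment(
    normalized: pd.DataFrame,
    config: ExperimentConfig,
    null_points: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Produce one DECall row per probe x timepoint.

    The credibility window is built per timepoint from ``null_points``
    (columns A, M — e.g. self-self spots) when given, otherwise from all
    spots of that timepoint's comparison (most-genes-unchanged assumption;
    the mode in use is logged).
    """
    th = config.thresholds
    rows = []
    for tp in config.timepoints:
        sub = normalized[normalized["timepoint"] == tp]
        if sub.empty:
            continue
        if null_points is not None:
            nullA, nullM = null_points["A"], null_points["M"]
            mode = "self-self reference"
        else:
            nullA, nullM = sub["A"], sub["M"]
            mode = "all spots of the comparison"
        logger.info("timepoint %s: HTself null set = %s (%d points)", tp, mode, len(nullA))
        window = build_htself_window(
            nullA, nullM,
            confidence=th["confidence"], window_width=th["window_width"],
            min_points=th["min_points"], grid_step=th["grid_step"],
        )
        sub = sub.copy()
        sub["status"] = call_spot(sub["M"].to_numpy(), sub["A"].to_numpy(), window)
        reps = sorted(sub["replicate_id"].unique())
        per_rep = {
            rep: {pid: call_gene(list(g["status"]), th["majority"])
                  for pid, g in sub[sub["replicate_id"] == rep].groupby("probe_id")}
            for rep in reps
        }
        probes = sorted(sub["probe_id"].unique())
        for pid in probes:
            calls = [per_rep[rep].get(pid, ("not_called", 0.0)) for rep in reps]
            if len(calls) == 1:
                calls.append(("not_called", 0.0))
            de = call_differential(calls[0], calls[1], unit_id=pid, timepoint=tp)
            rows.append(dataclasses.asdict(de))
    return pd.DataFrame(rows)


def above_background_sets(
    flagged: pd.DataFrame,
    config: ExperimentConfig,
    probe_strand: Mapping[str, str] | None = None,
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Per-sample expressed probe sets under the two-replicate rule.

    A probe is *expressed* in a sample iff, in each of the (>= 2) replicate
    arrays carrying that sample, the majority of its duplicate spots is
    well above background.  Returns the sets plus a counts table by sample
    (and by strand when ``probe_strand`` maps probe_id -> sense/antisense).
    """
    expressed: dict[str, set[str]] = {}
    for sample in config.samples:
        per_rep_sets = []
        for a in config.arrays:
            for ch, s in (("green", a.green_sample), ("red", a.red_sample)):
                if s != sample:
                    continue
                sub = flagged[(flagged["array_id"] == a.array_id) & (flagged["channel"] == ch)]
                frac = sub.groupby("probe_id")["is_well_above_bg"].mean()
                per_rep_sets.append(set(frac[frac > 0.5].index))
        if not per_rep_sets:
            expressed[sample] = set()
        else:
            expressed[sample] = set.intersection(*per_rep_sets)

    rows = []
    for sample, probes in expressed.items():
        if probe_strand:
            for strand in ("sense", "antisense"):
                total = sum(1 for p, s in probe_strand.items() if s == strand)
                above = sum(1 for p in probes if probe_strand.get(p) == strand)
                rows.append({"sample": sample, "strand": strand,
                             "total": total, "above_background": above,
                             "pct": percent_above_background(above, total)})
        else:
            rows.append({"sample": sample, "strand": "all",
                         "total": flagged["probe_id"].nunique(),
                         "above_background": len(probes),
                         "pct": percent_above_background(len(probes), flagged["probe_id"].nunique())})
    return expressed, pd.DataFrame(rows)


def percent_above_background(above: int, total: int) -> float:
    """Percentage of probes above background, to one decimal place."""
    if total == 0:
        return 0.0
    return round(100.0 * above / total, 1)
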