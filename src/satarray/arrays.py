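"""Two-channel signal processing: background flags, normalization, M/A.

The calling protocol treats each channel of each array as an independent
signal.  A spot enters the analysis only when its foreground is both
statistically above the local background (two-sided Welch t test on the
summary statistics) and practically above it (background-subtracted signal
exceeding ``k`` background standard deviations, k = 2.6 by default).
Normalization then proceeds in two per-signal steps: a global (linear)
median rescaling across the whole intensity range, followed by a
non-linear LOWESS correction of each channel's log2 intensity against a
per-probe pseudo-reference, which removes intensity-dependent dye bias.
Log ratios (M) and mean intensities (A) are recomputed from the normalized
channels, with dye-swapped arrays sign-harmonised to experiment-vs-control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import ExperimentConfig

logger = logging.getLogger(__name__)

LOG_FLOOR = 1e-6  # floor for background-subtracted signals before log2


class FlagError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# background flags
# ---------------------------------------------------------------------------

def compute_spot_flags(features: pd.DataFrame, alpha: float = 0.01, k: float = 2.6) -> pd.DataFrame:
    """Attach background-significance flags to a feature table.

    Adds ``bg_sub_signal`` (foreground minus background mean),
    ``is_pos_and_signif`` (Welch two-sample two-sided t test of foreground
    vs background pixels rejects at ``alpha`` *and* the foreground mean is
    strictly greater) and ``is_well_above_bg`` (additionally the
    background-subtracted signal strictly exceeds ``k`` background SDs).
    """
    fg_n = features["fg_n"].to_numpy(dtype=float)
    bg_n = features["bg_n"].to_numpy(dtype=float)
    if np.any(fg_n < 2) or np.any(bg_n < 2):
        raise FlagError("pixel counts must be >= 2 for the t test")
    fg = features["fg_mean"].to_numpy(dtype=float)
    bg = features["bg_mean"].to_numpy(dtype=float)
    v1 = features["fg_sd"].to_numpy(dtype=float) ** 2 / fg_n
    v2 = features["bg_sd"].to_numpy(dtype=float) ** 2 / bg_n
    denom = np.sqrt(v1 + v2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (fg - bg) / denom
        df = (v1 + v2) ** 2 / (v1**2 / (fg_n - 1) + v2**2 / (bg_n - 1))
        # zero-variance spots: identical fg/bg pixels; equal means are n.s.
        t = np.where(denom == 0,
                     np.where(fg == bg, 0.0, np.inf * np.sign(fg - bg)), t)
    df = np.where(np.isfinite(df), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)

    out = features.copy()
    out["bg_sub_signal"] = fg - bg
    out["is_pos_and_signif"] = (p < alpha) & (fg > bg)
    out["is_well_above_bg"] = out["is_pos_and_signif"] & (out["bg_sub_signal"] > k * features["bg_sd"])
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(
    features: pd.DataFrame,
    config: ExperimentConfig,
    frac: float | None = None,
    it: int | None = None,
) -> pd.DataFrame:
    """Normalize an experiment's feature tables and compute M/A per spot.

    Rows failing ``is_well_above_bg`` are excluded (not imputed).  Per
    channel: (1) median-scale the background-subtracted intensities to the
    experiment-wide median; (2) subtract a LOWESS fit of the channel's log2
    intensity deviation from a per-probe pseudo-reference (the median log2
    intensity of the probe over all channels/arrays).  M is oriented
    experiment minus control using each array's dye layout.

    Returns one row per usable spot: probe_id, array_id, spot, timepoint,
    replicate_id, M, A plus the per-channel normalized log2 intensities.
    """
    th = config.thresholds
    frac = th["lowess_frac"] if frac is None else frac
    it = th["lowess_it"] if it is None else it

    flagged = features
    if "is_well_above_bg" not in flagged.columns:
        flagged = compute_spot_flags(features, th["alpha"], th["bg_sd_multiplier"])
    usable = flagged[flagged["is_well_above_bg"]].copy()
    if usable.empty:
        raise NormalizationError("no spot passed the background flags")
    usable["signal"] = usable["bg_sub_signal"].clip(lower=LOG_FLOOR)

    # step 1: global median scaling per channel of each array
    target = float(usable["signal"].median())
    med = usable.groupby(["array_id", "channel"])["signal"].transform("median")
    if (med <= 0).any():
        raise NormalizationError("non-positive channel median")
    usable["signal"] = usable["signal"] * (target / med)
    usable["log2_intensity"] = np.log2(usable["signal"])

    # step 2: LOWESS of each channel's deviation from the per-probe
    # pseudo-reference, fitted against the reference intensity
    ref = usable.groupby("probe_id")["log2_intensity"].median()
    usable["ref"] = usable["probe_id"].map(ref)
    corrected = np.empty(len(usable))
    usable = usable.reset_index(drop=True)
    for (_, _), idx in usable.groupby(["array_id", "channel"]).groups.items():
        sub = usable.loc[idx]
        d = (sub["log2_intensity"] - sub["ref"]).to_numpy()
        x = sub["ref"].to_numpy()
        if len(idx) < 10 or np.ptp(x) == 0:
            trend = np.full(len(idx), np.median(d))
        else:
            trend = lowess(d, x, frac=frac, it=it, xvals=x)
            trend = np.where(np.isfinite(trend), trend, np.median(d))
        corrected[np.asarray(idx)] = sub["log2_intensity"].to_numpy() - trend
    usable["log2_norm"] = corrected

    # recombine channels into M/A per spot
    layout = {a.array_id: a for a in config.arrays}
    wide = usable.pivot_table(
        index=["probe_id", "array_id", "spot"],
        columns="channel", values="log2_norm", aggfunc="first",
    ).reset_index()
    if not {"green", "red"} <= set(wide.columns):
        raise NormalizationError("both channels required to form M/A")
    wide = wide.dropna(subset=["green", "red"])
    arr = wide["array_id"].map(layout)
    swap = arr.map(lambda a: a.dye_swap).to_numpy(dtype=bool)
    exp_log2 = np.where(swap, wide["green"], wide["red"])
    ctl_log2 = np.where(swap, wide["red"], wide["green"])
    wide["M"] = exp_log2 - ctl_log2
    wide["A"] = 0.5 * (wide["green"] + wide["red"])
    wide["timepoint"] = arr.map(lambda a: a.timepoint)
    wide["replicate_id"] = arr.map(lambda a: a.replicate_id)
    cols = ["probe_id", "array_id", "spot", "timepoint", "replicate_id",
            "green", "red", "M", "A"]
    return wide[cols].sort_values(["timepoint", "array_id", "probe_id", "spot"],
                                  kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# qPCR utility
# ---------------------------------------------------------------------------

def ddct_ratio(ct_target_exp: float, ct_ref_exp: float,
               ct_target_ctl: float, ct_ref_ctl: float) -> float:
    """Relative expression ratio by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) in the experimental condition minus the
    same difference in the control condition; the ratio is 2**(-ddCt).
    """
    ddct = (ct_target_exp - ct_ref_exp) - (ct_target_ctl - ct_ref_ctl)
    return float(2.0 ** (-ddct))
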