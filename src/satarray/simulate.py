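"""Synthetic fixtures with known ground truth.

Three generators cover the inputs the toolkit consumes:

* a transcript pool with planted open reading frames and a recorded true
  strand for every transcript (what EST assemblies provide);
* protein-hit reading frames and EST orientation counts whose majority
  matches the true strand with a configurable error rate (what similarity
  searches provide);
* two-channel spot-level feature tables with intensity-dependent dye bias,
  log-normal multiplicative foreground noise, Gaussian additive background,
  duplicate spots, dye-swapped biological replicates and planted log2 fold
  changes (what a feature-extraction export provides).

Every generator is deterministic for a fixed seed (all randomness flows
from one ``numpy`` seed sequence) and returns a truth table sufficient to
score any downstream caller without re-reading sequences.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ArrayLayout, ExperimentConfig
from .probes import ArrayDesign, TranscriptRecord, revcomp

DEFAULT_CATEGORIES = (
    "signal transduction", "carbohydrate metabolism", "cell wall metabolism",
    "stress response", "transcription factor", "transporters",
    "RNA metabolism", "protein metabolism", "lipid metabolism", "unknown",
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.array(list("ACGT"))


class SimConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# transcript pool
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimTranscriptomeSpec:
    """Parameters of the simulated transcript pool.

    ``length_range`` must allow at least 200 bp so the positional probe
    windows near the 3' end have room.  ``antisense_truth_fraction`` marks
    the fraction of transcripts recorded as carrying genuine antisense
    transcription (used by the array generator to plant correlated pairs).
    """

    n_transcripts: int = 100
    length_range: tuple[int, int] = (300, 900)
    coding_fraction: float = 0.7
    est_depth_range: tuple[int, int] = (4, 20)
    antisense_truth_fraction: float = 0.3
    gc_content: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 1:
            raise SimConfigError("n_transcripts must be >= 1")
        if self.length_range[0] < 200 or self.length_range[0] > self.length_range[1]:
            raise SimConfigError("length_range minimum must be >= 200 bp")
        for name in ("coding_fraction", "antisense_truth_fraction", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.est_depth_range[0] < 1:
            raise SimConfigError("est_depth_range minimum must be >= 1")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=n, p=p))


def _plant_orf(rng: np.random.Generator, seq: str) -> str:
    """Overwrite the middle of a sense-strand sequence with an open reading
    frame: ATG, stop-free codons, then a stop codon."""
    L = len(seq)
    orf_codons = max(20, int(0.5 * L) // 3)
    start = int(rng.integers(3, max(4, L - 3 * orf_codons - 6)))
    codons = ["ATG"]
    while len(codons) < orf_codons:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(str(rng.choice(sorted(_STOPS))))
    orf = "".join(codons)
    return seq[:start] + orf + seq[start + len(orf):]


def gen_transcriptome(spec: SimTranscriptomeSpec) -> tuple[list[TranscriptRecord], pd.DataFrame]:
    """Generate the transcript pool and its truth table.

    Each transcript records a true orientation; coding transcripts carry a
    planted ORF on the true strand (the stored sequence is the reverse
    complement of the mRNA when the true orientation is ``reverse``,
    emulating assemblies built in either direction).
    """
    rng = np.random.default_rng(spec.seed)
    transcripts: list[TranscriptRecord] = []
    rows = []
    for i in range(spec.n_transcripts):
        tid = f"T{i:05d}"
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        coding = bool(rng.random() < spec.coding_fraction)
        orientation = "forward" if rng.random() < 0.5 else "reverse"
        mrna = _random_seq(rng, L, spec.gc_content)
        if coding:
            mrna = _plant_orf(rng, mrna)
        stored = mrna if orientation == "forward" else revcomp(mrna)
        category = str(rng.choice(DEFAULT_CATEGORIES))
        has_antisense = bool(rng.random() < spec.antisense_truth_fraction)
        transcripts.append(TranscriptRecord(
            id=tid, sequence=stored, orientation="unknown",
            coding=coding, category=category,
        ))
        rows.append({"transcript_id": tid, "true_orientation": orientation,
                     "coding": coding, "length": L, "category": category,
                     "has_antisense": has_antisense})
    return transcripts, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orientation evidence
# ---------------------------------------------------------------------------

def gen_hits_and_ests(
    truth: pd.DataFrame,
    error_rate: float = 0.0,
    seed: int = 0,
    est_depth_range: tuple[int, int] = (4, 20),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate protein-hit frames (coding) and EST counts (non-coding).

    The majority evidence matches the recorded true orientation with
    probability exactly ``1 - error_rate``: the majority's correctness is
    drawn first and the individual records are then made consistent with it
    (strict majorities; exact ties never arise from this generator).
    """
    if not 0.0 <= error_rate <= 1.0:
        raise SimConfigError("error_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    hit_rows, est_rows = [], []
    for r in truth.itertuples(index=False):
        true_sign = 1 if r.true_orientation == "forward" else -1
        correct = rng.random() >= error_rate
        maj_sign = true_sign if correct else -true_sign
        if r.coding:
            # two frames carry the majority sign; the third usually agrees
            signs = [maj_sign, maj_sign,
                     maj_sign if rng.random() < 0.7 else -maj_sign]
            for rank, s in enumerate(signs, start=1):
                frame = int(s * rng.integers(1, 4))
                hit_rows.append({"transcript_id": r.transcript_id,
                                 "rank": rank, "frame": frame})
        else:
            depth = int(rng.integers(est_depth_range[0], est_depth_range[1] + 1))
            minority = int(rng.binomial(depth, 0.25))
            while 2 * minority >= depth:
                minority = int(rng.binomial(depth, 0.25))
            majority = depth - minority
            fwd, rev = (majority, minority) if maj_sign > 0 else (minority, majority)
            est_rows.append({"transcript_id": r.transcript_id,
                             "n_forward": fwd, "n_reverse": rev})
    hits = pd.DataFrame(hit_rows, columns=["transcript_id", "rank", "frame"])
    ests = pd.DataFrame(est_rows, columns=["transcript_id", "n_forward", "n_reverse"])
    return hits, ests


# ---------------------------------------------------------------------------
# array signals
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SimArraySpec:
    """Parameters of the simulated two-channel hybridisations.

    ``de_plan`` maps probe ids to planted log2 fold changes (scalar, applied
    at every timepoint, or a ``{timepoint: fold}`` mapping).  ``unexpressed``
    probes hybridise at background level only.  Default noise: 10%
    multiplicative foreground CV, background 50 +/- 10 intensity units —
    typical of mid-range two-colour scans once saturated and ghost spots are
    excluded.
    """

    design: ArrayDesign
    n_timepoints: int = 3
    de_plan: Mapping[str, object] = dataclasses.field(default_factory=dict)
    unexpressed: frozenset[str] | set[str] = dataclasses.field(default_factory=set)
    sat_correlation: float = 0.9
    dye_bias_amplitude: float = 0.3
    bg_mean: float = 50.0
    bg_sd: float = 10.0
    fg_noise_cv: float = 0.1
    baseline_range: tuple[float, float] = (7.0, 13.0)
    n_duplicates_per_array: int = 2
    pixels: int = 32
    dye_swap: bool = True
    timepoint_labels: Sequence[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_duplicates_per_array < 1:
            raise SimConfigError("n_duplicates_per_array must be >= 1")
        if self.bg_sd <= 0:
            raise SimConfigError("bg_sd must be positive")
        if not -1.0 <= self.sat_correlation <= 1.0:
            raise SimConfigError("sat_correlation must lie in [-1, 1]")
        if not 0.0 <= self.fg_noise_cv <= 1.0:
            raise SimConfigError("fg_noise_cv must lie in [0, 1]")
        probe_ids = set(self.design.probes["probe_id"])
        stray = set(self.de_plan) - probe_ids
        if stray:
            raise SimConfigError(
                f"de_plan probes absent from the design: {sorted(stray)[:5]}"
            )

    @property
    def timepoints(self) -> list[str]:
        if self.timepoint_labels is not None:
            return list(self.timepoint_labels)
        defaults = ["24h", "72h", "120h"]
        if self.n_timepoints <= 3:
            return defaults[: self.n_timepoints]
        return defaults + [f"t{i}" for i in range(4, self.n_timepoints + 1)]


def _fold_at(plan_entry, tp: str) -> float:
    if plan_entry is None:
        return 0.0
    if isinstance(plan_entry, Mapping):
        return float(plan_entry.get(tp, 0.0))
    return float(plan_entry)


def gen_array_signals(
    spec: SimArraySpec,
) -> tuple[pd.DataFrame, pd.DataFrame, ExperimentConfig]:
    """Simulate spot-level feature tables for the whole experiment.

    For each timepoint two biological-replicate arrays are produced (the
    second dye-swapped when ``dye_swap``), each spot replicated
    ``n_duplicates_per_array`` times.  A probe's foreground is

        baseline * 2^(+/- fold/2) * dye-bias(A) * lognormal-noise + background

    with the fold split symmetrically between the experimental and control
    channels and the dye bias a smooth quadratic of baseline intensity
    scaled by ``dye_bias_amplitude`` (applied to the red channel).  Returns
    ``(features, truth, config)`` where truth records the planted fold and
    expressed status per probe and timepoint.
    """
    rng = np.random.default_rng(spec.seed)
    probes = spec.design.probes["probe_id"].to_numpy()
    n_probes = len(probes)
    baseline = rng.uniform(*spec.baseline_range, size=n_probes)
    unexpressed = np.isin(probes, list(spec.unexpressed))

    b_lo, b_hi = spec.baseline_range
    mid, half = 0.5 * (b_lo + b_hi), 0.5 * (b_hi - b_lo)
    bias_log2 = spec.dye_bias_amplitude * (((baseline - mid) / half) ** 2 - 0.5)
    sigma = np.sqrt(np.log1p(spec.fg_noise_cv ** 2))

    arrays: list[ArrayLayout] = []
    feature_rows = []
    truth_rows = []
    for tp in spec.timepoints:
        folds = np.array([_fold_at(spec.de_plan.get(p), tp) for p in probes])
        for p, f, ux in zip(probes, folds, unexpressed):
            truth_rows.append({"probe_id": p, "timepoint": tp,
                               "true_log2_fold": f, "expressed": not ux})
        ctl, exp = f"ctl_{tp}", f"exp_{tp}"
        for rep in (1, 2):
            swapped = spec.dye_swap and rep == 2
            aid = f"{tp}_rep{rep}"
            arrays.append(ArrayLayout(
                array_id=aid,
                green_sample=exp if swapped else ctl,
                red_sample=ctl if swapped else exp,
                replicate_id=f"rep{rep}", timepoint=tp, dye_swap=swapped,
            ))
            for channel in ("green", "red"):
                on_green = (exp if swapped else ctl)
                sample = on_green if channel == "green" else (ctl if swapped else exp)
                is_exp = sample == exp
                log2_true = baseline + (0.5 if is_exp else -0.5) * folds
                true_sig = np.where(unexpressed, 0.0, 2.0 ** log2_true)
                if channel == "red":
                    true_sig = true_sig * 2.0 ** bias_log2
                for spot in range(1, spec.n_duplicates_per_array + 1):
                    if sigma > 0:
                        noise = rng.lognormal(-sigma**2 / 2, sigma, size=n_probes)
                    else:
                        noise = np.ones(n_probes)
                    bg_true = rng.normal(spec.bg_mean, spec.bg_sd / np.sqrt(spec.pixels),
                                         size=n_probes)
                    fg_mean = true_sig * noise + bg_true
                    bg_mean = rng.normal(spec.bg_mean, spec.bg_sd / np.sqrt(spec.pixels),
                                         size=n_probes)
                    fg_sd = np.maximum(spec.bg_sd, spec.fg_noise_cv * fg_mean)
                    feature_rows.append(pd.DataFrame({
                        "probe_id": probes,
                        "array_id": aid,
                        "spot": spot,
                        "channel": channel,
                        "sample_id": sample,
                        "fg_mean": fg_mean,
                        "fg_sd": fg_sd,
                        "fg_n": spec.pixels,
                        "bg_mean": bg_mean,
                        "bg_sd": spec.bg_sd,
                        "bg_n": spec.pixels,
                    }))
    features = pd.concat(feature_rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    config = ExperimentConfig(arrays=arrays, seed=spec.seed)
    return features, truth, config


# ---------------------------------------------------------------------------
# helpers for planting experiments
# ---------------------------------------------------------------------------

def gen_design(n_transcripts: int, duplicates: int = 2, seed: int = 0,
               sense_p350_fraction: float = 0.3) -> ArrayDesign:
    """Construct a synthetic probe design directly, without sequences.

    A stand-in for a screened design used when only the analysis layers are
    under study: every transcript gets a sense and an antisense P50 probe
    (ids ``T{i}|sense|50`` etc.), a random subset a sense P350 probe.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_transcripts):
        tid = f"T{i:05d}"
        rows.append({"transcript_id": tid, "strand": "sense", "pos3": 50,
                     "position_class": "P50", "role": "sense_P50", "paired": True})
        rows.append({"transcript_id": tid, "strand": "antisense", "pos3": 50,
                     "position_class": "P50", "role": "antisense_P50", "paired": True})
        if rng.random() < sense_p350_fraction:
            rows.append({"transcript_id": tid, "strand": "sense", "pos3": 350,
                         "position_class": "P350", "role": "sense_P350", "paired": True})
    cols = ["transcript_id", "strand", "pos3", "position_class", "role", "paired"]
    df = pd.DataFrame(rows, columns=cols)
    df["probe_id"] = df["transcript_id"] + "|" + df["strand"] + "|" + df["pos3"].astype(str)
    df["sequence"] = ""
    return ArrayDesign(probes=df, duplicates=duplicates)


def make_sat_de_plan(
    design: ArrayDesign,
    fraction_de: float = 0.05,
    fold_magnitude: float = 2.0,
    sat_correlation: float = 0.9,
    seed: int = 0,
) -> dict[str, float]:
    """Plant correlated sense/antisense fold changes on paired transcripts.

    A ``fraction_de`` subset of transcripts receives a sense fold of
    +/- ``fold_magnitude``; its antisense partner receives
    rho * fold + sqrt(1 - rho^2) * N(0, fold_magnitude), so the expected
    concordance of pair directions rises monotonically with rho.
    """
    rng = np.random.default_rng(seed)
    probes = design.probes
    plan: dict[str, float] = {}
    rho = sat_correlation
    for tid, grp in probes.groupby("transcript_id", sort=True):
        if rng.random() >= fraction_de:
            continue
        sense = grp[grp["strand"] == "sense"]
        anti = grp[grp["strand"] == "antisense"]
        f_s = float(fold_magnitude * rng.choice([-1.0, 1.0]))
        for pid in sense["probe_id"]:
            plan[pid] = f_s
        if len(anti):
            f_a = rho * f_s + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(0, fold_magnitude)
            plan[anti["probe_id"].iloc[0]] = float(f_a)
    return plan
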