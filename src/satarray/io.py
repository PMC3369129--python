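"""Readers, writers and experiment configuration.

All interchange is plain text: FASTA for sequences, TSV for tables, YAML for
experiment configuration.  Writers are deterministic (stable row order, floats
formatted to 6 significant digits) so that identical inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class ParseError(ValueError):
    """Raised when an input file violates the documented format."""


#: columns required of a feature table, one row per spot x channel
FEATURE_COLUMNS = [
    "probe_id",
    "array_id",
    "spot",
    "channel",
    "sample_id",
    "fg_mean",
    "fg_sd",
    "fg_n",
    "bg_mean",
    "bg_sd",
    "bg_n",
]

_FEATURE_DTYPES = {
    "probe_id": str,
    "array_id": str,
    "channel": str,
    "sample_id": str,
}


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; CRLF and LF line endings are both accepted.
    Duplicate record ids and empty sequences raise :class:`ParseError`
    naming the offending record.
    """
    records: dict[str, str] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r} (record #{i})")
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {rec.id!r} (record #{i})")
        records[rec.id] = seq
    return records


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a spot-level feature table (TSV).

    Returns ``(rows, rejected)``.  ``rows`` contains the typed, validated
    rows in file order; ``rejected`` holds rows dropped for violating basic
    sanity rules (negative SDs, pixel counts < 2) together with a ``reason``
    column.  Unknown extra columns are preserved but ignored downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype=_FEATURE_DTYPES)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    reasons = pd.Series("", index=df.index, dtype=str)
    reasons[df["fg_sd"] < 0] = "negative fg_sd"
    reasons[df["bg_sd"] < 0] = "negative bg_sd"
    reasons[(df["fg_n"] < 2) | (df["bg_n"] < 2)] = "pixel count < 2"
    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    return df[~bad].reset_index(drop=True), rejected.reset_index(drop=True)


def _format_float(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a TSV deterministically: stable order, 6 significant digits."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: f"{v:.6g}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ArrayLayout:
    """One hybridisation: which samples sit on which channel.

    ``dye_swap`` is true when the *experimental* sample was labelled on the
    green channel (the swapped orientation); when false the experimental
    sample is on red.
    """

    array_id: str
    green_sample: str
    red_sample: str
    replicate_id: str
    timepoint: str
    dye_swap: bool = False

    @property
    def experiment_sample(self) -> str:
        return self.green_sample if self.dye_swap else self.red_sample

    @property
    def control_sample(self) -> str:
        return self.red_sample if self.dye_swap else self.green_sample


@dataclasses.dataclass
class ExperimentConfig:
    """Hybridisation scheme plus analysis thresholds.

    Each timepoint must carry at least two replicate arrays so that the
    two-replicate agreement rule is applicable.
    """

    arrays: list[ArrayLayout]
    thresholds: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    DEFAULT_THRESHOLDS = {
        "alpha": 0.01,
        "bg_sd_multiplier": 2.6,
        "confidence": 0.90,
        "window_width": 1.0,
        "min_points": 30,
        "majority": 0.70,
        "lowess_frac": 0.3,
        "lowess_it": 3,
        "grid_step": 0.1,
    }

    def __post_init__(self) -> None:
        merged = dict(self.DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        ids = [a.array_id for a in self.arrays]
        if len(set(ids)) != len(ids):
            raise ParseError("duplicate array_id in experiment config")
        for tp in self.timepoints:
            if len(self.arrays_for(tp)) < 2:
                raise ParseError(
                    f"timepoint {tp!r} has fewer than 2 replicate arrays; "
                    "the two-replicate rule requires at least 2"
                )

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for a in self.arrays:
            if a.timepoint not in seen:
                seen.append(a.timepoint)
        return seen

    def arrays_for(self, timepoint: str) -> list[ArrayLayout]:
        return [a for a in self.arrays if a.timepoint == timepoint]

    @property
    def samples(self) -> list[str]:
        seen: list[str] = []
        for a in self.arrays:
            for s in (a.green_sample, a.red_sample):
                if s not in seen:
                    seen.append(s)
        return seen

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "arrays": [dataclasses.asdict(a) for a in self.arrays],
            "thresholds": self.thresholds,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        arrays = [ArrayLayout(**a) for a in doc["arrays"]]
        return cls(arrays=arrays, thresholds=doc.get("thresholds", {}), seed=doc.get("seed", 0))


def write_run_log(path: str | Path, stage: str, params: Mapping) -> None:
    """Emit a machine-readable parameter log sufficient to re-run a stage."""
    import satarray

    doc = {"stage": stage, "version": satarray.__version__, "params": dict(params)}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")
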