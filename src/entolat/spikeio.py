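"""Data model and on-disk formats for trial-aligned spike-timestamp datasets.

Conventions
-----------
Time origin is stimulus onset (t = 0).  The analysis epoch is the closed
interval [-pre_window, stim_duration + post_window]; the baseline window is
[-pre_window, 0), the ON window [0, stim_duration) and the OFF window
[stim_duration, stim_duration + post_window), all half-open.  Spike times are
stored in seconds; bin membership is floor((t + pre_window) / bin_width).
Trials are assumed already aligned to stimulus onset.

Formats
-------
* Spike table: CSV ``unit_id,condition,trial,spike_time_s`` — one row per
  spike, condition in {contra, ipsi, bilateral}.
* Unit metadata: CSV ``unit_id,subject_id,treatment,hemisphere[,ground_truth]``.
* Protocol / analysis config: a single YAML (or JSON, which YAML subsumes)
  document with the protocol fields, classifier thresholds, and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

CONDITIONS: tuple[str, ...] = ("contra", "ipsi", "bilateral")
TREATMENTS: tuple[str, ...] = ("dark", "light")
HEMISPHERES: tuple[str, ...] = ("left", "right")


class FormatError(ValueError):
    """A file does not conform to the documented tabular format."""


class ValidationError(ValueError):
    """Data violates a dataset invariant."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing layout of one recording.

    Defaults follow the flash protocol: 1 s stimulus, 1 s pre-stimulus
    baseline, 1 s post-offset window, 40 trials per condition, 25 ms PSTH
    bins, three monocular/binocular conditions.
    """

    stim_duration: float = 1.0
    pre_window: float = 1.0
    post_window: float = 1.0
    n_trials: int = 40
    bin_width: float = 0.025
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self):
        for name in ("stim_duration", "pre_window", "post_window", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_trials < 2:
            raise ValidationError("n_trials must be >= 2")
        if len(set(self.conditions)) != len(self.conditions) or len(self.conditions) != 3:
            raise ValidationError("conditions must be three distinct labels")
        total = self.pre_window + self.stim_duration + self.post_window
        n_bins = total / self.bin_width
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValidationError(
                f"bin_width {self.bin_width} does not divide the {total} s epoch"
            )

    @property
    def epoch_start(self) -> float:
        return -self.pre_window

    @property
    def epoch_end(self) -> float:
        return self.stim_duration + self.post_window

    @property
    def n_bins(self) -> int:
        return int(round((self.epoch_end - self.epoch_start) / self.bin_width))

    def bin_edges(self) -> np.ndarray:
        return self.epoch_start + self.bin_width * np.arange(self.n_bins + 1)

    def to_dict(self) -> dict:
        return {
            "stim_duration": self.stim_duration,
            "pre_window": self.pre_window,
            "post_window": self.post_window,
            "n_trials": self.n_trials,
            "bin_width": self.bin_width,
            "conditions": list(self.conditions),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StimulusProtocol":
        kwargs = {k: d[k] for k in
                  ("stim_duration", "pre_window", "post_window", "n_trials", "bin_width")
                  if k in d}
        if "conditions" in d:
            kwargs["conditions"] = tuple(d["conditions"])
        return cls(**kwargs)


@dataclass(frozen=True)
class UnitMeta:
    unit_id: str
    treatment: str
    hemisphere: str
    subject_id: str = ""
    ground_truth: str | None = None

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unit {self.unit_id}: unknown treatment {self.treatment!r}"
            )
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(
                f"unit {self.unit_id}: unknown hemisphere {self.hemisphere!r}"
            )


@dataclass
class SpikeDataset:
    """Spike timestamps per (unit, condition, trial) plus per-unit metadata."""

    protocol: StimulusProtocol
    units: list[UnitMeta]
    spikes: dict[tuple[str, str, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate unit_id in metadata")
        known = set(ids)
        p = self.protocol
        for (uid, cond, trial), times in self.spikes.items():
            if uid not in known:
                raise ValidationError(f"spikes for undeclared unit {uid!r}")
            if cond not in p.conditions:
                raise ValidationError(f"unit {uid}: unknown condition {cond!r}")
            if not (0 <= trial < p.n_trials):
                raise ValidationError(
                    f"unit {uid}: trial index {trial} outside [0, {p.n_trials})"
                )
            t = np.asarray(times, dtype=float)
            if t.size:
                if t.min() < p.epoch_start - 1e-12 or t.max() > p.epoch_end + 1e-12:
                    raise ValidationError(
                        f"unit {uid} trial {trial}: spike time outside "
                        f"[{p.epoch_start}, {p.epoch_end}]"
                    )
                if np.any(np.diff(t) <= 0):
                    raise ValidationError(
                        f"unit {uid} trial {trial}: spike times must be "
                        "strictly increasing (duplicates rejected)"
                    )
            self.spikes[(uid, cond, trial)] = t

    def unit_meta(self, unit_id: str) -> UnitMeta:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def trains(self, unit_id: str, condition: str) -> list[np.ndarray]:
        """All trials' spike trains for one unit/condition (empty arrays for
        trials without spikes)."""
        if condition not in self.protocol.conditions:
            raise KeyError(condition)
        if unit_id not in {u.unit_id for u in self.units}:
            raise KeyError(unit_id)
        empty = np.empty(0)
        return [
            self.spikes.get((unit_id, condition, tr), empty)
            for tr in range(self.protocol.n_trials)
        ]


# ---------------------------------------------------------------------------
# File I/O

_SPIKE_COLS = ["unit_id", "condition", "trial", "spike_time_s"]
_META_COLS = ["unit_id", "subject_id", "treatment", "hemisphere"]


def read_protocol(path: str | Path) -> StimulusProtocol:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if "protocol" in doc:
        doc = doc["protocol"]
    return StimulusProtocol.from_dict(doc)


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"protocol": protocol.to_dict()}, fh, sort_keys=False)


def read_spike_table(
    path: str | Path,
    meta_path: str | Path,
    protocol_path: str | Path | None = None,
    protocol: StimulusProtocol | None = None,
) -> SpikeDataset:
    """Load a spike table + unit metadata (+ protocol) into a validated dataset."""
    if protocol is None:
        if protocol_path is None:
            raise ValueError("provide either protocol_path or protocol")
        protocol = read_protocol(protocol_path)

    meta_df = pd.read_csv(meta_path, dtype=str).fillna("")
    missing = [c for c in _META_COLS if c not in meta_df.columns]
    if missing:
        raise FormatError(f"metadata file missing column(s): {', '.join(missing)}")
    units = [
        UnitMeta(
            unit_id=row.unit_id,
            subject_id=row.subject_id,
            treatment=row.treatment,
            hemisphere=row.hemisphere,
            ground_truth=(getattr(row, "ground_truth", "") or None),
        )
        for row in meta_df.itertuples(index=False)
    ]

    df = pd.read_csv(path)
    missing = [c for c in _SPIKE_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"spike table missing column(s): {', '.join(missing)}")
    spikes: dict[tuple[str, str, int], np.ndarray] = {}
    if len(df):
        df = df.sort_values(_SPIKE_COLS, kind="stable")
        for (uid, cond, trial), grp in df.groupby(
            ["unit_id", "condition", "trial"], sort=False
        ):
            spikes[(str(uid), str(cond), int(trial))] = grp["spike_time_s"].to_numpy(
                dtype=float
            )
    return SpikeDataset(protocol=protocol, units=units, spikes=spikes)


def write_spike_table(
    dataset: SpikeDataset, path: str | Path, meta_path: str | Path | None = None
) -> None:
    """Write the spike table (and optionally metadata) in deterministic order."""
    rows = []
    order = {c: i for i, c in enumerate(dataset.protocol.conditions)}
    for (uid, cond, trial), times in dataset.spikes.items():
        for t in times:
            rows.append((uid, cond, trial, t))
    rows.sort(key=lambda r: (r[0], order[r[1]], r[2], r[3]))
    df = pd.DataFrame(rows, columns=_SPIKE_COLS)
    df.to_csv(path, index=False, float_format="%.9g")
    if meta_path is not None:
        write_unit_meta(dataset.units, meta_path)


def write_unit_meta(units: list[UnitMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (u.unit_id, u.subject_id, u.treatment, u.hemisphere, u.ground_truth or "")
            for u in units
        ],
        columns=_META_COLS + ["ground_truth"],
    )
    df.to_csv(path, index=False)
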