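"""PSTH construction and extraction of per-unit response features.

The five dependent variables of the downstream statistics are: the
spontaneous firing rate (mean rate in the 1-s pre-stimulus window, averaged
over the three stimulation conditions) and, per condition, the ON and OFF
peak firing rates (optionally baseline-subtracted) and their latencies.  A
peak is the maximal PSTH bin rate within its window; its latency is the
center of that bin measured from the start of the window (stimulus onset for
ON, stimulus offset for OFF), with ties broken by the earliest maximal bin.
Latencies of windows with no spikes at all are undefined and reported as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikeio import SpikeDataset, StimulusProtocol

__all__ = ["PSTH", "ConditionFeatures", "ResponseFeatures",
           "compute_psth", "extract_features", "features_table"]


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged peristimulus time histogram of one unit/condition."""

    unit_id: str
    condition: str
    bin_edges: np.ndarray  # n_bins + 1 edges over the analysis epoch
    rate: np.ndarray  # Hz per bin, averaged over trials
    trial_counts: np.ndarray  # (n_trials, n_bins) spike counts

    @property
    def n_trials(self) -> int:
        return self.trial_counts.shape[0]

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def total_spikes(self) -> int:
        return int(self.trial_counts.sum())


def _bin_index(times: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
    idx = np.floor((times - protocol.epoch_start) / protocol.bin_width).astype(int)
    # a spike exactly at the epoch end belongs to the last bin
    return np.clip(idx, 0, protocol.n_bins - 1)


def compute_psth(dataset: SpikeDataset, unit_id: str, condition: str) -> PSTH:
    """Bin one unit/condition into the protocol's PSTH.

    rate[b] = sum_trials count[trial, b] / (n_trials * bin_width), so
    sum_b rate[b] * bin_width * n_trials recovers the total spike count.
    """
    p = dataset.protocol
    counts = np.zeros((p.n_trials, p.n_bins), dtype=np.int64)
    for trial, train in enumerate(dataset.trains(unit_id, condition)):
        if train.size:
            counts[trial] = np.bincount(_bin_index(train, p), minlength=p.n_bins)
    rate = counts.sum(axis=0) / (p.n_trials * p.bin_width)
    return PSTH(unit_id, condition, p.bin_edges(), rate, counts)


def _window_slices(p: StimulusProtocol) -> dict[str, slice]:
    pre = int(round(p.pre_window / p.bin_width))
    on = int(round(p.stim_duration / p.bin_width))
    off = int(round(p.post_window / p.bin_width))
    return {
        "baseline": slice(0, pre),
        "on": slice(pre, pre + on),
        "off": slice(pre + on, pre + on + off),
    }


@dataclass(frozen=True)
class ConditionFeatures:
    """Peak features of one stimulation condition."""

    on_peak_raw: float
    off_peak_raw: float
    on_peak_sub: float  # raw minus cross-condition spontaneous rate
    off_peak_sub: float
    on_latency: float  # s from stimulus onset; NaN if ON window empty
    off_latency: float  # s from stimulus offset; NaN if OFF window empty
    pre_peak: float  # max baseline-window bin rate of this condition
    baseline_mean: float  # mean baseline-window rate of this condition


@dataclass(frozen=True)
class ResponseFeatures:
    unit_id: str
    spontaneous_rate: float  # Hz, mean of the three conditions' baseline means
    by_condition: dict[str, ConditionFeatures]


def _peak(rate: np.ndarray, window: slice, bin_width: float) -> tuple[float, float]:
    """(peak rate, latency from window start) with earliest-bin tie-breaking."""
    seg = rate[window]
    peak = float(seg.max())
    if peak <= 0.0:
        return peak, float("nan")
    idx = int(np.argmax(seg))  # argmax returns the first maximal bin
    return peak, (idx + 0.5) * bin_width


def extract_features(dataset: SpikeDataset, unit_id: str) -> ResponseFeatures:
    """Compute all dependent variables of one unit from its three PSTHs."""
    p = dataset.protocol
    win = _window_slices(p)
    psths = {c: compute_psth(dataset, unit_id, c) for c in p.conditions}

    baseline_means = {
        c: float(psths[c].rate[win["baseline"]].mean()) for c in p.conditions
    }
    spont = float(np.mean(list(baseline_means.values())))

    by_cond: dict[str, ConditionFeatures] = {}
    for c in p.conditions:
        rate = psths[c].rate
        on_peak, on_lat = _peak(rate, win["on"], p.bin_width)
        off_peak, off_lat = _peak(rate, win["off"], p.bin_width)
        by_cond[c] = ConditionFeatures(
            on_peak_raw=on_peak,
            off_peak_raw=off_peak,
            on_peak_sub=on_peak - spont,
            off_peak_sub=off_peak - spont,
            on_latency=on_lat,
            off_latency=off_lat,
            pre_peak=float(rate[win["baseline"]].max()),
            baseline_mean=baseline_means[c],
        )
    return ResponseFeatures(unit_id, spont, by_cond)


def features_table(features: list[ResponseFeatures]):
    """Flatten features into a DataFrame (one row per unit, stable columns)."""
    import pandas as pd

    rows = []
    for f in features:
        row: dict[str, float | str] = {
            "unit_id": f.unit_id,
            "spontaneous_rate": f.spontaneous_rate,
        }
        for c, cf in f.by_condition.items():
            for name in ("on_peak_raw", "off_peak_raw", "on_peak_sub",
                         "off_peak_sub", "on_latency", "off_latency", "pre_peak"):
                row[f"{c}_{name}"] = getattr(cf, name)
        rows.append(row)
    return pd.DataFrame(rows)
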