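"""Unit selection and binocular-integration classification.

Three stages, applied per unit:

1. **Visual responsiveness screen.** In at least one condition, the raw ON or
   OFF peak must be at least ``responsiveness_fold`` (default 2) times that
   condition's pre-stimulus peak, and at least ``min_peak_rate`` Hz (default
   5).  Units failing everywhere are dropped from further analysis.

2. **Bilateral vs contralateral separation.** A responsive unit is labeled
   *bilateral* if any of six criteria fires, else *contralateral*:

   * ipsilateral sigma criterion (ON / OFF): the ipsilateral PSTH peak exceeds
     the mean of the ipsilateral baseline-window bin rates by more than
     ``ipsi_sigma`` (default 4) standard deviations of those bin rates;
   * peak Wilcoxon (ON / OFF): per-trial firing rates in each condition's own
     peak bin differ between contralateral and bilateral trials (rank-sum with
     continuity correction, two-sided, at ``alpha``);
   * rate Wilcoxon (ON / OFF): per-trial mean rates over the full 1-s window
     differ between contralateral and bilateral trials (same test).

3. **Integration sign.** For bilateral units, the ON (resp. OFF) interaction
   is *excitation* if either of the two ON (resp. OFF) Wilcoxon comparisons is
   significant with the bilateral per-trial window rates exceeding the
   contralateral ones in median, *suppression* in the opposite direction,
   *none* otherwise (including tied medians).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import PSTH, ResponseFeatures, _window_slices, compute_psth, extract_features
from .rankstats import wilcoxon_ranksum_cc
from .spikeio import SpikeDataset

__all__ = [
    "ClassifierThresholds",
    "UnitClassification",
    "is_visually_responsive",
    "ipsi_sigma_criterion",
    "bilateral_modulation_tests",
    "classify_unit",
    "classify_dataset",
]


@dataclass(frozen=True)
class ClassifierThresholds:
    responsiveness_fold: float = 2.0
    min_peak_rate: float = 5.0  # Hz
    ipsi_sigma: float = 4.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.responsiveness_fold <= 1:
            raise ValueError("responsiveness_fold must exceed 1")
        if self.min_peak_rate < 0:
            raise ValueError("min_peak_rate must be >= 0")
        if self.ipsi_sigma <= 0:
            raise ValueError("ipsi_sigma must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class UnitClassification:
    unit_id: str
    visually_responsive: bool
    response_class: str  # bilateral | contralateral | none
    criteria_fired: frozenset[str] = field(default_factory=frozenset)
    integration_on: str = "none"  # excitation | suppression | none
    integration_off: str = "none"


def is_visually_responsive(
    features: ResponseFeatures, thresholds: ClassifierThresholds | None = None
) -> bool:
    th = thresholds or ClassifierThresholds()
    for cf in features.by_condition.values():
        for peak in (cf.on_peak_raw, cf.off_peak_raw):
            if peak >= th.responsiveness_fold * cf.pre_peak and peak >= th.min_peak_rate:
                return True
    return False


def ipsi_sigma_criterion(
    psth_ipsi: PSTH,
    protocol,
    thresholds: ClassifierThresholds | None = None,
) -> dict[str, bool]:
    """Does the ipsilateral ON / OFF peak clear the baseline noise band?

    Noise mean and s.d. are estimated from the ipsilateral baseline-window bin
    rates.  A silent baseline (s.d. 0) degenerates the band; the criterion
    then fires iff the peak is nonzero and at least ``min_peak_rate``.
    """
    th = thresholds or ClassifierThresholds()
    win = _window_slices(protocol)
    base = psth_ipsi.rate[win["baseline"]]
    mu, sd = float(base.mean()), float(base.std(ddof=0))
    out = {}
    for w in ("on", "off"):
        peak = float(psth_ipsi.rate[win[w]].max())
        if sd == 0.0:
            fired = peak > mu and peak >= th.min_peak_rate
        else:
            fired = peak > mu + th.ipsi_sigma * sd
        out[f"fired_{w.upper()}"] = bool(fired)
    return out


def _window_trial_rates(psth: PSTH, window: slice) -> np.ndarray:
    """Per-trial mean firing rate (Hz) over a window."""
    counts = psth.trial_counts[:, window].sum(axis=1)
    duration = (window.stop - window.start) * psth.bin_width
    return counts / duration


def _peak_bin_trial_rates(psth: PSTH, window: slice) -> np.ndarray:
    """Per-trial firing rate (Hz) in the window's peak bin of the
    trial-averaged PSTH (earliest maximal bin)."""
    seg = psth.rate[window]
    peak_bin = window.start + int(np.argmax(seg))
    return psth.trial_counts[:, peak_bin] / psth.bin_width


def bilateral_modulation_tests(
    dataset: SpikeDataset,
    unit_id: str,
    thresholds: ClassifierThresholds | None = None,
    psths: dict[str, PSTH] | None = None,
) -> dict[str, float]:
    """Rank-sum p-values comparing contralateral vs bilateral responses.

    Peak tests compare per-trial rates in each condition's own peak bin; rate
    tests compare per-trial mean rates over the full ON (or OFF) window.  All
    four are two-sided Wilcoxon rank-sum tests with continuity correction.
    """
    p = dataset.protocol
    if p.n_trials < 2:
        raise ValueError("need at least 2 trials per condition")
    if psths is None:
        psths = {c: compute_psth(dataset, unit_id, c) for c in ("contra", "bilateral")}
    win = _window_slices(p)
    out: dict[str, float] = {}
    for w, key in (("on", "ON"), ("off", "OFF")):
        contra_peak = _peak_bin_trial_rates(psths["contra"], win[w])
        bilat_peak = _peak_bin_trial_rates(psths["bilateral"], win[w])
        _, out[f"peak_{key}_p"] = wilcoxon_ranksum_cc(contra_peak, bilat_peak)
        contra_rate = _window_trial_rates(psths["contra"], win[w])
        bilat_rate = _window_trial_rates(psths["bilateral"], win[w])
        _, out[f"rate_{key}_p"] = wilcoxon_ranksum_cc(contra_rate, bilat_rate)
    return out


def _integration_sign(
    psths: dict[str, PSTH], window: slice, peak_p: float, rate_p: float, alpha: float
) -> str:
    if not (peak_p < alpha or rate_p < alpha):
        return "none"
    contra = np.median(_window_trial_rates(psths["contra"], window))
    bilat = np.median(_window_trial_rates(psths["bilateral"], window))
    if bilat > contra:
        return "excitation"
    if bilat < contra:
        return "suppression"
    return "none"


def classify_unit(
    dataset: SpikeDataset,
    unit_id: str,
    thresholds: ClassifierThresholds | None = None,
    features: ResponseFeatures | None = None,
) -> UnitClassification:
    th = thresholds or ClassifierThresholds()
    if features is None:
        features = extract_features(dataset, unit_id)
    if not is_visually_responsive(features, th):
        return UnitClassification(unit_id, False, "none")

    p = dataset.protocol
    psths = {c: compute_psth(dataset, unit_id, c) for c in p.conditions}
    fired: set[str] = set()

    sigma = ipsi_sigma_criterion(psths["ipsi"], p, th)
    if sigma["fired_ON"]:
        fired.add("ipsi_sigma_ON")
    if sigma["fired_OFF"]:
        fired.add("ipsi_sigma_OFF")

    pvals = bilateral_modulation_tests(dataset, unit_id, th, psths)
    for key, crit in (
        ("peak_ON_p", "peak_wilcoxon_ON"),
        ("peak_OFF_p", "peak_wilcoxon_OFF"),
        ("rate_ON_p", "rate_wilcoxon_ON"),
        ("rate_OFF_p", "rate_wilcoxon_OFF"),
    ):
        if pvals[key] < th.alpha:
            fired.add(crit)

    if not fired:
        return UnitClassification(unit_id, True, "contralateral")

    win = _window_slices(p)
    return UnitClassification(
        unit_id,
        True,
        "bilateral",
        frozenset(fired),
        integration_on=_integration_sign(
            psths, win["on"], pvals["peak_ON_p"], pvals["rate_ON_p"], th.alpha
        ),
        integration_off=_integration_sign(
            psths, win["off"], pvals["peak_OFF_p"], pvals["rate_OFF_p"], th.alpha
        ),
    )


def classify_dataset(
    dataset: SpikeDataset, thresholds: ClassifierThresholds | None = None
) -> list[UnitClassification]:
    """Classify every unit of a dataset in metadata order."""
    return [classify_unit(dataset, u.unit_id, thresholds) for u in dataset.units]
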