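"""Unit selection and binocular-integration classification tests."""

import numpy as np
import pytest

from entolat import (
    ClassifierThresholds,
    bilateral_modulation_tests,
    classify_dataset,
    classify_unit,
    ipsi_sigma_criterion,
    is_visually_responsive,
    make_archetype,
    default_cohort_config,
    simulate_cohort,
)
from entolat.features import PSTH, ConditionFeatures, ResponseFeatures
from entolat.simulate import simulate_unit
from entolat.spikeio import StimulusProtocol

from conftest import build_dataset


def features_with_peaks(pre_peak: float, best_peak: float) -> ResponseFeatures:
    cf = ConditionFeatures(
        on_peak_raw=best_peak, off_peak_raw=0.0,
        on_peak_sub=best_peak, off_peak_sub=0.0,
        on_latency=0.1, off_latency=float("nan"),
        pre_peak=pre_peak, baseline_mean=pre_peak / 2,
    )
    quiet = ConditionFeatures(0.0, 0.0, 0.0, 0.0, float("nan"), float("nan"),
                              pre_peak, pre_peak / 2)
    return ResponseFeatures("u0", pre_peak / 2,
                            {"contra": cf, "ipsi": quiet, "bilateral": quiet})


def psth_with_rates(base_rates, on_rates, protocol) -> PSTH:
    rate = np.zeros(protocol.n_bins)
    rate[: len(base_rates)] = base_rates
    on_start = int(round(protocol.pre_window / protocol.bin_width))
    rate[on_start : on_start + len(on_rates)] = on_rates
    counts = np.zeros((protocol.n_trials, protocol.n_bins), dtype=int)
    return PSTH("u0", "ipsi", protocol.bin_edges(), rate, counts)


def dataset_from_unit(arch, protocol, seed):
    trains = simulate_unit(arch, protocol, np.random.default_rng(seed))
    return build_dataset(
        {("u0", c, tr): trains[(c, tr)]
         for c in protocol.conditions for tr in range(protocol.n_trials)
         if trains[(c, tr)].size},
        protocol=protocol,
    )


class TestVisualResponsiveness:
    @pytest.mark.parametrize(
        "pre_peak,best_peak,expected",
        [
            (8.0, 20.0, True),   # >= two-fold and >= 5 Hz
            (8.0, 15.0, False),  # below the two-fold threshold
            (1.0, 4.5, False),   # 4.5-fold but under the 5 Hz floor
        ],
    )
    def test_rule(self, pre_peak, best_peak, expected):
        f = features_with_peaks(pre_peak, best_peak)
        assert is_visually_responsive(f, ClassifierThresholds()) is expected

    def test_raising_thresholds_is_monotone(self):
        ds = simulate_cohort(default_cohort_config(n_units_per_cell=10, seed=13))
        feats = {}
        from entolat import extract_features
        for u in ds.units:
            feats[u.unit_id] = extract_features(ds, u.unit_id)
        loose = ClassifierThresholds(responsiveness_fold=1.5, min_peak_rate=2.0)
        strict = ClassifierThresholds(responsiveness_fold=3.0, min_peak_rate=10.0)
        n_loose = sum(is_visually_responsive(f, loose) for f in feats.values())
        n_strict = sum(is_visually_responsive(f, strict) for f in feats.values())
        assert n_strict <= n_loose


class TestIpsiSigmaCriterion:
    def test_silent_baseline_degenerate_rule(self, protocol):
        psth = psth_with_rates([0.0] * 40, [12.0], protocol)
        fired = ipsi_sigma_criterion(psth, protocol)
        assert fired["fired_ON"] and not fired["fired_OFF"]

    def test_peak_inside_noise_band_does_not_fire(self, protocol):
        base = [3.0, 5.0, 7.0] * 13 + [5.0]  # mean 5, sd ~1.61
        psth = psth_with_rates(base, [11.0], protocol)
        base_arr = np.array(base)
        assert 11.0 < base_arr.mean() + 4 * base_arr.std()
        assert not ipsi_sigma_criterion(psth, protocol)["fired_ON"]

    def test_strong_ipsi_response_fires_reliably(self, protocol):
        """An archetype with a 40 Hz ipsilateral transient over a 2 Hz
        baseline trips the 4-sigma criterion in essentially every cohort."""
        arch = make_archetype("bilateral_independent", baseline_rate=2.0,
                              on_amp_contra=80.0, ipsi_fraction=0.5)
        from entolat import compute_psth
        fired = 0
        n_seeds = 200
        for seed in range(n_seeds):
            ds = dataset_from_unit(arch, protocol, seed)
            psth = compute_psth(ds, "u0", "ipsi")
            fired += ipsi_sigma_criterion(psth, protocol)["fired_ON"]
        assert fired / n_seeds >= 0.99


class TestBilateralModulation:
    def test_identical_trains_give_p_one(self, protocol):
        rng = np.random.default_rng(5)
        trains = simulate_unit(make_archetype("contra_only"), protocol, rng)
        copied = {}
        for tr in range(protocol.n_trials):
            copied[("u0", "contra", tr)] = trains[("contra", tr)]
            copied[("u0", "bilateral", tr)] = trains[("contra", tr)]
        ds = build_dataset({k: v for k, v in copied.items() if v.size}, protocol=protocol)
        pvals = bilateral_modulation_tests(ds, "u0")
        assert all(p == 1.0 for p in pvals.values())

    def test_excitatory_modulation_power(self, protocol):
        """Doubling the bilateral ON amplitude (20 -> 40 Hz over a 2 Hz
        baseline) is detected by the ON rate test in >= 95% of cohorts."""
        arch = make_archetype(
            "bilateral_excitatory", baseline_rate=2.0, on_amp_contra=20.0,
            off_amp_contra=10.0, excitation_factor=2.0, transient_width=0.08,
        )
        hits = 0
        n_seeds = 500
        for seed in range(n_seeds):
            ds = dataset_from_unit(arch, protocol, seed)
            hits += bilateral_modulation_tests(ds, "u0")["rate_ON_p"] < 0.05
        assert hits / n_seeds >= 0.95


class TestClassifyUnit:
    def test_contra_only_rarely_mislabeled(self, protocol):
        """With bilateral identical to contralateral in distribution, the
        false-bilateral fraction stays below the documented uncorrected
        multiple-testing bound 2 * alpha * n_tests."""
        arch = make_archetype("contra_only", baseline_rate=5.0)
        n_seeds, mislabeled = 100, 0
        for seed in range(n_seeds):
            ds = dataset_from_unit(arch, protocol, 1000 + seed)
            cl = classify_unit(ds, "u0")
            assert cl.visually_responsive
            mislabeled += cl.response_class == "bilateral"
        assert mislabeled / n_seeds <= 2 * 0.05 * 4

    def test_suppressive_archetype_recovered(self, protocol):
        """A bilateral ON amplitude at half the contralateral one is labeled
        bilateral with suppressive ON integration in >= 90% of cohorts."""
        arch = make_archetype("bilateral_suppressive", baseline_rate=5.0,
                              on_amp_contra=60.0, off_amp_contra=30.0,
                              suppression_factor=0.5)
        n_seeds, hits = 500, 0
        for seed in range(n_seeds):
            ds = dataset_from_unit(arch, protocol, seed)
            cl = classify_unit(ds, "u0")
            hits += (cl.response_class == "bilateral"
                     and cl.integration_on == "suppression")
        assert hits / n_seeds >= 0.90

    def test_nonresponsive_unit_class_none(self, single_unit_factory):
        cl = classify_unit(single_unit_factory({}), "u0")
        assert not cl.visually_responsive
        assert cl.response_class == "none"
        assert cl.integration_on == "none" and cl.integration_off == "none"

    def test_determinism(self):
        ds = simulate_cohort(default_cohort_config(n_units_per_cell=4, seed=23))
        assert classify_dataset(ds) == classify_dataset(ds)

    def test_lowering_alpha_never_increases_bilateral_count(self):
        ds = simulate_cohort(default_cohort_config(n_units_per_cell=8, seed=29))
        n_bilateral = {}
        for alpha in (0.05, 0.005):
            cls = classify_dataset(ds, ClassifierThresholds(alpha=alpha))
            n_bilateral[alpha] = sum(c.response_class == "bilateral" for c in cls)
        assert n_bilateral[0.005] <= n_bilateral[0.05]
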