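"""Synthetic spike-train cohorts with known ground truth.

The generator emulates the recording protocol of a lateralized flash-response
experiment: every unit is observed under contralateral, ipsilateral and
bilateral eye stimulation for ``n_trials`` trials each.  A unit is an
inhomogeneous Poisson process whose intensity is a constant baseline plus two
Gaussian transients — an ON bump after stimulus onset and an OFF bump after
stimulus offset — with condition-dependent amplitudes:

    lambda_c(t) = max(0, b + A_on[c] g(t; t_on, w) + A_off[c] g(t - D; t_off, w))

where g is a unit-peak Gaussian, D the stimulus duration, and the max(., 0)
clip allows suppressive bilateral interactions (A_on[bilateral] below
A_on[contra], possibly negative).  Sampling uses Lewis-Shedler thinning with
the constant majorant b + max(0, A_on[c]) + max(0, A_off[c]).

Five archetypes cover the response taxonomy the classifier targets:
``nonresponsive``, ``contra_only`` (bilateral response identical to
contralateral), ``bilateral_excitatory`` (bilateral amplitude above
contralateral), ``bilateral_suppressive`` (below), and
``bilateral_independent`` (ipsilateral response present, no bilateral
modulation).  Cohort-level treatment x hemisphere effects (baseline and
amplitude multipliers, latency shifts) and per-cell archetype mixtures are
knobs encoding directions of effects, not fitted values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .spikeio import (
    CONDITIONS,
    HEMISPHERES,
    TREATMENTS,
    SpikeDataset,
    StimulusProtocol,
    UnitMeta,
)

ARCHETYPE_LABELS = (
    "nonresponsive",
    "contra_only",
    "bilateral_excitatory",
    "bilateral_suppressive",
    "bilateral_independent",
)

BILATERAL_LABELS = frozenset(
    {"bilateral_excitatory", "bilateral_suppressive", "bilateral_independent"}
)


@dataclass(frozen=True)
class UnitArchetype:
    """Generative parameters of one unit."""

    label: str
    baseline_rate: float  # Hz
    on_amp: dict[str, float]  # condition -> Hz above baseline at the peak
    off_amp: dict[str, float]
    on_latency: float  # s after stimulus onset
    off_latency: float  # s after stimulus offset
    transient_width: float  # Gaussian s.d. in s

    def __post_init__(self):
        if self.label not in ARCHETYPE_LABELS:
            raise ValueError(f"unknown archetype label {self.label!r}")
        if self.baseline_rate < 0 or self.transient_width <= 0:
            raise ValueError("baseline_rate must be >= 0, transient_width > 0")


def make_archetype(
    label: str,
    baseline_rate: float = 5.0,
    on_amp_contra: float = 60.0,
    off_amp_contra: float = 30.0,
    ipsi_fraction: float = 0.5,
    excitation_factor: float = 1.5,
    suppression_factor: float = 0.5,
    on_latency: float = 0.15,
    off_latency: float = 0.2,
    transient_width: float = 0.04,
) -> UnitArchetype:
    """Build an archetype from a small template.

    ``ipsi_fraction`` scales the ipsilateral amplitudes of archetypes with an
    ipsilateral response; ``excitation_factor`` / ``suppression_factor`` scale
    the bilateral amplitudes relative to contralateral for the two modulated
    archetypes.
    """
    a_on, a_off = on_amp_contra, off_amp_contra
    if label == "nonresponsive":
        on = {c: 0.0 for c in CONDITIONS}
        off = {c: 0.0 for c in CONDITIONS}
    elif label == "contra_only":
        on = {"contra": a_on, "ipsi": 0.0, "bilateral": a_on}
        off = {"contra": a_off, "ipsi": 0.0, "bilateral": a_off}
    elif label == "bilateral_excitatory":
        on = {"contra": a_on, "ipsi": ipsi_fraction * a_on,
              "bilateral": excitation_factor * a_on}
        off = {"contra": a_off, "ipsi": ipsi_fraction * a_off,
               "bilateral": excitation_factor * a_off}
    elif label == "bilateral_suppressive":
        on = {"contra": a_on, "ipsi": 0.0, "bilateral": suppression_factor * a_on}
        off = {"contra": a_off, "ipsi": 0.0, "bilateral": suppression_factor * a_off}
    elif label == "bilateral_independent":
        on = {"contra": a_on, "ipsi": ipsi_fraction * a_on, "bilateral": a_on}
        off = {"contra": a_off, "ipsi": ipsi_fraction * a_off, "bilateral": a_off}
    else:
        raise ValueError(f"unknown archetype label {label!r}")
    return UnitArchetype(label, baseline_rate, on, off,
                         on_latency, off_latency, transient_width)


def rate_function(
    archetype: UnitArchetype,
    condition: str,
    t: float | np.ndarray,
    protocol: StimulusProtocol | None = None,
) -> np.ndarray:
    """Instantaneous firing rate lambda(t) in Hz (vectorized over t)."""
    stim = (protocol or StimulusProtocol()).stim_duration
    ta = np.asarray(t, dtype=float)
    w = archetype.transient_width
    on = archetype.on_amp[condition] * np.exp(
        -0.5 * ((ta - archetype.on_latency) / w) ** 2
    )
    off = archetype.off_amp[condition] * np.exp(
        -0.5 * ((ta - stim - archetype.off_latency) / w) ** 2
    )
    return np.maximum(archetype.baseline_rate + on + off, 0.0)


def simulate_unit(
    archetype: UnitArchetype,
    protocol: StimulusProtocol,
    rng: np.random.Generator,
) -> dict[tuple[str, int], np.ndarray]:
    """Draw spike trains for all conditions and trials of one unit.

    Returns a mapping (condition, trial) -> sorted spike times.  Sampling is
    Lewis-Shedler thinning of a homogeneous process at the constant majorant
    rate, independently per trial.
    """
    out: dict[tuple[str, int], np.ndarray] = {}
    t0, t1 = protocol.epoch_start, protocol.epoch_end
    span = t1 - t0
    for cond in protocol.conditions:
        majorant = (
            archetype.baseline_rate
            + max(0.0, archetype.on_amp[cond])
            + max(0.0, archetype.off_amp[cond])
        )
        if majorant <= 0.0:
            for trial in range(protocol.n_trials):
                out[(cond, trial)] = np.empty(0)
            continue
        counts = rng.poisson(majorant * span, size=protocol.n_trials)
        total = int(counts.sum())
        times = rng.uniform(t0, t1, size=total)
        u = rng.uniform(0.0, 1.0, size=total)
        accept = u * majorant < rate_function(archetype, cond, times, protocol)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        for trial in range(protocol.n_trials):
            sl = slice(offsets[trial], offsets[trial + 1])
            kept = times[sl][accept[sl]]
            out[(cond, trial)] = np.unique(kept)  # sorted, duplicates dropped
    return out


@dataclass(frozen=True)
class CellEffect:
    """Multiplicative/additive modulation applied to all units of one
    treatment x hemisphere cell."""

    baseline_mult: float = 1.0
    amp_mult: float = 1.0
    latency_shift: float = 0.0  # s, added to both ON and OFF latencies

    def __post_init__(self):
        if self.baseline_mult <= 0 or self.amp_mult <= 0:
            raise ValueError("multipliers must be positive")


@dataclass(frozen=True)
class CohortEffects:
    """Per-cell effects and archetype mixtures, keyed (treatment, hemisphere)."""

    cells: dict[tuple[str, str], CellEffect]
    mixtures: dict[tuple[str, str], dict[str, float]]

    def __post_init__(self):
        for key in self.mixtures:
            total = sum(self.mixtures[key].values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture for cell {key} sums to {total}, not 1")
            for lab in self.mixtures[key]:
                if lab not in ARCHETYPE_LABELS:
                    raise ValueError(f"unknown archetype {lab!r} in mixture {key}")


@dataclass(frozen=True)
class SimConfig:
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    n_units_per_cell: int = 50
    template: dict = field(default_factory=dict)  # kwargs of make_archetype
    effects: CohortEffects | None = None
    heterogeneity_sd: float = 0.25  # lognormal sigma of per-unit rate jitter
    n_subjects_per_cell: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_units_per_cell < 1:
            raise ValueError("n_units_per_cell must be >= 1")


# Directions encoded: light incubation raises baseline activity and response
# amplitudes in both hemispheres and shortens latencies; in dark-incubated
# animals the right hemisphere has the stronger, faster responses.  Magnitudes
# are generator conventions, chosen to give clearly detectable effects at
# cohort sizes of tens of units per cell.
DEFAULT_COHORT_EFFECTS = CohortEffects(
    cells={
        ("dark", "left"): CellEffect(1.0, 1.0, 0.0),
        ("dark", "right"): CellEffect(1.15, 1.25, -0.025),
        ("light", "left"): CellEffect(1.5, 1.35, -0.035),
        ("light", "right"): CellEffect(1.5, 1.35, -0.035),
    },
    mixtures={
        cell: {
            "nonresponsive": 0.15,
            "contra_only": 0.35,
            "bilateral_excitatory": 0.20,
            "bilateral_suppressive": 0.15,
            "bilateral_independent": 0.15,
        }
        for cell in [(t, h) for t in TREATMENTS for h in HEMISPHERES]
    },
)


def default_cohort_config(
    n_units_per_cell: int = 50, seed: int = 0, **template_kwargs
) -> SimConfig:
    """The default cohort preset (see module docstring for what it encodes)."""
    return SimConfig(
        protocol=StimulusProtocol(),
        n_units_per_cell=n_units_per_cell,
        template=template_kwargs,
        effects=DEFAULT_COHORT_EFFECTS,
        seed=seed,
    )


def _apply_effects(
    arch: UnitArchetype, eff: CellEffect, jitter: float, protocol: StimulusProtocol
) -> UnitArchetype:
    bm = eff.baseline_mult * jitter
    am = eff.amp_mult * jitter
    on_lat = min(max(arch.on_latency + eff.latency_shift, 0.02),
                 protocol.stim_duration - 0.02)
    off_lat = min(max(arch.off_latency + eff.latency_shift, 0.02),
                  protocol.post_window - 0.02)
    return replace(
        arch,
        baseline_rate=arch.baseline_rate * bm,
        on_amp={c: v * am for c, v in arch.on_amp.items()},
        off_amp={c: v * am for c, v in arch.off_amp.items()},
        on_latency=on_lat,
        off_latency=off_lat,
    )


def simulate_cohort(config: SimConfig) -> SpikeDataset:
    """Simulate a full treatment x hemisphere cohort with ground truth.

    Units are generated in a fixed cell / unit order from a single seeded
    generator, so a fixed seed yields a bit-reproducible dataset.
    """
    rng = np.random.default_rng(config.seed)
    effects = config.effects or DEFAULT_COHORT_EFFECTS
    protocol = config.protocol
    units: list[UnitMeta] = []
    spikes: dict[tuple[str, str, int], np.ndarray] = {}

    for treatment in TREATMENTS:
        for hemisphere in HEMISPHERES:
            cell = (treatment, hemisphere)
            eff = effects.cells.get(cell, CellEffect())
            mix = effects.mixtures.get(
                cell, {"contra_only": 0.5, "bilateral_excitatory": 0.5}
            )
            labels = sorted(mix)
            probs = np.array([mix[lab] for lab in labels])
            for i in range(config.n_units_per_cell):
                label = labels[rng.choice(len(labels), p=probs)]
                jitter = math.exp(rng.normal(0.0, config.heterogeneity_sd))
                arch = _apply_effects(
                    make_archetype(label, **config.template), eff, jitter, protocol
                )
                uid = f"{treatment[0]}{hemisphere[0]}{i:04d}"
                subject = f"chick_{treatment[0]}{hemisphere[0]}{i % config.n_subjects_per_cell}"
                units.append(
                    UnitMeta(uid, treatment, hemisphere, subject, ground_truth=label)
                )
                for (cond, trial), times in simulate_unit(arch, protocol, rng).items():
                    spikes[(uid, cond, trial)] = times

    return SpikeDataset(protocol=protocol, units=units, spikes=spikes)
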