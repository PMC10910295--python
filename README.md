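# entolat

Analysis toolkit for lateralized visual responses of single units recorded
under monocular and binocular stimulation, such as recordings from the avian
entopallium — the telencephalic endpoint of the tectofugal visual pathway —
in dark- versus light-incubated chicks.

The package answers three questions about a population of spike-sorted units
recorded while flashing the contralateral eye, the ipsilateral eye, or both:

1. **Which units are visually responsive, and which integrate both eyes?**
   Units pass a responsiveness screen (an ON or OFF peristimulus-time-histogram
   peak at least two-fold above the best pre-stimulus peak, and at least
   5 Hz), then are labeled *bilaterally responsive* if any of six criteria
   fires: the ipsilateral peak exceeds the baseline noise band by 4σ (ON or
   OFF), or a Wilcoxon rank-sum test with continuity correction (p < 0.05)
   detects a bilateral-vs-contralateral difference in per-trial peak-bin rates
   or 1-s window rates (ON or OFF). Bilateral units are further typed as
   showing *excitatory* or *suppressive* binocular integration from the
   direction of the significant comparison.

2. **Do incubation treatment and hemisphere shape the responses?** For each
   dependent variable (spontaneous rate; baseline-subtracted ON/OFF peak
   rates; ON/OFF peak latencies) a Scheirer-Ray-Hare test — the rank-based
   two-factor extension of the Kruskal-Wallis test — tests treatment,
   hemisphere and their interaction:

   H_effect = SS_effect(ranks) / [SS_total(ranks) / (N − 1)] ~ χ²(df),

   with η² = (H − k + 1)/(n − k) effect sizes and Dunn's pairwise z-tests on
   mean ranks (Bonferroni-flagged) after significant interactions.

3. **How common is binocular integration?** Cell-by-cell and pooled
   bilateral/contralateral counts and percentages, plus a pooled
   two-proportion z-test comparing the cohort's bilateral fraction against an
   external reference count.

Because real recordings are not required to exercise any of this, the package
ships a generative model: units are inhomogeneous Poisson processes (sampled
by Lewis-Shedler thinning) with Gaussian ON/OFF transients whose amplitudes
encode five response archetypes, with treatment × hemisphere effect knobs and
recorded ground truth for recovery testing.

## Worked example

```python
from entolat import default_cohort_config, run_analysis, simulate_cohort

dataset = simulate_cohort(default_cohort_config(n_units_per_cell=40, seed=1))
report = run_analysis(dataset, reference_proportion=(478, 1544),
                      out_dir="example_analysis")
```

prints (via `examples/04_full_pipeline.py`):

```
treatment hemisphere  n_responsive  n_bilateral  n_contralateral  pct_bilateral  pct_contralateral
     dark       left            37           28                9             76                 24
     dark      right            34           24               10             71                 29
     dark left+right            71           52               19             73                 27
    light       left            35           22               13             63                 37
    light      right            34           27                7             79                 21
    light left+right            69           49               20             71                 29

integration counts: {'excitation_on': 36, 'excitation_off': 27, 'suppression_on': 34, 'suppression_off': 26}
spontaneous rate, treatment effect: H(1) = 35.62, p = 2.39e-09, eta2 = 0.350
bilateral fraction 0.72 vs reference 0.31: z = -9.82, p = 8.91e-23
```

Of 160 simulated units, 140 pass the responsiveness screen; about 70% are
labeled bilateral (the preset mixes 50% truly binocular archetypes with the
classifier's expected false-positive rate). The factorial rank test detects
the injected light-incubation increase in spontaneous firing (H(1) = 35.6, a
large effect), and the cohort's bilateral fraction is far above the external
reference proportion (|z| ≈ 10). The other examples in `examples/` walk
through simulation, feature extraction/classification, and the statistical
toolbox individually.

A thin CLI wraps the same pipeline:

```
entolat simulate --out-dir sim --seed 1 --n-units 40
entolat analyze --spikes sim/spikes.csv --meta sim/units.csv \
                --protocol sim/protocol.yaml --out-dir out
entolat report --analysis-dir out
```

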