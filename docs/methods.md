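# Methods

## Timing model and conventions

One trial is the closed epoch [−1, 2] s around stimulus onset (t = 0):
1 s pre-stimulus baseline, 1 s stimulus (ON window, [0, 1)), 1 s
post-offset (OFF window, [1, 2)); all windows are half-open. The default
protocol uses 40 trials per condition and three conditions — contralateral,
ipsilateral and bilateral eye stimulation — with 25 ms PSTH bins (120 bins
per trial). Spikes are stored in seconds; bin membership is
floor((t + 1)/0.025), with a spike exactly at the epoch end assigned to the
last bin. Trials are assumed pre-aligned to onset; acquisition and spike
sorting are out of scope.

## Dependent variables

Per unit: the **spontaneous rate** is the mean baseline-window rate averaged
over the three conditions (a single per-unit value, so baseline subtraction
is a constant shift within a unit). Per condition: **ON/OFF peaks** are the
maximal PSTH bin rates in their windows (raw, and minus the spontaneous
rate); **latencies** are the center of the peak bin measured from the start
of the window (onset for ON, offset for OFF). Ties among equal-max bins are
broken by the earliest bin — deterministic and aligned with response-onset
intuition. Whether the peak bin is located on the raw or baseline-subtracted
PSTH is immaterial for latency (the subtraction is constant per unit); we
use the raw PSTH. Windows containing no spikes have undefined latency,
encoded NaN and excluded from statistics rather than fabricated. The
pre-stimulus peak used by the responsiveness screen is computed per condition
from that condition's own baseline window (the conservative reading of an
otherwise unpooled criterion).

## Classification

1. **Responsiveness**: some condition's raw ON or OFF peak ≥ 2 × that
   condition's pre-stimulus peak and ≥ 5 Hz. The 5 Hz floor applies to raw
   peaks (the screen precedes baseline subtraction). Raising either
   threshold can only shrink the responsive set (monotonicity is tested).
2. **Bilateral vs contralateral**: OR of six criteria.
   *Ipsilateral 4σ*: noise mean/s.d. are the ipsilateral PSTH's
   baseline-window bin-rate mean/s.d. — the only stimulus-free estimate
   available; a silent baseline (s.d. 0) degenerates the band, and the
   criterion then requires a nonzero peak of at least the 5 Hz floor.
   *Peak tests*: per-trial rates in each condition's own average-PSTH peak
   bin, contralateral vs bilateral trials, two-sided Wilcoxon rank-sum with
   tie correction and 0.5 continuity correction at α = 0.05. *Rate tests*:
   per-trial mean rates over the whole 1-s ON (or OFF) window, same test.
   The per-observation unit for "peak" comparisons is a modeling choice (the
   population construct is a distribution of peaks without a defined trial
   unit); per-trial counts in the average peak bin is the simplest
   construction consistent with the trial design. The six criteria are
   evaluated uncorrected at α per test; with four data-driven tests this
   admits a documented false-bilateral rate bounded by ~2·α·4 on truly
   contralateral units (measured ≈ 0.15–0.19 at 40 trials; the tests are
   positively correlated).
3. **Integration sign** (bilateral units only): for ON (resp. OFF),
   excitation if the peak or rate comparison is significant with the
   bilateral per-trial window rates above the contralateral ones in median,
   suppression if below, none otherwise (tied medians → none).

## Rank statistics

All procedures share a mid-rank (tie-averaged) ranking primitive.

**Scheirer-Ray-Hare.** Rank all N values jointly; compute factorial sums of
squares of the ranks; H_effect = SS_effect/(SS_total/(N−1)), referred to
χ²(df). Dividing by the total rank mean square absorbs the tie correction,
so with one constant factor the statistic reduces exactly to the
tie-corrected Kruskal-Wallis H (tested to 1e-9). Real cohorts are
unbalanced, so sums of squares come from Type II model comparison on the
ranks (fits via least squares on treatment-coded dummies); Type I
(sequential) is switchable via `ss_type`. For balanced designs both
coincide with the textbook cell/margin formulas. All-tied input yields NaN
statistics with p = 1 and a warning; an empty cell of the full cross is an
error naming the cell.

**Effect size.** η² = (H − k + 1)/(n − k) from the Kruskal-Wallis effect-size
formula, with k = 2 for main effects and, by convention, k = 4 (the cells)
for the interaction, since the formula is defined for a one-way grouping.
Labels: < 0.01 negligible, < 0.06 small, < 0.14 moderate, ≥ 0.14 large.

**Dunn post-hoc.** z_ij = (R̄_i − R̄_j)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))
(1/n_i + 1/n_j)], two-sided normal p, Bonferroni over the requested set
(default: the four cell contrasts Dark L–R, Light L–R, Left D–L, Right D–L,
so m = 4 per variable). Post-hocs run when the interaction is significant.

**Wilcoxon rank-sum.** Tie-corrected normal approximation with 0.5 continuity
correction shrinking |W − E[W]| (matching the standard "with continuity
correction" output); exact enumeration is used only as a test oracle for
n ≤ 8 per group, where the approximation stays within ≈ 0.013–0.06 of the
exact two-sided p on tie-free samples.

**Two-proportion z.** Pooled-variance form; the pipeline's proportion
comparison uses operand order reference − observed, so a cohort richer in
bilateral units than the reference yields negative z.

## Pipeline scope

Statistics run separately on the two responsive populations: bilaterally
responsive units are analyzed under all three conditions (13 variables);
contralaterally responsive units only under the contralateral condition
(5 variables) — matching the scope in which each population is meaningful.
No subject-level random effect is modeled; units are the observational unit.
Cell and pooled percentages are integers, round-half-away-from-zero,
recomputed from counts. Reports are deterministic byte-for-byte given the
dataset and thresholds (the run manifest carries a config hash, no
timestamps). Diagnostic plots (peak-rate violins, latency histograms) are
optional behind a flag; their aesthetics are unspecified.

## Synthetic cohorts

A unit is an inhomogeneous Poisson process
λ_c(t) = max(0, b + A_on[c]·g(t; t_on, w) + A_off[c]·g(t − 1; t_off, w)),
g a unit-peak Gaussian — the simplest transient with an explicit peak
latency, matching how latency is measured. Suppression is modeled as a
reduced (possibly negative) bilateral amplitude with the rate clipped at 0.
Sampling is Lewis-Shedler thinning under the constant majorant
b + max(0, A_on) + max(0, A_off); a fixed seed makes cohorts
bit-reproducible.

Archetype template defaults: baseline 5 Hz; contralateral ON/OFF amplitudes
60/30 Hz; ON latency 150 ms, OFF latency 200 ms, width (s.d.) 40 ms;
ipsilateral amplitudes 50% of contralateral where present; bilateral
amplitudes 1.5× contralateral (excitatory), 0.5× (suppressive) — i.e. ≥ 50%
amplitude contrasts, and transient amplitudes an order of magnitude above
the baseline PSTH noise s.d. (√(b/(n_trials·Δ)) ≈ 2.2 Hz), which is what
"strong effects" means in the recovery tests. Per-unit heterogeneity is a
shared lognormal multiplier (σ = 0.25) on baseline and amplitudes.

The default cohort preset encodes effect *directions* only, with magnitudes
chosen to be clearly detectable at tens of units per cell: light incubation
raises baseline (×1.5) and amplitudes (×1.35) in both hemispheres and
shortens latencies by 35 ms; in dark-incubated cohorts the right hemisphere
is stronger (×1.15 baseline, ×1.25 amplitude) and 25 ms faster. Each cell
mixes archetypes 15% nonresponsive, 35% contra-only, 20% excitatory, 15%
suppressive, 15% independent-ipsilateral.

What the generator does **not** emulate: refractoriness and bursting,
across-unit noise correlations, slow drift, spike-sorting contamination, and
subject-level clustering. Passing recovery tests therefore demonstrates the
analysis chain is correct under its own assumptions (Poisson variability,
transient responses, independent units), not that real recordings meet those
assumptions.

## Verification problem sizes

Chosen as the package's standard verification settings: rank-test oracle
agreement on 100 random unbalanced 2×2 instances (tolerance 1e-9 against a
statsmodels Type II rank-ANOVA and a first-principles Dunn formula); null
calibration of the factorial test over 2,000 replicates (25/cell), expecting
per-effect rejection in [0.03, 0.07] at α = 0.05; classifier recovery over
10 cohorts of 200 units/cell at 40 trials (balanced accuracy and ON
integration-sign accuracy ≥ 0.90); end-to-end power over 100 cohorts of 40
units/cell (treatment effect on spontaneous rate detected at p < 0.05 in
≥ 95%). With the preset above, measured values land at ≈ 0.91 balanced
accuracy (sensitivity ≈ 1, specificity limited by the uncorrected
multiple-criteria false-positive rate discussed above), ≈ 0.98 sign
accuracy, and power 1.0.

## Known limitations

- The uncorrected OR over six selection criteria caps contralateral
  specificity near 0.85 at α = 0.05; this mirrors the selection procedure
  as specified rather than an optimal detector.
- η² for interactions via the k = 4 one-way convention is a documented
  convention, not a uniquely defined quantity.
- The normal-approximation Wilcoxon p is inaccurate for very small trial
  counts (n < 10); the package targets 40-trial protocols.
- Latency resolution is one PSTH bin (25 ms); effects smaller than a bin are
  invisible by construction.
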