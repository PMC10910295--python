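"""End-to-end analysis: features -> classification -> summaries -> statistics.

The statistics stage runs separately on the two unit populations: for
bilaterally responsive units every dependent variable is analyzed under all
three stimulation conditions; for contralaterally responsive units only the
contralateral condition is analyzed.  Dependent variables per condition are
the baseline-subtracted ON/OFF peak firing rates and the ON/OFF peak
latencies, plus one population-level spontaneous firing rate.  Each variable
gets a Scheirer-Ray-Hare treatment x hemisphere test with eta-squared effect
sizes; variables with a significant interaction get Dunn post-hoc z-tests for
the four standard cell contrasts, with a Bonferroni flag.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierThresholds, UnitClassification, classify_unit
from .features import ResponseFeatures, extract_features, features_table
from .rankstats import (
    DunnResult,
    FactorialSample,
    SRHResult,
    dunn_posthoc,
    eta_squared_label,
    scheirer_ray_hare,
    two_proportion_z,
)
from .spikeio import HEMISPHERES, TREATMENTS, SpikeDataset, UnitMeta

log = logging.getLogger("entolat")

CELLS = [(t, h) for t in TREATMENTS for h in HEMISPHERES]
POSTHOC_PAIRS = [
    ("dark_left", "dark_right"),
    ("light_left", "light_right"),
    ("dark_left", "light_left"),
    ("dark_right", "light_right"),
]


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class CohortRow:
    treatment: str
    hemisphere: str  # "left", "right" or "left+right" for pooled rows
    n_responsive: int
    n_bilateral: int
    n_contralateral: int

    @property
    def pct_bilateral(self) -> int | None:
        if self.n_responsive == 0:
            return None
        return _round_half_away(100.0 * self.n_bilateral / self.n_responsive)

    @property
    def pct_contralateral(self) -> int | None:
        if self.n_responsive == 0:
            return None
        return _round_half_away(100.0 * self.n_contralateral / self.n_responsive)


@dataclass(frozen=True)
class CohortSummary:
    rows: list[CohortRow]
    n_total_units: int
    n_responsive: int
    n_bilateral: int
    n_contralateral: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "treatment": r.treatment,
                    "hemisphere": r.hemisphere,
                    "n_responsive": r.n_responsive,
                    "n_bilateral": r.n_bilateral,
                    "n_contralateral": r.n_contralateral,
                    "pct_bilateral": "" if r.pct_bilateral is None else r.pct_bilateral,
                    "pct_contralateral": ""
                    if r.pct_contralateral is None
                    else r.pct_contralateral,
                }
                for r in self.rows
            ]
        )


def summarize_cohort(
    classifications: list[UnitClassification], metas: list[UnitMeta]
) -> CohortSummary:
    """Count responsive / bilateral / contralateral units per cell and per
    pooled treatment row; percentages are recomputed from counts with
    round-half-away-from-zero."""
    by_id = {m.unit_id: m for m in metas}
    counts = {cell: [0, 0, 0] for cell in CELLS}  # responsive, bilateral, contra
    for cl in classifications:
        m = by_id[cl.unit_id]
        if not cl.visually_responsive:
            continue
        c = counts[(m.treatment, m.hemisphere)]
        c[0] += 1
        if cl.response_class == "bilateral":
            c[1] += 1
        elif cl.response_class == "contralateral":
            c[2] += 1
    rows: list[CohortRow] = []
    for t in TREATMENTS:
        for h in HEMISPHERES:
            rows.append(CohortRow(t, h, *counts[(t, h)]))
        pooled = [sum(counts[(t, h)][i] for h in HEMISPHERES) for i in range(3)]
        rows.append(CohortRow(t, "left+right", *pooled))
    total_resp = sum(counts[c][0] for c in CELLS)
    return CohortSummary(
        rows=rows,
        n_total_units=len(metas),
        n_responsive=total_resp,
        n_bilateral=sum(counts[c][1] for c in CELLS),
        n_contralateral=sum(counts[c][2] for c in CELLS),
    )


def compare_bilateral_proportion(
    summary: CohortSummary, reference_successes: int, reference_total: int
) -> dict:
    """Pooled two-proportion z-test of the cohort's bilateral fraction against
    an external reference count (operand order: reference minus observed)."""
    obs_x, obs_n = summary.n_bilateral, summary.n_responsive
    if obs_n <= 0 or reference_total <= 0:
        raise ValueError("both totals must be positive")
    z, p, degenerate = two_proportion_z(
        reference_successes, reference_total, obs_x, obs_n
    )
    return {
        "z": z,
        "p": p,
        "degenerate": degenerate,
        "observed_proportion": obs_x / obs_n,
        "reference_proportion": reference_successes / reference_total,
        "observed": (obs_x, obs_n),
        "reference": (reference_successes, reference_total),
    }


# ---------------------------------------------------------------------------
# Statistics layer

# (variable name, condition or None, feature attribute)
def _variables_for(population: str) -> list[tuple[str, str | None, str]]:
    conds = ["contra", "ipsi", "bilateral"] if population == "bilateral" else ["contra"]
    out: list[tuple[str, str | None, str]] = [("spontaneous_rate", None, "")]
    for c in conds:
        out += [
            (f"{c}_on_peak", c, "on_peak_sub"),
            (f"{c}_on_latency", c, "on_latency"),
            (f"{c}_off_peak", c, "off_peak_sub"),
            (f"{c}_off_latency", c, "off_latency"),
        ]
    return out


@dataclass(frozen=True)
class VariableStats:
    variable: str
    srh: SRHResult
    dunn: DunnResult | None  # post-hoc, run when the interaction is significant


@dataclass(frozen=True)
class AnalysisReport:
    summary: CohortSummary
    features: list[ResponseFeatures]
    classifications: list[UnitClassification]
    stats_bilateral: list[VariableStats] = field(default_factory=list)
    stats_contralateral: list[VariableStats] = field(default_factory=list)
    integration_counts: dict[str, int] = field(default_factory=dict)
    proportion_test: dict | None = None
    manifest: dict = field(default_factory=dict)


def _variable_values(
    feats: dict[str, ResponseFeatures], unit_ids: list[str],
    condition: str | None, attr: str,
) -> np.ndarray:
    vals = []
    for uid in unit_ids:
        f = feats[uid]
        vals.append(
            f.spontaneous_rate if condition is None
            else getattr(f.by_condition[condition], attr)
        )
    return np.asarray(vals, dtype=float)


def _population_stats(
    population: str,
    unit_ids: list[str],
    feats: dict[str, ResponseFeatures],
    metas: dict[str, UnitMeta],
    alpha: float,
) -> list[VariableStats]:
    cells_present = {(metas[u].treatment, metas[u].hemisphere) for u in unit_ids}
    if not set(CELLS) <= cells_present:
        missing = sorted(set(CELLS) - cells_present)
        log.warning(
            "population %r lacks cell(s) %s; statistics skipped", population, missing
        )
        return []
    out: list[VariableStats] = []
    for name, condition, attr in _variables_for(population):
        values = _variable_values(feats, unit_ids, condition, attr)
        keep = ~np.isnan(values)  # undefined latencies excluded
        ids = [u for u, k in zip(unit_ids, keep) if k]
        if not ids:
            continue
        v = values[keep]
        fa = np.array([metas[u].treatment for u in ids])
        fb = np.array([metas[u].hemisphere for u in ids])
        cells = {(t, h) for t, h in zip(fa, fb)}
        if not set(CELLS) <= cells:
            log.warning("variable %s: empty cell after NaN removal; skipped", name)
            continue
        srh = scheirer_ray_hare(FactorialSample(v, fa, fb))
        dunn = None
        if srh.p_ab < alpha:
            groups = np.array([f"{t}_{h}" for t, h in zip(fa, fb)])
            dunn = dunn_posthoc(v, groups, POSTHOC_PAIRS)
        out.append(VariableStats(name, srh, dunn))
    return out


def _integration_counts(classifications: list[UnitClassification]) -> dict[str, int]:
    counts = {f"{sign}_{w}": 0 for sign in ("excitation", "suppression") for w in ("on", "off")}
    for cl in classifications:
        if cl.response_class != "bilateral":
            continue
        for w in ("on", "off"):
            sign = getattr(cl, f"integration_{w}")
            if sign != "none":
                counts[f"{sign}_{w}"] += 1
    return counts


def run_analysis(
    dataset: SpikeDataset,
    thresholds: ClassifierThresholds | None = None,
    reference_proportion: tuple[int, int] | None = None,
    out_dir: str | Path | None = None,
    config_meta: dict | None = None,
    make_plots: bool = False,
) -> AnalysisReport:
    """Run the full pipeline on one dataset.

    Deterministic given the dataset and thresholds; if ``out_dir`` is given,
    every table is written there as CSV plus a JSON run manifest.
    ``reference_proportion`` is an optional (successes, total) external count
    the cohort's bilateral fraction is compared against.
    """
    th = thresholds or ClassifierThresholds()
    metas = {u.unit_id: u for u in dataset.units}
    log.info("analysis start: %d units", len(dataset.units))

    feats_list = [extract_features(dataset, u.unit_id) for u in dataset.units]
    feats = {f.unit_id: f for f in feats_list}
    classifications = [
        classify_unit(dataset, u.unit_id, th, features=feats[u.unit_id])
        for u in dataset.units
    ]
    summary = summarize_cohort(classifications, dataset.units)
    log.info(
        "classification: %d responsive (%d bilateral / %d contralateral) of %d",
        summary.n_responsive, summary.n_bilateral,
        summary.n_contralateral, summary.n_total_units,
    )

    bilateral_ids = [c.unit_id for c in classifications if c.response_class == "bilateral"]
    contra_ids = [c.unit_id for c in classifications if c.response_class == "contralateral"]
    stats_b = (
        _population_stats("bilateral", bilateral_ids, feats, metas, th.alpha)
        if bilateral_ids else []
    )
    stats_c = (
        _population_stats("contralateral", contra_ids, feats, metas, th.alpha)
        if contra_ids else []
    )

    proportion = None
    if reference_proportion is not None and summary.n_responsive > 0:
        proportion = compare_bilateral_proportion(summary, *reference_proportion)

    manifest = {
        "package_version": __version__,
        "n_units": len(dataset.units),
        "thresholds": {
            "responsiveness_fold": th.responsiveness_fold,
            "min_peak_rate": th.min_peak_rate,
            "ipsi_sigma": th.ipsi_sigma,
            "alpha": th.alpha,
        },
        "protocol": dataset.protocol.to_dict(),
        "config": config_meta or {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]

    report = AnalysisReport(
        summary=summary,
        features=feats_list,
        classifications=classifications,
        stats_bilateral=stats_b,
        stats_contralateral=stats_c,
        integration_counts=_integration_counts(classifications),
        proportion_test=proportion,
        manifest=manifest,
    )
    if out_dir is not None:
        write_report(report, out_dir, make_plots=make_plots)
    return report


# ---------------------------------------------------------------------------
# Report files


def _stats_frame(stats: list[VariableStats]) -> pd.DataFrame:
    rows = []
    for vs in stats:
        s = vs.srh
        for effect, H, df, p, eta2 in (
            ("treatment", s.H_a, s.df_a, s.p_a, s.eta2_a),
            ("hemisphere", s.H_b, s.df_b, s.p_b, s.eta2_b),
            ("interaction", s.H_ab, s.df_ab, s.p_ab, s.eta2_ab),
        ):
            rows.append(
                {
                    "variable": vs.variable,
                    "effect": effect,
                    "H": H,
                    "df": df,
                    "p": p,
                    "eta2": eta2,
                    "eta2_label": eta_squared_label(eta2),
                }
            )
    return pd.DataFrame(
        rows, columns=["variable", "effect", "H", "df", "p", "eta2", "eta2_label"]
    )


def _posthoc_frame(stats: list[VariableStats], population: str) -> pd.DataFrame:
    rows = []
    for vs in stats:
        if vs.dunn is None:
            continue
        for cmp_ in vs.dunn.comparisons:
            rows.append(
                {
                    "population": population,
                    "variable": vs.variable,
                    "pair": f"{cmp_.group_i} vs {cmp_.group_j}",
                    "z": cmp_.z,
                    "p_raw": cmp_.p_raw,
                    "p_bonferroni": cmp_.p_bonferroni,
                    "significant_after_bonferroni": cmp_.p_bonferroni < 0.05,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["population", "variable", "pair", "z", "p_raw",
                 "p_bonferroni", "significant_after_bonferroni"],
    )


def write_report(report: AnalysisReport, out_dir: str | Path, make_plots: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.summary.to_frame().to_csv(out / "summary_table1.csv", index=False)
    features_table(report.features).to_csv(out / "features.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        [
            {
                "unit_id": c.unit_id,
                "visually_responsive": c.visually_responsive,
                "response_class": c.response_class,
                "criteria_fired": ";".join(sorted(c.criteria_fired)),
                "integration_on": c.integration_on,
                "integration_off": c.integration_off,
            }
            for c in report.classifications
        ]
    ).to_csv(out / "classification.csv", index=False)
    _stats_frame(report.stats_bilateral).to_csv(out / "stats_bilateral.csv", index=False, float_format="%.9g")
    _stats_frame(report.stats_contralateral).to_csv(out / "stats_contralateral.csv", index=False, float_format="%.9g")
    posthoc_parts = [
        _posthoc_frame(report.stats_bilateral, "bilateral"),
        _posthoc_frame(report.stats_contralateral, "contralateral"),
    ]
    nonempty = [f for f in posthoc_parts if len(f)]
    posthoc = pd.concat(nonempty, ignore_index=True) if nonempty else posthoc_parts[0]
    posthoc.to_csv(out / "posthoc.csv", index=False, float_format="%.9g")
    pd.DataFrame([report.integration_counts]).to_csv(
        out / "integration_counts.csv", index=False
    )
    if report.proportion_test is not None:
        pd.DataFrame([{
            "z": report.proportion_test["z"],
            "p": report.proportion_test["p"],
            "observed_successes": report.proportion_test["observed"][0],
            "observed_total": report.proportion_test["observed"][1],
            "reference_successes": report.proportion_test["reference"][0],
            "reference_total": report.proportion_test["reference"][1],
        }]).to_csv(out / "proportion_test.csv", index=False, float_format="%.9g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
    if make_plots:
        _write_plots(report, out)


def _write_plots(report: AnalysisReport, out: Path) -> None:
    """Optional diagnostic plots: peak-rate violins and latency histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = features_table(report.features)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    axes[0].violinplot(
        [df[f"{c}_on_peak_sub"].dropna() for c in ("contra", "ipsi", "bilateral")],
        showmedians=True,
    )
    axes[0].set_xticks([1, 2, 3], ["contra", "ipsi", "bilateral"])
    axes[0].set_ylabel("ON peak rate - spontaneous (Hz)")
    lat = df["contra_on_latency"].dropna()
    axes[1].hist(lat, bins=20)
    axes[1].set_xlabel("contralateral ON peak latency (s)")
    fig.tight_layout()
    fig.savefig(out / "diagnostics.png", dpi=120)
    plt.close(fig)
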