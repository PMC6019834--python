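"""Report assembly: change tables, MCID tables, adjusted comparisons.

Two entry paths feed the comparison machinery:

* **patient-level** — a :class:`~mcidkit.pipeline.LongitudinalCohort`,
  from which change scores, MCID estimates and subgroup ICCs are
  computed;
* **summary-statistics** — a table of printed rows (instrument, scheme,
  period, n, mean, sd, icc), from which adjusted intervals are exactly
  reproducible without raw data.  A packaged reference table of
  published MCID subgroup summaries for CAT/CCQ/SGRQ over a
  rehabilitation year ships with the library.

Displayed values are rounded half-away-from-zero at one decimal;
machine outputs keep full precision.
"""
from __future__ import annotations

import importlib.resources
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .comparison import (
    LITERATURE_THRESHOLDS,
    AdjustedComparison,
    OverlapResult,
    adjust_estimate,
    build_adjusted,
    compare_literature,
    icc_baseline_followup,
    overlap_matrix,
)
from .pipeline import (
    FOLLOWUPS,
    LongitudinalCohort,
    MCIDEstimate,
    compute_changes,
    estimate_mcid,
    mean_change_test,
)
from .util import config_hash, display1

__all__ = [
    "load_reference_summaries",
    "change_table",
    "mcid_table",
    "subgroup_icc",
    "comparisons_from_cohort",
    "comparisons_from_summary",
    "comparison_table",
    "literature_table",
    "run_metadata",
    "write_tables",
    "forest_plot",
]

DEFAULT_PERIODS: tuple[tuple[str, str], ...] = tuple(
    ("T0", tp) for tp in FOLLOWUPS)


def load_reference_summaries() -> pd.DataFrame:
    """Packaged published subgroup summary rows (mean, SD, N, ICC)."""
    with importlib.resources.files("mcidkit.data") \
            .joinpath("reference_summaries.csv").open() as fh:
        return pd.read_csv(fh)


def _star(p: float) -> str:
    return "*" if (p == p and p < 0.05) else ""


def change_table(
    cohort: LongitudinalCohort,
    instruments: Sequence[str] | None = None,
    periods: Sequence[tuple[str, str]] = DEFAULT_PERIODS,
) -> pd.DataFrame:
    """Full-cohort change scores per instrument x period.

    One row per instrument x period with mean, 95% CI, paired-test p,
    standardised values, and 1-decimal display strings with a
    significance star (p < 0.05).
    """
    instruments = list(instruments or cohort.instruments)
    rows = []
    for inst in instruments:
        spec = cohort.instruments[inst]
        for period in periods:
            try:
                ch = compute_changes(cohort, inst, period)
            except ValueError:
                continue
            if len(ch) < 2:
                warnings.warn(
                    f"{inst} {period}: fewer than 2 complete pairs; skipped")
                continue
            res = mean_change_test(ch)
            f = 100.0 / spec.scale_max
            rows.append({
                "instrument": inst, "period": f"{period[1]}-{period[0]}",
                "n": res.n, "mean": res.mean, "sd": res.sd,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "p": res.p, "n_excluded": ch.n_excluded,
                "std_mean": res.mean * f,
                "std_ci_low": res.ci95[0] * f, "std_ci_high": res.ci95[1] * f,
                "display": (
                    f"{display1(res.mean)}{_star(res.p)}"
                    f" ({display1(res.ci95[0])} to {display1(res.ci95[1])})"
                ),
            })
    return pd.DataFrame(rows)


def mcid_table(
    cohort: LongitudinalCohort,
    instruments: Sequence[str] | None = None,
    schemes: Sequence[str] = ("grc15", "grc5"),
    periods: Sequence[tuple[str, str]] = DEFAULT_PERIODS,
    min_n: int = 10,
) -> tuple[pd.DataFrame, list[MCIDEstimate]]:
    """MCID estimates for the minimally-improved anchor subgroups."""
    instruments = list(instruments or cohort.instruments)
    rows, estimates = [], []
    for inst in instruments:
        for scheme in schemes:
            for period in periods:
                col = cohort.anchor_col(scheme, period[1])
                if col not in cohort.data.columns:
                    continue
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        est = estimate_mcid(
                            cohort, inst, scheme, period, min_n=min_n)
                except ValueError:
                    continue
                estimates.append(est)
                rows.append({
                    "instrument": inst, "scheme": scheme,
                    "period": f"{period[1]}-{period[0]}",
                    "subgroup": est.subgroup, "n": est.n,
                    "mean": est.mean, "sd": est.sd,
                    "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                    "std_mean": est.standardized_mean,
                    "std_ci_low": est.standardized_ci95[0],
                    "std_ci_high": est.standardized_ci95[1],
                    "p": est.p_vs_baseline,
                    "anchor_r": (est.eligibility.coefficient
                                 if est.eligibility else float("nan")),
                    "anchor_eligible": (est.eligibility.eligible
                                        if est.eligibility else None),
                    "low_n": est.low_n,
                    "display": (
                        f"{display1(est.mean)}{_star(est.p_vs_baseline)}"
                        f" ±{display1(est.sd)}"
                        f" ({display1(est.ci95[0])} to "
                        f"{display1(est.ci95[1])})"
                    ),
                })
    return pd.DataFrame(rows), estimates


def subgroup_icc(
    cohort: LongitudinalCohort,
    estimate: MCIDEstimate,
    form: str = "icc1",
) -> float:
    """Baseline-follow-up ICC on the estimate's anchor subgroup."""
    from .anchors import categorize

    base_tp, follow_tp = estimate.period
    df = cohort.data
    ratings = cohort.anchor(estimate.scheme, follow_tp)
    base = cohort.scores(estimate.instrument, base_tp)
    follow = cohort.scores(estimate.instrument, follow_tp)
    mask = base.notna() & follow.notna() & ratings.notna()
    if estimate.scheme == "grc15":
        cats = ratings[mask].map(lambda v: categorize(int(v), "grc15"))
    else:
        cats = ratings[mask].map(lambda v: categorize(v, "grc5"))
    sub = mask[mask].index[cats == estimate.subgroup]
    return icc_baseline_followup(
        df.loc[sub, cohort.score_col(estimate.instrument, base_tp)],
        df.loc[sub, cohort.score_col(estimate.instrument, follow_tp)],
        form=form,
    )


def comparisons_from_cohort(
    cohort: LongitudinalCohort,
    estimates: Sequence[MCIDEstimate],
    mode: str = "formula",
    alpha: float = 0.05,
    icc_form: str = "icc1",
    scale: str = "native",
) -> list[AdjustedComparison]:
    """Adjusted comparisons for a set of estimates, ICCs from the data."""
    out = []
    for est in estimates:
        if est.degenerate:
            continue
        rho = subgroup_icc(cohort, est, form=icc_form)
        out.append(adjust_estimate(est, rho, alpha=alpha, mode=mode,
                                   scale=scale))
    return out


def comparisons_from_summary(
    summary: pd.DataFrame,
    mode: str = "formula",
    alpha: float = 0.05,
    scale: str = "native",
) -> list[AdjustedComparison]:
    """Adjusted comparisons from printed summary rows.

    ``summary`` needs columns instrument, scheme, period, n, mean, sd,
    icc — the replication surface for published comparison tables.
    """
    required = {"instrument", "scheme", "period", "n", "mean", "sd", "icc"}
    if not required.issubset(summary.columns):
        raise ValueError(f"summary table needs columns {sorted(required)}")
    return [
        build_adjusted(
            row["mean"], row["sd"], int(row["n"]), row["icc"],
            instrument=row["instrument"], period=str(row["period"]),
            scheme=row["scheme"], alpha=alpha, mode=mode, scale=scale,
        )
        for _, row in summary.iterrows()
    ]


def comparison_table(comparisons: Sequence[AdjustedComparison]) -> pd.DataFrame:
    """Flat table of adjusted comparisons (full precision + display)."""
    rows = []
    for c in comparisons:
        rows.append({
            "instrument": c.instrument, "scheme": c.scheme,
            "period": (c.period if isinstance(c.period, str)
                       else "-".join(reversed(c.period))),
            "n": c.n, "mean": c.mean, "sd": c.sd, "icc": c.icc,
            "z_star": c.z_star, "se": c.se,
            "ci_low": c.ci_adj[0], "ci_high": c.ci_adj[1],
            "se_display": display1(c.se),
            "ci_display": (f"{display1(c.ci_adj[0])} to "
                           f"{display1(c.ci_adj[1])}"),
        })
    return pd.DataFrame(rows)


def literature_table(
    comparisons: Sequence[AdjustedComparison],
    thresholds: Mapping[str, object] = LITERATURE_THRESHOLDS,
) -> pd.DataFrame:
    """Each comparison vs the published instrument threshold."""
    rows = []
    for c in comparisons:
        thr = thresholds.get(c.instrument)
        if thr is None:
            continue
        verdict = compare_literature(c, thr)
        rows.append({
            "comparison": c.label, "threshold": verdict.threshold,
            "inside_ci": verdict.inside,
            "significantly_different": verdict.significant,
        })
    return pd.DataFrame(rows)


def run_metadata(config_like, seed: int | None = None) -> dict:
    """Reproducibility stamp attached to every written output."""
    return {
        "package": "mcidkit",
        "version": __version__,
        "config_hash": config_hash(config_like),
        "seed": seed,
        "created": datetime.now(timezone.utc).isoformat(timespec="seconds"),
    }


def write_tables(
    out_dir: str | Path,
    tables: Mapping[str, pd.DataFrame],
    metadata: dict,
    overlap: OverlapResult | None = None,
) -> list[Path]:
    """Write CSV tables, a JSON report and the metadata block."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    payload: dict = {"metadata": metadata}
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
        payload[name] = json.loads(table.to_json(orient="records"))
    if overlap is not None:
        p = out / "overlap_matrix.csv"
        overlap.significant.to_csv(p)
        written.append(p)
        payload["forest"] = json.loads(
            overlap.forest.to_json(orient="records"))
    p = out / "report.json"
    p.write_text(json.dumps(payload, indent=2, default=str))
    written.append(p)
    return written


def forest_plot(comparisons: Sequence[AdjustedComparison], path=None):
    """Minimal forest plot of adjusted intervals (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 0.5 * len(comparisons) + 1))
    ys = np.arange(len(comparisons))[::-1]
    for y, c in zip(ys, comparisons):
        ax.plot(list(c.ci_adj), [y, y], color="k")
        ax.plot([c.mean], [y], marker="s", color="k")
    ax.set_yticks(ys)
    ax.set_yticklabels([c.label for c in comparisons])
    ax.axvline(0.0, color="grey", lw=0.5)
    ax.set_xlabel("change score (negative = improvement)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
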