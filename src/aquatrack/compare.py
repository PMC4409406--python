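"""Treatment comparisons and the summary table.

The testing scheme is fixed per metric, with the *individual* as the unit
of replication for location tests (each marked animal contributes one
value per metric):

====================  ==========================  ===========================
metric                2 treatments                >2 treatments
====================  ==========================  ===========================
resting_time          Welch's t-test              one-way ANOVA
fractal_dimension     Welch's t-test              one-way ANOVA
                      (both on log(D−1)-transformed values)
step_length           Wilcoxon rank-sum           Kruskal–Wallis
turning_angle         Watson–Wheeler on pooled relocation angles
====================  ==========================  ===========================

Fractal dimensions at or below 1 are clipped to 1 + 1e−6 before the log
transform (flagged in the result notes).  Turning angles are pooled across
replicates within each treatment before testing; the pseudo-replication
this entails is a property of the design, not corrected here.  No
multiple-testing correction is applied — each metric is reported on its
own.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .circular import circular_summary, watson_wheeler
from .results import ComparisonResult

__all__ = ["ComparisonResult", "compare_treatments", "build_summary_table", "METRICS"]

#: metric name -> column holding the per-individual (or per-angle) values
METRIC_COLUMNS = {
    "resting_time": "resting_fraction",
    "step_length": "mean_step_cm",
    "fractal_dimension": "fractal_D",
    "turning_angle": "angle_deg",
}

METRICS = tuple(METRIC_COLUMNS)

_D_CLIP = 1e-6


def compare_treatments(
    table: pd.DataFrame,
    metric: str,
    groups: list[str] | None = None,
    *,
    value_column: str | None = None,
) -> ComparisonResult:
    """Run the scheme's test for one metric across treatments.

    Parameters
    ----------
    table
        For location metrics: a per-individual table with columns
        ``treatment`` and the metric's value column (see
        ``METRIC_COLUMNS``).  For ``turning_angle``: a long-format table of
        pooled relocation angles with columns ``treatment, angle_deg``.
    metric
        One of ``resting_time``, ``step_length``, ``fractal_dimension``,
        ``turning_angle``.
    groups
        Optional subset/order of treatment labels; defaults to all labels
        present.
    """
    if metric not in METRIC_COLUMNS:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {sorted(METRIC_COLUMNS)}"
        )
    col = value_column or METRIC_COLUMNS[metric]
    if "treatment" not in table.columns or col not in table.columns:
        raise ValueError(f"table must have columns 'treatment' and {col!r}")
    if groups is None:
        groups = list(pd.unique(table["treatment"]))
    if len(groups) < 2:
        raise ValueError("need at least 2 treatment groups")
    arrays = [
        table.loc[table["treatment"] == g, col].to_numpy(dtype=float)
        for g in groups
    ]
    sizes = {g: len(a) for g, a in zip(groups, arrays)}

    if metric == "turning_angle":
        res = watson_wheeler(dict(zip(groups, arrays)))
        res.metric = metric
        return res

    for g, a in zip(groups, arrays):
        if len(a) < 3:
            raise ValueError(
                f"group {g!r} has {len(a)} individuals; location tests need >= 3"
            )

    transform = None
    notes = ""
    if metric == "fractal_dimension":
        n_clip = sum(int(np.count_nonzero(a <= 1.0)) for a in arrays)
        if n_clip:
            notes = f"{n_clip} value(s) at or below D=1 clipped before log(D-1)"
            warnings.warn(notes, stacklevel=2)
        arrays = [np.log(np.maximum(a, 1.0 + _D_CLIP) - 1.0) for a in arrays]
        transform = "log(D-1)"

    if metric in ("resting_time", "fractal_dimension"):
        if len(groups) == 2:
            res = stats.ttest_ind(arrays[0], arrays[1], equal_var=False)
            return ComparisonResult(
                metric, "welch_t", float(res.statistic), float(res.df),
                float(res.pvalue), transform=transform,
                n_per_group=sizes, notes=notes,
            )
        res = stats.f_oneway(*arrays)
        k = len(groups)
        N = sum(sizes.values())
        return ComparisonResult(
            metric, "anova_oneway", float(res.statistic), (k - 1, N - k),
            float(res.pvalue), transform=transform,
            n_per_group=sizes, notes=notes,
        )

    # step_length: rank tests
    if len(groups) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return ComparisonResult(
            metric, "wilcoxon_rank_sum", float(res.statistic), None,
            float(res.pvalue), n_per_group=sizes,
        )
    res = stats.kruskal(*arrays)
    return ComparisonResult(
        metric, "kruskal_wallis", float(res.statistic), len(groups) - 1,
        float(res.pvalue), n_per_group=sizes,
    )


def build_summary_table(
    per_individual: pd.DataFrame,
    angles: pd.DataFrame | None = None,
    bookkeeping: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assemble the per-treatment summary of movement parameters.

    Parameters
    ----------
    per_individual
        One row per individual with columns ``treatment`` and any of
        ``resting_fraction``, ``mean_step_cm``, ``fractal_D``,
        ``duration_mean_s``.  Means and SDs are taken over individuals;
        with a single individual the SD is reported as missing (NaN).
    angles
        Optional long-format pooled relocation angles (``treatment,
        angle_deg``); summarised circularly (circular mean and SD) with the
        arithmetic SD exported alongside.
    bookkeeping
        Optional per-treatment coverage rows (``treatment,
        available_points_pct, n_paths, mean_duration_s, sd_duration_s``)
        from :func:`~aquatrack.trajectory.summarize_paths`, passed through.

    Returns a DataFrame indexed by treatment whose columns mirror the
    conventional arena summary: coverage, path counts and durations,
    resting %, step length, turning angle, fractal D, each as mean ± SD.
    """
    if "treatment" not in per_individual.columns:
        raise ValueError("per_individual must have a 'treatment' column")
    rows = {}
    for treatment, grp in per_individual.groupby("treatment", sort=False):
        if len(grp) == 0:
            raise ValueError(f"treatment {treatment!r} has no individuals")
        row: dict[str, float] = {"n_individuals": len(grp)}
        for col, label in [
            ("resting_fraction", "resting_pct"),
            ("mean_step_cm", "step_cm"),
            ("fractal_D", "fractal_D"),
            ("duration_mean_s", "duration_s"),
        ]:
            if col not in grp.columns:
                continue
            vals = grp[col].to_numpy(dtype=float)
            scale = 100.0 if label == "resting_pct" else 1.0
            row[f"{label}_mean"] = scale * float(np.mean(vals))
            row[f"{label}_sd"] = (
                scale * float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan
            )
        rows[treatment] = row

    if angles is not None:
        for treatment, grp in angles.groupby("treatment", sort=False):
            if treatment not in rows:
                rows[treatment] = {}
            a = grp["angle_deg"].to_numpy(dtype=float)
            if len(a) >= 2:
                cs = circular_summary(a)
                rows[treatment]["turn_mean_deg"] = cs.mean_deg
                rows[treatment]["turn_sd_circular_deg"] = cs.sd_deg
                rows[treatment]["turn_sd_arithmetic_deg"] = cs.sd_arithmetic_deg
                rows[treatment]["turn_n"] = cs.n

    if bookkeeping is not None:
        for _, r in bookkeeping.iterrows():
            t = r["treatment"]
            if t not in rows:
                rows[t] = {}
            for col in (
                "available_points_pct",
                "n_paths",
                "mean_duration_s",
                "sd_duration_s",
            ):
                if col in bookkeeping.columns:
                    rows[t][col] = r[col]

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "treatment"
    return out
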