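"""Per-case aggregation and condition comparisons (mean ± SEM, t-tests).

The unit of replication is the donor case: per-field values are averaged to
one value per case and condition, condition summaries are mean ± SEM across
cases (SEM = sd/sqrt(n_cases)), and conditions are compared with two-sided
t-tests at alpha = 0.05.  Welch's unequal-variance test is the default; a
paired test is available because vehicle and treated cultures from one
donor share the case.  No multiple-testing correction is applied; the
report states how many comparisons were made.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import ExperimentConfig

__all__ = ["AssaySummary", "aggregate", "t_test", "summarize_experiment", "report"]


@dataclass(frozen=True)
class AssaySummary:
    """One metric's condition comparison."""

    metric: str
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    significant: bool
    condition_a: str = "vehicle"
    condition_b: str = "mcsf"
    paired: bool = False


def sem(values: np.ndarray) -> float:
    """Standard error of the mean: sd (ddof=1) / sqrt(n)."""
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < 2:
        return np.nan
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def aggregate(
    per_field: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Average per-field values to one row per (case, condition).

    If the per-field table lacks case/condition identifiers they are joined
    from the layout on ``field_id``; a field with no layout entry raises.
    Fields with missing values for a metric (e.g. zero-microglia fields)
    are excluded from that metric's case mean.
    """
    df = per_field.copy()
    if "case_id" not in df.columns or df["case_id"].eq("").any():
        if layout is None:
            raise ValueError("per-field table lacks case ids and no layout given")
        df = df.drop(columns=["case_id", "condition", "well_id"], errors="ignore")
        missing = set(df.field_id) - set(layout.field_id)
        if missing:
            raise ValueError(f"fields with no layout entry: {sorted(missing)[:5]}")
        df = df.merge(
            layout[["field_id", "case_id", "condition"]], on="field_id", how="left"
        )
    if metrics is None:
        metrics = [
            c
            for c in df.columns
            if c not in ("field_id", "well_id", "case_id", "condition")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    grouped = (
        df.groupby(["case_id", "condition"], sort=True)[metrics].mean().reset_index()
    )
    return grouped


def t_test(
    group_a: np.ndarray, group_b: np.ndarray, paired: bool = False
) -> tuple[float, float, float]:
    """Two-sided t-test; Welch by default, optionally paired by case."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        keep = ~(np.isnan(a) | np.isnan(b))
        a, b = a[keep], b[keep]
        if len(a) < 2:
            raise ValueError("paired t-test needs at least 2 complete pairs")
        res = sps.ttest_rel(a, b)
        df = float(len(a) - 1)
    else:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs at least 2 values per group")
        res = sps.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    t = float(res.statistic)
    p = float(res.pvalue)
    if np.isnan(t):  # identical zero-variance groups
        t, p = 0.0, 1.0
    return t, df, p


def summarize_experiment(
    per_case: pd.DataFrame,
    metrics: list[str] | None = None,
    *,
    condition_a: str = "vehicle",
    condition_b: str = "mcsf",
    paired: bool = False,
    alpha: float = 0.05,
) -> list[AssaySummary]:
    """Compare every metric between two conditions across case means."""
    if metrics is None:
        metrics = [
            c
            for c in per_case.columns
            if c not in ("case_id", "condition")
            and pd.api.types.is_numeric_dtype(per_case[c])
        ]
    pivot = per_case.pivot(index="case_id", columns="condition")
    out = []
    for metric in metrics:
        a = pivot[(metric, condition_a)].to_numpy(dtype=float)
        b = pivot[(metric, condition_b)].to_numpy(dtype=float)
        t, df, p = t_test(a, b, paired=paired)
        a_clean = a[~np.isnan(a)]
        b_clean = b[~np.isnan(b)]
        out.append(
            AssaySummary(
                metric=metric,
                mean_a=float(np.mean(a_clean)),
                sem_a=sem(a_clean),
                mean_b=float(np.mean(b_clean)),
                sem_b=sem(b_clean),
                n_a=len(a_clean),
                n_b=len(b_clean),
                t=t,
                df=df,
                p=p,
                significant=bool(p < alpha),
                condition_a=condition_a,
                condition_b=condition_b,
                paired=paired,
            )
        )
    return out


def report(
    summaries: list[AssaySummary], cfg: ExperimentConfig | None = None
) -> tuple[str, pd.DataFrame]:
    """Plain-text report and machine-readable table of all comparisons.

    Output ordering is deterministic (metric name order as given); the text
    echoes every configurable analysis decision.
    """
    table = pd.DataFrame([s.__dict__ for s in summaries])
    lines = ["Condition comparison report", "=" * 27, ""]
    if cfg is not None:
        lines += [
            "settings:",
            f"  threshold method: Otsu on illumination-flattened channel",
            f"  positivity threshold k: {cfg.positivity_k} sd over background",
            f"  cargo min area fraction: {cfg.cargo_min_area_fraction}",
            f"  EFF definition: {cfg.eff_definition}",
            f"  perimeter method: {cfg.perimeter_method}",
            f"  t-test: {'paired' if cfg.paired else 'Welch unpaired'}, "
            f"alpha = {cfg.alpha}",
            f"  config hash: {cfg.config_hash()}",
            "",
        ]
    if not summaries:
        lines.append("no comparisons (empty input)")
    for s in summaries:
        star = " *" if s.significant else ""
        lines.append(
            f"{s.metric}: {s.condition_a} {s.mean_a:.4g} ± {s.sem_a:.2g} "
            f"(n={s.n_a}) vs {s.condition_b} {s.mean_b:.4g} ± {s.sem_b:.2g} "
            f"(n={s.n_b}); t={s.t:.3f}, df={s.df:.2f}, p={s.p:.3g}{star}"
        )
    lines.append("")
    lines.append(
        f"{len(summaries)} comparisons made; no multiple-testing correction applied."
    )
    return "\n".join(lines) + "\n", table
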