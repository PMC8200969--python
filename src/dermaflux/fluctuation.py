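"""Longitudinal analytics: daily triples, weekly averages, delta fluctuation
and the baseline/treatment statistical comparisons.

Conventions: weeks -4..-1 are the baseline period, weeks 1..4 the treatment
period. Weekly grand means average per subject first, then over subjects.
Incomplete days are skipped for delta fluctuation (never imputed); weekly
means use available cases. Paired comparisons use the Wilcoxon signed-rank
test, study-vs-study comparisons Welch's t; baseline timepoint contrasts
are Holm-adjusted across the three pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    TIMEPOINT_ORDER,
    Metric,
    MetricRecord,
    TimePoint,
    records_to_frame,
)
from .stats import (
    ALPHA,
    InsufficientDataError,
    TestResult,
    holm_adjust,
    welch_t,
    wilcoxon_signed_rank,
)

__all__ = [
    "DailyTriple",
    "ComparisonResult",
    "delta_fluctuation",
    "build_daily_triples",
    "delta_fluctuation_table",
    "weekly_average",
    "compare_timepoints_baseline",
    "treatment_effect",
    "compare_studies",
]

MIN_PAIRED_SUBJECTS = 6
MIN_GROUP_SUBJECTS = 3

_TP_VALUES = [tp.value for tp in TIMEPOINT_ORDER]


@dataclass(frozen=True)
class DailyTriple:
    """The three timepoint values of one subject-day for one metric."""

    subject_id: str
    study_day: int
    metric: Metric
    values: dict[TimePoint, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(TIMEPOINT_ORDER):
            raise ValueError("DailyTriple requires exactly the three timepoints")


@dataclass(frozen=True)
class ComparisonResult:
    method: str
    statistic: float
    p_value: float
    n: int
    significant: bool
    adjusted: bool
    label: str = ""


def delta_fluctuation(triple: DailyTriple) -> float:
    """Within-day spread: highest minus lowest of the three timepoint values."""
    vals = list(triple.values.values())
    return max(vals) - min(vals)


def _to_frame(records: Sequence[MetricRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def _metric_frame(records, metric: Metric | str) -> pd.DataFrame:
    df = _to_frame(records)
    metric = Metric(metric)
    return df[df["metric"] == metric.value].copy()


def build_daily_triples(
    records, metric: Metric | str
) -> tuple[list[DailyTriple], pd.DataFrame]:
    """Assemble complete subject-days; incomplete days go to the report.

    Returns ``(triples, completeness)`` where ``completeness`` lists every
    subject-day with its number of present timepoints.
    """
    df = _metric_frame(records, metric)
    metric = Metric(metric)
    triples: list[DailyTriple] = []
    report_rows = []
    for (subject, day), grp in df.groupby(["subject_id", "study_day"], sort=True):
        present = dict(zip(grp["timepoint"], grp["value_au"]))
        complete = len(present) == 3 and set(present) == set(_TP_VALUES)
        report_rows.append(
            {"subject_id": subject, "study_day": day, "n_timepoints": len(present), "complete": complete}
        )
        if complete:
            triples.append(
                DailyTriple(
                    subject_id=str(subject),
                    study_day=int(day),
                    metric=metric,
                    values={TimePoint(tp): float(v) for tp, v in present.items()},
                )
            )
    completeness = pd.DataFrame(
        report_rows, columns=["subject_id", "study_day", "n_timepoints", "complete"]
    )
    return triples, completeness


def delta_fluctuation_table(records, metric: Metric | str) -> pd.DataFrame:
    """Per complete subject-day: delta fluctuation plus week index and period."""
    triples, _ = build_daily_triples(records, metric)
    rows = [
        {
            "subject_id": t.subject_id,
            "study_day": t.study_day,
            "week_index": _week(t.study_day),
            "delta": delta_fluctuation(t),
        }
        for t in triples
    ]
    df = pd.DataFrame(rows, columns=["subject_id", "study_day", "week_index", "delta"])
    df["period"] = np.where(df["week_index"] < 0, "baseline", "treatment")
    return df


def _week(day: int) -> int:
    from .core_io import week_from_day

    return week_from_day(int(day))


def weekly_average(records, metric: Metric | str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Week x timepoint grand means (subject means first, then over subjects).

    Returns ``(means, counts)``; ``counts`` holds the number of subjects
    contributing to each cell. Empty cells are NaN / 0.
    """
    df = _metric_frame(records, metric)
    subj = (
        df.groupby(["week_index", "timepoint", "subject_id"])["value_au"]
        .mean()
        .reset_index()
    )
    means = (
        subj.groupby(["week_index", "timepoint"])["value_au"]
        .mean()
        .unstack("timepoint")
        .reindex(columns=_TP_VALUES)
    )
    counts = (
        subj.groupby(["week_index", "timepoint"])["value_au"]
        .size()
        .unstack("timepoint")
        .reindex(columns=_TP_VALUES)
        .fillna(0)
        .astype(int)
    )
    return means, counts


def _subject_means(df: pd.DataFrame, by_timepoint: bool = True) -> pd.DataFrame:
    keys = ["subject_id"] + (["timepoint"] if by_timepoint else [])
    return df.groupby(keys)["value_au"].mean().reset_index()


def compare_timepoints_baseline(
    records, metric: Metric | str, adjust: bool = True
) -> list[ComparisonResult]:
    """Wilcoxon signed-rank on baseline subject means for all timepoint pairs.

    Subjects must have all three timepoints in the baseline period; fewer
    than 6 such subjects is an error. P-values are Holm-adjusted across the
    three pairs unless ``adjust`` is False.
    """
    df = _metric_frame(records, metric)
    df = df[df["week_index"] < 0]
    subj = _subject_means(df)
    wide = subj.pivot(index="subject_id", columns="timepoint", values="value_au")
    wide = wide.reindex(columns=_TP_VALUES).dropna()
    if len(wide) < MIN_PAIRED_SUBJECTS:
        raise InsufficientDataError(
            f"need >= {MIN_PAIRED_SUBJECTS} subjects with complete baseline pairs, got {len(wide)}"
        )
    pairs = list(combinations(_TP_VALUES, 2))
    raw: list[TestResult] = [
        wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy()) for a, b in pairs
    ]
    pvals = [r.p_value for r in raw]
    adj = holm_adjust(pvals) if adjust else np.asarray(pvals)
    return [
        ComparisonResult(
            method=r.method,
            statistic=r.statistic,
            p_value=float(p),
            n=r.n,
            significant=bool(p < ALPHA),
            adjusted=adjust,
            label=f"{a}_vs_{b}",
        )
        for (a, b), r, p in zip(pairs, raw, adj)
    ]


def treatment_effect(
    records, metric: Metric | str, baseline: str = "week-4"
) -> dict[str, ComparisonResult]:
    """Treatment-vs-baseline comparisons.

    Per timepoint: paired Wilcoxon of subject means at week 4 against the
    baseline reference (``week-4`` = week -4, ``week-1`` = week -1, or
    ``pooled`` = all baseline weeks). Plus a paired test of subject-mean
    delta fluctuation, treatment period vs baseline period.
    """
    df = _metric_frame(records, metric)
    base_week = {"week-4": -4, "week-1": -1}.get(baseline)
    if baseline != "pooled" and base_week is None:
        raise ValueError(f"baseline must be 'week-4', 'week-1' or 'pooled', got {baseline!r}")
    base_df = df[df["week_index"] < 0] if baseline == "pooled" else df[df["week_index"] == base_week]
    treat_df = df[df["week_index"] == 4]

    out: dict[str, ComparisonResult] = {}
    for tp in _TP_VALUES:
        b = base_df[base_df["timepoint"] == tp].groupby("subject_id")["value_au"].mean()
        t = treat_df[treat_df["timepoint"] == tp].groupby("subject_id")["value_au"].mean()
        common = b.index.intersection(t.index)
        if len(common) < MIN_PAIRED_SUBJECTS:
            raise InsufficientDataError(
                f"timepoint {tp}: need >= {MIN_PAIRED_SUBJECTS} paired subjects, got {len(common)}"
            )
        res = wilcoxon_signed_rank(t.loc[common].to_numpy(), b.loc[common].to_numpy())
        out[tp] = ComparisonResult(
            method=res.method,
            statistic=res.statistic,
            p_value=res.p_value,
            n=res.n,
            significant=res.p_value < ALPHA,
            adjusted=False,
            label=f"{tp}_week4_vs_{baseline}",
        )

    deltas = delta_fluctuation_table(records, metric)
    dsub = deltas.pivot_table(index="subject_id", columns="period", values="delta", aggfunc="mean")
    dsub = dsub.reindex(columns=["baseline", "treatment"]).dropna()
    if len(dsub) < MIN_PAIRED_SUBJECTS:
        raise InsufficientDataError(
            f"delta fluctuation: need >= {MIN_PAIRED_SUBJECTS} paired subjects, got {len(dsub)}"
        )
    res = wilcoxon_signed_rank(dsub["treatment"].to_numpy(), dsub["baseline"].to_numpy())
    out["delta_fluctuation"] = ComparisonResult(
        method=res.method,
        statistic=res.statistic,
        p_value=res.p_value,
        n=res.n,
        significant=res.p_value < ALPHA,
        adjusted=False,
        label="delta_fluctuation_treatment_vs_baseline",
    )
    return out


def compare_studies(records_a, records_b, metric: Metric | str) -> ComparisonResult:
    """Welch's t-test on subject baseline means of two independent cohorts."""
    means = []
    for records in (records_a, records_b):
        df = _metric_frame(records, metric)
        df = df[df["week_index"] < 0]
        m = df.groupby("subject_id")["value_au"].mean()
        if len(m) < MIN_GROUP_SUBJECTS:
            raise InsufficientDataError(
                f"need >= {MIN_GROUP_SUBJECTS} subjects per group, got {len(m)}"
            )
        means.append(m.to_numpy())
    res = welch_t(means[0], means[1])
    return ComparisonResult(
        method=res.method,
        statistic=res.statistic,
        p_value=res.p_value,
        n=res.n,
        significant=res.p_value < ALPHA,
        adjusted=False,
        label="study_a_vs_study_b_baseline",
    )


def plot_weekly(means: pd.DataFrame, metric, path) -> None:
    """Weekly-average fluctuation plot: one line per timepoint over weeks."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    weeks = means.index.to_numpy()
    for tp in means.columns:
        ax.plot(weeks, means[tp].to_numpy(), marker="o", label=tp)
    ax.axvline(0, color="gray", linestyle="--", linewidth=1)
    ax.set_xlabel("week index (baseline < 0 < treatment)")
    ax.set_ylabel(f"{Metric(metric).value} (au)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def comparisons_to_frame(results: Sequence[ComparisonResult] | dict[str, ComparisonResult]) -> pd.DataFrame:
    if isinstance(results, dict):
        results = list(results.values())
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "method": r.method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n": r.n,
                "significant": r.significant,
                "adjusted": r.adjusted,
            }
            for r in results
        ]
    )
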