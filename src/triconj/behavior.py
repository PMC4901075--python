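"""Across-task ANOVA and Tukey post-hoc comparisons of behavioural measures.

The primary ANOVA treats task cells as independent groups, matching the
reported between-cells (2, 57) degrees-of-freedom layout for 20 subjects and
three tasks; a within-subject (repeated-measures) variant is available via
``repeated=True``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "anova_tasks", "tukey_posthoc"]

MEASURES = ("accuracy", "mean_rt")


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_error: int
    p: float


def _groups(table: pd.DataFrame, measure: str) -> list[np.ndarray]:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    tasks = sorted(table["task"].unique())
    if len(tasks) < 2:
        raise ValueError("need >= 2 tasks")
    groups = []
    for task in tasks:
        vals = table.loc[table["task"] == task, measure].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"need >= 2 subjects per task, task {task!r} has {len(vals)}")
        groups.append(vals)
    return groups


def anova_tasks(
    table: pd.DataFrame, measure: str, repeated: bool = False
) -> AnovaResult:
    """One-way ANOVA of a behavioural measure across tasks.

    With ``repeated=False`` (default) tasks are independent cells with
    df = (k - 1, N - k); with ``repeated=True`` the subject effect is removed
    and df = (k - 1, (k - 1)(n - 1)).
    """
    groups = _groups(table, measure)
    k = len(groups)
    if not repeated:
        F, p = stats.f_oneway(*groups)
        n_total = sum(len(g) for g in groups)
        return AnovaResult(
            F=float(F), df_between=k - 1, df_error=n_total - k, p=float(p)
        )
    wide = table.pivot_table(index="subject", columns="task", values=measure)
    if wide.isna().any().any():
        raise ValueError("repeated-measures ANOVA needs every task for every subject")
    data = wide.to_numpy(dtype=float)
    n = data.shape[0]
    grand = data.mean()
    ss_tasks = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_tasks - ss_subj
    df_b = k - 1
    df_e = (k - 1) * (n - 1)
    ms_err = ss_err / df_e
    F = np.inf if ms_err <= 0 else (ss_tasks / df_b) / ms_err
    return AnovaResult(
        F=float(F), df_between=df_b, df_error=df_e, p=float(stats.f.sf(F, df_b, df_e))
    )


def tukey_posthoc(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Studentized-range pairwise comparisons for the task groups."""
    groups = _groups(table, measure)
    tasks = sorted(table["task"].unique())
    res = stats.tukey_hsd(*groups)
    rows = []
    for i in range(len(tasks)):
        for j in range(i + 1, len(tasks)):
            rows.append(
                (
                    tasks[i],
                    tasks[j],
                    float(np.mean(groups[i]) - np.mean(groups[j])),
                    float(res.pvalue[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["task_a", "task_b", "mean_diff", "p_adj"])
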