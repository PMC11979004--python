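"""Data-filtering cascade applied before any statistical analysis.

General filters (shared by every downstream analysis), in order:

1. participants who discontinued the study (incomplete session range);
2. the first gameplay of each game per participant (practice effects);
3. gameplays beyond the per-task schedule totals (1-back > 96,
   2-back > 160), inadvertently started extra rounds;
4. gameplays without any response;
5. participants who gave the identical response to every trial of a
   task (the observed case: a consistent "yes" in the 1-back game),
   removed from that task entirely.

After the general stage the cascade branches: the signal-detection
branch removes extreme outliers on hit and false-alarm rates with Tukey
fences at 3 x IQR, applied to each rate separately and removing the
union; the reaction-time branch removes gameplays whose mean RT lies
outside mean +/- 3 sd of the task's gameplay-level RTs.  Every stage
logs its removal count into a :class:`FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .study_design import Schedule
from .cohort import TASKS

__all__ = [
    "FilterReport",
    "general_filter",
    "compute_rates",
    "tukey_extreme_outliers",
    "rt_outlier_filter",
    "run_filter_pipeline",
]

REQUIRED_COLUMNS = (
    "participant_id", "group", "task", "stim_session", "gameplay_index",
    "n_targets", "n_nontargets", "hits", "false_alarms", "mean_rt", "n_responses",
)


@dataclass
class FilterReport:
    """Per-stage removal accounting.

    ``stages`` is an ordered list of (name, n_removed, n_remaining).
    ``percent_removed(task)`` reports, per task, the percentage of records
    removed by stages after the general filter, relative to the post-
    general-filter record count — the way the original removal
    percentages are quoted.
    """

    n_input: int = 0
    stages: list[tuple[str, int, int]] = field(default_factory=list)
    baseline_per_task: dict[str, int] = field(default_factory=dict)
    removed_after_baseline: dict[str, int] = field(default_factory=dict)

    def log(self, name: str, n_removed: int, n_remaining: int) -> None:
        if self.stages and n_remaining > self.stages[-1][2]:
            raise ValueError("remaining count increased across stages")
        self.stages.append((name, int(n_removed), int(n_remaining)))

    def count(self, stage: str) -> int:
        for name, removed, _ in self.stages:
            if name == stage:
                return removed
        raise KeyError(f"no stage named {stage!r}")

    @property
    def n_output(self) -> int:
        return self.stages[-1][2] if self.stages else self.n_input

    def percent_removed(self, task: str) -> float:
        base = self.baseline_per_task.get(task)
        if not base:
            return 0.0
        return 100.0 * self.removed_after_baseline.get(task, 0) / base

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "stages": [
                {"stage": s, "removed": r, "remaining": n} for s, r, n in self.stages
            ],
            "percent_removed": {t: self.percent_removed(t)
                                for t in self.baseline_per_task},
        }

    def __str__(self) -> str:
        lines = [f"input records: {self.n_input}"]
        for s, r, n in self.stages:
            lines.append(f"  {s:<28s} -{r:5d}  -> {n}")
        for t, b in self.baseline_per_task.items():
            lines.append(f"  {t}: {self.percent_removed(t):.1f}% removed post-baseline")
        return "\n".join(lines)


def _check_columns(table: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"gameplay table is missing columns: {sorted(missing)}")
    unknown = set(table["task"].unique()) - set(TASKS)
    if unknown:
        raise ValueError(f"unknown task labels: {sorted(unknown)}")


def general_filter(table: pd.DataFrame, schedule: Schedule | None = None,
                   first_gameplay_scope: str = "study",
                   ) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the shared filtering stages, in their stated order.

    ``first_gameplay_scope`` controls the "initial round" stage: the
    default ``"study"`` drops the first gameplay per participant per task
    over the whole study; ``"session"`` drops the first per session.
    """
    _check_columns(table)
    sched = schedule or Schedule()
    report = FilterReport(n_input=len(table))
    t = table

    # 1. dropouts: participants whose records stop before the last session
    last = t.groupby("participant_id")["stim_session"].max()
    dropouts = set(last.index[last < sched.n_sessions])
    kept = t[~t["participant_id"].isin(dropouts)]
    report.log("dropout_participants", len(t) - len(kept), len(kept))
    t = kept

    # 2. first gameplay of each game (practice effects)
    if first_gameplay_scope == "study":
        grp = ["participant_id", "task"]
    elif first_gameplay_scope == "session":
        grp = ["participant_id", "task", "stim_session"]
    else:
        raise ValueError(f"unknown first_gameplay_scope {first_gameplay_scope!r}")
    first = t.groupby(grp)["gameplay_index"].transform("min")
    kept = t[t["gameplay_index"] != first]
    report.log("first_gameplay", len(t) - len(kept), len(kept))
    t = kept

    # 3. gameplays beyond the schedule totals
    limits = {"sm_1back": sched.total_sm, "mm_2back": sched.total_mm}
    within = t["gameplay_index"] <= t["task"].map(limits)
    kept = t[within]
    report.log("excess_gameplays", len(t) - len(kept), len(kept))
    t = kept

    # 4. no-response gameplays
    kept = t[t["n_responses"] > 0]
    report.log("no_response", len(t) - len(kept), len(kept))
    t = kept

    # 5. degenerate responders: identical response on every trial of a task
    all_yes = (t["hits"] == t["n_targets"]) & (t["false_alarms"] == t["n_nontargets"])
    all_no = (t["hits"] == 0) & (t["false_alarms"] == 0)
    degen = (all_yes | all_no).groupby([t["participant_id"], t["task"]]).transform("all")
    kept = t[~degen]
    report.log("constant_responder", len(t) - len(kept), len(kept))
    t = kept

    report.baseline_per_task = t["task"].value_counts().to_dict()
    return t.reset_index(drop=True), report


def compute_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Attach per-gameplay hit and false-alarm rates.

    hit_rate = hits / n_targets, fa_rate = false_alarms / n_nontargets.
    Records with a zero denominator are flagged ``rate_unusable`` rather
    than silently dropped.
    """
    t = table.copy()
    unusable = (t["n_targets"] <= 0) | (t["n_nontargets"] <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t["hit_rate"] = np.where(unusable, np.nan, t["hits"] / t["n_targets"])
        t["fa_rate"] = np.where(unusable, np.nan,
                                t["false_alarms"] / t["n_nontargets"])
    t["rate_unusable"] = unusable
    return t


def tukey_extreme_outliers(values, k: float = 3.0) -> np.ndarray:
    """Boolean mask of extreme outliers by Tukey fences.

    Flags values outside [Q1 - k*IQR, Q3 + k*IQR].  Quartiles use linear
    interpolation between order statistics (the convention matters: fence
    membership can change under a different quantile rule).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for Tukey fences")
    q1, q3 = np.percentile(x[~np.isnan(x)], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    return (x < lo) | (x > hi)


def rt_outlier_filter(table: pd.DataFrame, per: str = "task",
                      ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove gameplays with mean RT outside mean +/- 3 sd, per task.

    Bounds are computed once on the input (single pass) from all
    gameplay-level mean RTs of the task, pooled across groups and
    participants.  ``per="participant"`` computes bounds within each
    participant x task instead.  sd = 0 removes nothing.
    """
    if per == "task":
        grp = ["task"]
    elif per == "participant":
        grp = ["participant_id", "task"]
    else:
        raise ValueError(f"unknown grouping {per!r}")
    report = FilterReport(n_input=len(table))
    g = table.groupby(grp)["mean_rt"]
    mean, sd = g.transform("mean"), g.transform("std").fillna(0.0)
    ok = (table["mean_rt"] >= mean - 3 * sd) & (table["mean_rt"] <= mean + 3 * sd)
    kept = table[ok]
    report.log("rt_mean3sd", len(table) - len(kept), len(kept))
    return kept.reset_index(drop=True), report


def run_filter_pipeline(table: pd.DataFrame, branch: str,
                        schedule: Schedule | None = None,
                        ) -> tuple[pd.DataFrame, FilterReport]:
    """General filter followed by the branch-specific outlier stage.

    ``branch="sdt"`` adds Tukey 3xIQR fences on hit and false-alarm rates
    (masks computed per task, independently for each rate, union
    removed); ``branch="rt"`` adds the mean +/- 3 sd RT filter.  The
    returned report covers every stage and carries the per-task removal
    percentages relative to the post-general-filter baseline.
    """
    if branch not in ("sdt", "rt"):
        raise ValueError(f"unknown branch {branch!r}")
    t, report = general_filter(table, schedule)
    baseline = dict(report.baseline_per_task)

    if branch == "sdt":
        t = compute_rates(t)
        usable = t[~t["rate_unusable"]]
        report.log("unusable_rates", len(t) - len(usable), len(usable))
        t = usable
        masks = {}
        for rate in ("hit_rate", "fa_rate"):
            m = np.zeros(len(t), dtype=bool)
            for task in t["task"].unique():
                sel = (t["task"] == task).to_numpy()
                m[sel] = tukey_extreme_outliers(t.loc[sel, rate])
            masks[rate] = m
        union = masks["hit_rate"] | masks["fa_rate"]
        kept = t[~union]
        report.log("tukey_rate_outliers", int(union.sum()), len(kept))
        removed_tasks = t.loc[union, "task"]
        t = kept.reset_index(drop=True)
    else:
        g = t.groupby("task")["mean_rt"]
        mean, sd = g.transform("mean"), g.transform("std").fillna(0.0)
        ok = (t["mean_rt"] >= mean - 3 * sd) & (t["mean_rt"] <= mean + 3 * sd)
        removed_tasks = t.loc[~ok, "task"]
        kept = t[ok].reset_index(drop=True)
        report.log("rt_mean3sd", int((~ok).sum()), len(kept))
        t = kept

    report.baseline_per_task = baseline
    report.removed_after_baseline = removed_tasks.value_counts().to_dict()
    return t, report
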