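"""Intervention schedule arithmetic and baseline between-group comparisons.

The trial delivers 16 stimulation sessions. Within a session participants
play two n-back card games on a tablet: a block of five 2-back ("memory
match", MM) gameplays, six 1-back ("speed match", SM) gameplays, and a
closing block of five 2-back gameplays, all inside the 20-minute
stimulation window.  Baseline equivalence of the two arms (active vs.
sham) is assessed from printed summary statistics with two-sample t-tests
for continuous variables and a chi-squared test for the gender table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Schedule",
    "GroupSummary",
    "TestResult",
    "build_schedule",
    "two_sample_t",
    "chi_squared_2x2",
    "baseline_table",
]


@dataclass(frozen=True)
class Schedule:
    """Per-session layout of the n-back training programme.

    A session is ordered MM-block, SM-block, MM-block.  Durations are in
    seconds; the slack between summed gameplay time and ``session_duration``
    is intermission time and is not modelled further.
    """

    n_sessions: int = 16
    mm_block_size: int = 5
    mm_blocks_per_session: int = 2
    sm_per_session: int = 6
    sm_duration: float = 45.0
    mm_duration: float = 60.0
    session_duration: float = 1200.0

    def __post_init__(self) -> None:
        counts = (
            self.n_sessions,
            self.mm_block_size,
            self.mm_blocks_per_session,
            self.sm_per_session,
        )
        if any(int(c) != c or c <= 0 for c in counts):
            raise ValueError(f"schedule counts must be positive integers, got {counts}")
        if self.gameplay_time_per_session > self.session_duration:
            raise ValueError(
                "summed gameplay time "
                f"{self.gameplay_time_per_session:.0f}s exceeds session duration "
                f"{self.session_duration:.0f}s"
            )

    @property
    def mm_per_session(self) -> int:
        return self.mm_block_size * self.mm_blocks_per_session

    @property
    def total_sm(self) -> int:
        """Total 1-back gameplays over the full intervention (96 by default)."""
        return self.n_sessions * self.sm_per_session

    @property
    def total_mm(self) -> int:
        """Total 2-back gameplays over the full intervention (160 by default)."""
        return self.n_sessions * self.mm_per_session

    @property
    def gameplay_time_per_session(self) -> float:
        return self.mm_per_session * self.mm_duration + self.sm_per_session * self.sm_duration

    @property
    def intermission_time(self) -> float:
        return self.session_duration - self.gameplay_time_per_session

    def session_order(self) -> list[str]:
        """Task labels of one session in play order."""
        mm = ["mm_2back"] * self.mm_block_size
        sm = ["sm_1back"] * self.sm_per_session
        return mm + sm + mm

    def to_dict(self) -> dict:
        return {
            "n_sessions": self.n_sessions,
            "mm_block_size": self.mm_block_size,
            "mm_blocks_per_session": self.mm_blocks_per_session,
            "sm_per_session": self.sm_per_session,
            "sm_duration": self.sm_duration,
            "mm_duration": self.mm_duration,
            "session_duration": self.session_duration,
            "total_sm": self.total_sm,
            "total_mm": self.total_mm,
            "gameplay_time_per_session": self.gameplay_time_per_session,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one arm for a continuous baseline variable."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    test: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def build_schedule(n_sessions: int = 16, **layout) -> Schedule:
    """Build the intervention schedule; defaults reproduce the 96/160 totals."""
    return Schedule(n_sessions=n_sessions, **layout)


def two_sample_t(a: GroupSummary, b: GroupSummary, pooled: bool = True) -> TestResult:
    """Two-sided two-sample t-test from group summaries.

    ``pooled=True`` uses the classic pooled-variance Student test with
    df = n1 + n2 - 2; otherwise Welch's test with Satterthwaite df.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("both groups have zero sd: t statistic undefined")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled
    )
    if pooled:
        df = a.n + b.n - 2
    else:
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p_value=float(res.pvalue),
        test="pooled t" if pooled else "welch t",
    )


def chi_squared_2x2(table, continuity_correction: bool = True) -> TestResult:
    """Chi-squared test of independence on a 2x2 count table (df = 1).

    The continuity correction subtracts n/2 from \\|ad - bc\\| before
    squaring (Yates); it is on by default.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {tab.shape}")
    if (tab < 0).any():
        raise ValueError("cell counts must be non-negative")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-squared undefined")
    chi2, p, df, _ = stats.chi2_contingency(tab, correction=continuity_correction)
    return TestResult(
        statistic=float(chi2),
        df=float(df),
        p_value=float(p),
        test="chi2 (Yates)" if continuity_correction else "chi2",
    )


_CONTINUOUS_BASELINE = ("age", "education_years", "moca")


def baseline_table(cohort: pd.DataFrame, pooled: bool = True) -> dict[str, TestResult]:
    """Between-group baseline tests on a participant table.

    Continuous variables (age, education_years, moca) get two-sample
    t-tests; gender gets a continuity-corrected chi-squared on the 2x2
    group-by-gender table.  Returns one :class:`TestResult` per variable.
    """
    required = set(_CONTINUOUS_BASELINE) | {"group", "gender"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort is missing baseline columns: {sorted(missing)}")
    groups = sorted(cohort["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, got {groups}")

    out: dict[str, TestResult] = {}
    for var in _CONTINUOUS_BASELINE:
        summaries = []
        for g in groups:
            vals = cohort.loc[cohort["group"] == g, var].to_numpy(dtype=float)
            summaries.append(GroupSummary(len(vals), float(vals.mean()), float(vals.std(ddof=1))))
        try:
            out[var] = two_sample_t(*summaries, pooled=pooled)
        except ValueError:
            # identical constant values in both arms: no evidence of difference
            out[var] = TestResult(statistic=0.0, df=sum(s.n for s in summaries) - 2,
                                  p_value=1.0, test="degenerate t")
    counts = pd.crosstab(cohort["group"], cohort["gender"]).to_numpy()
    out["gender"] = chi_squared_2x2(counts, continuity_correction=True)
    return out
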