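"""Synthetic trial cohort and gameplay-level behavioral data.

The raw behavioral data of the trial this pipeline targets are not
publicly deposited, so analyses are exercised on a generator that
reproduces the data's statistical structure: two parallel arms (38
active / 39 sham, ages 55-84, MoCA around 25.4), 16 stimulation
sessions of six 1-back and ten 2-back gameplays, per-gameplay hit and
false-alarm counts driven by latent learning curves, and
gamma-distributed reaction times.

The latent model is equal-variance Gaussian signal detection: with
sensitivity d'(g) and criterion c(g) at gameplay index g,

    P(hit) = Phi(d'/2 - c),      P(false alarm) = Phi(-d'/2 - c),

so the signal-detection module's probit estimators are the exact
inverse of the generator (this is what makes round-trip and parameter
recovery tests possible).  Both d'(g) and c(g) follow quadratic
learning curves with a group main effect and a group-by-gameplay
interaction; log mean reaction time follows the same polynomial
structure plus age and MoCA covariates.

Contaminant injection adds the artefacts the filtering pipeline must
remove: dropouts, excess gameplays past the per-task schedule,
no-response gameplays, and one constant-"yes" responder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .study_design import Schedule

__all__ = [
    "CurveCoefs",
    "RTCoefs",
    "Contamination",
    "GeneratorParams",
    "generate_cohort",
    "generate_gameplays",
    "inject_contaminants",
    "TASKS",
]

TASKS = ("sm_1back", "mm_2back")


@dataclass(frozen=True)
class CurveCoefs:
    """Quadratic learning curve on the probit scale.

    latent(g) = b0 + b_g*g + b_g2*g^2 + (b_group + b_gxg*g) * [active],
    with g the 1-based gameplay index.
    """

    b0: float = 0.0
    b_g: float = 0.0
    b_g2: float = 0.0
    b_group: float = 0.0
    b_gxg: float = 0.0

    def evaluate(self, g: np.ndarray, active: np.ndarray) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        active = np.asarray(active, dtype=float)
        vals = (self.b0 + self.b_g * g + self.b_g2 * g**2
                + (self.b_group + self.b_gxg * g) * active)
        if not np.isfinite(vals).all():
            raise ValueError("non-finite latent curve value (NaN coefficient?)")
        return vals


@dataclass(frozen=True)
class RTCoefs:
    """Log-scale mean reaction-time curve (ms)."""

    g0: float = np.log(700.0)
    g_g: float = -0.01
    g_g2: float = 3.8e-05
    g_group: float = -0.05
    g_gxg: float = 2.0e-03
    g_age: float = 0.005
    g_moca: float = -0.01

    def evaluate(self, g, active, age_c, moca_c) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        vals = (self.g0 + self.g_g * g + self.g_g2 * g**2
                + (self.g_group + self.g_gxg * g) * np.asarray(active, dtype=float)
                + self.g_age * np.asarray(age_c, dtype=float)
                + self.g_moca * np.asarray(moca_c, dtype=float))
        if not np.isfinite(vals).all():
            raise ValueError("non-finite RT linear predictor (NaN coefficient?)")
        return vals


@dataclass(frozen=True)
class Contamination:
    """Artefacts injected on top of the clean generated table."""

    n_dropouts: int = 0
    dropout_after_session: int = 8
    n_excess_gameplays: int = 0
    n_no_response: int = 0
    constant_yes_responder: bool = False


# Defaults emulate the trial's observed structure: a flat 1-back (the task
# is at ceiling for healthy adults, no group effect) and a rising,
# ceiling-limited 2-back with a positive group-by-gameplay interaction.
_SM_DPRIME = CurveCoefs(b0=2.4, b_g=1.5e-04, b_g2=0.0, b_group=0.0, b_gxg=0.0)
_MM_DPRIME = CurveCoefs(b0=1.2, b_g=4.74e-03, b_g2=-1.55e-05, b_group=0.04, b_gxg=4.47e-04)
_SM_CRIT = CurveCoefs(b0=0.15, b_g=-5.0e-04, b_g2=0.0, b_group=0.0, b_gxg=0.0)
_MM_CRIT = CurveCoefs(b0=0.45, b_g=-3.88e-03, b_g2=1.81e-05, b_group=0.03, b_gxg=-8.94e-04)
_SM_RT = RTCoefs(g0=np.log(650.0), g_g=-9.9e-03, g_g2=5.6e-05, g_group=-0.06, g_gxg=3.1e-04)
_MM_RT = RTCoefs(g0=np.log(850.0), g_g=-0.01, g_g2=3.76e-05, g_group=-0.05, g_gxg=2.09e-03)


@dataclass(frozen=True)
class GeneratorParams:
    """Everything the generator needs, one seed, deterministic output."""

    n_active: int = 38
    n_sham: int = 39
    age_mean: float = 69.8
    age_sd: float = 7.2
    age_bounds: tuple[float, float] = (55.0, 85.0)
    moca_mean: float = 25.4
    moca_sd: float = 3.0
    education_mean: float = 13.3
    education_sd: float = 4.4
    female_fraction: float = 0.58
    dprime_coefs: dict = field(default_factory=lambda: {"sm_1back": _SM_DPRIME,
                                                        "mm_2back": _MM_DPRIME})
    criterion_coefs: dict = field(default_factory=lambda: {"sm_1back": _SM_CRIT,
                                                           "mm_2back": _MM_CRIT})
    rt_coefs: dict = field(default_factory=lambda: {"sm_1back": _SM_RT,
                                                    "mm_2back": _MM_RT})
    rt_shape: float = 20.0
    trials_per_gameplay: dict = field(default_factory=lambda: {"sm_1back": 30,
                                                               "mm_2back": 20})
    target_fraction: float = 0.3
    participant_sd_dprime: float = 0.25
    participant_sd_criterion: float = 0.15
    participant_sd_log_rt: float = 0.08
    contamination: Contamination = field(default_factory=Contamination)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_active <= 0 or self.n_sham <= 0:
            raise ValueError("group sizes must be positive")
        if not (0.0 < self.target_fraction < 1.0):
            raise ValueError("target_fraction must lie in (0, 1)")
        if self.rt_shape <= 0:
            raise ValueError("rt_shape must be positive")
        lo, hi = self.age_bounds
        if not lo < hi:
            raise ValueError("impossible age truncation bounds")


def generate_cohort(params: GeneratorParams | None = None) -> pd.DataFrame:
    """Draw the participant table.

    Ages are truncated-normal within ``age_bounds``; MoCA is rounded to an
    integer and clipped to the 0-30 scale.  Deterministic given
    ``params.seed``.
    """
    p = params or GeneratorParams()
    rng = np.random.default_rng(p.seed)
    n = p.n_active + p.n_sham
    lo, hi = p.age_bounds
    a, b = (lo - p.age_mean) / p.age_sd, (hi - p.age_mean) / p.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=p.age_mean, scale=p.age_sd,
                               size=n, random_state=rng)
    moca = np.clip(np.round(rng.normal(p.moca_mean, p.moca_sd, size=n)), 0, 30)
    edu = np.clip(rng.normal(p.education_mean, p.education_sd, size=n), 5, 25)
    gender = np.where(rng.random(n) < p.female_fraction, "F", "M")
    group = np.array(["active"] * p.n_active + ["sham"] * p.n_sham)
    return pd.DataFrame({
        "participant_id": [f"P{i:03d}" for i in range(1, n + 1)],
        "group": group,
        "age": np.round(ages, 1),
        "gender": gender,
        "education_years": np.round(edu, 1),
        "moca": moca.astype(int),
    })


def _open_clip(p: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    return np.clip(p, eps, 1.0 - eps)


def generate_gameplays(cohort: pd.DataFrame, schedule: Schedule | None = None,
                       params: GeneratorParams | None = None,
                       tasks: tuple[str, ...] = TASKS) -> pd.DataFrame:
    """Simulate every gameplay of every participant.

    One row per participant x task x gameplay index.  Hits and false
    alarms are binomial draws from the SDT probabilities of the latent
    curves; ``mean_rt`` averages per-response gamma draws whose mean is
    exp(linear predictor) and shape ``rt_shape``.  Per-participant normal
    intercept shifts add between-subject heterogeneity.

    Randomness is keyed per participant (seed sequence spawned from
    ``params.seed`` and the participant row), so a participant's records
    do not depend on table ordering.
    """
    p = params or GeneratorParams()
    sched = schedule or Schedule()
    age_c = cohort["age"] - cohort["age"].mean()
    moca_c = cohort["moca"] - cohort["moca"].mean()

    totals = {"sm_1back": sched.total_sm, "mm_2back": sched.total_mm}
    per_session = {"sm_1back": sched.sm_per_session, "mm_2back": sched.mm_per_session}

    frames = []
    for row_i, row in enumerate(cohort.itertuples(index=False)):
        rng = np.random.default_rng([p.seed, 7_919, row_i])
        active = 1.0 if row.group == "active" else 0.0
        for task in tasks:
            n_total = totals[task]
            g = np.arange(1, n_total + 1)
            d_lat = p.dprime_coefs[task].evaluate(g, np.full(n_total, active))
            c_lat = p.criterion_coefs[task].evaluate(g, np.full(n_total, active))
            d_lat = d_lat + rng.normal(0.0, p.participant_sd_dprime)
            c_lat = c_lat + rng.normal(0.0, p.participant_sd_criterion)
            p_hit = _open_clip(stats.norm.cdf(d_lat / 2.0 - c_lat))
            p_fa = _open_clip(stats.norm.cdf(-d_lat / 2.0 - c_lat))

            n_trials = p.trials_per_gameplay[task]
            n_targets = rng.binomial(n_trials, p.target_fraction, size=n_total)
            n_targets = np.clip(n_targets, 1, n_trials - 1)
            n_nontargets = n_trials - n_targets
            hits = rng.binomial(n_targets, p_hit)
            fas = rng.binomial(n_nontargets, p_fa)

            lp = p.rt_coefs[task].evaluate(
                g, np.full(n_total, active),
                np.full(n_total, age_c.iloc[row_i]),
                np.full(n_total, moca_c.iloc[row_i]),
            ) + rng.normal(0.0, p.participant_sd_log_rt)
            mu = np.exp(lp)
            # mean of n iid Gamma(shape k, mean mu) is Gamma(n*k, mean mu)
            k = p.rt_shape * n_trials
            mean_rt = rng.gamma(k, mu / k)

            frames.append(pd.DataFrame({
                "participant_id": row.participant_id,
                "group": row.group,
                "task": task,
                "stim_session": (g - 1) // per_session[task] + 1,
                "gameplay_index": g,
                "n_targets": n_targets,
                "n_nontargets": n_nontargets,
                "hits": hits,
                "false_alarms": fas,
                "mean_rt": mean_rt,
                "n_responses": n_trials,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out


def inject_contaminants(table: pd.DataFrame, params: GeneratorParams | None = None
                        ) -> tuple[pd.DataFrame, dict]:
    """Add the artefacts the preprocessing filters are designed to remove.

    Returns the contaminated table and a manifest describing exactly what
    was injected, for assertion in tests:

    - ``dropouts``: participants truncated after ``dropout_after_session``
      (their later records are deleted);
    - ``excess``: 1-back gameplays appended past the schedule total;
    - ``no_response``: 2-back records whose ``n_responses`` is zeroed;
    - ``constant_yes``: one participant answering "yes" on every 1-back
      trial (hits = targets, false alarms = nontargets).
    """
    p = params or GeneratorParams()
    c = p.contamination
    table = table.copy()
    rng = np.random.default_rng([p.seed, 104_729])
    pids = sorted(table["participant_id"].unique())
    manifest: dict = {"dropouts": [], "excess": 0, "no_response": 0, "constant_yes": None}

    used: set[str] = set()

    if c.n_dropouts > len(pids):
        raise ValueError("more dropouts requested than participants")
    drop = [str(x) for x in rng.choice(pids, size=c.n_dropouts, replace=False)]
    for pid in drop:
        table = table[~((table["participant_id"] == pid)
                        & (table["stim_session"] > c.dropout_after_session))]
        manifest["dropouts"].append(pid)
    used.update(drop)

    if c.n_excess_gameplays:
        sm_max = int(table.loc[table["task"] == "sm_1back", "gameplay_index"].max())
        candidates = [pid for pid in pids if pid not in used]
        pid = candidates[0]
        base = table[(table["participant_id"] == pid) & (table["task"] == "sm_1back")]
        extra = base.iloc[-1:].copy()
        rows = []
        for j in range(c.n_excess_gameplays):
            r = extra.copy()
            r["gameplay_index"] = sm_max + 1 + j
            rows.append(r)
        table = pd.concat([table] + rows, ignore_index=True)
        manifest["excess"] = c.n_excess_gameplays
        manifest["excess_participant"] = pid

    if c.n_no_response:
        # avoid first gameplays: those fall to the practice-effect filter
        # before the no-response stage could see them
        mm = table.index[(table["task"] == "mm_2back")
                         & (table["gameplay_index"] > 1)
                         & (~table["participant_id"].isin(manifest["dropouts"]))]
        if c.n_no_response > len(mm):
            raise ValueError("not enough 2-back records to blank")
        chosen = rng.choice(mm, size=c.n_no_response, replace=False)
        table.loc[chosen, "n_responses"] = 0
        table.loc[chosen, "mean_rt"] = np.nan
        table.loc[chosen, ["hits", "false_alarms"]] = 0
        manifest["no_response"] = c.n_no_response

    if c.constant_yes_responder:
        candidates = [pid for pid in pids if pid not in used
                      and pid != manifest.get("excess_participant")]
        if not candidates:
            raise ValueError("no uncontaminated participant left for constant-yes role")
        pid = candidates[-1]
        mask = (table["participant_id"] == pid) & (table["task"] == "sm_1back")
        table.loc[mask, "hits"] = table.loc[mask, "n_targets"]
        table.loc[mask, "false_alarms"] = table.loc[mask, "n_nontargets"]
        manifest["constant_yes"] = pid

    return table.reset_index(drop=True), manifest
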