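"""Session-wise post hoc contrasts: EMMs, Bonferroni, Cohen's d.

After fitting a model with stimulation session as a 16-level factor
crossed with group, the between-group effect at each session is
summarised by estimated marginal means (model predictions on a
reference grid with continuous covariates at their means), the
Bonferroni-adjusted p of the group difference (one contrast per
session, k = 16 by default), and Cohen's d with a 95% CI, classified
into the conventional size bands (very small < 0.2 <= small < 0.5 <=
moderate < 0.8 <= large; boundary values go to the larger class).

For a log-link gamma GLM the contrast is formed on the link scale and
also reported back-transformed as a response ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import FitResult

__all__ = [
    "SessionContrast",
    "emms_by_session",
    "pairwise_session_contrasts",
    "cohens_d_ci",
    "classify_effect_size",
    "session_contrast_table",
]

SIZE_BANDS = ((0.2, "very small"), (0.5, "small"), (0.8, "moderate"))


@dataclass(frozen=True)
class SessionContrast:
    stim_session: int
    emm_active: float
    emm_sham: float
    emm_diff: float
    ci_low: float
    ci_high: float
    p_unadjusted: float
    p_bonf: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    size_class: str
    ratio: float | None = None    # exp(diff) for log-link models

    def __post_init__(self) -> None:
        if self.p_bonf + 1e-12 < self.p_unadjusted:
            raise ValueError("adjusted p below unadjusted p")


def _design_row(res, data_row: pd.DataFrame) -> np.ndarray:
    """Design-matrix row for one reference-grid point via the fit's formula."""
    from patsy import dmatrix

    di = res.model.data.design_info
    return np.asarray(dmatrix(di, data_row, return_type="matrix"))[0]


def emms_by_session(fit: FitResult, data: pd.DataFrame,
                    covariates: tuple[str, ...] = ()) -> pd.DataFrame:
    """Estimated marginal means per (group, stimulation session).

    The reference grid crosses every session with every group, holding
    each named continuous covariate at its sample mean.  Cells absent
    from the data are flagged (``estimable`` False) instead of silently
    predicted.  Returns one row per grid point with the EMM, its SE, and
    the design row used (needed downstream for contrast covariances).
    For log-link fits the EMM is on the link scale; a back-transformed
    column is included.
    """
    res = fit.sm_result
    sessions = sorted(pd.unique(data["stim_session"]))
    groups = [g for g in ("sham", "active") if g in set(data["group"])]
    cov_means = {c: float(data[c].mean()) for c in covariates}

    observed = set(map(tuple, data[["group", "stim_session"]].itertuples(index=False)))
    rows = []
    for s in sessions:
        for g in groups:
            point = pd.DataFrame({"group": pd.Categorical([g], categories=groups),
                                  "stim_session": [s], **{c: [v] for c, v in cov_means.items()}})
            x = _design_row(res, point)
            est = float(x @ res.params)
            se = float(np.sqrt(x @ res.cov_params() @ x))
            rows.append({
                "stim_session": s, "group": g, "emm": est, "se": se,
                "estimable": (g, s) in observed, "_design_row": x,
            })
    out = pd.DataFrame(rows)
    out.attrs["link"] = "log" if fit.spec.family == "gamma_log" else "identity"
    out.attrs["df_resid"] = fit.df_resid
    out.attrs["cov_params"] = np.asarray(res.cov_params())
    out.attrs["params"] = np.asarray(res.params)
    if out.attrs["link"] == "log":
        out["emm_response"] = np.exp(out["emm"])
    return out


def cohens_d_ci(d: float, n1: int, n2: int) -> tuple[float, float]:
    """Normal-approximation 95% CI for a two-sample Cohen's d."""
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(d - 1.96 * se), float(d + 1.96 * se)


def classify_effect_size(d: float) -> str:
    """Map |d| through the conventional size bands.

    Boundary values join the larger class: 0.2 is small, 0.5 moderate,
    0.8 large.
    """
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    a = abs(d)
    for cut, label in SIZE_BANDS:
        if a < cut:
            return label
    return "large"


def pairwise_session_contrasts(emms: pd.DataFrame, fit: FitResult,
                               data: pd.DataFrame, k: int | None = None,
                               sd_basis: str = "residual",
                               ) -> list[SessionContrast]:
    """Active-minus-sham contrast at every stimulation session.

    The difference and its SE come from the fit's coefficient
    covariance; the CI and p use the t distribution on the residual df;
    Bonferroni multiplies by ``k`` (default: number of sessions, the
    multiplicity family of session-wise testing) and caps at 1.

    Cohen's d divides the difference by ``sd_basis``: the model residual
    standard deviation (default) or the observed pooled per-session SD
    of the response (``"pooled"``).  Counts per group per session come
    from the analysis data.
    """
    res = fit.sm_result
    sessions = sorted(emms["stim_session"].unique())
    if k is None:
        k = len(sessions)
    missing = emms.loc[~emms["estimable"], ["group", "stim_session"]]
    if len(missing):
        raise ValueError(f"empty design cells, contrast undefined: {missing.to_dict('records')}")

    if fit.spec.family == "gaussian_identity":
        resid_sd = float(np.sqrt(res.scale))
    else:
        # link-scale spread: dispersion phi relates var(y)=phi*mu^2, so on
        # the log scale sd approx sqrt(phi)
        resid_sd = float(np.sqrt(fit.dispersion))

    response = fit.spec.response
    out = []
    for s in sessions:
        sub = emms[emms["stim_session"] == s].set_index("group")
        xa, xs = sub.loc["active", "_design_row"], sub.loc["sham", "_design_row"]
        c = xa - xs
        diff = float(c @ emms.attrs["params"])
        se = float(np.sqrt(c @ emms.attrs["cov_params"] @ c))
        df = emms.attrs["df_resid"]
        tstat = diff / se if se > 0 else np.inf * np.sign(diff)
        p = float(2 * stats.t.sf(abs(tstat), df)) if se > 0 else (1.0 if diff == 0 else 0.0)
        if se == 0 and diff == 0:
            p = 1.0
        tcrit = stats.t.ppf(0.975, df)
        p_bonf = min(1.0, k * p)

        rows_s = data[data["stim_session"] == s]
        n1 = int((rows_s["group"] == "active").sum())
        n2 = int((rows_s["group"] == "sham").sum())
        if sd_basis == "residual":
            denom = resid_sd
        elif sd_basis == "pooled":
            ya = rows_s.loc[rows_s["group"] == "active", response].to_numpy(dtype=float)
            ys = rows_s.loc[rows_s["group"] == "sham", response].to_numpy(dtype=float)
            if fit.spec.family == "gamma_log":
                ya, ys = np.log(ya), np.log(ys)
            denom = np.sqrt(((len(ya) - 1) * ya.var(ddof=1)
                             + (len(ys) - 1) * ys.var(ddof=1))
                            / (len(ya) + len(ys) - 2))
        else:
            raise ValueError(f"unknown sd_basis {sd_basis!r}")
        if denom <= 0:
            raise ValueError("zero sd basis: Cohen's d undefined")
        d_val = diff / denom
        d_lo, d_hi = cohens_d_ci(d_val, max(n1, 1), max(n2, 1))

        out.append(SessionContrast(
            stim_session=int(s),
            emm_active=float(sub.loc["active", "emm"]),
            emm_sham=float(sub.loc["sham", "emm"]),
            emm_diff=diff,
            ci_low=diff - tcrit * se,
            ci_high=diff + tcrit * se,
            p_unadjusted=p,
            p_bonf=p_bonf,
            cohens_d=float(d_val),
            d_ci_low=d_lo,
            d_ci_high=d_hi,
            size_class=classify_effect_size(d_val),
            ratio=float(np.exp(diff)) if fit.spec.family == "gamma_log" else None,
        ))
    return out


def session_contrast_table(contrasts: list[SessionContrast]) -> pd.DataFrame:
    """Flatten a contrast list to a tidy DataFrame (one row per session)."""
    return pd.DataFrame([{
        "stim_session": c.stim_session,
        "emm_active": c.emm_active,
        "emm_sham": c.emm_sham,
        "emm_diff": c.emm_diff,
        "ci_low": c.ci_low,
        "ci_high": c.ci_high,
        "p_unadjusted": c.p_unadjusted,
        "p_bonf": c.p_bonf,
        "cohens_d": c.cohens_d,
        "d_ci_low": c.d_ci_low,
        "d_ci_high": c.d_ci_high,
        "size_class": c.size_class,
        "ratio": c.ratio,
    } for c in contrasts])
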