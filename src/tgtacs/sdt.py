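"""Equal-variance Gaussian signal-detection measures.

The sensitivity index and response criterion are computed from hit and
false-alarm rates through the probit (standard-normal quantile) Z:

    d' = Z(hit rate) - Z(false-alarm rate)
    C  = -0.5 * (Z(hit rate) + Z(false-alarm rate))

Because individual gameplays frequently produce perfect hit rates or
zero false-alarm rates, rates are first averaged per group and gameplay
index and only then transformed; a residual boundary rate is pulled into
the open interval by the 1/(2N) rule before the probit is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "aggregate_group_rates",
    "clip_rates",
    "dprime",
    "criterion",
    "rates_from_sdt",
]


def clip_rates(rate, n_trials):
    """Map rates into the open interval [1/(2N), 1 - 1/(2N)].

    N is the effective trial count behind the rate (for an aggregated
    rate, trials per gameplay times contributing participants).  Interior
    rates are untouched.
    """
    n = np.asarray(n_trials, dtype=float)
    if (n < 1).any() if n.ndim else n < 1:
        raise ValueError("n_trials must be >= 1")
    lo = 1.0 / (2.0 * n)
    return np.clip(np.asarray(rate, dtype=float), lo, 1.0 - lo)


def _probit_checked(rate, name: str):
    r = np.asarray(rate, dtype=float)
    if ((r <= 0) | (r >= 1)).any():
        raise ValueError(
            f"{name} at the 0/1 boundary; apply clip_rates before the probit"
        )
    return stats.norm.ppf(r)


def dprime(hit_rate, fa_rate):
    """Sensitivity d' = Z(hit) - Z(fa); rates must lie strictly in (0, 1)."""
    return _probit_checked(hit_rate, "hit rate") - _probit_checked(fa_rate, "false-alarm rate")


def criterion(hit_rate, fa_rate):
    """Response criterion C = -0.5 (Z(hit) + Z(fa)); negative = liberal."""
    return -0.5 * (_probit_checked(hit_rate, "hit rate")
                   + _probit_checked(fa_rate, "false-alarm rate"))


def rates_from_sdt(d: float, c: float) -> tuple[float, float]:
    """Forward SDT map: latent (d', c) to (hit, false-alarm) probabilities.

    Exact inverse of (:func:`dprime`, :func:`criterion`); used by the
    data generator and by round-trip tests.
    """
    return float(stats.norm.cdf(d / 2.0 - c)), float(stats.norm.cdf(-d / 2.0 - c))


def aggregate_group_rates(table: pd.DataFrame, clip: bool = True) -> pd.DataFrame:
    """Group-mean rates per gameplay, with d' and C.

    Expects an sdt-branch filtered table carrying ``hit_rate`` and
    ``fa_rate`` columns.  For every (group, task, gameplay_index) cell the
    arithmetic means of the individual rates are taken; empty cells are
    simply absent from the output.  ``n_contributing`` counts the
    participant-gameplays entering the mean; the boundary clip uses
    N = trials-per-gameplay x n_contributing.
    """
    for col in ("hit_rate", "fa_rate"):
        if col not in table.columns:
            raise ValueError(f"missing {col}; run compute_rates first")
    t = table.assign(_total_trials=table["n_targets"] + table["n_nontargets"])
    g = t.groupby(["group", "task", "gameplay_index"], sort=True)
    out = g.agg(
        mean_hit_rate=("hit_rate", "mean"),
        mean_fa_rate=("fa_rate", "mean"),
        n_contributing=("hit_rate", "size"),
        n_trials=("_total_trials", "mean"),
        stim_session=("stim_session", "first"),
    ).reset_index()
    out["n_trials"] = out["n_trials"].round().astype(int)

    n_eff = out["n_trials"] * out["n_contributing"]
    if clip:
        hit = clip_rates(out["mean_hit_rate"], n_eff)
        fa = clip_rates(out["mean_fa_rate"], n_eff)
    else:
        hit, fa = out["mean_hit_rate"].to_numpy(), out["mean_fa_rate"].to_numpy()
    out["d_prime"] = dprime(hit, fa)
    out["criterion"] = criterion(hit, fa)
    return out
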