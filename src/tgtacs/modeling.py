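"""Linear models and gamma GLMs with AIC-guided model selection.

The behavioral endpoints are modelled the way the trial's analysis did:
sensitivity and criterion series (group means per gameplay) with
ordinary linear models, reaction times (positively skewed,
gamma-like) with gamma GLMs under a log link.  Candidate formulas cross
the gameplay index (linear and quadratic) with the treatment group and
optionally adjust for mean-centered age and baseline MoCA; candidates
are ranked by AIC, with likelihood-ratio tests reported for nested
pairs.  Reported per-term metrics follow the conventional set: beta,
SE, t, p, 95% CI, standardized beta with its CI, plus model-level
log-likelihood, AIC, and R2 (Nagelkerke's for GLMs).

Formula dialect: ``response ~ terms`` with ``+``, ``*`` (crossing),
``:`` (interaction), ``term^2`` (square of a numeric term) and
``C(factor)``.  ``gameplay^2`` is expanded to ``I(gameplay**2)`` and
handed to the patsy-backed statsmodels formula interface; treatment
coding uses sham as the reference level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "ModelSpec",
    "FitResult",
    "center_covariates",
    "fit_lm",
    "fit_gamma_glm",
    "fit_model",
    "standardized_coefficients",
    "nagelkerke_r2",
    "optimize_model",
]

_SQUARE_RE = re.compile(r"([A-Za-z_]\w*)\s*\^\s*2")


def expand_formula(formula: str) -> str:
    """Rewrite ``x^2`` as ``I(x**2)`` so patsy sees a numeric square."""
    return _SQUARE_RE.sub(r"I(\1**2)", formula)


@dataclass(frozen=True)
class ModelSpec:
    """A response, a right-hand side, and an error family."""

    formula: str
    family: str = "gaussian_identity"  # or "gamma_log"
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("gaussian_identity", "gamma_log"):
            raise ValueError(f"unknown family {self.family!r}")
        if "~" not in self.formula:
            raise ValueError("formula must contain '~'")
        rhs = self.formula.split("~", 1)[1]
        if re.search(r"\^\s*2", rhs):
            base = {m.group(1) for m in _SQUARE_RE.finditer(rhs)}
            plain = set(re.findall(r"(?<![\w*])([A-Za-z_]\w*)(?!\w)", _SQUARE_RE.sub("", rhs)))
            if not base <= plain:
                raise ValueError(
                    f"squared terms {sorted(base - plain)} appear without their linear term"
                )

    @property
    def response(self) -> str:
        return self.formula.split("~", 1)[0].strip()

    @property
    def patsy_formula(self) -> str:
        return expand_formula(self.formula)


@dataclass
class FitResult:
    """Per-term and model-level metrics of one fitted LM or GLM."""

    spec: ModelSpec
    terms: pd.DataFrame           # index: term; beta, se, stat, p, ci_low, ci_high
    loglik: float
    aic: float
    n_obs: int
    df_resid: float
    r_squared: float | None = None
    adj_r_squared: float | None = None
    nagelkerke_r_squared: float | None = None
    dispersion: float | None = None
    std_terms: pd.DataFrame | None = None
    sm_result: object = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        return len(self.terms)

    def to_dict(self) -> dict:
        d = {
            "formula": self.spec.formula,
            "family": self.spec.family,
            "loglik": self.loglik,
            "aic": self.aic,
            "n_obs": self.n_obs,
            "df_resid": self.df_resid,
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "nagelkerke_r_squared": self.nagelkerke_r_squared,
            "dispersion": self.dispersion,
            "terms": self.terms.reset_index().to_dict(orient="records"),
        }
        if self.std_terms is not None:
            d["std_terms"] = self.std_terms.reset_index().to_dict(orient="records")
        return d


def center_covariates(table: pd.DataFrame,
                      columns: tuple[str, ...] = ("age", "moca"),
                      suffix: str = "_c") -> pd.DataFrame:
    """Mean-center covariates, storing the means as DataFrame attrs.

    Adds ``<col>_c`` columns; idempotent in the sense that centering an
    already-centered column again changes nothing (its mean is zero).
    """
    t = table.copy()
    means = dict(t.attrs.get("covariate_means", {}))
    for col in columns:
        if col not in t.columns:
            raise ValueError(f"missing covariate column {col!r}")
        vals = t[col].to_numpy(dtype=float)
        if np.isnan(vals).all():
            raise ValueError(f"covariate {col!r} is entirely missing")
        m = float(np.nanmean(vals))
        t[col + suffix] = vals - m
        means[col] = m
    t.attrs["covariate_means"] = means
    return t


def _prepare(data: pd.DataFrame) -> pd.DataFrame:
    d = data.copy()
    if "group" in d.columns and not isinstance(d["group"].dtype, pd.CategoricalDtype):
        # sham as reference level so "group[T.active]" is the treatment effect
        levels = [l for l in ("sham", "active") if l in set(d["group"])]
        d["group"] = pd.Categorical(d["group"], categories=levels or None)
    return d


def _term_table(res, use_t: bool) -> pd.DataFrame:
    ci = np.asarray(res.conf_int())
    return pd.DataFrame({
        "beta": np.asarray(res.params),
        "se": np.asarray(res.bse),
        "stat": np.asarray(res.tvalues),
        "p": np.asarray(res.pvalues),
        "ci_low": ci[:, 0],
        "ci_high": ci[:, 1],
    }, index=list(res.params.index))


def fit_lm(spec: ModelSpec, data: pd.DataFrame, standardize: bool = True) -> FitResult:
    """Ordinary least squares with t-based inference."""
    if spec.family != "gaussian_identity":
        raise ValueError("fit_lm requires the gaussian_identity family")
    d = _prepare(data)
    model = smf.ols(spec.patsy_formula, data=d)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError("more terms than observations")
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(_rank_deficiency_message(model))
    res = model.fit()
    fr = FitResult(
        spec=spec,
        terms=_term_table(res, use_t=True),
        loglik=float(res.llf),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        df_resid=float(res.df_resid),
        r_squared=float(res.rsquared),
        adj_r_squared=float(res.rsquared_adj),
        sm_result=res,
    )
    if standardize:
        fr.std_terms = standardized_coefficients(fr, d)
    return fr


def fit_gamma_glm(spec: ModelSpec, data: pd.DataFrame,
                  standardize: bool = True) -> FitResult:
    """Gamma GLM with log link, fitted by IRLS.

    Dispersion is the Pearson chi-squared estimate; CIs are Wald.
    """
    if spec.family != "gamma_log":
        raise ValueError("fit_gamma_glm requires the gamma_log family")
    d = _prepare(data)
    resp = d[spec.response]
    if (resp <= 0).any():
        raise ValueError("gamma GLM requires strictly positive responses")
    model = smf.glm(spec.patsy_formula, data=d,
                    family=sm.families.Gamma(link=sm.families.links.Log()))
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(_rank_deficiency_message(model))
    res = model.fit(maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in 200 iterations for {spec.formula!r}; "
            f"deviance trace tail: {getattr(res, 'fit_history', {}).get('deviance', [])[-5:]}"
        )
    null = smf.glm(f"{spec.response} ~ 1", data=d,
                   family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    fr = FitResult(
        spec=spec,
        terms=_term_table(res, use_t=False),
        loglik=float(res.llf),
        aic=float(res.aic),
        n_obs=int(res.nobs),
        df_resid=float(res.df_resid),
        dispersion=float(res.pearson_chi2 / res.df_resid),
        sm_result=res,
    )
    fr.nagelkerke_r_squared = nagelkerke_r2(fr, _glm_null_result(null, spec))
    if standardize:
        fr.std_terms = standardized_coefficients(fr, d)
    return fr


def _glm_null_result(null_res, spec: ModelSpec) -> FitResult:
    return FitResult(
        spec=ModelSpec(f"{spec.response} ~ 1", family=spec.family),
        terms=_term_table(null_res, use_t=False),
        loglik=float(null_res.llf),
        aic=float(null_res.aic),
        n_obs=int(null_res.nobs),
        df_resid=float(null_res.df_resid),
        sm_result=null_res,
    )


def fit_model(spec: ModelSpec, data: pd.DataFrame, **kw) -> FitResult:
    """Dispatch on family."""
    if spec.family == "gaussian_identity":
        return fit_lm(spec, data, **kw)
    return fit_gamma_glm(spec, data, **kw)


def _rank_deficiency_message(model) -> str:
    X = model.exog
    names = model.exog_names
    bad = []
    # greedy scan: columns that do not increase the rank of the preceding block
    r = 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            bad.append(names[j])
        r = rj
    return f"design matrix is rank deficient; offending terms: {bad}"


def _continuous_rhs_columns(res) -> list[str]:
    """Design columns that are genuinely continuous (not intercept/contrasts)."""
    X = np.asarray(res.model.exog)
    names = res.model.exog_names
    out = []
    for j, name in enumerate(names):
        col = X[:, j]
        uniq = np.unique(col)
        if name == "Intercept" or len(uniq) <= 2:
            continue  # intercept and 0/1 contrast columns stay untouched
        out.append(name)
    return out


def standardized_coefficients(fit: FitResult, data: pd.DataFrame) -> pd.DataFrame:
    """Standardized betas by refit on scaled variables.

    Continuous design columns are divided by their sd; for LMs the
    response is also scaled to unit sd.  Factor contrast columns and the
    intercept are untouched, and for GLMs only the predictors are
    standardized (the log link already puts the response on a relative
    scale).  Returns a per-term table of std beta and its 95% CI.
    """
    res = fit.sm_result
    X = pd.DataFrame(np.asarray(res.model.exog), columns=res.model.exog_names)
    cont = _continuous_rhs_columns(res)
    sds = {c: X[c].std(ddof=1) for c in cont}
    for c, s in sds.items():
        if s == 0:
            raise ValueError(f"zero-variance predictor {c!r}")
        X[c] = X[c] / s
    y = np.asarray(res.model.endog, dtype=float)
    if fit.spec.family == "gaussian_identity":
        sy = y.std(ddof=1)
        if sy == 0:
            raise ValueError("zero-variance response")
        refit = sm.OLS(y / sy, X).fit()
    else:
        refit = sm.GLM(y, X,
                       family=sm.families.Gamma(link=sm.families.links.Log())).fit()
    ci = np.asarray(refit.conf_int())
    return pd.DataFrame({
        "std_beta": np.asarray(refit.params),
        "std_ci_low": ci[:, 0],
        "std_ci_high": ci[:, 1],
    }, index=list(res.params.index))


def nagelkerke_r2(fit: FitResult, null_fit: FitResult) -> float:
    """Max-rescaled (Nagelkerke) likelihood-ratio R-squared.

    R2_CS = 1 - exp(2 (ll0 - ll1) / n), divided by its maximum
    1 - exp(2 ll0 / n).
    """
    if null_fit.n_obs != fit.n_obs:
        raise ValueError("null fit is on a different number of observations")
    ll1, ll0, n = fit.loglik, null_fit.loglik, fit.n_obs
    if ll1 < ll0 - 1e-8:
        raise ValueError("model log-likelihood below the null's: fit worse than null")
    r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
    denom = 1.0 - np.exp(2.0 * ll0 / n)
    if denom <= 0:
        return float(np.clip(r2_cs, 0.0, 1.0))
    return float(np.clip(r2_cs / denom, 0.0, 1.0))


def _term_names(spec: ModelSpec) -> frozenset[str]:
    rhs = spec.patsy_formula.split("~", 1)[1]
    # expand a*b to a, b, a:b for nesting checks
    parts: set[str] = set()
    for piece in re.split(r"\+", rhs):
        piece = piece.strip()
        if not piece or piece == "1":
            continue
        if "*" in piece:
            subs = [s.strip() for s in piece.split("*")]
            parts.update(subs)
            parts.add(":".join(subs))
        else:
            parts.add(piece)
    return frozenset(parts)


def is_nested(a: ModelSpec, b: ModelSpec) -> bool:
    """True if a's terms are a subset of b's (same response, same family)."""
    return (a.response == b.response and a.family == b.family
            and _term_names(a) < _term_names(b))


def optimize_model(candidates: list[ModelSpec], data: pd.DataFrame,
                   ) -> tuple[ModelSpec, pd.DataFrame]:
    """Fit every candidate on the same rows and rank by AIC.

    Returns the winning spec (lowest AIC; ties broken toward fewer
    terms, then first listed) and a ledger DataFrame with AIC,
    log-likelihood, df, ΔAIC, and likelihood-ratio p-values against the
    winner for specs nested with it.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate specs")
    rows_used = None
    fits = []
    for spec in candidates:
        fit = fit_model(spec, data, standardize=False)
        if rows_used is None:
            rows_used = fit.n_obs
        elif fit.n_obs != rows_used:
            raise ValueError(
                "candidates were fitted on different row subsets; AIC incomparable"
            )
        fits.append(fit)

    order = sorted(range(len(fits)),
                   key=lambda i: (round(fits[i].aic, 10), fits[i].k_params, i))
    best_i = order[0]
    best_fit = fits[best_i]

    records = []
    for i, (spec, fit) in enumerate(zip(candidates, fits)):
        lr_p = np.nan
        small, big = None, None
        if i != best_i:
            if is_nested(spec, candidates[best_i]):
                small, big = fit, best_fit
            elif is_nested(candidates[best_i], spec):
                small, big = best_fit, fit
        if small is not None:
            lr = 2.0 * (big.loglik - small.loglik)
            df = big.k_params - small.k_params
            if df > 0:
                lr_p = float(stats.chi2.sf(max(lr, 0.0), df))
        records.append({
            "formula": spec.formula,
            "family": spec.family,
            "k": fit.k_params,
            "loglik": fit.loglik,
            "aic": fit.aic,
            "delta_aic": fit.aic - best_fit.aic,
            "lr_p_vs_best": lr_p,
            "best": i == best_i,
        })
    ledger = pd.DataFrame.from_records(records).sort_values("aic").reset_index(drop=True)
    return candidates[best_i], ledger
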