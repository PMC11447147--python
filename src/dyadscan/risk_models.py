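"""Regression stages: endophenotype linear models and the AD logistic model.

The endophenotype models are ordinary least squares fits, in the subset of
female cases with complete CSF data, of four outcomes (age of onset and the
three CSF markers) on a fixed 10-predictor set: both parental-history
indicators, the same-birthplace flag, age at lumbar puncture, education,
age of onset (when not the outcome), APOE e4 carriership, the other CSF
markers (mutual adjustment) and year of birth.  Subjects with both parents
affected are retained here with both indicators set to 1 — the univariate
both-affected exclusion applies only to the dyad tables.

The AD risk model is a logistic regression of case status on sex, age,
education, APOE e4 carriership and the same-birthplace flag, fitted by an
in-house iteratively reweighted least squares (IRLS/Newton) routine with
step halving, so that the deviance trace is available (it is guaranteed
non-increasing) and Nagelkerke's R^2 can be reported.  Because controls
have no onset, the age column uses age of onset for cases and age at
assessment for controls.

OLS is delegated to :mod:`statsmodels`; the logistic fit is deliberately
not, so it can expose its iteration diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort_io import CohortTable, same_town_vector
from .errors import (
    ConvergenceError,
    RankDeficiencyError,
    SampleSizeError,
    SeparationError,
)

_Z95 = stats.norm.ppf(0.975)

ENDO_OUTCOMES = ("age_of_onset", "csf_abeta42", "csf_ttau", "csf_ptau")

#: predictor order for the endophenotype models (outcome removed per model)
ENDO_PREDICTORS = (
    "paternal_history",
    "maternal_history",
    "same_town",
    "age_at_lp",
    "education",
    "age_of_onset",
    "apoe_e4_carrier",
    "csf_abeta42",
    "csf_ttau",
    "csf_ptau",
    "year_of_birth",
)

LOGISTIC_PREDICTORS = (
    "sex_female",
    "age",
    "education",
    "apoe_e4_carrier",
    "same_town",
)


@dataclass
class RegressionTerm:
    name: str
    estimate: float  # beta (linear) or log-odds (logistic)
    se: float
    ci95: tuple[float, float]
    p: float
    odds_ratio: float | None = None
    or_ci95: tuple[float, float] | None = None


@dataclass
class RegressionFit:
    family: str  # linear | logistic
    outcome: str
    terms: list[RegressionTerm]
    n: int
    df_resid: int
    # linear statistics
    r_squared: float | None = None
    f_statistic: float | None = None
    f_p: float | None = None
    # logistic statistics
    minus2ll: float | None = None
    null_minus2ll: float | None = None
    nagelkerke_r2: float | None = None
    n_iterations: int | None = None
    deviance_trace: list[float] = field(default_factory=list)

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        out = {
            "family": self.family,
            "outcome": self.outcome,
            "n": self.n,
            "df_resid": self.df_resid,
            "terms": [
                {
                    "name": t.name,
                    "estimate": t.estimate,
                    "se": t.se,
                    "ci95": list(t.ci95),
                    "p": t.p,
                    **(
                        {"odds_ratio": t.odds_ratio, "or_ci95": list(t.or_ci95)}
                        if t.odds_ratio is not None
                        else {}
                    ),
                }
                for t in self.terms
            ],
        }
        for name in ("r_squared", "f_statistic", "f_p", "minus2ll", "nagelkerke_r2"):
            v = getattr(self, name)
            if v is not None:
                out[name] = v
        return out


# ---------------------------------------------------------------------------
# design assembly


def _model_frame(cohort: CohortTable) -> pd.DataFrame:
    """Numeric covariate frame shared by both regression stages."""
    frame = cohort.frame
    out = pd.DataFrame(index=frame.index)
    out["case"] = (frame["status"] == "case").astype(float)
    out["sex_female"] = (frame["sex"] == "female").astype(float)
    for name in ("paternal_history", "maternal_history"):
        s = frame[name]
        out[name] = np.where(s == "yes", 1.0, np.where(s == "no", 0.0, np.nan))
    town = same_town_vector(frame)
    out["same_town"] = np.where(
        town == "same", 1.0, np.where(town == "different", 0.0, np.nan)
    )
    apoe = frame["apoe"]
    out["apoe_e4_carrier"] = apoe.map(
        lambda v: np.nan
        if v is None or (isinstance(v, float) and np.isnan(v))
        else float("e4" in v)
    )
    for name in (
        "age_at_assessment",
        "age_of_onset",
        "education",
        "year_of_birth",
        "csf_abeta42",
        "csf_ttau",
        "csf_ptau",
        "age_at_lp",
    ):
        out[name] = frame[name].astype(float)
    # Table-4-style age: onset for cases, assessment age for controls
    out["age"] = np.where(
        out["case"] == 1.0, out["age_of_onset"], out["age_at_assessment"]
    )
    return out


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    # name the offending columns: those predictable from the preceding ones
    collinear = []
    for j in range(1, X.shape[1]):
        sub = X[:, :j]
        coef, _, _, _ = np.linalg.lstsq(sub, X[:, j], rcond=None)
        resid = X[:, j] - sub @ coef
        denom = max(float(np.abs(X[:, j]).max()), 1.0)
        if float(np.abs(resid).max()) / denom < 1e-8:
            collinear.append(names[j])
    raise RankDeficiencyError(
        "design matrix is rank deficient; collinear term(s): "
        + (", ".join(collinear) if collinear else "undetermined")
    )


def _linear_fit(y: np.ndarray, X: np.ndarray, names: list[str], outcome: str) -> RegressionFit:
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = [
        RegressionTerm(
            name=names[k],
            estimate=float(res.params[k]),
            se=float(res.bse[k]),
            ci95=(float(ci[k, 0]), float(ci[k, 1])),
            p=float(res.pvalues[k]),
        )
        for k in range(len(names))
    ]
    return RegressionFit(
        family="linear",
        outcome=outcome,
        terms=terms,
        n=int(res.nobs),
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared),
        f_statistic=float(res.fvalue),
        f_p=float(res.f_pvalue),
    )


def fit_endophenotype_models(cohort: CohortTable) -> dict[str, RegressionFit]:
    """OLS fits for the four endophenotype outcomes in female cases with CSF.

    Complete-case per model; per-model n is reported in each fit.  Raises
    :class:`SampleSizeError` when a subset cannot support the predictors and
    :class:`RankDeficiencyError` (naming terms) on collinear designs.
    """
    mf = _model_frame(cohort)
    base = (
        (mf["case"] == 1.0)
        & (mf["sex_female"] == 1.0)
        & mf["csf_abeta42"].notna()
        & mf["csf_ttau"].notna()
        & mf["csf_ptau"].notna()
        & mf["age_at_lp"].notna()
    )
    fits: dict[str, RegressionFit] = {}
    for outcome in ENDO_OUTCOMES:
        predictors = [p for p in ENDO_PREDICTORS if p != outcome]
        cols = [outcome] + predictors
        sub = mf.loc[base, cols].dropna()
        n, k = len(sub), len(predictors)
        if n <= k + 1:
            raise SampleSizeError(
                f"outcome {outcome!r}: n={n} too small for {k} predictors "
                f"(need at least {k + 2} complete cases)"
            )
        names = ["intercept"] + predictors
        X = np.column_stack(
            [np.ones(n)] + [sub[p].to_numpy(dtype=float) for p in predictors]
        )
        _check_rank(X, names)
        fits[outcome] = _linear_fit(sub[outcome].to_numpy(dtype=float), X, names, outcome)
    return fits


# ---------------------------------------------------------------------------
# logistic model (in-house IRLS)


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood
    return float(-np.sum(np.logaddexp(0.0, eta)) + np.sum(y * eta))


def _irls_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    """Newton/IRLS with step halving; returns (beta, cov, deviance trace, iters)."""
    n, k = X.shape
    beta = np.zeros(k)
    pbar = min(max(y.mean(), 1e-10), 1 - 1e-10)
    beta[0] = math.log(pbar / (1 - pbar))  # assumes intercept first
    eta = X @ beta
    dev = -2.0 * _log_likelihood(y, eta)
    trace = [dev]
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        grad = X.T @ (y - mu)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        H = X.T @ (X * w[:, None])
        if np.linalg.norm(grad) < tol:
            if trace[-1] < 1e-6 or np.abs(beta).max() > 30.0:
                raise SeparationError(
                    "perfect separation: deviance vanished at convergence; "
                    "Wald statistics would be invalid"
                )
            return beta, np.linalg.inv(H), trace, it - 1
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix: {exc}") from exc
        # step halving keeps the deviance non-increasing
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_eta = X @ cand
            cand_dev = -2.0 * _log_likelihood(y, cand_eta)
            if cand_dev <= dev + 1e-12:
                break
            scale *= 0.5
        beta, eta, dev = cand, cand_eta, cand_dev
        trace.append(dev)
        if np.abs(beta).max() > 50.0:
            raise SeparationError(
                "perfect separation suspected (diverging coefficients); "
                "Wald statistics would be invalid"
            )
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def fit_ad_logistic(cohort: CohortTable) -> RegressionFit:
    """Maximum-likelihood logistic fit of case status on the demographic terms.

    Reports per-term odds ratios with Wald CIs, -2 log-likelihood and
    Nagelkerke's R^2; the deviance trace of the IRLS iterations is attached
    for diagnostics.  Perfect separation raises :class:`SeparationError`.
    """
    mf = _model_frame(cohort)
    cols = ["case"] + list(LOGISTIC_PREDICTORS)
    sub = mf.loc[:, cols].dropna()
    y = sub["case"].to_numpy(dtype=float)
    n, k = len(sub), len(LOGISTIC_PREDICTORS)
    if n <= k + 1:
        raise SampleSizeError(f"n={n} too small for {k} predictors")
    if y.min() == y.max():
        raise SampleSizeError("outcome has a single class; logistic fit undefined")
    names = ["intercept"] + list(LOGISTIC_PREDICTORS)
    X = np.column_stack(
        [np.ones(n)] + [sub[p].to_numpy(dtype=float) for p in LOGISTIC_PREDICTORS]
    )
    _check_rank(X, names)
    beta, cov, trace, iters = _irls_logistic(X, y)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    terms = []
    for j, name in enumerate(names):
        lo, hi = beta[j] - _Z95 * se[j], beta[j] + _Z95 * se[j]
        terms.append(
            RegressionTerm(
                name=name,
                estimate=float(beta[j]),
                se=float(se[j]),
                ci95=(float(lo), float(hi)),
                p=float(pvals[j]),
                odds_ratio=float(math.exp(beta[j])),
                or_ci95=(float(math.exp(lo)), float(math.exp(hi))),
            )
        )
    dev = trace[-1]
    pbar = y.mean()
    null_dev = -2.0 * (
        y.sum() * math.log(pbar) + (n - y.sum()) * math.log(1 - pbar)
    )
    r2_cs = 1.0 - math.exp((dev - null_dev) / n)
    r2_max = 1.0 - math.exp(-null_dev / n)
    nagelkerke = r2_cs / r2_max if r2_max > 0 else 0.0
    return RegressionFit(
        family="logistic",
        outcome="case",
        terms=terms,
        n=n,
        df_resid=n - len(names),
        minus2ll=float(dev),
        null_minus2ll=float(null_dev),
        nagelkerke_r2=float(nagelkerke),
        n_iterations=iters,
        deviance_trace=[float(d) for d in trace],
    )
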