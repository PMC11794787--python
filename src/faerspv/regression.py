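"""Two-stage logistic risk-factor analysis.

Stage one screens each candidate covariate (age, sex, one indicator per
ATC level-1 co-medication class) in a single-covariate logistic model;
variables with p < 0.05 enter stage two, a multivariate logistic fit.
Two outcomes are analysed: CVAE occurrence over the whole cohort, and
fatal outcome within the CVAE subgroup (with the cardiovascular
co-medication class excluded from the latter, since cardiovascular
drugs there proxy the outcome's own treatment).

The fitter is Newton/IRLS maximum likelihood with a hard iteration cap;
under separation or non-convergence the last iterate is reported and
flagged rather than raised, because sparse pharmacovigilance strata make
separation routine.  For the fatal analysis age is additionally
summarised with a two-sample t statistic alongside its logistic slope,
as both are conventional for a continuous covariate at this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mappings import ATC1_LABELS

log = logging.getLogger(__name__)

TOL = 1e-8
MAX_ITER = 100
Z95 = 1.96


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    converged: bool
    n_iter: int
    separation: bool
    loglik: float


def fit_logistic(X: np.ndarray, y: np.ndarray) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``X`` must already contain the intercept column.  Convergence when
    the largest coefficient change falls below 1e-8, capped at 100
    iterations.  Standard errors come from the inverse observed Fisher
    information at the final iterate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        info = (X * w[:, None]).T @ X
        score = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, score, rcond=None)[0]
        beta = beta + delta
        if np.max(np.abs(delta)) < TOL:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(p, np.inf)
    loglik = float(np.sum(y * np.log(mu + 1e-300) + (1 - y) * np.log(1 - mu + 1e-300)))
    separation = (not converged) or bool(np.max(np.abs(beta)) > 15) or bool(
        np.any(~np.isfinite(se)) or np.any(se > 1e3)
    )
    if separation:
        log.warning("fit_logistic: separation/non-convergence flagged (iter=%d)", it)
    return LogisticFit(beta=beta, se=se, converged=converged, n_iter=it,
                       separation=separation, loglik=loglik)


@dataclass
class RegressionResult:
    variable: str
    stage: str  # "univariate" | "multivariate"
    wald_chi2: float
    p: float
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    flags: str = ""
    t_stat: float = float("nan")  # two-sample t, filled for age when requested
    t_p: float = float("nan")


def _wald_row(variable: str, stage: str, b: float, se: float, flags: str = "") -> RegressionResult:
    wald = (b / se) ** 2 if se > 0 and np.isfinite(se) else float("nan")
    p = float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else float("nan")
    with np.errstate(over="ignore"):  # CI explodes under separation; inf is fine
        return RegressionResult(
            variable=variable,
            stage=stage,
            wald_chi2=wald,
            p=p,
            beta=b,
            se=se,
            or_=float(np.exp(b)),
            ci_low=float(np.exp(b - Z95 * se)),
            ci_high=float(np.exp(b + Z95 * se)),
            flags=flags,
        )


def build_design(
    cohort: pd.DataFrame, outcome: str = "cvae"
) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix and outcome vector from a labelled cohort.

    ``outcome="cvae"`` models CVAE occurrence over the whole cohort;
    ``outcome="fatal_within_cvae"`` models death among CVAE reports and
    drops the cardiovascular co-medication class (``atc_C``).  Rows with
    missing age or sex are excluded listwise.  A constant outcome
    raises, as no fit is meaningful.
    """
    df = cohort
    if outcome == "cvae":
        y_col = "is_cvae"
    elif outcome == "fatal_within_cvae":
        df = df[df["is_cvae"]]
        y_col = "is_fatal"
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    atc_cols = [c for c in df.columns if c.startswith("atc_")]
    if outcome == "fatal_within_cvae":
        atc_cols = [c for c in atc_cols if c != "atc_C"]

    design = pd.DataFrame(index=df.index)
    design["age"] = df["age_years"].astype(float)
    design["sex"] = df["sex"].map({"M": 1.0, "F": 0.0})
    for c in atc_cols:
        label = ATC1_LABELS.get(c.removeprefix("atc_"), c)
        design[label] = df[c].astype(float)
    y = df[y_col].astype(float).to_numpy()

    keep = design["age"].notna() & design["sex"].notna()
    design = design[keep.to_numpy()].reset_index(drop=True)
    y = y[keep.to_numpy()]
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant; fit refused")
    return design, y


def univariate_screen(
    design: pd.DataFrame, y: np.ndarray, age_t_test: bool = False
) -> list[RegressionResult]:
    """One single-covariate logistic fit per variable.

    Constant covariates are skipped with a warning.  With
    ``age_t_test=True`` the age row also carries the two-sample
    t-statistic between outcome groups.
    """
    results = []
    for var in design.columns:
        x = design[var].to_numpy(dtype=float)
        if np.unique(x).size < 2:
            log.warning("univariate_screen: %r is constant, skipped", var)
            continue
        X = np.column_stack([np.ones_like(x), x])
        fit = fit_logistic(X, y)
        flags = "separation" if fit.separation else ""
        row = _wald_row(var, "univariate", fit.beta[1], fit.se[1], flags)
        if age_t_test and var == "age":
            t, tp = stats.ttest_ind(x[y == 1], x[y == 0], equal_var=True)
            row.t_stat, row.t_p = float(t), float(tp)
        results.append(row)
    return results


def select_significant(results: Sequence[RegressionResult], alpha: float = 0.05) -> list[str]:
    return [r.variable for r in results if np.isfinite(r.p) and r.p < alpha]


def multivariate_fit(
    design: pd.DataFrame, y: np.ndarray, selected: Sequence[str]
) -> list[RegressionResult]:
    """Joint logistic fit over the screened-in variables."""
    if not selected:
        raise ValueError("no variables selected for the multivariate stage")
    X = np.column_stack(
        [np.ones(len(design))] + [design[v].to_numpy(dtype=float) for v in selected]
    )
    fit = fit_logistic(X, y)
    flags = "separation" if fit.separation else ""
    return [
        _wald_row(var, "multivariate", fit.beta[i + 1], fit.se[i + 1], flags)
        for i, var in enumerate(selected)
    ]


def two_stage(
    design: pd.DataFrame, y: np.ndarray, age_t_test: bool = False
) -> tuple[list[RegressionResult], list[RegressionResult]]:
    """Univariate screen then multivariate fit of the selected set."""
    uni = univariate_screen(design, y, age_t_test=age_t_test)
    selected = select_significant(uni)
    multi = multivariate_fit(design, y, selected) if selected else []
    return uni, multi


def results_frame(results: Sequence[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "stage": r.stage,
                "variable": r.variable,
                "wald_chi2": r.wald_chi2,
                "p": r.p,
                "beta": r.beta,
                "se": r.se,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "flags": r.flags,
                "t_stat": r.t_stat,
                "t_p": r.t_p,
            }
            for r in results
        ]
    )
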