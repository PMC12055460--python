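"""Multiple imputation of the income covariate and Rubin's-rules pooling.

Income is a 7-level ordered category missing for roughly 7% of subjects.
Imputation assumes MAR and uses a continuation-ratio chain of binary
logistic regressions in the category order: the k-th model predicts
membership in level k among subjects at level k or above.  Each
imputation draws model parameters from their approximate posterior
(multivariate normal at the MLE), so between-imputation variance
reflects estimation uncertainty.  The abstinence outcome is a predictor;
for censored subjects it enters as an explicit "missing" level so the
full cohort stays imputable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import INCOME_LEVELS, Cohort
from .ipw import build_design

__all__ = ["ImputationSet", "MIPool", "impute_income", "pool_estimates",
           "DEFAULT_IMPUTATION_PREDICTORS"]

#: predictors of income in the imputation model: outcome plus every fully
#: observed baseline covariate except registration mode
DEFAULT_IMPUTATION_PREDICTORS = (
    "Y3", "age", "gender", "race_eth", "geography", "insurance", "products", "ttfu",
)


@dataclass
class ImputationSet:
    """m completed cohorts; only income differs between them and the input."""

    m: int
    seed: int
    cohorts: list[Cohort]
    predictors: tuple[str, ...] = DEFAULT_IMPUTATION_PREDICTORS

    def __post_init__(self) -> None:
        if self.m != len(self.cohorts):
            raise ValueError("m does not match the number of completed cohorts")
        for c in self.cohorts:
            if c.data["income"].isna().any():
                raise ValueError("completed cohort still has missing income")

    def save(self, directory) -> None:
        """Write the m completed cohorts as CSV files plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, cohort in enumerate(self.cohorts, start=1):
            cohort.to_csv(directory / f"imputation_{i:02d}.csv")
        manifest = {"m": self.m, "seed": self.seed, "predictors": list(self.predictors)}
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass(frozen=True)
class MIPool:
    """Rubin's-rules combination of m estimates (log scale for ratios)."""

    estimates: tuple[float, ...]
    variances: tuple[float, ...]
    pooled_estimate: float
    within_var: float
    between_var: float
    total_var: float
    df: float

    @property
    def m(self) -> int:
        return len(self.estimates)

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def ci95(self) -> tuple[float, float]:
        from scipy.stats import norm, t
        q = norm.ppf(0.975) if np.isinf(self.df) else t.ppf(0.975, self.df)
        return (self.pooled_estimate - q * self.se, self.pooled_estimate + q * self.se)

    def p_value(self) -> float:
        from scipy.stats import norm, t
        if self.se == 0:
            return 1.0 if self.pooled_estimate == 0 else np.finfo(float).tiny
        z = self.pooled_estimate / self.se
        sf = norm.sf(abs(z)) if np.isinf(self.df) else t.sf(abs(z), self.df)
        return float(min(max(2 * sf, np.finfo(float).tiny), 1.0))


def pool_estimates(estimates, variances) -> MIPool:
    """Combine per-imputation estimates by Rubin's rules.

    pooled = mean(estimates); W = mean(variances); B = sample variance of
    the estimates; T = W + (1 + 1/m) B; df = (m-1) (1 + W / ((1+1/m) B))^2,
    infinite when B = 0 (all estimates identical).
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.shape != var.shape:
        raise ValueError("estimates and variances differ in length")
    m = est.size
    if m < 2:
        raise ValueError("Rubin's rules need m >= 2 imputations")
    if np.any(var < 0):
        raise ValueError("variances must be nonnegative")
    qbar = float(est.mean())
    W = float(var.mean())
    # identical estimates must give exactly B = 0 (degenerate path), not
    # the rounding dust np.var leaves behind
    B = 0.0 if np.ptp(est) == 0.0 else float(est.var(ddof=1))
    T = W + (1.0 + 1.0 / m) * B
    if B > 0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
    else:
        df = np.inf
    return MIPool(estimates=tuple(est), variances=tuple(var), pooled_estimate=qbar,
                  within_var=W, between_var=B, total_var=T, df=float(df))


def _outcome_as_factor(data: pd.DataFrame) -> pd.Series:
    """Y recoded to a 3-level factor: '0', '1', 'missing' (nonresponders)."""
    y = data["Y"]
    out = pd.Series(np.where(y.isna(), "missing", y.astype("Float64").astype(str)),
                    index=data.index)
    return out.str.replace(".0", "", regex=False)


def _income_level_order(values: pd.Series) -> list[str]:
    observed = [v for v in values.dropna().unique()]
    if set(observed) <= set(INCOME_LEVELS):
        return [lv for lv in INCOME_LEVELS if lv in observed]
    return sorted(observed)


def _fit_split(y: np.ndarray, X: pd.DataFrame):
    """One continuation-ratio split: MLE and covariance, with an
    intercept-only fallback when the stratum is too small or separated."""
    try:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
        params = np.asarray(res.params, dtype=float)
        cov = np.asarray(res.cov_params(), dtype=float)
        if res.converged and np.all(np.isfinite(params)) and np.all(np.isfinite(cov)):
            return params, cov, list(X.columns)
    except Exception:
        pass
    # fallback: empirical proportion with a weakly-informative prior
    p = (y.sum() + 0.5) / (y.size + 1.0)
    alpha = float(np.log(p / (1 - p)))
    var = 1.0 / (y.size * p * (1 - p))
    params = np.zeros(X.shape[1])
    params[0] = alpha
    cov = np.zeros((X.shape[1], X.shape[1]))
    cov[0, 0] = var
    return params, cov, list(X.columns)


def _draw_params(params: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # eigendecomposition handles the degenerate (fallback) covariance
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return params + root @ rng.standard_normal(params.size)


def impute_income(cohort: Cohort, m: int = 25, seed: int = 0,
                  predictors=DEFAULT_IMPUTATION_PREDICTORS) -> ImputationSet:
    """Multiply impute missing income values.

    Returns ``m`` completed cohorts.  Observed income values are never
    altered; with no missing income the result is ``m`` identical copies.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    data = cohort.data
    miss = data["income"].isna().to_numpy()
    if not miss.any():
        return ImputationSet(m=m, seed=seed, cohorts=[cohort.copy() for _ in range(m)],
                             predictors=tuple(predictors))

    frame = data.copy()
    frame["Y3"] = _outcome_as_factor(frame)
    for name in predictors:
        if frame[name].isna().any():
            raise ValueError(f"imputation predictor {name!r} has missing values")

    levels = _income_level_order(data["income"])
    if len(levels) < 2:
        raise ValueError("income must have at least two observed categories")

    X_all = build_design(frame, predictors)
    obs_idx = np.flatnonzero(~miss)
    income_obs = data["income"].to_numpy(dtype=object)

    # fit the continuation-ratio chain once, on observed-income subjects
    splits = []
    at_or_above = np.ones(len(data), dtype=bool)
    for level in levels[:-1]:
        rows = obs_idx[at_or_above[obs_idx]]
        y = (income_obs[rows] == level).astype(float)
        if y.size == 0 or y.min() == y.max():
            # degenerate stratum: assign by the (smoothed) empirical rate
            p = (y.sum() + 0.5) / (y.size + 1.0) if y.size else 0.5
            params = np.zeros(X_all.shape[1])
            params[0] = np.log(p / (1 - p))
            cov = np.zeros((X_all.shape[1], X_all.shape[1]))
            splits.append((level, params, cov))
        else:
            params, cov, _ = _fit_split(y, X_all.iloc[rows])
            splits.append((level, params, cov))
        at_or_above &= income_obs != level

    rngs = [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(m)]
    Xv = X_all.to_numpy()
    miss_idx = np.flatnonzero(miss)

    completed: list[Cohort] = []
    for rng in rngs:
        filled = income_obs.copy()
        remaining = miss_idx.copy()
        for level, params, cov in splits:
            if remaining.size == 0:
                break
            beta = _draw_params(params, cov, rng)
            p = 1.0 / (1.0 + np.exp(-(Xv[remaining] @ beta)))
            take = rng.random(remaining.size) < p
            filled[remaining[take]] = level
            remaining = remaining[~take]
        filled[remaining] = levels[-1]
        df = data.copy()
        df["income"] = filled
        completed.append(Cohort(df))

    return ImputationSet(m=m, seed=seed, cohorts=completed, predictors=tuple(predictors))
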