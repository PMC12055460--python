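"""Inverse-probability weights for censoring (IPCW) and treatment (IPTW).

IPCW reweights survey responders to stand in for the full registered
cohort: each responder counts for 1 / Pr(C = 0 | A, Z).  IPTW balances
measured confounders across service-intensity arms: each subject counts
for the reciprocal of the probability of the intensity level actually
received, 1 / Pr(A = a | Z).  The product (IPTCW) is the analytic weight
of the marginal structural model.  Both probability models are
maximum-likelihood logistic regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import Cohort

__all__ = [
    "WeightModelSpec",
    "FittedProbabilityModel",
    "WeightSet",
    "PositivityError",
    "fit_probability_model",
    "compute_ipcw",
    "compute_iptw",
    "combine_weights",
    "stabilize",
    "truncate",
    "summarize_weights",
    "DEFAULT_CENSORING_PREDICTORS",
    "DEFAULT_TREATMENT_PREDICTORS",
]

#: censoring-model predictors: intervention group, age, race/ethnicity,
#: health insurance plan and geographic residence
DEFAULT_CENSORING_PREDICTORS = ("A", "age", "race_eth", "insurance", "geography")

#: treatment-model predictors: age, health insurance plan and income
DEFAULT_TREATMENT_PREDICTORS = ("age", "insurance", "income")

#: fitted probabilities are floored here before inversion
PROBABILITY_FLOOR = 1e-6


class PositivityError(ValueError):
    """A fitted probability reached 0 or 1 for some covariate pattern."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message: str, trace: Sequence[float] = ()):  # noqa: D107
        super().__init__(message)
        self.trace = list(trace)


@dataclass(frozen=True)
class WeightModelSpec:
    """Which probability model to fit and how to post-process the weights."""

    target: str  # "censoring" | "treatment"
    predictors: tuple[str, ...]
    stabilized: bool = False
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.target not in ("censoring", "treatment"):
            raise ValueError(f"unknown weight target {self.target!r}")
        if not self.predictors:
            raise ValueError("predictor list must be non-empty")
        if "A" in self.predictors and self.target != "censoring":
            raise ValueError("treatment A may only predict censoring")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not (0 <= lo < hi <= 100):
                raise ValueError("truncation percentiles must satisfy 0 <= lo < hi <= 100")


def build_design(data: pd.DataFrame, predictors: Sequence[str]) -> pd.DataFrame:
    """Design matrix with intercept; categorical predictors are coded as
    indicators against the most frequent level (the reference).  The
    token ``"1"`` denotes the intercept alone (for intercept-only models)."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(data))}
    for name in predictors:
        if name == "1":
            continue
        s = data[name]
        if s.isna().any():
            raise ValueError(f"predictor {name!r} has missing values")
        if pd.api.types.is_numeric_dtype(s):
            cols[name] = s.to_numpy(dtype=float)
        else:
            ref = s.value_counts().idxmax()
            for level in sorted(lv for lv in s.unique() if lv != ref):
                cols[f"{name}[{level}]"] = (s == level).to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class FittedProbabilityModel:
    """Logistic fit: coefficients plus per-subject event probabilities.

    For a censoring target the modeled event is *remaining uncensored*
    (C = 0); for a treatment target it is receiving high intensity
    (A = 1).  ``probabilities`` is aligned with the cohort rows.
    """

    spec: WeightModelSpec
    params: pd.Series
    probabilities: np.ndarray
    ids: np.ndarray
    converged: bool
    n_iter: int

    def coefficients_json(self) -> dict:
        return {"target": self.spec.target, "converged": self.converged,
                "n_iter": self.n_iter, "params": self.params.to_dict()}


def fit_probability_model(cohort: Cohort, spec: WeightModelSpec) -> FittedProbabilityModel:
    """Fit the logistic regression behind a weight model by IRLS."""
    data = cohort.data
    if spec.target == "censoring":
        y = (data["C"] == 0).to_numpy(dtype=float)  # event: responder
    else:
        y = data["A"].to_numpy(dtype=float)  # event: high intensity
    if y.min() == y.max():
        raise ValueError(f"{spec.target} model: dependent variable has a single class")

    X = build_design(data, spec.predictors)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise ConvergenceError(
            f"{spec.target} model did not converge in {len(res.fit_history['deviance'])} "
            "IRLS iterations (possible separation)",
            trace=res.fit_history["deviance"],
        )
    p = np.asarray(res.mu, dtype=float)
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        bad = int(np.argmax((p <= 0.0) | (p >= 1.0)))
        pattern = data.iloc[bad][list(spec.predictors)].to_dict() if "A" not in spec.predictors \
            else data.iloc[bad][[c for c in spec.predictors]].to_dict()
        raise PositivityError(f"fitted probability at 0/1 (separation) for pattern {pattern}")
    return FittedProbabilityModel(
        spec=spec, params=res.params, probabilities=p,
        ids=data["id"].to_numpy(), converged=bool(res.converged),
        n_iter=len(res.fit_history["deviance"]),
    )


@dataclass
class WeightSet:
    """Per-subject inverse-probability weights of one kind."""

    ids: np.ndarray
    probabilities: np.ndarray
    weights: np.ndarray
    kind: str  # "IPCW" | "IPTW" | "IPTCW"
    stabilized: bool = False
    truncated: tuple[float, float] | None = None
    n_floored: int = 0

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.probabilities) == len(self.weights)):
            raise ValueError("ids/probabilities/weights length mismatch")

    def __len__(self) -> int:
        return len(self.weights)

    def restrict(self, ids: np.ndarray) -> "WeightSet":
        """Subset to the given subject ids (order follows ``ids``)."""
        pos = pd.Series(np.arange(len(self.ids)), index=self.ids)
        try:
            idx = pos.loc[ids].to_numpy()
        except KeyError as exc:
            raise ValueError(f"weight set does not cover requested subjects: {exc}") from None
        return replace(self, ids=self.ids[idx], probabilities=self.probabilities[idx],
                       weights=self.weights[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "probability": self.probabilities, "weight": self.weights,
            "kind": self.kind, "stabilized": self.stabilized,
            "truncated": self.truncated is not None,
        })


def _floor_probabilities(p: np.ndarray) -> tuple[np.ndarray, int]:
    if np.any(p < np.finfo(float).tiny):
        raise PositivityError(
            "fitted probability at the machine floor; the weight would overflow — "
            "consider truncation or a simpler model"
        )
    n_floored = int((p < PROBABILITY_FLOOR).sum())
    return np.maximum(p, PROBABILITY_FLOOR), n_floored


def compute_ipcw(cohort: Cohort, model: FittedProbabilityModel) -> WeightSet:
    """IPCW = 1 / Pr(C = 0 | A, Z), defined for responders only."""
    if model.spec.target != "censoring":
        raise ValueError("IPCW requires a censoring-target model")
    resp = (cohort.data["C"] == 0).to_numpy()
    p, n_floored = _floor_probabilities(model.probabilities[resp])
    return WeightSet(ids=model.ids[resp], probabilities=p, weights=1.0 / p,
                     kind="IPCW", n_floored=n_floored)


def compute_iptw(cohort: Cohort, model: FittedProbabilityModel) -> WeightSet:
    """IPTW = reciprocal of the probability of the intensity actually received."""
    if model.spec.target != "treatment":
        raise ValueError("IPTW requires a treatment-target model")
    A = cohort.data["A"].to_numpy()
    e = model.probabilities
    p_received = np.where(A == 1, e, 1.0 - e)
    p_received, n_floored = _floor_probabilities(p_received)
    return WeightSet(ids=model.ids, probabilities=p_received, weights=1.0 / p_received,
                     kind="IPTW", n_floored=n_floored)


def combine_weights(a: WeightSet, b: WeightSet) -> WeightSet:
    """IPTCW: elementwise product of an IPCW set and an IPTW set.

    The IPCW set lives on responders; the IPTW set may cover the full
    cohort and is restricted to the responder subset.  Commutative.
    """
    kinds = {a.kind, b.kind}
    if kinds != {"IPCW", "IPTW"}:
        raise ValueError(f"combine_weights needs one IPCW and one IPTW set, got {kinds}")
    ipcw, iptw = (a, b) if a.kind == "IPCW" else (b, a)
    iptw = iptw.restrict(ipcw.ids)
    return WeightSet(
        ids=ipcw.ids.copy(),
        probabilities=ipcw.probabilities * iptw.probabilities,
        weights=ipcw.weights * iptw.weights,
        kind="IPTCW",
        stabilized=ipcw.stabilized or iptw.stabilized,
        n_floored=ipcw.n_floored + iptw.n_floored,
    )


def stabilize(weights: WeightSet, cohort: Cohort) -> WeightSet:
    """Multiply weights by a marginal numerator.

    IPTW numerator: the marginal share of subjects receiving the same
    intensity, Pr(A = a).  IPCW numerator: the response probability given
    treatment alone, Pr(C = 0 | A), from a saturated treatment-only
    censoring model.  Stabilized IPTW has mean ~1.
    """
    if weights.stabilized:
        raise ValueError("weight set is already stabilized")
    data = cohort.data.set_index("id")
    A = data.loc[weights.ids, "A"].to_numpy()
    if weights.kind == "IPTW":
        full_A = cohort.data["A"].to_numpy()
        p1 = full_A.mean()
        numer = np.where(A == 1, p1, 1.0 - p1)
    elif weights.kind == "IPCW":
        resp_by_arm = cohort.data.groupby("A")["C"].apply(lambda c: (c == 0).mean())
        numer = np.where(A == 1, resp_by_arm.get(1, np.nan), resp_by_arm.get(0, np.nan))
    else:
        raise ValueError("stabilize IPCW/IPTW components before combining")
    return replace(weights, weights=numer * weights.weights, stabilized=True)


def truncate(weights: WeightSet, lower_pct: float, upper_pct: float) -> WeightSet:
    """Clip weights to their empirical [lower_pct, upper_pct] percentiles.

    Percentiles use linear interpolation.  Re-truncating a set already
    clipped at the same percentiles is a no-op, making the operation
    idempotent.
    """
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("require 0 <= lower_pct < upper_pct <= 100")
    if weights.truncated == (lower_pct, upper_pct):
        return replace(weights)
    lo, hi = np.percentile(weights.weights, [lower_pct, upper_pct])
    return replace(weights, weights=np.clip(weights.weights, lo, hi),
                   truncated=(lower_pct, upper_pct))


#: percentiles reported by :func:`summarize_weights`
SUMMARY_PERCENTILES = (1, 25, 50, 75, 99)


def summarize_weights(weights: WeightSet) -> dict:
    """Distribution summary: mean, sd, extrema and selected percentiles."""
    w = np.asarray(weights.weights, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight set")
    pct = np.percentile(w, SUMMARY_PERCENTILES)
    return {
        "kind": weights.kind,
        "n": int(w.size),
        "mean": float(w.mean()),
        "sd": float(w.std(ddof=1)) if w.size > 1 else 0.0,
        "min": float(w.min()),
        "max": float(w.max()),
        **{f"p{q}": float(v) for q, v in zip(SUMMARY_PERCENTILES, pct)},
        "stabilized": weights.stabilized,
        "truncated": weights.truncated,
        "n_floored": weights.n_floored,
    }
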