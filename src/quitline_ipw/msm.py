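"""Marginal structural model: weighted modified Poisson regression.

The outcome model is a Poisson working likelihood with log link on the
binary abstinence indicator, design = intercept + treatment, so the
treatment coefficient is a log risk ratio.  Weights (IPCW, IPTW or
IPTCW) enter the estimating equations; the variance is the robust
sandwich A^-1 B A^-1 with

    A = sum_i w_i mu_i x_i x_i',     B = sum_i w_i^2 (y_i - mu_i)^2 x_i x_i',

i.e. the weighted estimating-equation (HC0) form, which corrects the
misspecified Poisson variance for a binary outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .cohort import Cohort
from .ipw import ConvergenceError, WeightSet

__all__ = [
    "MSMFit",
    "QuitRate",
    "fit_modified_poisson",
    "quit_rate",
    "estimate_all",
    "format_fit_row",
    "results_table",
    "TABLE_LABELS",
]

#: fixed labels for the four-estimator comparison, in reporting order
TABLE_LABELS = (
    "Complete case (Unadjusted)",
    "Adjusting for selection bias using IPCW",
    "Adjusting for confounding using IPTW",
    "Adjusting for both confounding and selection bias using IPTCW",
)

_ESTIMATOR_LABELS = {
    "complete_case": TABLE_LABELS[0],
    "ipcw": TABLE_LABELS[1],
    "iptw": TABLE_LABELS[2],
    "iptcw": TABLE_LABELS[3],
}


@dataclass
class MSMFit:
    """Fitted treatment effect on the risk-ratio scale."""

    log_rr: float
    robust_se: float
    rr: float
    ci95: tuple[float, float]
    p: float
    intercept: float
    robust_cov: np.ndarray
    n_used: int
    weight_kind: str  # "none" | "IPCW" | "IPTW" | "IPTCW"
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValueError("risk ratio must be positive")
        lo, hi = self.ci95
        if not (lo < self.rr < hi):
            raise ValueError("confidence interval must bracket the point estimate")
        if not (0 < self.p <= 1):
            raise ValueError("p-value out of (0, 1]")


@dataclass
class QuitRate:
    """(Weighted) proportion abstinent among responders, with a Wald CI."""

    estimate: float
    ci95: tuple[float, float]
    weight_kind: str
    n_responders: int
    n_effective: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError("quit rate must lie in [0, 1]")


def _responder_arrays(cohort: Cohort, weights: WeightSet | None):
    resp = cohort.responders()
    if resp["Y"].isna().any():
        raise ValueError("responders with missing outcome")
    y = resp["Y"].to_numpy(dtype=float)
    a = resp["A"].to_numpy(dtype=float)
    if weights is None:
        w = np.ones(len(resp))
        kind = "none"
    else:
        ws = weights.restrict(resp["id"].to_numpy())
        w = np.asarray(ws.weights, dtype=float)
        kind = weights.kind
    if np.any(w < 0):
        raise ValueError("negative weights")
    return y, a, w, kind


def fit_modified_poisson(cohort: Cohort, weights: WeightSet | None = None) -> MSMFit:
    """Fit the MSM among responders; weights may be None for complete-case.

    Raises if only one treatment arm is present, if any weight is
    negative, or if IRLS does not converge.
    """
    y, a, w, kind = _responder_arrays(cohort, weights)
    if a.min() == a.max():
        raise ValueError("both treatment arms must be present among responders")

    X = np.column_stack([np.ones_like(a), a])
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    res = model.fit(maxiter=100, tol=1e-8)
    if not res.converged:
        raise ConvergenceError("modified Poisson IRLS did not converge",
                               trace=res.fit_history["deviance"])
    mu = np.asarray(res.mu)
    A_mat = X.T @ (X * (w * mu)[:, None])
    B_mat = X.T @ (X * (w ** 2 * (y - mu) ** 2)[:, None])
    A_inv = np.linalg.inv(A_mat)
    cov = A_inv @ B_mat @ A_inv

    log_rr = float(res.params[1])
    se = float(np.sqrt(cov[1, 1]))
    z = log_rr / se if se > 0 else 0.0
    p = float(max(2.0 * norm.sf(abs(z)), np.finfo(float).tiny))
    lo, hi = np.exp(log_rr - 1.959963984540054 * se), np.exp(log_rr + 1.959963984540054 * se)
    return MSMFit(
        log_rr=log_rr, robust_se=se, rr=float(np.exp(log_rr)), ci95=(float(lo), float(hi)),
        p=min(p, 1.0), intercept=float(res.params[0]), robust_cov=cov,
        n_used=len(y), weight_kind=kind,
        iterations=len(res.fit_history["deviance"]), converged=True,
    )


def quit_rate(cohort: Cohort, weights: WeightSet | None = None) -> QuitRate:
    """Weighted quit rate sum(w*y)/sum(w) with a Kish effective-size Wald CI."""
    y, _, w, kind = _responder_arrays(cohort, weights)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    p = float((w * y).sum() / total)
    n_eff = float(total ** 2 / (w ** 2).sum())
    se = np.sqrt(max(p * (1 - p), 0.0) / n_eff)
    lo, hi = max(p - 1.959963984540054 * se, 0.0), min(p + 1.959963984540054 * se, 1.0)
    return QuitRate(estimate=p, ci95=(lo, hi), weight_kind=kind,
                    n_responders=len(y), n_effective=n_eff)


def estimate_all(cohort: Cohort, ipcw: WeightSet, iptw: WeightSet,
                 iptcw: WeightSet) -> dict[str, MSMFit]:
    """The four-estimator comparison on a shared responder subset.

    Returns fits keyed by the fixed reporting labels, in order:
    complete case, IPCW, IPTW (restricted to responders), IPTCW.
    """
    weight_sets: dict[str, WeightSet | None] = {
        "complete_case": None, "ipcw": ipcw, "iptw": iptw, "iptcw": iptcw,
    }
    out: dict[str, MSMFit] = {}
    for key, ws in weight_sets.items():
        try:
            out[_ESTIMATOR_LABELS[key]] = fit_modified_poisson(cohort, ws)
        except Exception as exc:
            raise RuntimeError(f"estimator {key!r} failed: {exc}") from exc
    return out


def _format_p(p: float) -> str:
    """SAS-style p-value: four decimals, no leading zero."""
    return f"{p:.4f}".lstrip("0") if p >= 5e-5 else "<.0001"


def format_fit_row(fit: MSMFit) -> str:
    """Render one estimator row, e.g. ``1.18 (1.04-1.34), P = .0130``."""
    lo, hi = fit.ci95
    return f"{fit.rr:.2f} ({lo:.2f}-{hi:.2f}), P = {_format_p(fit.p)}"


def results_table(fits: dict[str, MSMFit]) -> pd.DataFrame:
    """Results as a table with columns Risk ratio, 95% CI and P."""
    rows = []
    for label, fit in fits.items():
        lo, hi = fit.ci95
        rows.append({"Estimator": label, "Risk ratio": round(fit.rr, 2),
                     "95% CI": f"{lo:.2f}-{hi:.2f}", "P": _format_p(fit.p)})
    return pd.DataFrame(rows)
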