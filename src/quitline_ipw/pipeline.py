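"""End-to-end orchestration: simulate/load, impute, weight, fit, diagnose.

One configuration drives the whole analysis: a cohort is loaded from CSV
or simulated from a packaged scenario, income is multiply imputed when
missing, inverse-probability weights are estimated within each completed
data set, the four estimators (complete case, IPCW, IPTW, IPTCW) are fit
per imputation, and Rubin's rules pool the log risk ratios.  Simulated
cohorts carry their true marginal risk ratio, so the report includes
per-estimator bias.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, PotentialTruth, generate_cohort, inject_income_missingness, load_scenario
from .diagnostics import balance_table, comparison_table, response_rates
from .ipw import (
    DEFAULT_CENSORING_PREDICTORS,
    DEFAULT_TREATMENT_PREDICTORS,
    WeightModelSpec,
    combine_weights,
    compute_ipcw,
    compute_iptw,
    fit_probability_model,
    stabilize,
    summarize_weights,
    truncate,
)
from .missing_data import impute_income, pool_estimates
from .msm import TABLE_LABELS, fit_modified_poisson, quit_rate

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "model_misspec_check",
           "ESTIMATORS"]

logger = logging.getLogger("quitline_ipw")

ESTIMATORS = ("complete_case", "ipcw", "iptw", "iptcw")

_LABELS = dict(zip(ESTIMATORS, TABLE_LABELS))

#: extended covariate set for the model-misspecification sensitivity check:
#: all measured baseline covariates except registration mode and tobacco products
MISSPEC_EXTENDED_COVARIATES = (
    "age", "gender", "race_eth", "income", "insurance", "geography", "ttfu",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one analysis run."""

    scenario: str | None = None
    cohort_csv: str | None = None
    n: int | None = None
    seed: int = 0
    imputation: bool = True
    m_imputations: int = 25
    censoring_predictors: tuple[str, ...] = DEFAULT_CENSORING_PREDICTORS
    treatment_predictors: tuple[str, ...] = DEFAULT_TREATMENT_PREDICTORS
    stabilized: bool = False
    truncation: tuple[float, float] | None = None
    estimators: tuple[str, ...] = ESTIMATORS
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.cohort_csv is None):
            raise ValueError("config must name exactly one of scenario or cohort_csv")
        if not self.estimators:
            raise ValueError("at least one estimator must be requested")
        unknown = set(self.estimators) - set(ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator(s): {sorted(unknown)}")
        if self.m_imputations < 2:
            raise ValueError("m_imputations must be >= 2")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        for key in ("censoring_predictors", "treatment_predictors", "estimators"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("truncation") is not None:
            d["truncation"] = tuple(d["truncation"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario, "cohort_csv": self.cohort_csv, "n": self.n,
            "seed": self.seed, "imputation": self.imputation,
            "m_imputations": self.m_imputations,
            "censoring_predictors": list(self.censoring_predictors),
            "treatment_predictors": list(self.treatment_predictors),
            "stabilized": self.stabilized,
            "truncation": list(self.truncation) if self.truncation else None,
            "estimators": list(self.estimators), "output_dir": self.output_dir,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineReport:
    """Machine-readable results of one pipeline run."""

    config: PipelineConfig
    estimates: dict[str, dict]          # per estimator: rr, ci95, p, ...
    quit_rates: dict[str, dict]
    weight_summaries: dict[str, dict]
    diagnostics: dict[str, object] = field(default_factory=dict)
    truth: dict | None = None           # true_marginal_rr + per-estimator bias
    n_imputations_used: int = 0
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "provenance": self.provenance,
            "estimates": self.estimates,
            "quit_rates": self.quit_rates,
            "weight_summaries": self.weight_summaries,
            "truth": self.truth,
            "n_imputations_used": self.n_imputations_used,
        }

    def estimates_frame(self) -> pd.DataFrame:
        rows = []
        for key in self.config.estimators:
            e = self.estimates[key]
            lo, hi = e["ci95"]
            p = e["p"]
            rows.append({"Estimator": _LABELS[key], "Risk ratio": round(e["rr"], 2),
                         "95% CI": f"{lo:.2f}-{hi:.2f}",
                         "P": (f"{p:.4f}".lstrip("0") if p >= 5e-5 else "<.0001")})
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        df = self.estimates_frame()
        lines = ["Risk ratio of abstinence, high- vs low-intensity services", ""]
        lines.append(df.to_string(index=False))
        lines.append("")
        lines.append("Quit rates among responders:")
        for key in self.config.estimators:
            q = self.quit_rates[key]
            lo, hi = q["ci95"]
            lines.append(f"  {_LABELS[key]}: {100 * q['estimate']:.2f}% "
                         f"(95% CI {100 * lo:.2f}-{100 * hi:.2f})")
        if self.truth is not None:
            lines.append("")
            lines.append(f"True marginal RR: {self.truth['true_marginal_rr']:.4f}")
            for key in self.config.estimators:
                lines.append(f"  bias[{key}] = {self.truth['bias'][key]:+.4f}")
        return "\n".join(lines)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))
        (directory / "report.txt").write_text(self.to_text() + "\n")
        self.estimates_frame().to_csv(directory / "estimates.csv", index=False)


def _weight_sets(cohort: Cohort, config: PipelineConfig) -> dict[str, object]:
    """Estimate IPCW, IPTW and IPTCW on one (completed) cohort."""
    cens_model = fit_probability_model(
        cohort, WeightModelSpec(target="censoring", predictors=config.censoring_predictors))
    treat_model = fit_probability_model(
        cohort, WeightModelSpec(target="treatment", predictors=config.treatment_predictors))
    ipcw = compute_ipcw(cohort, cens_model)
    iptw = compute_iptw(cohort, treat_model)
    if config.stabilized:
        ipcw = stabilize(ipcw, cohort)
        iptw = stabilize(iptw, cohort)
    iptcw = combine_weights(ipcw, iptw)
    if config.truncation is not None:
        lo, hi = config.truncation
        ipcw, iptw, iptcw = (truncate(w, lo, hi) for w in (ipcw, iptw, iptcw))
    return {"ipcw": ipcw, "iptw": iptw, "iptcw": iptcw,
            "models": {"censoring": cens_model, "treatment": treat_model}}


def _fit_one(cohort: Cohort, ws: dict, estimator: str):
    weights = {"complete_case": None, "ipcw": ws["ipcw"], "iptw": ws["iptw"],
               "iptcw": ws["iptcw"]}[estimator]
    try:
        fit = fit_modified_poisson(cohort, weights)
        rate = quit_rate(cohort, weights)
    except Exception as exc:
        raise RuntimeError(f"estimator {estimator!r} failed: {exc}") from exc
    return fit, rate


def _load_or_simulate(config: PipelineConfig) -> tuple[Cohort, PotentialTruth | None]:
    if config.cohort_csv is not None:
        cohort = Cohort.from_csv(config.cohort_csv)
        logger.info("loaded cohort of %d subjects from %s", len(cohort), config.cohort_csv)
        return cohort, None
    spec = load_scenario(config.scenario, n=config.n, seed=config.seed)
    cohort, truth = generate_cohort(spec)
    cohort = inject_income_missingness(cohort, spec)
    logger.info("simulated scenario %r: n=%d, seed=%d", spec.name, spec.n, spec.seed)
    return cohort, truth


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis described by ``config``."""
    cohort, truth = _load_or_simulate(config)

    diagnostics: dict[str, object] = {
        "comparison_by_treatment": comparison_table(cohort, "treatment"),
        "comparison_by_response": comparison_table(cohort, "response"),
        "response_rates": {
            "overall": response_rates(cohort, "overall"),
            "by_treatment": response_rates(cohort, "treatment"),
        },
    }

    has_missing_income = "income" in cohort.data.columns and cohort.data["income"].isna().any()
    if has_missing_income and config.imputation:
        imp = impute_income(cohort, m=config.m_imputations, seed=config.seed)
        completed = imp.cohorts
    elif has_missing_income:
        raise ValueError("cohort has missing income but imputation is disabled")
    else:
        completed = [cohort]
    logger.info("analysis datasets: %d", len(completed))

    per_imp: dict[str, list] = {est: [] for est in config.estimators}
    rates: dict[str, list] = {est: [] for est in config.estimators}
    first_ws = None
    for completed_cohort in completed:
        ws = _weight_sets(completed_cohort, config)
        if first_ws is None:
            first_ws = ws
        for est in config.estimators:
            fit, rate = _fit_one(completed_cohort, ws, est)
            per_imp[est].append(fit)
            rates[est].append(rate)

    estimates: dict[str, dict] = {}
    quit_rates: dict[str, dict] = {}
    for est in config.estimators:
        fits = per_imp[est]
        if len(fits) == 1:
            fit = fits[0]
            estimates[est] = {
                "label": _LABELS[est], "rr": fit.rr, "log_rr": fit.log_rr,
                "se": fit.robust_se, "ci95": list(fit.ci95), "p": fit.p,
                "n_used": fit.n_used, "pooled": False,
            }
            r = rates[est][0]
            quit_rates[est] = {"estimate": r.estimate, "ci95": list(r.ci95),
                               "n_responders": r.n_responders, "pooled": False}
        else:
            pool = pool_estimates([f.log_rr for f in fits], [f.robust_se ** 2 for f in fits])
            lo, hi = pool.ci95()
            estimates[est] = {
                "label": _LABELS[est], "rr": float(np.exp(pool.pooled_estimate)),
                "log_rr": pool.pooled_estimate, "se": pool.se,
                "ci95": [float(np.exp(lo)), float(np.exp(hi))], "p": pool.p_value(),
                "n_used": fits[0].n_used, "pooled": True, "m": pool.m, "df": pool.df,
                "between_var": pool.between_var, "within_var": pool.within_var,
            }
            rpool = pool_estimates(
                [r.estimate for r in rates[est]],
                [max(r.estimate * (1 - r.estimate), 0.0) / r.n_effective for r in rates[est]],
            )
            rlo, rhi = rpool.ci95()
            quit_rates[est] = {"estimate": rpool.pooled_estimate,
                               "ci95": [max(rlo, 0.0), min(rhi, 1.0)],
                               "n_responders": rates[est][0].n_responders, "pooled": True}

    weight_summaries = {k: summarize_weights(first_ws[k]) for k in ("ipcw", "iptw", "iptcw")}
    diagnostics["balance_iptw"] = balance_table(completed[0], first_ws["iptw"])

    truth_block = None
    if truth is not None:
        true_rr = truth.true_marginal_rr
        truth_block = {"true_marginal_rr": true_rr,
                       "bias": {est: estimates[est]["rr"] - true_rr
                                for est in config.estimators}}

    report = PipelineReport(
        config=config, estimates=estimates, quit_rates=quit_rates,
        weight_summaries=weight_summaries, diagnostics=diagnostics,
        truth=truth_block, n_imputations_used=len(completed) if len(completed) > 1 else 0,
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    "version": __version__},
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


@dataclass
class MisspecCheck:
    """Side-by-side minimal vs extended-covariate pipeline runs."""

    minimal: PipelineReport
    extended: PipelineReport
    tolerance: float

    def table(self) -> pd.DataFrame:
        rows = []
        for est in self.minimal.config.estimators:
            rr_min = self.minimal.estimates[est]["rr"]
            rr_ext = self.extended.estimates[est]["rr"]
            diff = abs(rr_min - rr_ext)
            rows.append({"estimator": est, "rr_minimal": rr_min, "rr_extended": rr_ext,
                         "abs_difference": diff, "flagged": diff > self.tolerance})
        return pd.DataFrame(rows)


def model_misspec_check(config: PipelineConfig, tolerance: float = 0.01) -> MisspecCheck:
    """Sensitivity check: refit with all baseline covariates except
    registration mode and tobacco products in both weight models, and
    compare risk ratios against the minimal-set run."""
    minimal = run_pipeline(replace(config, output_dir=None))
    extended_cfg = replace(
        config, output_dir=None,
        censoring_predictors=("A",) + MISSPEC_EXTENDED_COVARIATES,
        treatment_predictors=MISSPEC_EXTENDED_COVARIATES,
    )
    extended = run_pipeline(extended_cfg)
    return MisspecCheck(minimal=minimal, extended=extended, tolerance=tolerance)
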