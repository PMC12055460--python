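"""Synthetic quitline cohorts with known potential-outcome truth.

A scenario describes baseline covariates (marginal distributions), a
logistic treatment-assignment model (confounding), a logistic censoring
model that may depend on treatment (loss to follow-up, possibly a
collider), and a log-link binary outcome model whose treatment
coefficient is a conditional log risk ratio.  Because the outcome model
is generative, every cohort carries exact per-subject counterfactual
risks and hence the true marginal risk ratio — the estimand every
weighting estimator is judged against.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "CovariateSpec",
    "ModelSpec",
    "ScenarioSpec",
    "Cohort",
    "PotentialTruth",
    "ScenarioError",
    "generate_cohort",
    "inject_income_missingness",
    "true_marginal_rr",
    "load_scenario",
    "available_scenarios",
]

#: risks from the log-link outcome model are capped at this probability
RISK_CAP = 0.95

#: scenarios where the cap binds for more than this share of subjects are rejected
MAX_CAPPED_FRACTION = 0.001

#: canonical column order for cohort CSV files
COHORT_COLUMNS = (
    "id", "age", "gender", "race_eth", "income", "insurance",
    "geography", "ttfu", "products", "regmode", "A", "C", "Y",
)

INCOME_LEVELS = (
    "lt_10k", "10k_14k", "15k_19k", "20k_24k", "25k_34k", "35k_49k", "50k_plus",
)


class ScenarioError(ValueError):
    """A scenario specification is internally inconsistent or unusable."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    Categorical covariates carry ``levels`` with matching ``probs``;
    continuous covariates are truncated normal with ``mean``, ``sd`` and
    ``(lower, upper)`` range bounds.
    """

    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] | None = None
    probs: tuple[float, ...] | None = None
    mean: float | None = None
    sd: float | None = None
    lower: float | None = None
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels or not self.probs:
                raise ScenarioError(f"categorical covariate {self.name!r} needs levels and probs")
            if len(self.levels) != len(self.probs):
                raise ScenarioError(f"{self.name!r}: levels/probs length mismatch")
            if any(p < 0 for p in self.probs):
                raise ScenarioError(f"{self.name!r}: negative probability")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ScenarioError(f"{self.name!r}: probabilities sum to {sum(self.probs)}, not 1")
        elif self.kind == "continuous":
            if self.mean is None or self.sd is None or self.lower is None or self.upper is None:
                raise ScenarioError(f"continuous covariate {self.name!r} needs mean/sd/lower/upper")
            if self.sd <= 0:
                raise ScenarioError(f"{self.name!r}: sd must be positive")
            if self.lower >= self.upper:
                raise ScenarioError(f"{self.name!r}: range bounds out of order")
        else:
            raise ScenarioError(f"{self.name!r}: unknown kind {self.kind!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CovariateSpec":
        d = dict(d)
        if d.get("kind") == "categorical":
            levels = tuple(str(x) for x in d["levels"])
            if "counts" in d:  # integer margins, e.g. straight from a published table
                counts = np.asarray(d["counts"], dtype=float)
                probs = tuple(counts / counts.sum())
            else:
                probs = tuple(float(p) for p in d["probs"])
            return cls(name=d["name"], kind="categorical", levels=levels, probs=probs)
        return cls(
            name=d["name"], kind="continuous",
            mean=float(d["mean"]), sd=float(d["sd"]),
            lower=float(d["lower"]), upper=float(d["upper"]),
        )


@dataclass(frozen=True)
class ModelSpec:
    """Intercept plus named linear terms on the link scale.

    Term syntax: ``"age"`` — a continuous covariate, entered centred at
    its specified mean; ``"insurance:Uninsured"`` — indicator for one
    level of a categorical covariate; ``"A"`` — the binary treatment
    (allowed in censoring and outcome models only).
    """

    intercept: float
    terms: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(intercept=float(d.get("intercept", 0.0)),
                   terms={str(k): float(v) for k, v in dict(d.get("terms", {})).items()})

    def validate(self, covariates: Sequence[CovariateSpec], allow_treatment: bool) -> None:
        by_name = {c.name: c for c in covariates}
        for term in self.terms:
            if term == "A":
                if not allow_treatment:
                    raise ScenarioError("treatment term 'A' not allowed in this model")
                continue
            name, _, level = term.partition(":")
            cov = by_name.get(name)
            if cov is None:
                raise ScenarioError(f"model term {term!r} references unknown covariate {name!r}")
            if level:
                if cov.kind != "categorical" or level not in cov.levels:
                    raise ScenarioError(f"model term {term!r}: no such level on {name!r}")
            elif cov.kind != "continuous":
                raise ScenarioError(f"model term {term!r}: categorical covariate needs a ':level'")

    def linear_predictor(self, data: pd.DataFrame,
                         covariates: Sequence[CovariateSpec],
                         A: np.ndarray | None = None) -> np.ndarray:
        by_name = {c.name: c for c in covariates}
        lp = np.full(len(data), self.intercept, dtype=float)
        for term, coef in self.terms.items():
            if term == "A":
                if A is None:
                    raise ValueError("model uses treatment but no A supplied")
                lp += coef * np.asarray(A, dtype=float)
                continue
            name, _, level = term.partition(":")
            if level:
                lp += coef * (data[name].to_numpy() == level)
            else:
                lp += coef * (data[name].to_numpy(dtype=float) - by_name[name].mean)
        return lp


@dataclass(frozen=True)
class ScenarioSpec:
    """Complete description of a synthetic cohort's data-generating process."""

    n: int
    seed: int
    covariates: tuple[CovariateSpec, ...]
    treatment_model: ModelSpec
    censoring_model: ModelSpec
    outcome_model: ModelSpec
    income_missing_rate: float = 0.0
    income_missing_mechanism: str = "MCAR"  # "MCAR" | "MAR"
    income_missing_model: ModelSpec | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ScenarioError("n must be >= 1")
        if not (0.0 <= self.income_missing_rate < 1.0):
            raise ScenarioError("income_missing_rate must be in [0, 1)")
        if self.income_missing_mechanism not in ("MCAR", "MAR"):
            raise ScenarioError(f"unknown missingness mechanism {self.income_missing_mechanism!r}")
        self.treatment_model.validate(self.covariates, allow_treatment=False)
        self.censoring_model.validate(self.covariates, allow_treatment=True)
        self.outcome_model.validate(self.covariates, allow_treatment=True)
        if self.income_missing_model is not None:
            self.income_missing_model.validate(self.covariates, allow_treatment=False)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioSpec":
        miss = dict(d.get("income_missing", {}))
        return cls(
            n=int(d["n"]),
            seed=int(d["seed"]),
            covariates=tuple(CovariateSpec.from_dict(c) for c in d["covariates"]),
            treatment_model=ModelSpec.from_dict(d["treatment_model"]),
            censoring_model=ModelSpec.from_dict(d["censoring_model"]),
            outcome_model=ModelSpec.from_dict(d["outcome_model"]),
            income_missing_rate=float(miss.get("rate", 0.0)),
            income_missing_mechanism=str(miss.get("mechanism", "MCAR")),
            income_missing_model=(ModelSpec.from_dict(miss["model"]) if "model" in miss else None),
            name=str(d.get("name", "custom")),
        )

    @classmethod
    def from_file(cls, path: str) -> "ScenarioSpec":
        with open(path) as fh:
            if str(path).endswith(".json"):
                return cls.from_dict(json.load(fh))
            return cls.from_dict(yaml.safe_load(fh))

    def with_overrides(self, n: int | None = None, seed: int | None = None) -> "ScenarioSpec":
        out = self
        if n is not None:
            out = replace(out, n=n)
        if seed is not None:
            out = replace(out, seed=seed)
        return out


@dataclass
class Cohort:
    """Subject-level table: id, baseline covariates, A, C and Y.

    Y is a nullable integer column, present exactly for responders
    (C = 0).  Covariate columns may contain missing values only after
    :func:`inject_income_missingness`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("id", "A", "C"):
            if col not in df.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if df["id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        for col in ("A", "C"):
            vals = set(pd.unique(df[col]))
            if not vals <= {0, 1}:
                raise ValueError(f"{col} must be binary 0/1")
        y = df["Y"]
        if (y.notna() != (df["C"] == 0)).any():
            raise ValueError("Y must be observed exactly when C == 0")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def responders(self) -> pd.DataFrame:
        return self.data[self.data["C"] == 0]

    def covariate_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("id", "A", "C", "Y")]

    def copy(self) -> "Cohort":
        return Cohort(self.data.copy())

    def to_csv(self, path) -> None:
        cols = [c for c in COHORT_COLUMNS if c in self.data.columns]
        cols += [c for c in self.data.columns if c not in cols]
        self.data[cols].to_csv(path, index=False, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "Cohort":
        df = pd.read_csv(path, dtype={"Y": "Int64"}, keep_default_na=True)
        df["A"] = df["A"].astype(int)
        df["C"] = df["C"].astype(int)
        return cls(df)


@dataclass(frozen=True)
class PotentialTruth:
    """Per-subject counterfactual risks under high (1) and low (0) intensity."""

    risk1: np.ndarray
    risk0: np.ndarray

    def __post_init__(self) -> None:
        r1, r0 = np.asarray(self.risk1), np.asarray(self.risk0)
        if r1.shape != r0.shape:
            raise ValueError("risk1/risk0 shape mismatch")
        if ((r1 < 0) | (r1 > 1) | (r0 < 0) | (r0 > 1)).any():
            raise ValueError("potential risks must lie in [0, 1]")

    @property
    def true_marginal_rr(self) -> float:
        return true_marginal_rr(self)


def true_marginal_rr(truth: PotentialTruth) -> float:
    """True marginal causal risk ratio, mean(risk1) / mean(risk0)."""
    r1, r0 = np.asarray(truth.risk1, float), np.asarray(truth.risk0, float)
    if r1.size == 0:
        raise ValueError("empty potential-outcome truth")
    m0 = r0.mean()
    if m0 <= 0:
        raise ValueError("mean counterfactual risk under low intensity is zero")
    return float(r1.mean() / m0)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named independent RNG streams so toggling one stage never perturbs another."""
    names = ("covariates", "treatment", "censoring", "outcome", "missingness")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _draw_covariates(spec: ScenarioSpec, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"id": np.arange(spec.n, dtype=int)}
    for cov in spec.covariates:
        if cov.kind == "categorical":
            cols[cov.name] = rng.choice(np.asarray(cov.levels, dtype=object),
                                        size=spec.n, p=np.asarray(cov.probs))
        else:
            a = (cov.lower - cov.mean) / cov.sd
            b = (cov.upper - cov.mean) / cov.sd
            cols[cov.name] = truncnorm.rvs(a, b, loc=cov.mean, scale=cov.sd,
                                           size=spec.n, random_state=rng)
    return pd.DataFrame(cols)


def _check_risk_cap(spec: ScenarioSpec, data: pd.DataFrame,
                    lp1: np.ndarray, lp0: np.ndarray) -> None:
    cap = np.log(RISK_CAP)
    capped = (lp1 > cap) | (lp0 > cap)
    frac = capped.mean()
    if frac <= MAX_CAPPED_FRACTION:
        return
    # name the term contributing most, on average, among capped subjects
    sub = data.loc[capped]
    worst_term, worst_val = "intercept", spec.outcome_model.intercept
    for term, coef in spec.outcome_model.terms.items():
        if term == "A":
            contrib = max(coef, 0.0)
        else:
            name, _, level = term.partition(":")
            if level:
                contrib = coef * (sub[name].to_numpy() == level).mean()
            else:
                cov = next(c for c in spec.covariates if c.name == name)
                contrib = coef * (sub[name].to_numpy(dtype=float) - cov.mean).mean()
        if contrib > worst_val:
            worst_term, worst_val = term, contrib
    raise ScenarioError(
        f"outcome risks exceed the cap of {RISK_CAP} for {frac:.2%} of subjects "
        f"(limit {MAX_CAPPED_FRACTION:.1%}); largest contribution from term "
        f"{worst_term!r} — reduce its coefficient or the intercept"
    )


def generate_cohort(spec: ScenarioSpec) -> tuple[Cohort, PotentialTruth]:
    """Simulate one cohort and its counterfactual truth.

    Treatment is drawn from the logistic treatment model, censoring from
    the logistic censoring model given realized treatment, and the
    outcome from the log-link outcome model.  Both potential outcomes
    share one uniform draw per subject (consistency: the observed Y is
    the potential outcome under the received treatment).  Y is blanked
    for censored subjects.  Identical (spec, seed) reproduce the cohort
    exactly.  Income missingness is NOT applied here — see
    :func:`inject_income_missingness`.
    """
    streams = _substreams(spec.seed)
    data = _draw_covariates(spec, streams["covariates"])

    p_treat = expit(spec.treatment_model.linear_predictor(data, spec.covariates))
    A = (streams["treatment"].random(spec.n) < p_treat).astype(int)

    p_cens = expit(spec.censoring_model.linear_predictor(data, spec.covariates, A=A))
    C = (streams["censoring"].random(spec.n) < p_cens).astype(int)

    ones, zeros = np.ones(spec.n), np.zeros(spec.n)
    lp1 = spec.outcome_model.linear_predictor(data, spec.covariates, A=ones)
    lp0 = spec.outcome_model.linear_predictor(data, spec.covariates, A=zeros)
    _check_risk_cap(spec, data, lp1, lp0)
    cap = np.log(RISK_CAP)
    risk1 = np.exp(np.minimum(lp1, cap))
    risk0 = np.exp(np.minimum(lp0, cap))

    u = streams["outcome"].random(spec.n)
    y_pot = np.where(A == 1, u < risk1, u < risk0).astype(int)
    Y = pd.array(y_pot, dtype="Int64")
    Y[C == 1] = pd.NA

    data = data.assign(A=A, C=C, Y=Y)
    return Cohort(data), PotentialTruth(risk1=risk1, risk0=risk0)


def inject_income_missingness(cohort: Cohort, spec: ScenarioSpec) -> Cohort:
    """Blank the income covariate for a target share of subjects.

    MCAR blanks uniformly at random; MAR gives each subject a logistic
    missingness probability driven by fully observed covariates, with the
    intercept calibrated so the expected missing share equals the target
    rate.  Uses its own seed substream, so the rest of the cohort is
    untouched relative to a run without missingness.
    """
    if spec.income_missing_rate >= 1.0:
        raise ScenarioError("income_missing_rate must be < 1")
    if "income" not in cohort.data.columns:
        raise ScenarioError("cohort has no income covariate")
    rate = spec.income_missing_rate
    if rate == 0.0:
        return cohort

    rng = _substreams(spec.seed)["missingness"]
    data = cohort.data.copy()
    if spec.income_missing_mechanism == "MCAR" or spec.income_missing_model is None:
        p = np.full(len(data), rate)
    else:
        shape = spec.income_missing_model.linear_predictor(data, spec.covariates)
        shape -= shape.mean()

        def mean_rate(alpha: float) -> float:
            return float(expit(alpha + shape).mean()) - rate

        alpha = brentq(mean_rate, -30.0, 30.0)
        p = expit(alpha + shape)

    miss = rng.random(len(data)) < p
    data["income"] = data["income"].astype(object)
    data.loc[miss, "income"] = np.nan
    return Cohort(data)


#: published six-category age grouping
AGE_BIN_EDGES = (18, 25, 35, 45, 55, 65, 200)
AGE_BIN_LABELS = ("18-24", "25-34", "35-44", "45-54", "55-64", "65+")


def bin_age(cohort: Cohort, column: str = "age_cat") -> Cohort:
    """Add a categorical age column using the six standard categories.

    Weight models can then use ``age_cat`` in place of the continuous
    ``age`` term.
    """
    data = cohort.data.copy()
    data[column] = pd.cut(data["age"], bins=AGE_BIN_EDGES, labels=AGE_BIN_LABELS,
                          right=False, include_lowest=True).astype(str)
    return Cohort(data)


def available_scenarios() -> list[str]:
    """Names of the scenario configuration files shipped with the package."""
    root = importlib.resources.files("quitline_ipw") / "scenarios"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name: str, n: int | None = None, seed: int | None = None) -> ScenarioSpec:
    """Load a packaged scenario by name, optionally overriding n and seed."""
    path = importlib.resources.files("quitline_ipw") / "scenarios" / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        ) from None
    return ScenarioSpec.from_dict(yaml.safe_load(text)).with_overrides(n=n, seed=seed)
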