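"""Descriptive comparisons, response rates, censoring tallies and balance.

Reproduces the descriptive machinery of a quitline evaluation: baseline
tables comparing covariates across service-intensity arms or across
responders/nonresponders (Pearson chi-square for categoricals, pooled
two-sample t test for continuous age), response-rate summaries, a tally
of censoring reasons, and covariate-balance tables with standardized
differences before and after weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, ttest_ind

from .cohort import Cohort
from .ipw import WeightSet

__all__ = [
    "ComparisonTable",
    "StructuralZeroError",
    "comparison_table",
    "response_rates",
    "censoring_reasons",
    "balance_table",
    "SMD_THRESHOLD",
]

#: conventional balance threshold on the standardized difference
SMD_THRESHOLD = 0.1

CENSORING_REASON_CATEGORIES = ("refused", "deceased", "unreachable", "other")

_Z975 = 1.959963984540054


class StructuralZeroError(ValueError):
    """A contingency table has an expected count of zero."""


@dataclass
class ComparisonTable:
    """Counts/percents per group plus one test row per covariate."""

    grouping: str
    group_labels: tuple[str, str]
    rows: pd.DataFrame    # covariate, level, count/percent per group
    tests: pd.DataFrame   # covariate, test, statistic, p

    def to_text(self) -> str:
        lines = [f"Grouping: {self.grouping} ({self.group_labels[0]} vs {self.group_labels[1]})"]
        tests = self.tests.set_index("covariate")
        for cov, sub in self.rows.groupby("covariate", sort=False):
            t = tests.loc[cov]
            lines.append(f"{cov}  [{t['test']} = {t['statistic']:.4g}, P = {t['p']:.4g}]")
            for _, r in sub.iterrows():
                cells = "  ".join(
                    f"{r[f'count_{g}']:.0f} ({r[f'percent_{g}']:.2f})" if np.isfinite(r[f'count_{g}'])
                    else f"{r[f'mean_{g}']:.2f} ± {r[f'sd_{g}']:.2f}"
                    for g in self.group_labels
                )
                lines.append(f"  {r['level']}: {cells}")
        return "\n".join(lines)


def _group_indicator(cohort: Cohort, grouping: str) -> tuple[pd.Series, tuple[str, str]]:
    if grouping == "treatment":
        g = cohort.data["A"].map({0: "low", 1: "high"})
        labels = ("low", "high")
    elif grouping == "response":
        g = cohort.data["C"].map({0: "responder", 1: "nonresponder"})
        labels = ("responder", "nonresponder")
    else:
        raise ValueError("grouping must be 'treatment' or 'response'")
    if g.nunique() < 2:
        raise ValueError(f"grouping {grouping!r} has an empty group")
    return g, labels


def pearson_chi2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on a 2 x k table."""
    table = np.asarray(table, dtype=float)
    expected = table.sum(axis=1, keepdims=True) * table.sum(axis=0, keepdims=True) / table.sum()
    if np.any(expected == 0):
        raise StructuralZeroError("contingency table has a zero expected count")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return float(stat), float(p)


def comparison_table(cohort: Cohort, grouping: str = "treatment") -> ComparisonTable:
    """Baseline characteristics by treatment arm or by response status."""
    g, labels = _group_indicator(cohort, grouping)
    data = cohort.data
    rows: list[dict] = []
    tests: list[dict] = []
    for cov in cohort.covariate_columns():
        s = data[cov]
        if pd.api.types.is_numeric_dtype(s):
            x0 = s[g == labels[0]].to_numpy(dtype=float)
            x1 = s[g == labels[1]].to_numpy(dtype=float)
            stat, p = ttest_ind(x0, x1, equal_var=True)
            tests.append({"covariate": cov, "test": "t", "statistic": float(stat), "p": float(p)})
            row = {"covariate": cov, "level": "mean ± SD"}
            for lab, x in zip(labels, (x0, x1)):
                row[f"count_{lab}"] = np.nan
                row[f"percent_{lab}"] = np.nan
                row[f"mean_{lab}"] = float(x.mean())
                row[f"sd_{lab}"] = float(x.std(ddof=1))
            rows.append(row)
        else:
            ct = pd.crosstab(s, g)
            ct = ct.reindex(columns=list(labels), fill_value=0)
            stat, p = pearson_chi2(ct.to_numpy().T)
            tests.append({"covariate": cov, "test": "chi2", "statistic": stat, "p": p})
            totals = ct.sum(axis=0)
            for level, r in ct.iterrows():
                row = {"covariate": cov, "level": level}
                for lab in labels:
                    row[f"count_{lab}"] = float(r[lab])
                    row[f"percent_{lab}"] = float(100.0 * r[lab] / totals[lab])
                    row[f"mean_{lab}"] = np.nan
                    row[f"sd_{lab}"] = np.nan
                rows.append(row)
    return ComparisonTable(grouping=grouping, group_labels=labels,
                           rows=pd.DataFrame(rows), tests=pd.DataFrame(tests))


def response_rates(cohort: Cohort, by: str = "overall") -> dict[str, dict]:
    """Follow-up response (C = 0) rates, overall or per treatment arm."""
    data = cohort.data
    if by == "overall":
        strata = {"overall": data}
    elif by == "treatment":
        strata = {"low": data[data["A"] == 0], "high": data[data["A"] == 1]}
    else:
        raise ValueError("by must be 'overall' or 'treatment'")
    out = {}
    for name, sub in strata.items():
        if len(sub) == 0:
            raise ValueError(f"empty stratum {name!r}")
        responders = int((sub["C"] == 0).sum())
        out[name] = {"responders": responders, "total": int(len(sub)),
                     "rate": responders / len(sub)}
    return out


def censoring_reasons(cohort: Cohort, reasons: Mapping) -> pd.DataFrame:
    """Tally reasons for loss to follow-up among censored subjects.

    ``reasons`` maps subject id -> one of refused | deceased |
    unreachable | other, and must cover exactly the censored subjects.
    """
    data = cohort.data
    censored_ids = set(data.loc[data["C"] == 1, "id"])
    given_ids = set(reasons.keys())
    extra = given_ids - censored_ids
    if extra:
        raise ValueError(f"censoring reason given for uncensored subject(s): {sorted(extra)[:5]}")
    missing = censored_ids - given_ids
    if missing:
        raise ValueError(f"censored subject(s) without a reason: {sorted(missing)[:5]}")
    if not censored_ids:
        return pd.DataFrame(columns=["reason", "count", "percent"])
    values = pd.Series(list(reasons.values()))
    bad = set(values.unique()) - set(CENSORING_REASON_CATEGORIES)
    if bad:
        raise ValueError(f"unknown censoring reason(s): {sorted(bad)}")
    counts = values.value_counts()
    total = counts.sum()
    rows = [{"reason": r, "count": int(counts.get(r, 0)),
             "percent": 100.0 * counts.get(r, 0) / total}
            for r in CENSORING_REASON_CATEGORIES if counts.get(r, 0) > 0]
    return pd.DataFrame(rows)


def standardized_difference(p1: float, p2: float) -> float:
    """SMD for a binary covariate level: (p1 - p2)/sqrt((p1(1-p1)+p2(1-p2))/2)."""
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        return 0.0
    return float((p1 - p2) / denom)


def _weighted_prop(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted proportion and its Kish effective sample size."""
    total = w.sum()
    p = float((w * x).sum() / total)
    n_eff = float(total ** 2 / (w ** 2).sum())
    return p, n_eff


def _ci(p: float, n: float) -> tuple[float, float]:
    se = np.sqrt(max(p * (1 - p), 0.0) / n)
    return (max(p - _Z975 * se, 0.0), min(p + _Z975 * se, 1.0))


def balance_table(cohort: Cohort, weights: WeightSet) -> pd.DataFrame:
    """Covariate balance across treatment arms before and after weighting.

    One row per categorical covariate level (and one per continuous
    covariate), with per-arm proportions/means, 95% CIs, and unweighted
    and weighted standardized differences.  Levels degenerate in both
    arms get SMD 0 and a flag.
    """
    data = cohort.data.set_index("id").loc[weights.ids].reset_index()
    A = data["A"].to_numpy()
    w = np.asarray(weights.weights, dtype=float)
    m1, m0 = A == 1, A == 0
    if not (m1.any() and m0.any()):
        raise ValueError("both arms required for balance assessment")

    rows = []
    for cov in [c for c in data.columns if c not in ("id", "A", "C", "Y")]:
        s = data[cov]
        if pd.api.types.is_numeric_dtype(s):
            x = s.to_numpy(dtype=float)
            mu1, mu0 = x[m1].mean(), x[m0].mean()
            v1, v0 = x[m1].var(ddof=1), x[m0].var(ddof=1)
            smd_u = (mu1 - mu0) / np.sqrt((v1 + v0) / 2.0) if (v1 + v0) > 0 else 0.0
            wm1 = (w[m1] * x[m1]).sum() / w[m1].sum()
            wm0 = (w[m0] * x[m0]).sum() / w[m0].sum()
            wv1 = (w[m1] * (x[m1] - wm1) ** 2).sum() / w[m1].sum()
            wv0 = (w[m0] * (x[m0] - wm0) ** 2).sum() / w[m0].sum()
            smd_w = (wm1 - wm0) / np.sqrt((wv1 + wv0) / 2.0) if (wv1 + wv0) > 0 else 0.0
            rows.append({
                "covariate": cov, "level": "(continuous)",
                "unweighted_1": mu1, "unweighted_0": mu0,
                "weighted_1": wm1, "weighted_0": wm0,
                "smd_unweighted": float(smd_u), "smd_weighted": float(smd_w),
                "degenerate": False,
                "flag_imbalance": abs(smd_w) > SMD_THRESHOLD,
            })
            continue
        for level in sorted(s.dropna().unique()):
            x = (s == level).to_numpy(dtype=float)
            p1, p0 = x[m1].mean(), x[m0].mean()
            pw1, ne1 = _weighted_prop(x[m1], w[m1])
            pw0, ne0 = _weighted_prop(x[m0], w[m0])
            degenerate = p1 in (0.0, 1.0) and p0 in (0.0, 1.0)
            smd_u = 0.0 if degenerate else standardized_difference(p1, p0)
            smd_w = 0.0 if degenerate else standardized_difference(pw1, pw0)
            rows.append({
                "covariate": cov, "level": level,
                "unweighted_1": p1, "unweighted_0": p0,
                "unweighted_1_ci": _ci(p1, m1.sum()), "unweighted_0_ci": _ci(p0, m0.sum()),
                "weighted_1": pw1, "weighted_0": pw0,
                "weighted_1_ci": _ci(pw1, ne1), "weighted_0_ci": _ci(pw0, ne0),
                "smd_unweighted": smd_u, "smd_weighted": smd_w,
                "degenerate": degenerate,
                "flag_imbalance": abs(smd_w) > SMD_THRESHOLD,
            })
    return pd.DataFrame(rows)
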