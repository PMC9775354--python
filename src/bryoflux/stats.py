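"""Statistical comparisons: t-tests (including from printed summary statistics),
trend regression, and fixed-effects ANCOVA with AIC model selection.

The ANCOVA compares rate-vs-temperature models between experimental groups.
Between-sample variation is controlled with a fixed blocking factor — the
replicate index within group — which is the fixed-effects analogue of a
per-sample random intercept that keeps the group contrast estimable (a raw
sample-identity factor would be collinear with group, since every sample
belongs to exactly one group). Candidate models are compared by AIC; models
within 2 AIC of the best are treated as equivalent and the one with fewest
parameters is selected. Term tests on the selected model use Type III partial
F statistics under sum-to-zero contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import DegenerateDesignError, InvalidInputError

T_CAP = 1e6  # reported instead of an infinite paired-t statistic


@dataclass(frozen=True)
class SummaryStats:
    """Mean ± SE with replicate count, as printed in a results table."""

    mean: float
    se: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise InvalidInputError("n must be at least 2")
        if self.se < 0:
            raise InvalidInputError("se must be non-negative")

    @property
    def sd(self) -> float:
        return self.se * np.sqrt(self.n)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    capped: bool = False


def ttest_from_summary(a: SummaryStats, b: SummaryStats, var_equal: bool = True
                       ) -> TTestResult:
    """Two-sample t-test from summary statistics (pooled or Welch).

    With equal group sizes the pooled statistic reduces to
    (mean_a − mean_b)/√(se_a² + se_b²) with df = n_a + n_b − 2.
    """
    if var_equal:
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / df
        t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    else:
        va, vb = a.se ** 2, b.se ** 2
        t = (a.mean - b.mean) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def ttest_paired(x, y) -> TTestResult:
    """Paired t-test on differences, df = n − 1.

    Zero-variance differences yield a flagged, capped statistic (0 when the
    mean difference is also zero) instead of an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must have equal lengths")
    n = len(x)
    if n < 2:
        raise InvalidInputError("need at least 2 pairs")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return TTestResult(0.0, float(df), 1.0, capped=True)
        t = np.sign(d.mean()) * T_CAP
        return TTestResult(float(t), float(df), 0.0, capped=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    r2: float
    adj_r2: float
    f: float
    p: float
    n: int


def linear_trend(x, y) -> TrendFit:
    """Ordinary least-squares trend with adjusted R² and the overall F test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise DegenerateDesignError("need at least 3 points")
    if np.allclose(x, x[0]):
        raise DegenerateDesignError("covariate is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f=float(res.fvalue),
        p=float(res.f_pvalue),
        n=len(x),
    )


@dataclass(frozen=True)
class ModelComparison:
    """AIC table, the selected model and its Type III term tests."""

    table: tuple                      # (name, aic, n_params) rows
    selected: str
    terms: tuple = field(default=())  # (effect, F, p) rows for the selected model

    @property
    def group_selected(self) -> bool:
        return "group" in self.selected

    @property
    def group_min_p(self) -> float:
        """Smallest Type III p over the group-involving terms (NaN if absent)."""
        ps = [p for e, _, p in self.terms if "group" in e.lower()]
        return min(ps) if ps else float("nan")


def select_by_aic(candidates):
    """Pick from (name, aic, n_params) rows: lowest AIC, but models within
    2 AIC of the best are equivalent and the fewest-parameter one wins."""
    best_aic = min(aic for _, aic, _ in candidates)
    eligible = [c for c in candidates if c[1] - best_aic < 2.0]
    return min(eligible, key=lambda c: (c[2], c[1]))[0]


_ANCOVA_FORMULAS = {
    "covariate": "rate ~ temperature + C(block, Sum)",
    "covariate+group": "rate ~ temperature + C(group, Sum) + C(block, Sum)",
    "covariate*group": "rate ~ temperature * C(group, Sum) + C(block, Sum)",
}


def _with_blocks(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    ranks = {}
    for g, sub in out.groupby("group"):
        for k, sid in enumerate(sorted(sub["sample_id"].unique())):
            ranks[(g, sid)] = f"r{k + 1}"
    out["block"] = [ranks[(g, s)] for g, s in zip(out["group"], out["sample_id"])]
    return out


def ancova_group_by_temperature(records: pd.DataFrame, response: str = "dr"
                                ) -> ModelComparison:
    """Group-by-temperature ANCOVA for one response (``"np"`` or ``"dr"``).

    ``records`` needs columns temperature, group, sample_id and the response
    (either as a ``rate`` column or named after the response).
    """
    df = records.copy()
    if "rate" not in df.columns:
        if response not in df.columns:
            raise InvalidInputError(f"records must contain a 'rate' or {response!r} column")
        df["rate"] = df[response]
    if "temperature" not in df.columns and "temperature_C" in df.columns:
        df["temperature"] = df["temperature_C"]
    groups = df["group"].unique()
    if len(groups) < 2:
        raise DegenerateDesignError("need at least 2 groups")
    for g in groups:
        if df.loc[df["group"] == g, "sample_id"].nunique() < 2:
            raise DegenerateDesignError(f"group {g!r} has fewer than 2 samples")
    df = _with_blocks(df)
    # centre the covariate so Type III main effects are evaluated at the
    # mean temperature rather than at 0 °C
    df["temperature"] = df["temperature"] - df["temperature"].mean()

    fits = {}
    rows = []
    for name, formula in _ANCOVA_FORMULAS.items():
        res = smf.ols(formula, data=df).fit()
        fits[name] = res
        rows.append((name, float(res.aic), len(res.params)))
    selected = select_by_aic(rows)
    anova = sm.stats.anova_lm(fits[selected], typ=3)
    terms = tuple(
        (str(idx), float(row["F"]), float(row["PR(>F)"]))
        for idx, row in anova.iterrows()
        if idx not in ("Intercept", "Residual")
    )
    return ModelComparison(table=tuple(rows), selected=selected, terms=terms)


def holm_correction(pvalues):
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
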