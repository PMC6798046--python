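"""Downstream stages: gene-pair correlation, coexpression survival, and
study-covariate regression.

The survival stage stratifies patients by the mean of two genes' expression
(strictly above the cohort median = "high" coexpression), compares
disease-free survival between the groups with the two-sample log-rank test,
and estimates the hazard ratio of the high group from a Cox proportional-
hazards model with the single binary group covariate (Breslow tie
handling).  The covariate stage regresses per-study log2 fold change on
sample size, population region (country) and study year by ordinary least
squares; the multi-level country factor is tested jointly with a partial
F-test so it yields a single p-value like the numeric factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import optimize, stats

from .effects import Z95

HIGH = "high"
LOW = "low"


@dataclass(frozen=True)
class SurvivalCohort:
    """Per-patient two-gene expression plus follow-up time and event flag."""

    data: pd.DataFrame  # columns: patient_id, expr_a, expr_b, time, event

    REQUIRED = ("patient_id", "expr_a", "expr_b", "time", "event")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"survival cohort missing column(s) {missing}")
        if (self.data["time"] < 0).any():
            raise ValueError("follow-up times must be non-negative")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class SurvivalResult:
    chi2: float
    p: float
    hr: float
    hr_ci95: tuple[float, float]
    n_high: int
    n_low: int
    cox_p: float


@dataclass(frozen=True)
class MlrFactor:
    """One regression factor: coefficient(s), 95% CI(s) and a single p."""

    name: str
    coef: tuple[float, ...]
    ci95: tuple[tuple[float, float], ...]
    p: float


@dataclass(frozen=True)
class MlrResult:
    factors: Mapping[str, MlrFactor]
    n: int
    r2: float


class CoxSeparationError(RuntimeError):
    """The partial likelihood has no finite maximiser (separation)."""


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with the t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size))


def coexpression_groups(cohort: SurvivalCohort) -> pd.Series:
    """Median-split coexpression labels from the mean of the two genes.

    The per-patient score is (expr_a + expr_b)/2; patients strictly above
    the cohort median are "high", the rest (ties included) "low".
    """
    if len(cohort) < 4:
        raise ValueError("need at least 4 patients for a median split")
    score = (cohort.data["expr_a"] + cohort.data["expr_b"]) / 2.0
    if np.ptp(score.values) == 0:
        raise ValueError("all coexpression scores identical: no split possible")
    median = float(score.median())
    labels = pd.Series(
        np.where(score > median, HIGH, LOW),
        index=cohort.data.index,
        name="group",
    )
    return labels


def logrank(cohort: SurvivalCohort, labels: pd.Series) -> tuple[float, float]:
    """Two-group log-rank test (chi-square statistic with 1 df)."""
    is_high = labels == HIGH
    if is_high.all() or (~is_high).all():
        raise ValueError("both groups must be non-empty")
    if int(cohort.data["event"].sum()) == 0:
        raise ValueError("no events observed: log-rank test undefined")
    d = cohort.data
    res = logrank_test(
        d.loc[is_high, "time"],
        d.loc[~is_high, "time"],
        event_observed_A=d.loc[is_high, "event"],
        event_observed_B=d.loc[~is_high, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def _cox_event_table(
    time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> list[tuple[int, int, int, int]]:
    """Per event time: (d events, s events with x=1, n0 at risk, n1 at risk)."""
    rows = []
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s = int(x[dead].sum())
        n1 = int(x[at_risk].sum())
        n0 = int(at_risk.sum()) - n1
        rows.append((d, s, n0, n1))
    return rows


def cox_partial_loglik(
    beta: float, time: np.ndarray, event: np.ndarray, x: np.ndarray
) -> float:
    """Breslow-ties Cox partial log-likelihood for a binary covariate."""
    ll = 0.0
    eb = math.exp(beta)
    for d, s, n0, n1 in _cox_event_table(time, event, x):
        ll += s * beta - d * math.log(n0 + n1 * eb)
    return ll


def cox_hr(
    cohort: SurvivalCohort, labels: pd.Series
) -> tuple[float, tuple[float, float], float]:
    """Hazard ratio of the high group from a single-covariate Cox model.

    The partial likelihood (Breslow ties) is maximised by a bracketed
    one-dimensional root search on its score function; the CI and Wald p
    come from the observed information at the maximum.  Returns
    ``(hr, (ci_low, ci_high), wald_p)``.
    """
    is_high = labels == HIGH
    if is_high.all() or (~is_high).all():
        raise ValueError("both groups must be non-empty")
    d = cohort.data
    time = d["time"].to_numpy(dtype=float)
    event = d["event"].to_numpy(dtype=int)
    if int(event.sum()) < 2:
        raise ValueError("need at least 2 events to estimate a hazard ratio")
    x = is_high.to_numpy(dtype=int)
    table = _cox_event_table(time, event, x)

    def score(beta: float) -> float:
        eb = math.exp(beta)
        u = 0.0
        for dd, s, n0, n1 in table:
            u += s - dd * (n1 * eb) / (n0 + n1 * eb)
        return u

    lo, hi = -30.0, 30.0
    if score(lo) * score(hi) > 0:
        raise CoxSeparationError(
            "score function has no sign change: the groups' event orderings "
            "are separated and the hazard ratio is unbounded"
        )
    beta_hat = float(optimize.brentq(score, lo, hi, xtol=1e-12))

    eb = math.exp(beta_hat)
    info = 0.0
    for dd, s, n0, n1 in table:
        pj = (n1 * eb) / (n0 + n1 * eb)
        info += dd * pj * (1.0 - pj)
    if info <= 0:
        raise CoxSeparationError("observed information is not positive")
    se = 1.0 / math.sqrt(info)
    wald_p = float(2.0 * stats.norm.sf(abs(beta_hat) / se))
    hr = math.exp(beta_hat)
    ci = (math.exp(beta_hat - Z95 * se), math.exp(beta_hat + Z95 * se))
    return hr, ci, wald_p


def survival_analysis(cohort: SurvivalCohort) -> SurvivalResult:
    """Median-split coexpression survival: log-rank plus Cox hazard ratio."""
    labels = coexpression_groups(cohort)
    chi2, p = logrank(cohort, labels)
    hr, ci, cox_p = cox_hr(cohort, labels)
    return SurvivalResult(
        chi2=chi2,
        p=p,
        hr=hr,
        hr_ci95=ci,
        n_high=int((labels == HIGH).sum()),
        n_low=int((labels == LOW).sum()),
        cox_p=cox_p,
    )


def km_curve_data(cohort: SurvivalCohort, labels: pd.Series) -> pd.DataFrame:
    """Kaplan–Meier step-function points per group, for plotting."""
    from lifelines import KaplanMeierFitter

    frames = []
    for name in (LOW, HIGH):
        sel = labels == name
        if not sel.any():
            continue
        km = KaplanMeierFitter()
        km.fit(cohort.data.loc[sel, "time"], cohort.data.loc[sel, "event"])
        sf = km.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf.insert(0, "group", name)
        frames.append(sf)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# study-covariate multiple linear regression
# ---------------------------------------------------------------------------


def fit_linear_model(y: Sequence[float], design: pd.DataFrame):
    """OLS of y on an intercept plus the design columns (statsmodels fit).

    A constant response collapses the fit to the degenerate convention:
    slope coefficients 0, residual variance 0, p-values 1.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = sm.add_constant(design.astype(float), has_constant="add")
    if len(y) < X.shape[1] + 1:
        raise ValueError(
            f"need more observations ({len(y)}) than model columns "
            f"({X.shape[1]}) plus one"
        )
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]} columns): "
            f"{list(X.columns)}"
        )
    return sm.OLS(y, X).fit()


def mlr_covariates(table: pd.DataFrame) -> MlrResult:
    """Regress per-study log2 fold change on study-level covariates.

    ``table`` needs columns ``lfc``, ``sample_size``, ``country`` and
    ``date`` (one row per study for a single gene).  Country enters as dummy
    variables against the alphabetically first country and is reported with
    one joint partial-F p-value; sample size and date get coefficient
    t-tests.
    """
    for col in ("lfc", "sample_size", "country", "date"):
        if col not in table.columns:
            raise ValueError(f"covariate table missing column {col!r}")
    countries = sorted(table["country"].astype(str).unique())
    if len(countries) < 2:
        raise ValueError(
            "at least 2 distinct countries are required to test the "
            "population-region factor"
        )
    y = table["lfc"].to_numpy(dtype=float)
    dummies = pd.get_dummies(
        pd.Categorical(table["country"].astype(str), categories=countries),
        prefix="country",
        drop_first=True,
    ).set_index(table.index)
    design = pd.concat(
        [table[["sample_size", "date"]].astype(float), dummies], axis=1
    )

    if np.ptp(y) == 0:  # constant response: degenerate-fit convention
        factors = {
            name: MlrFactor(name=name, coef=(0.0,) * k, ci95=((0.0, 0.0),) * k, p=1.0)
            for name, k in (
                ("sample_size", 1),
                ("country", len(countries) - 1),
                ("date", 1),
            )
        }
        return MlrResult(factors=factors, n=len(y), r2=0.0)

    full = fit_linear_model(y, design)
    reduced = fit_linear_model(y, table[["sample_size", "date"]].astype(float))
    f_stat, country_p, _ = full.compare_f_test(reduced)

    conf = full.conf_int(alpha=0.05)
    factors: dict[str, MlrFactor] = {}
    for name in ("sample_size", "date"):
        factors[name] = MlrFactor(
            name=name,
            coef=(float(full.params[name]),),
            ci95=((float(conf.loc[name, 0]), float(conf.loc[name, 1])),),
            p=float(full.pvalues[name]),
        )
    cnames = list(dummies.columns)
    factors["country"] = MlrFactor(
        name="country",
        coef=tuple(float(full.params[c]) for c in cnames),
        ci95=tuple(
            (float(conf.loc[c, 0]), float(conf.loc[c, 1])) for c in cnames
        ),
        p=float(country_p),
    )
    return MlrResult(factors=factors, n=len(y), r2=float(full.rsquared))
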