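"""Survival evaluation battery for immune-score prognostics.

Kaplan–Meier curves with 5-year (60-month) rates and Greenwood log–log
confidence intervals, log-rank tests, unadjusted and multivariable Cox
proportional-hazards models (Efron tie correction by default, Breslow by
flag), Harrell's C-index, a seeded bootstrap comparison of C-indices
between nested risk models with Bonferroni correction, Pearson
correlation, and Kruskal–Wallis / Chi-square cohort baseline tests.

Cohort tables are pandas DataFrames with ``time_months`` (positive,
months) and ``event`` (1 = death, 0 = censored) columns plus covariates.
Risk-score orientation throughout: a higher risk score predicts shorter
survival, so a protective category (e.g. a high immune score) carries a
hazard ratio below 1.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger(__name__)

TIME_COL = "time_months"
EVENT_COL = "event"
FIVE_YEARS_MONTHS = 60.0


def _check_table(df: pd.DataFrame) -> None:
    for col in (TIME_COL, EVENT_COL):
        if col not in df.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    t = df[TIME_COL].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t <= 0):
        raise ValueError("time_months must be finite and positive")
    e = df[EVENT_COL].to_numpy()
    if not np.isin(e, [0, 1]).all():
        raise ValueError("event must be binary 0/1")


# --------------------------------------------------------------------------
# Kaplan–Meier
# --------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit curve for one group; step function carried forward."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int
    n_events: int

    def rate_at(self, t: float) -> float:
        """Survival probability at time t (last step value carried forward)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float) -> tuple[float, float]:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0, 1.0
        return float(self.ci_low[idx]), float(self.ci_high[idx])


def km_estimate(df: pd.DataFrame, group_col: str) -> dict[str, KMCurve]:
    """Kaplan–Meier estimate per group with Greenwood log–log CIs."""
    _check_table(df)
    curves: dict[str, KMCurve] = {}
    for label, sub in df.groupby(group_col, observed=True):
        if len(sub) == 0:
            raise ValueError(f"group {label!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[TIME_COL], sub[EVENT_COL], label=str(label))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        curves[str(label)] = KMCurve(
            label=str(label),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=kmf.event_table["at_risk"].to_numpy(),
            ci_low=ci.iloc[:, 0].to_numpy(dtype=float),
            ci_high=ci.iloc[:, 1].to_numpy(dtype=float),
            n=len(sub),
            n_events=int(sub[EVENT_COL].sum()),
        )
    if not curves:
        raise ValueError(f"no groups found in column {group_col!r}")
    return curves


def logrank_test(df: pd.DataFrame, group_col: str) -> tuple[float, int, float]:
    """Log-rank test across groups: (chi-square, df, p)."""
    _check_table(df)
    labels = df[group_col]
    k = labels.nunique()
    if k < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if df[EVENT_COL].sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(df[TIME_COL], labels, df[EVENT_COL])
    return float(res.test_statistic), k - 1, float(res.p_value)


# --------------------------------------------------------------------------
# Cox proportional hazards
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CoxTerm:
    log_hr: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class CoxFit:
    terms: dict[str, CoxTerm]
    n: int
    n_events: int
    ties: str
    strata: str | None = None

    def term(self, name: str) -> CoxTerm:
        return self.terms[name]


def _design_matrix(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Dummy-code categorical covariates (first level is the reference)."""
    parts = []
    for col in covariates:
        if col not in df.columns:
            raise ValueError(f"covariate {col!r} not in table")
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).rename(col))
        else:
            dummies = pd.get_dummies(s, prefix=col, prefix_sep="=", drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def cox_fit(
    df: pd.DataFrame,
    covariates: list[str],
    strata: str | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Cox partial-likelihood fit with Wald CIs and p-values.

    Categorical covariates are dummy-coded against their first level.
    Raises with an explicit diagnostic on constant covariates, absence of
    events, or non-convergence / monotone likelihood (detected as
    non-finite or exploding estimates).
    """
    _check_table(df)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(df[EVENT_COL].sum())
    if n_events == 0:
        raise ValueError("Cox model needs at least one event (all records censored)")
    X = _design_matrix(df, covariates)
    strata_values = df[strata].to_numpy() if strata is not None else None
    for col in X.columns:
        v = X[col].to_numpy()
        if strata_values is None:
            groups = [np.ones(len(v), dtype=bool)]
        else:
            groups = [strata_values == s for s in np.unique(strata_values)]
        if all(np.all(v[g] == v[g][0]) for g in groups if g.any()):
            raise ValueError(f"covariate {col!r} is constant within all strata")

    model = PHReg(
        endog=df[TIME_COL].to_numpy(dtype=float),
        exog=X.to_numpy(dtype=float),
        status=df[EVENT_COL].to_numpy(dtype=int),
        ties=ties,
        strata=strata_values,
    )
    try:
        with _warnings.catch_warnings():
            # degenerate fits are detected below from the estimates; the
            # optimizer's own warning would otherwise flood bootstrap loops
            _warnings.simplefilter("ignore")
            res = model.fit(disp=False)
    except Exception as exc:  # pragma: no cover - backend specific
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))) or np.any(
        np.abs(params) > 50
    ):
        raise RuntimeError(
            "Cox fit is degenerate (monotone likelihood / perfect separation); "
            f"estimates: {dict(zip(X.columns, params))}"
        )
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        terms = _build_terms(X.columns, params, bse, z)
    return CoxFit(terms=terms, n=len(df), n_events=n_events, ties=ties, strata=strata)


def _build_terms(names, params, bse, z) -> dict[str, CoxTerm]:
    return {
        name: CoxTerm(
            log_hr=float(b),
            hr=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)),
            ci_high=float(np.exp(b + z * se)),
            p=float(2 * stats.norm.sf(abs(b / se))) if se > 0 else float("nan"),
        )
        for name, b, se in zip(names, params, bse)
    }


def cox_linear_predictor(df: pd.DataFrame, fit: CoxFit, covariates: list[str]) -> np.ndarray:
    """Risk score X·β̂ for the records in ``df`` under a fitted model."""
    X = _design_matrix(df, covariates)
    beta = np.array([fit.terms[c].log_hr for c in X.columns])
    return X.to_numpy(dtype=float) @ beta


# --------------------------------------------------------------------------
# Harrell's C
# --------------------------------------------------------------------------


def harrell_c(time, event, risk) -> float:
    """Harrell's concordance index.

    A pair is usable when censoring lets the order of failures be
    established: the earlier observed time is an event, or the times are
    equal with exactly one event (the event fails first). Higher risk
    predicting the earlier failure is concordant; risk ties count 0.5.
    Pairs with equal times and equal event status are not usable.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=int)
    r = np.asarray(risk, dtype=float)
    if not (len(t) == len(e) == len(r)):
        raise ValueError("time, event and risk must be aligned")
    # i indexes the (potentially) earlier failure of each ordered pair
    ti, tj = t[:, None], t[None, :]
    ei = e[:, None]
    ri, rj = r[:, None], r[None, :]
    usable = ((ti < tj) & (ei == 1)) | ((ti == tj) & (ei == 1) & (e[None, :] == 0))
    np.fill_diagonal(usable, False)
    n_usable = int(usable.sum())
    if n_usable == 0:
        raise ValueError("no usable pairs (censoring pattern leaves nothing orderable)")
    concordant = int((usable & (ri > rj)).sum())
    tied = int((usable & (ri == rj)).sum())
    return (concordant + 0.5 * tied) / n_usable


# --------------------------------------------------------------------------
# bootstrap C-index comparison
# --------------------------------------------------------------------------


@dataclass
class CIndexComparison:
    samples: dict[str, np.ndarray]  # per-model bootstrap C-index draws
    means: dict[str, float]
    p_values: dict[tuple[str, str], float]
    p_adjusted: dict[tuple[str, str], float]
    B: int
    seed: int
    n_redraws: int = 0
    model_covariates: dict[str, list[str]] = field(default_factory=dict)


def bootstrap_c_compare(
    df: pd.DataFrame,
    model_specs: dict[str, list[str]],
    B: int = 1000,
    seed: int = 0,
    ties: str = "efron",
) -> CIndexComparison:
    """Bootstrap comparison of Cox-model discrimination.

    For each of ``B`` resamples (with replacement) every model spec is
    refitted and its apparent Harrell's C on the resample recorded.
    Pairwise two-sided p-values come from the empirical bootstrap
    distribution of C differences; Bonferroni adjusts across pairs.
    Resamples without events are redrawn (max 10 retries each).
    """
    _check_table(df)
    if len(model_specs) < 2:
        raise ValueError("need at least 2 model specs to compare")
    if B < 100:
        raise ValueError(f"B must be ≥ 100 for a usable bootstrap p-value, got {B}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    n = len(df)
    names = list(model_specs)
    samples = {name: np.empty(B) for name in names}
    n_redraws = 0
    for b in range(B):
        for attempt in range(11):
            idx = rng.integers(0, n, size=n)
            boot = df.iloc[idx].reset_index(drop=True)
            if boot[EVENT_COL].sum() == 0:
                n_redraws += 1
                logger.warning("bootstrap resample %d had zero events; redrawing", b)
                continue
            try:
                cs = {}
                for name in names:
                    fit = cox_fit(boot, model_specs[name], ties=ties)
                    risk = cox_linear_predictor(boot, fit, model_specs[name])
                    cs[name] = harrell_c(boot[TIME_COL], boot[EVENT_COL], risk)
            except (ValueError, RuntimeError) as exc:
                n_redraws += 1
                logger.warning("bootstrap resample %d unusable (%s); redrawing", b, exc)
                continue
            for name in names:
                samples[name][b] = cs[name]
            break
        else:
            raise RuntimeError("10 consecutive unusable bootstrap resamples; cohort too sparse")

    means = {name: float(samples[name].mean()) for name in names}
    pairs = [(a, b2) for i, a in enumerate(names) for b2 in names[i + 1 :]]
    p_values: dict[tuple[str, str], float] = {}
    for a, b2 in pairs:
        d = samples[a] - samples[b2]
        p_le = (1 + int(np.sum(d <= 0))) / (B + 1)
        p_ge = (1 + int(np.sum(d >= 0))) / (B + 1)
        p_values[(a, b2)] = min(1.0, 2.0 * min(p_le, p_ge))
    m = len(pairs)
    p_adjusted = {k: min(1.0, v * m) for k, v in p_values.items()}
    return CIndexComparison(
        samples=samples,
        means=means,
        p_values=p_values,
        p_adjusted=p_adjusted,
        B=B,
        seed=seed,
        n_redraws=n_redraws,
        model_covariates={k: list(v) for k, v in model_specs.items()},
    )


# --------------------------------------------------------------------------
# simple association tests
# --------------------------------------------------------------------------


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def cohort_baseline_tests(
    groups: dict[str, pd.DataFrame], variables: list[str] | None = None
) -> pd.DataFrame:
    """Baseline-characteristics comparison across cohort groups.

    Kruskal–Wallis for numeric variables, Chi-square on the contingency
    table for categoricals; Bonferroni-adjusted p-values across variables.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    frames = list(groups.values())
    if variables is None:
        common = set.intersection(*(set(f.columns) for f in frames))
        variables = sorted(common - {TIME_COL, EVENT_COL, "patient_id"})
    rows = []
    for var in variables:
        series = [f[var] for f in frames]
        if all(pd.api.types.is_numeric_dtype(s) for s in series):
            stat, p = stats.kruskal(*[s.to_numpy(dtype=float) for s in series])
            test = "kruskal-wallis"
        else:
            stacked = pd.concat(
                [s.astype(str).to_frame(var).assign(_g=name) for name, s in zip(groups, series)]
            )
            table = pd.crosstab(stacked[var], stacked["_g"])
            if table.to_numpy().sum() == 0:
                raise ValueError(f"contingency table for {var!r} is empty")
            # classic (uncorrected) Pearson statistic, as the textbook formula
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
            test = "chi-square"
        rows.append({"variable": var, "test": test, "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * len(out))
    return out
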