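"""Survival analysis: Kaplan-Meier, log-rank, Cox PH fits, concordance.

Time-to-event is transformation-free survival in months at slide level, with
administrative right-censoring at eight years (96 months). Cox proportional-
hazards models are fitted by partial-likelihood maximization (Efron tie
handling by default — follow-up is month-resolved, so ties are common and
Efron is less biased than Breslow). Hazard ratios for continuous covariates
(IEL scores, age) are reported per standard deviation by default: the
covariates are z-standardized before fitting, so HRs are scale-free; pass
``standardize=False`` for per-raw-unit HRs.

Categorical encodings
---------------------
sex: female=0/male=1. binary grade: low=0/high=1. WHO grade: ordinal 1/2/3
(``who``), or the binary contrasts ``who_g1`` (mild vs moderate+severe) and
``who_g2`` (mild+moderate vs severe). Site and scanner enter single-covariate
(univariate) fits as one ordinal-coded column; multi-covariate fits expand
them one-hot against the largest category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalInput",
    "SurvivalFit",
    "right_censor",
    "km_estimate",
    "cox_fit",
    "concordance_index",
    "model_comparison",
    "encode_covariates",
    "standard_model_grid",
]

SITE_ORDER = ("buccal_mucosa", "tongue", "floor_of_mouth", "other")
SCANNER_ORDER = ("aperio_cs2", "nanozoomer_s360", "p1000")
WHO_ORDER = ("mild", "moderate", "severe")

DEFAULT_HORIZON_MONTHS = 96.0


@dataclass
class SurvivalInput:
    """Censored follow-up plus raw (unencoded) covariates, one row per slide."""

    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame
    horizon_months: float = DEFAULT_HORIZON_MONTHS

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if len(self.time) != len(self.event) or len(self.time) != len(self.covariates):
            raise ValueError("time, event and covariates must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all follow-up times must be > 0")
        if np.any(self.time > self.horizon_months):
            raise ValueError("times exceed the censoring horizon; apply right_censor first")


@dataclass
class SurvivalFit:
    """Per-covariate hazard ratios and model-level summaries of one Cox fit."""

    summary: pd.DataFrame  # index: term; columns: coef, hr, ci_low, ci_high, se, p
    c_index: float
    loglik: float
    n: int
    n_events: int
    ties: str
    dropped: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def hr(self) -> pd.Series:
        return self.summary["hr"]


def right_censor(
    frame: pd.DataFrame,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    time_col: str = "months",
    event_col: str = "transformed",
) -> SurvivalInput:
    """Apply administrative right-censoring at ``horizon_months``.

    Events strictly after the horizon become censorings at the horizon;
    events and censorings at or before it are unchanged (the horizon itself
    is inclusive). All other columns of ``frame`` are carried as covariates.
    """
    time = np.asarray(frame[time_col], dtype=float)
    event = np.asarray(frame[event_col], dtype=bool)
    if np.any(time <= 0):
        raise ValueError("all follow-up times must be > 0")
    past = time > horizon_months
    event = event & ~past
    time = np.minimum(time, horizon_months)
    covs = frame.drop(columns=[time_col, event_col])
    return SurvivalInput(time=time, event=event, covariates=covs.reset_index(drop=True),
                         horizon_months=horizon_months)


# -- covariate encoding -------------------------------------------------------


def _ordinal(series: pd.Series, order: Sequence[str], start: int = 0) -> pd.Series:
    codes = series.map({lvl: i + start for i, lvl in enumerate(order)})
    if codes.isna().any():
        bad = series[codes.isna()].unique().tolist()
        raise ValueError(f"unknown level(s) {bad} for ordinal column {series.name!r}")
    return codes.astype(float)


def encode_covariates(
    covs: pd.DataFrame,
    terms: Sequence[str],
    *,
    multivariate: bool | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Build the numeric design matrix for the requested terms.

    ``multivariate=None`` resolves to one-hot site/scanner when more than one
    term is requested, ordinal coding otherwise (mirroring a one-row-per-
    parameter univariate table). Continuous columns are z-standardized when
    ``standardize`` is set; binary and ordinal codes are left as is.
    """
    if multivariate is None:
        multivariate = len(terms) > 1
    cols: dict[str, pd.Series] = {}
    for term in terms:
        if term == "sex":
            cols["sex"] = _ordinal(covs["sex"], ("female", "male"))
        elif term == "binary":
            cols["binary"] = _ordinal(covs["binary_grade"], ("low", "high"))
        elif term == "who":
            cols["who"] = _ordinal(covs["who_grade"], WHO_ORDER, start=1)
        elif term == "who_g1":
            cols["who_g1"] = (covs["who_grade"] != "mild").astype(float)
        elif term == "who_g2":
            cols["who_g2"] = (covs["who_grade"] == "severe").astype(float)
        elif term in ("site", "scanner"):
            order = SITE_ORDER if term == "site" else SCANNER_ORDER
            series = covs[term]
            if multivariate:
                ref = series.value_counts().idxmax()
                for lvl in order:
                    if lvl == ref or lvl not in set(series):
                        continue
                    cols[f"{term}_{lvl}"] = (series == lvl).astype(float)
            else:
                cols[term] = _ordinal(series, order)
        else:
            values = pd.to_numeric(covs[term])
            uniq = np.unique(values.dropna())
            is_binary = len(uniq) <= 2 and set(uniq).issubset({0.0, 1.0})
            if standardize and not is_binary:
                sd = values.std(ddof=1)
                if sd == 0:
                    raise ValueError(f"covariate {term!r} is constant")
                values = (values - values.mean()) / sd
            cols[term] = values.astype(float)
    X = pd.DataFrame(cols).reset_index(drop=True)
    return X


# -- Kaplan-Meier + log-rank --------------------------------------------------


def km_estimate(
    si: SurvivalInput, groups: Sequence
) -> tuple[dict, float, float]:
    """Product-limit survival curves per group plus a log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves[label]`` is a DataFrame of
    step coordinates (``time``, ``survival``, ``at_risk``). The log-rank test
    is the two-sided chi-square across all groups.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    groups = np.asarray(groups)
    if len(groups) != len(si.time):
        raise ValueError("group labels must match the number of subjects")
    if si.event.sum() < 1:
        raise ValueError("need at least one event for survival estimation")
    curves = {}
    for label in pd.unique(groups):
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} has zero subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(si.time[mask], si.event[mask])
        df = kmf.survival_function_.reset_index()
        df.columns = ["time", "survival"]
        df["at_risk"] = [kmf.event_table.at[t, "at_risk"] for t in df["time"]]
        curves[label] = df
    res = multivariate_logrank_test(si.time, groups, si.event)
    return curves, float(res.test_statistic), float(res.p_value)


# -- concordance --------------------------------------------------------------


def concordance_index(
    times: np.ndarray, events: np.ndarray, risk_scores: np.ndarray
) -> float:
    """Harrell's C for risk scores (higher risk should mean earlier event).

    A pair (i, j) is comparable when the earlier time belongs to a subject
    with an observed event. A comparable pair is concordant when the subject
    with the shorter time has the strictly higher risk score; ties in the
    risk score count 1/2. Invariant under strictly monotone transforms of
    the scores.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    r = np.asarray(risk_scores, dtype=float)
    if not (len(t) == len(e) == len(r)):
        raise ValueError("times, events, risk_scores must have equal length")
    # comparable[i, j]: t_i < t_j and subject i had the event
    comparable = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (no event precedes another subject's time)")
    conc = (r[:, None] > r[None, :]) & comparable
    tied = (r[:, None] == r[None, :]) & comparable
    return float((conc.sum() + 0.5 * tied.sum()) / n_comp)


# -- Cox proportional hazards -------------------------------------------------


def cox_fit(
    si: SurvivalInput,
    covariates: Sequence[str],
    ties: str = "efron",
    *,
    standardize: bool = True,
    multivariate: bool | None = None,
) -> SurvivalFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    ``covariates`` are term names resolved by :func:`encode_covariates`.
    Hazard ratios are ``exp(coef)`` with 95% Wald confidence intervals from
    the observed information; the model C-index is Harrell's C on the linear
    predictor. Complete separation is flagged (not fatal) when a coefficient
    is huge with a huge standard error.
    """
    from statsmodels.duration.hazard_regression import PHReg

    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie-handling method {ties!r}")
    X = encode_covariates(si.covariates, covariates, multivariate=multivariate,
                          standardize=standardize)
    for col in X.columns:
        if X[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant in this cohort")
    n_events = int(si.event.sum())
    if n_events < X.shape[1]:
        raise ValueError(
            f"{n_events} events cannot support {X.shape[1]} covariates"
        )
    model = PHReg(si.time, X.to_numpy(), status=si.event.astype(int), ties=ties)
    try:
        res = model.fit(disp=False)
    except Exception as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(f"Cox fit failed to converge: {err}") from err
    coef = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    if not np.all(np.isfinite(coef)) or not np.all(np.isfinite(se)):
        raise RuntimeError("Cox fit did not converge (non-finite estimates)")
    z = stats.norm.ppf(0.975)
    pvals = 2 * stats.norm.sf(np.abs(coef / se))
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "se": se,
            "p": pvals,
        },
        index=list(X.columns),
    )
    flags = []
    if np.any((np.abs(coef) > 10) & (se > 10)):
        flags.append("possible complete separation")
    linpred = X.to_numpy() @ coef
    c = concordance_index(si.time, si.event, linpred)
    return SurvivalFit(
        summary=summary,
        c_index=c,
        loglik=float(model.loglike(coef)),
        n=len(si.time),
        n_events=n_events,
        ties=ties,
        flags=flags,
    )


# -- model comparison grids ---------------------------------------------------


def standard_model_grid(grade: str = "binary") -> list[tuple[str, list[str]]]:
    """The {grade} x {none, +age+sex+site} x {none, +iel_c, +iel_pc} grid."""
    base: list[tuple[str, list[str]]] = []
    for clin_name, clin in (("", []), (" + age + sex + site", ["age", "sex", "site"])):
        for score_name, score in (("", []), (" + iel_c", ["iel_c"]), (" + iel_pc", ["iel_pc"])):
            base.append((f"{grade}{clin_name}{score_name}", [grade] + clin + score))
    return base


def model_comparison(
    si: SurvivalInput,
    specs: Sequence[tuple[str, Sequence[str]]],
    ties: str = "efron",
    standardize: bool = True,
) -> pd.DataFrame:
    """Fit each covariate set and tabulate in-sample C-indices.

    One row per spec: name, covariates, c_index, loglik, n_events. A pure
    function of the input; identical specs give identical rows.
    """
    rows = []
    for name, covs in specs:
        fit = cox_fit(si, list(covs), ties=ties, standardize=standardize)
        rows.append(
            {
                "model": name,
                "covariates": "+".join(covs),
                "c_index": fit.c_index,
                "loglik": fit.loglik,
                "n_events": fit.n_events,
            }
        )
    return pd.DataFrame(rows)
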