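"""Five-year disease-specific survival analysis.

The event of interest is disease-specific death: a patient who is dead AND
"with tumour" at death.  Patients who die tumour-free are censored at their
death time (competing-risk-naive censoring); alive patients are censored at
last follow-up; and every time is administratively censored at the analysis
horizon (default 1826 days = 5 years).

Cox proportional-hazards fitting, Kaplan-Meier estimation and the log-rank
test are delegated to lifelines (Efron tie handling).  Model selection is a
backward stepwise loop on the partial-likelihood AIC
(AIC = -2 log PL + 2 k), dropping whole covariate blocks (all dummies of a
categorical factor together).  The model-level p reported for each
univariate fit is the partial log-likelihood-ratio test, asymptotically
equivalent to the score (log-rank) test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "MISSING_CATEGORIES",
    "CoxResult",
    "StepwiseResult",
    "build_survival_table",
    "univariate_screen",
    "km_logrank",
    "multivariate_stepwise",
]

#: Categorical levels treated as missing (removed per-covariate).
MISSING_CATEGORIES = frozenset({"NX", "MX", "TX", "RX", "Unknown", "unknown", ""})

DEFAULT_HORIZON_DAYS = 1826  # 5 years


@dataclass
class CoxResult:
    """One fitted proportional-hazards model (univariate screen entry)."""

    covariate: str
    terms: pd.DataFrame  # term, hazard_ratio, ci_low, ci_high, p
    model_p: float
    n_used: int
    n_events: int
    aic: float
    tie_method: str = "Efron"


@dataclass
class StepwiseResult:
    """Final model of the backward-stepwise AIC selection."""

    covariates: list[str]
    terms: pd.DataFrame
    aic: float
    aic_trace: list[float] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)
    n_used: int = 0
    n_events: int = 0


def build_survival_table(
    records: pd.DataFrame,
    horizon_days: int = DEFAULT_HORIZON_DAYS,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Derive (time, event) pairs for disease-specific survival.

    ``records`` needs columns ``patient``, ``vital_status`` (alive/dead),
    ``tumour_status`` (with tumour / tumour free / unknown),
    ``days_to_death`` and ``days_to_last_followup``.  Time is days-to-death
    when available, days-to-last-follow-up otherwise; rows without a
    positive time are dropped with a log message.  Any columns named in
    ``covariates`` are carried through unchanged.
    """
    required = {"patient", "vital_status", "tumour_status",
                "days_to_death", "days_to_last_followup"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"clinical records missing columns {sorted(missing)}")

    vital = records["vital_status"].astype(str).str.strip().str.lower()
    tumour = records["tumour_status"].astype(str).str.strip().str.lower()
    dead = vital == "dead"
    with_tumour = tumour == "with tumour"

    death_t = pd.to_numeric(records["days_to_death"], errors="coerce")
    fup_t = pd.to_numeric(records["days_to_last_followup"], errors="coerce")
    time = death_t.where(death_t.notna(), fup_t)
    event = (dead & with_tumour).astype(int)

    valid = time.notna() & (time > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropping %d record(s) without positive survival time",
                       n_dropped)

    out = pd.DataFrame({
        "patient": records["patient"].astype(str),
        "time": time.astype(float),
        "event": event,
    })
    for cov in covariates or []:
        out[cov] = records[cov].to_numpy()
    out = out.loc[valid.to_numpy()].reset_index(drop=True)

    # administrative censoring at the horizon
    over = out["time"] > horizon_days
    out.loc[over, "time"] = float(horizon_days)
    out.loc[over, "event"] = 0
    return out


def _clean_covariate(series: pd.Series) -> pd.Series:
    """Map unknown/X categorical levels to NaN; pass numerics through."""
    if pd.api.types.is_numeric_dtype(series) or pd.api.types.is_bool_dtype(series):
        return pd.to_numeric(series, errors="coerce")
    s = series.astype("string").str.strip()
    return s.mask(s.isin(MISSING_CATEGORIES))


def _design_block(series: pd.Series, name: str,
                  reference: str | None = None) -> pd.DataFrame:
    """Design columns for one covariate (dummy-coded if categorical)."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype(float).to_frame(name)
    levels = sorted(series.dropna().unique())
    ref = reference if reference in levels else levels[0]
    dummies = pd.get_dummies(series, prefix=name, dtype=float)
    return dummies.drop(columns=f"{name}_{ref}")


def _fit_cox(frame: pd.DataFrame) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(frame, duration_col="time", event_col="event")
    return cph


def _terms_frame(cph: CoxPHFitter) -> pd.DataFrame:
    summary = cph.summary
    return pd.DataFrame({
        "term": summary.index,
        "hazard_ratio": summary["exp(coef)"].to_numpy(),
        "ci_low": summary["exp(coef) lower 95%"].to_numpy(),
        "ci_high": summary["exp(coef) upper 95%"].to_numpy(),
        "p": summary["p"].to_numpy(),
    }).reset_index(drop=True)


def univariate_screen(
    table: pd.DataFrame,
    covariates: list[str],
    references: dict[str, str] | None = None,
) -> list[CoxResult]:
    """One proportional-hazards fit per covariate (complete-case each).

    Categorical covariates are dummy-coded against a reference level (the
    first sorted level unless overridden).  Covariates that are constant
    after missing-value removal, or whose fit fails, are skipped with a log
    message.
    """
    references = references or {}
    results: list[CoxResult] = []
    for cov in covariates:
        if cov not in table.columns:
            raise ValueError(f"covariate {cov!r} not in survival table")
        sub = table[["time", "event"]].copy()
        sub[cov] = _clean_covariate(table[cov])
        sub = sub.dropna().reset_index(drop=True)
        if sub.empty or sub[cov].nunique() < 2:
            logger.warning("covariate %r degenerate (constant or empty); skipped",
                           cov)
            continue
        if sub["event"].sum() < 1:
            logger.warning("covariate %r has no events after removal; skipped", cov)
            continue
        design = _design_block(sub[cov], cov, references.get(cov))
        frame = pd.concat([sub[["time", "event"]], design], axis=1)
        try:
            cph = _fit_cox(frame)
        except Exception as exc:  # lifelines convergence failures
            logger.warning("Cox fit failed for covariate %r: %s", cov, exc)
            continue
        results.append(
            CoxResult(
                covariate=cov,
                terms=_terms_frame(cph),
                model_p=float(cph.log_likelihood_ratio_test().p_value),
                n_used=int(len(frame)),
                n_events=int(frame["event"].sum()),
                aic=float(cph.AIC_partial_),
            )
        )
    return results


def km_logrank(
    table: pd.DataFrame, group_covariate: str
) -> tuple[dict, float]:
    """Kaplan-Meier curve per group plus the k-sample log-rank p-value."""
    groups = _clean_covariate(table[group_covariate])
    sub = table[["time", "event"]].copy()
    sub["group"] = groups
    sub = sub.dropna()
    labels = sorted(sub["group"].unique(), key=str)
    if len(labels) < 2:
        raise ValueError(
            f"log-rank needs >= 2 groups; {group_covariate!r} has {len(labels)}"
        )
    fitters: dict = {}
    for label in labels:
        grp = sub[sub["group"] == label]
        kmf = KaplanMeierFitter(label=str(label))
        kmf.fit(grp["time"], event_observed=grp["event"])
        fitters[label] = kmf
    test = multivariate_logrank_test(sub["time"], sub["group"], sub["event"])
    return fitters, float(test.p_value)


def multivariate_stepwise(
    table: pd.DataFrame,
    screen: list[CoxResult],
    p_enter: float = 0.2,
    references: dict[str, str] | None = None,
) -> StepwiseResult:
    """Backward stepwise Cox selection on AIC from a univariate screen.

    The initial model contains every covariate whose univariate model-level
    p is below ``p_enter``; rows with a missing value in any entering
    covariate are removed (complete-case).  At each step the covariate
    block whose removal lowers AIC the most is dropped; selection stops
    when no removal lowers AIC.
    """
    references = references or {}
    entering = [r.covariate for r in screen if r.model_p < p_enter]
    if not entering:
        raise ValueError(f"no covariate passes the univariate screen at "
                         f"p < {p_enter}")

    sub = table[["time", "event"]].copy()
    for cov in entering:
        sub[cov] = _clean_covariate(table[cov])
    sub = sub.dropna().reset_index(drop=True)
    if sub["event"].sum() < 1:
        raise ValueError("no events left after complete-case removal")

    blocks = {
        cov: _design_block(sub[cov], cov, references.get(cov))
        for cov in entering
    }

    def fit_model(covs: list[str]) -> tuple[CoxPHFitter, float]:
        frame = pd.concat(
            [sub[["time", "event"]]] + [blocks[c] for c in covs], axis=1
        )
        cph = _fit_cox(frame)
        return cph, float(cph.AIC_partial_)

    current = list(entering)
    cph, current_aic = fit_model(current)
    trace = [current_aic]
    dropped: list[str] = []
    while len(current) > 1:
        candidates = []
        for cov in current:
            reduced = [c for c in current if c != cov]
            try:
                cand_cph, cand_aic = fit_model(reduced)
            except Exception as exc:
                logger.warning("stepwise candidate without %r failed: %s",
                               cov, exc)
                continue
            candidates.append((cand_aic, cov, cand_cph))
        if not candidates:
            break
        best_aic, best_cov, best_cph = min(candidates, key=lambda t: t[0])
        if best_aic >= current_aic:
            break
        current = [c for c in current if c != best_cov]
        dropped.append(best_cov)
        cph, current_aic = best_cph, best_aic
        trace.append(current_aic)
    return StepwiseResult(
        covariates=current,
        terms=_terms_frame(cph),
        aic=current_aic,
        aic_trace=trace,
        dropped=dropped,
        n_used=int(len(sub)),
        n_events=int(sub["event"].sum()),
    )
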