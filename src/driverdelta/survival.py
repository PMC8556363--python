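"""Outcome screening: Kaplan-Meier, Cox models, 2x2 association.

The candidate screen takes mutation types that are differentially
prevalent between disease states after burden adjustment, keeps those
seen in at least a minimum fraction of localized tumors, and asks which
of them predict metastatic relapse of localized disease with
univariable Cox proportional-hazards models, correcting across the
candidate set with Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from driverdelta.catalog import MutationMatrix, SampleRecord
from driverdelta.differential import DifferentialResult, adjust_fdr
from driverdelta.prevalence import Z95, class_prevalence

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Cox partial-likelihood maximization failed (e.g. separation)."""


@dataclass
class SurvivalRecord:
    """One time-to-event observation for one sample and endpoint."""

    sample_id: str
    endpoint: str
    time: float
    event: bool

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.sample_id}: non-positive time")


@dataclass
class CoxResult:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int
    n_events: int
    log_hr: float
    se: float


@dataclass
class TwoByTwoResult:
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float


def km_logrank(
    times: Sequence[float],
    events: Sequence[int],
    groups: Sequence,
) -> tuple:
    """Kaplan-Meier curves per group plus a log-rank test.

    Returns ``(curves, chi2, p)`` where ``curves`` maps group label to a
    DataFrame with ``time`` and ``survival`` columns (the product-limit
    estimate evaluated at the group's event/censor times).  With a
    single group the test statistics are NaN.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if np.any(times <= 0):
        raise ValueError("all times must be positive")
    labels = pd.unique(groups)
    curves = {}
    for label in labels:
        mask = groups == label
        if mask.sum() == 0:
            raise ValueError(f"group {label!r} has zero members")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.values, "survival": sf.iloc[:, 0].values}
        )
    if len(labels) < 2:
        return curves, float("nan"), float("nan")
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


def cox_fit(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> list:
    """Cox proportional hazards fit, one result per covariate.

    Maximizes the partial likelihood with Efron (default) or Breslow
    tie handling.  Raises :class:`ConvergenceError` on non-convergence
    or (quasi-)complete separation, which drives coefficients to
    infinity — e.g. a marker whose carriers all relapse.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    covariates = pd.DataFrame(covariates)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise ValueError("at least one event is required")
    for col in covariates.columns:
        if covariates[col].nunique() <= 1:
            raise ValueError(f"covariate {col!r} is constant")
    model = PHReg(times, covariates.values, status=events, ties=ties)
    with np.errstate(all="ignore"):
        fit = model.fit(disp=False, maxiter=200, tol=1e-8)
    params = np.asarray(fit.params, dtype=float)
    bse = np.asarray(fit.bse, dtype=float)
    if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
        raise ConvergenceError("non-finite Cox estimates")
    if np.any(np.abs(params) > 20):
        raise ConvergenceError(
            "coefficient magnitude suggests complete separation: "
            + ", ".join(
                f"{c}={b:.2f}" for c, b in zip(covariates.columns, params)
            )
        )
    results = []
    for name, beta, se in zip(covariates.columns, params, bse):
        z = beta / se
        results.append(
            CoxResult(
                covariate=str(name),
                hr=float(np.exp(beta)),
                ci_low=float(np.exp(beta - Z95 * se)),
                ci_high=float(np.exp(beta + Z95 * se)),
                wald_p=float(2 * stats.norm.sf(abs(z))),
                n=len(times),
                n_events=int(events.sum()),
                log_hr=float(beta),
                se=float(se),
            )
        )
    return results


def schoenfeld_ph_test(
    covariates: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    ties: str = "efron",
) -> dict:
    """Proportional-hazards check via scaled Schoenfeld residuals.

    Correlates each covariate's Schoenfeld residuals with event-time
    rank (Pearson) and reports the correlation-test p-value; a small p
    indicates a time-varying effect, i.e. a PH violation.
    """
    covariates = pd.DataFrame(covariates)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    fit_results = cox_fit(covariates, times, events, ties=ties)
    beta = np.array([r.log_hr for r in fit_results])
    x = covariates.values.astype(float)
    risk = np.exp(x @ beta)

    event_idx = np.flatnonzero(events == 1)
    order = event_idx[np.argsort(times[event_idx])]
    residuals = []
    for i in order:
        at_risk = times >= times[i]
        w = risk[at_risk]
        xbar = (x[at_risk] * w[:, None]).sum(axis=0) / w.sum()
        residuals.append(x[i] - xbar)
    residuals = np.asarray(residuals)
    ranks = np.arange(len(order), dtype=float)

    out = {}
    for j, name in enumerate(covariates.columns):
        resid = residuals[:, j]
        if np.ptp(resid) == 0 or len(resid) < 3:
            out[str(name)] = float("nan")
            continue
        _, p = stats.pearsonr(resid, ranks)
        out[str(name)] = float(p)
    return out


def two_by_two(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """Odds ratio with Woolf CI and two-sided Fisher's exact p.

    Layout: rows = exposure (mutation present / absent), columns =
    outcome (event / no event): ``a`` exposed with event, ``b`` exposed
    without, ``c`` unexposed with event, ``d`` unexposed without.  A
    zero cell triggers the Haldane-Anscombe +0.5 correction for the
    OR and CI only; the Fisher p always uses the raw counts.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("both margins must be positive")
    fisher_p = float(stats.fisher_exact(counts, alternative="two-sided")[1])
    if np.any(counts == 0):
        counts = counts + 0.5
    aa, bb, cc, dd = counts.ravel()
    odds_ratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(odds_ratio) - Z95 * se)
    ci_high = math.exp(math.log(odds_ratio) + Z95 * se)
    return TwoByTwoResult(int(a), int(b), int(c), int(d),
                          float(odds_ratio), ci_low, ci_high, fisher_p)


def screen_candidates(
    differential: Sequence[DifferentialResult],
    matrix: MutationMatrix,
    samples: Sequence[SampleRecord],
    endpoint: str = "metastasis",
    alpha: float = 0.05,
    min_localized_prevalence: float = 0.05,
    check_ph: bool = True,
) -> pd.DataFrame:
    """Filter differential mutations and screen them against outcome.

    Keeps mutation types with differential q < ``alpha`` and localized
    prevalence >= ``min_localized_prevalence``, fits a univariable Cox
    model of carrier status on the requested endpoint among localized
    samples, and BH-corrects across the candidate set.  Candidates whose
    carrier covariate violates proportional hazards fall back to a
    log-rank p-value (noted in the ``test`` column).
    """
    localized = [s for s in samples if s.state == "localized"]
    with_outcome = [s for s in localized if endpoint in s.outcomes]
    if localized and not with_outcome:
        raise KeyError(f"no localized sample carries endpoint {endpoint!r}")

    rows = []
    for res in differential:
        if res.flag is not None or not np.isfinite(res.q_value):
            continue
        if res.q_value >= alpha:
            continue
        try:
            prev = class_prevalence(
                matrix, res.mutation_type, samples=samples, state="localized"
            )
        except ValueError:
            continue
        if prev.p_hat < min_localized_prevalence:
            continue

        ids, carrier, t, e = [], [], [], []
        for s in with_outcome:
            cell = matrix.data.at[s.sample_id, res.mutation_type] \
                if s.sample_id in matrix.data.index else np.nan
            if np.isnan(cell):
                continue
            ids.append(s.sample_id)
            carrier.append(cell)
            time, event = s.outcomes[endpoint]
            t.append(time)
            e.append(int(event))
        row = {
            "mutation_type": res.mutation_type,
            "prevalence_localized": prev.p_hat,
            "differential_q": res.q_value,
            "n": len(ids),
            "n_events": int(sum(e)),
            "hr": float("nan"),
            "ci_low": float("nan"),
            "ci_high": float("nan"),
            "p": float("nan"),
            "test": "cox_wald",
        }
        cov = pd.DataFrame({"carrier": carrier}, index=ids)
        try:
            fit = cox_fit(cov, t, e)[0]
            row.update(hr=fit.hr, ci_low=fit.ci_low, ci_high=fit.ci_high,
                       p=fit.wald_p)
            if check_ph:
                ph_p = schoenfeld_ph_test(cov, t, e).get("carrier", float("nan"))
                if np.isfinite(ph_p) and ph_p < 0.05:
                    _, _, lr_p = km_logrank(t, e, np.asarray(carrier))
                    row.update(p=lr_p, test="logrank")
        except (ValueError, ConvergenceError) as exc:
            logger.warning("%s: Cox fit failed (%s); log-rank fallback",
                           res.mutation_type, exc)
            try:
                _, _, lr_p = km_logrank(t, e, np.asarray(carrier))
                row.update(p=lr_p, test="logrank")
            except ValueError:
                row.update(test="failed")
        rows.append(row)

    report = pd.DataFrame(rows)
    if report.empty:
        return pd.DataFrame(
            columns=["mutation_type", "prevalence_localized", "differential_q",
                     "n", "n_events", "hr", "ci_low", "ci_high", "p", "test",
                     "q", "selected"]
        )
    ok = report["p"].notna()
    report["q"] = np.nan
    if ok.any():
        report.loc[ok, "q"] = adjust_fdr(report.loc[ok, "p"].values)
    report["selected"] = report["q"] < alpha
    return report
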