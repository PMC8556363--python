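"""Kaplan-Meier/log-rank, Cox models, 2x2 association, candidate screen."""

import math

import numpy as np
import pandas as pd
import pytest

from driverdelta.catalog import SampleRecord
from driverdelta.differential import DifferentialResult
from driverdelta.survival import (
    ConvergenceError,
    cox_fit,
    km_logrank,
    schoenfeld_ph_test,
    screen_candidates,
    two_by_two,
)
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def test_km_single_group_equals_empirical_survival():
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.ones(5, dtype=int)
    curves, chi2, p = km_logrank(times, events, ["g"] * 5)
    curve = curves["g"].set_index("time")["survival"]
    for i, t in enumerate(times):
        assert curve.loc[t] == pytest.approx((5 - i - 1) / 5)
    assert math.isnan(chi2)


def test_km_curve_shape_properties():
    rng = np.random.default_rng(3)
    times = rng.exponential(10, size=50) + 0.01
    events = rng.integers(0, 2, size=50)
    events[0] = 1
    curves, _, _ = km_logrank(times, events, ["g"] * 50)
    surv = curves["g"]["survival"].values
    assert surv[0] <= 1.0 + 1e-12
    assert np.all(np.diff(surv) <= 1e-12)  # non-increasing


def test_logrank_identical_groups_null():
    times = np.array([1, 2, 3, 4, 1, 2, 3, 4], dtype=float)
    events = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    groups = np.array(["a"] * 4 + ["b"] * 4)
    _, chi2, p = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(0.0, abs=1e-9)
    assert p == pytest.approx(1.0, abs=1e-9)


def test_logrank_matches_hand_hypergeometric_tally():
    """Eight-patient toy: the statistic equals the classic O-E tally with
    hypergeometric variance, computed here step by step."""
    times = np.array([1, 2, 3, 4, 5, 6, 7, 8], dtype=float)
    events = np.array([1, 1, 1, 0, 1, 1, 0, 1])
    groups = np.array(["a", "b", "a", "b", "a", "b", "a", "b"])

    observed_a = expected_a = variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & (groups == "a")).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & (groups == "a")).sum()
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    chi2_hand = (observed_a - expected_a) ** 2 / variance

    _, chi2, _ = km_logrank(times, events, groups)
    assert chi2 == pytest.approx(chi2_hand, rel=1e-6)


def test_km_rejects_bad_input():
    with pytest.raises(ValueError):
        km_logrank([0.0, 1.0], [1, 1], ["a", "b"])


# ---------------------------------------------------------------------------
# Cox proportional hazards


def _exponential_cohort(rng, n=200, log_hr=1.0, p_carrier=0.3, censor_q=0.6):
    carrier = (rng.random(n) < p_carrier).astype(float)
    rate = 0.01 * np.exp(log_hr * carrier)
    t_event = rng.exponential(1.0 / rate)
    c = rng.uniform(0, np.quantile(t_event, censor_q), size=n)
    events = (t_event <= c).astype(int)
    times = np.minimum(t_event, c) + 1e-9
    return pd.DataFrame({"carrier": carrier}), times, events


def test_cox_null_covariate_near_unity(rng):
    cov, times, events = _exponential_cohort(rng, n=300, log_hr=0.0)
    res = cox_fit(cov, times, events)[0]
    assert abs(res.log_hr) < 3 * res.se
    assert res.ci_low <= res.hr <= res.ci_high


def test_cox_single_covariate_matches_grid_search_oracle():
    """1-D partial-likelihood grid search agrees with the solver."""
    times = np.array([2.0, 4.0, 5.0, 7.0, 9.0, 11.0, 13.0, 17.0])
    events = np.array([1, 1, 0, 1, 1, 0, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 1.0, 0.0])

    def neg_log_partial_likelihood(beta):
        ll = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
        return -ll

    grid = np.linspace(-4, 4, 16001)
    beta_grid = grid[np.argmin([neg_log_partial_likelihood(b) for b in grid])]
    res = cox_fit(pd.DataFrame({"x": x}), times, events)[0]
    assert res.log_hr == pytest.approx(beta_grid, abs=2e-3)


def test_cox_ties_options_and_time_rescaling(rng):
    cov, times, events = _exponential_cohort(rng, n=150, log_hr=0.8)
    efron = cox_fit(cov, times, events, ties="efron")[0]
    breslow = cox_fit(cov, times, events, ties="breslow")[0]
    assert efron.hr == pytest.approx(breslow.hr, rel=0.05)
    rescaled = cox_fit(cov, times * 12.0, events)[0]
    assert rescaled.log_hr == pytest.approx(efron.log_hr, abs=1e-6)


def test_cox_binary_label_swap_antisymmetry(rng):
    cov, times, events = _exponential_cohort(rng, n=200, log_hr=0.7)
    fwd = cox_fit(cov, times, events)[0]
    swapped = cox_fit(1.0 - cov, times, events)[0]
    assert swapped.log_hr == pytest.approx(-fwd.log_hr, abs=1e-6)


def test_cox_errors_on_degenerate_input(rng):
    cov, times, events = _exponential_cohort(rng, n=50)
    with pytest.raises(ValueError, match="constant"):
        cox_fit(pd.DataFrame({"c": np.ones(50)}), times, events)
    with pytest.raises(ValueError, match="event"):
        cox_fit(cov, times, np.zeros(50, dtype=int))


def test_cox_complete_separation_raises():
    """All carriers relapse before any non-carrier event: the partial
    likelihood is maximized at infinity and must be reported as such."""
    times = np.concatenate([np.arange(1, 19), np.arange(100, 130)]).astype(float)
    events = np.concatenate([np.ones(18), np.zeros(30)]).astype(int)
    carrier = np.concatenate([np.ones(18), np.zeros(30)])
    with pytest.raises(ConvergenceError):
        cox_fit(pd.DataFrame({"carrier": carrier}), times, events)


def test_schoenfeld_test_null_is_calm(rng):
    cov, times, events = _exponential_cohort(rng, n=250, log_hr=0.5)
    p = schoenfeld_ph_test(cov, times, events)["carrier"]
    assert 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# 2x2 association


@pytest.mark.parametrize(
    "a, b, c, d, or_expected, ci_low, ci_high",
    [
        (9, 27, 18, 323, 5.98, 2.45, 14.6),   # metastatic relapse carriers
        (20, 71, 38, 360, 2.67, 1.47, 4.85),  # progression carriers
    ],
)
def test_two_by_two_reproduces_reported_odds_ratios(
    a, b, c, d, or_expected, ci_low, ci_high
):
    res = two_by_two(a, b, c, d)
    assert round(res.odds_ratio, 2) == pytest.approx(or_expected)
    assert round(res.ci_low, 2) == pytest.approx(ci_low)
    assert float(f"{res.ci_high:.3g}") == pytest.approx(ci_high)
    assert res.fisher_p < 0.05


def test_two_by_two_null_table():
    res = two_by_two(10, 10, 10, 10)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.fisher_p == pytest.approx(1.0)


def test_two_by_two_zero_cell_haldane():
    res = two_by_two(0, 10, 5, 10)
    assert res.odds_ratio == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))
    assert np.isfinite(res.ci_low)


def test_two_by_two_margin_errors():
    with pytest.raises(ValueError):
        two_by_two(0, 0, 5, 5)
    with pytest.raises(ValueError):
        two_by_two(-1, 2, 3, 4)


def test_two_by_two_matches_cross_product_and_swap_invariance(rng):
    for _ in range(400):
        a, b, c, d = rng.integers(1, 50, size=4)
        res = two_by_two(a, b, c, d)
        assert res.odds_ratio == pytest.approx((a * d) / (b * c))
        swapped = two_by_two(d, c, b, a)  # simultaneous row and column swap
        assert swapped.odds_ratio == pytest.approx(res.odds_ratio)
        assert swapped.fisher_p == pytest.approx(res.fisher_p)


# ---------------------------------------------------------------------------
# candidate screen


def _screen_setup(rng, prevalence, hr, n=300, q=0.001):
    """Localized cohort with one candidate mutation at the requested
    prevalence whose carriers relapse at ``hr``-fold the baseline rate."""
    carrier = (rng.random(n) < prevalence).astype(float)
    rate = 0.01 * np.exp(math.log(hr) * carrier)
    t_event = rng.exponential(1.0 / rate)
    c = rng.uniform(0, np.quantile(t_event, 0.8), size=n)
    samples = []
    for i in range(n):
        t = max(min(t_event[i], c[i]), 1e-6)
        samples.append(
            SampleRecord(
                sample_id=f"S{i}", cohort="t", state="localized",
                snv_burden_per_mbp=1.0, pga=0.05,
                outcomes={"metastasis": (t, bool(t_event[i] <= c[i]))},
            )
        )
    matrix = make_matrix(
        {(f"S{i}", "G:CNA_loss"): carrier[i] for i in range(n)},
        [f"S{i}" for i in range(n)], ["G:CNA_loss"],
    )
    result = DifferentialResult(
        mutation_type="G:CNA_loss", gene_id="G", mclass="CNA_loss",
        n_mcrpc=100, n_localized=n, p_mcrpc=0.3, p_localized=prevalence,
        observed_delta=0.2, expected_delta=0.05, adjusted_delta=0.15,
        delta_ci_low=0.1, delta_ci_high=0.2, p_value=q, q_value=q,
        direction="enriched_mCRPC",
    )
    return [result], matrix, samples


def test_screen_retains_prognostic_candidate(rng):
    results, matrix, samples = _screen_setup(rng, prevalence=0.1, hr=4.0)
    report = screen_candidates(results, matrix, samples)
    assert len(report) == 1
    row = report.iloc[0]
    assert row["mutation_type"] == "G:CNA_loss"
    assert row["hr"] > 1.5
    assert bool(row["selected"])


def test_screen_prevalence_gate_excludes_rare_candidate(rng):
    results, matrix, samples = _screen_setup(rng, prevalence=0.03, hr=4.0)
    report = screen_candidates(results, matrix, samples)
    assert report.empty


def test_screen_skips_non_significant_differential(rng):
    results, matrix, samples = _screen_setup(rng, prevalence=0.1, hr=4.0)
    results[0].q_value = 0.5
    report = screen_candidates(results, matrix, samples)
    assert report.empty


def test_screen_empty_input_and_missing_endpoint(rng):
    results, matrix, samples = _screen_setup(rng, prevalence=0.1, hr=4.0)
    assert screen_candidates([], matrix, samples).empty
    with pytest.raises(KeyError):
        screen_candidates(results, matrix, samples, endpoint="overall")
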