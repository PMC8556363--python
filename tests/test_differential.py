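"""Burden-weighted Monte-Carlo null, empirical p-values, and FDR."""

import dataclasses
import math

import numpy as np
import pytest

from driverdelta.catalog import DriverCatalogEntry, GenomicInterval, SampleRecord
from driverdelta.differential import (
    NullModelConfig,
    adjust_fdr,
    delta_ci_yates,
    differential_table,
    empirical_pvalue,
    per_sample_hit_probability,
    simulate_null,
)
from driverdelta import synthetic as syn


def _sample(state="localized", burden=1.0, pga=0.05, ref="genome", sid="S1"):
    return SampleRecord(sample_id=sid, cohort="t", state=state,
                        snv_burden_per_mbp=burden, pga=pga,
                        burden_reference=ref)


def _snv_entry(footprint=0.002):
    return DriverCatalogEntry(gene_id="G", label="G", chromosome="1",
                              classes=frozenset({"SNV"}),
                              snv_footprint_mbp=footprint)


def _cna_entry(span=100_000):
    return DriverCatalogEntry(gene_id="G", label="G", chromosome="1",
                              classes=frozenset({"CNA_loss"}),
                              cna_footprint_bp=span)


# ---------------------------------------------------------------------------
# per-sample hit probability


def test_snv_hit_probability_closed_form():
    """b=10/Mbp over a 3000 Mbp genome and a 2 kb footprint gives
    30000 trials at p = 6.67e-7, so P(hit) ~ 1 - exp(-0.02)."""
    config = NullModelConfig(n_iter=100, genome_mbp=3000.0)
    p = per_sample_hit_probability(_sample(burden=10.0), _snv_entry(0.002),
                                   "SNV", config)
    expected = 1.0 - (1.0 - 0.002 / 3000.0) ** 30000
    assert p == pytest.approx(expected, rel=1e-12)
    assert p == pytest.approx(0.0198, abs=2e-4)


def test_zero_burden_gives_zero_probability():
    config = NullModelConfig(n_iter=100)
    assert per_sample_hit_probability(
        _sample(burden=0.0), _snv_entry(), "SNV", config) == 0.0
    assert per_sample_hit_probability(
        _sample(pga=0.0), _cna_entry(), "CNA_loss", config) == 0.0


def test_exome_reference_scales_trial_count():
    config = NullModelConfig(n_iter=100, exome_mbp=38.0)
    p_exome = per_sample_hit_probability(
        _sample(burden=2.0, ref="exome"), _snv_entry(0.002), "SNV", config)
    expected = 1.0 - (1.0 - 0.002 / 38.0) ** round(2.0 * 38.0)
    assert p_exome == pytest.approx(expected, rel=1e-12)


def test_cna_probability_monotone_in_pga():
    config = NullModelConfig(n_iter=100)
    probs = [
        per_sample_hit_probability(_sample(pga=v), _cna_entry(), "CNA_loss",
                                   config)
        for v in np.linspace(0.01, 1.0, 25)
    ]
    assert all(b >= a for a, b in zip(probs, probs[1:]))
    assert probs[-1] < 1.0  # segment process does not saturate


def test_oversized_footprint_errors():
    config = NullModelConfig(n_iter=100)
    with pytest.raises(ValueError):
        per_sample_hit_probability(_sample(burden=1.0, ref="exome"),
                                   _snv_entry(footprint=50.0), "SNV", config)


# ---------------------------------------------------------------------------
# null simulation


def test_simulate_null_matches_closed_form_expectation(rng):
    config = NullModelConfig(n_iter=20_000, seed=11)
    p_mut = rng.uniform(0.0, 0.4, size=60)
    states = np.array(["mCRPC"] * 25 + ["localized"] * 35)
    expected, sims = simulate_null(p_mut, states, config)
    analytic = p_mut[:25].mean() - p_mut[25:].mean()
    var = (p_mut[:25] * (1 - p_mut[:25])).sum() / 25**2 \
        + (p_mut[25:] * (1 - p_mut[25:])).sum() / 35**2
    se = math.sqrt(var / config.n_iter)
    assert abs(expected - analytic) < 3 * se


def test_simulate_null_reproducible_and_validated():
    config = NullModelConfig(n_iter=500, seed=42)
    p_mut = np.full(10, 0.2)
    states = np.array(["mCRPC"] * 5 + ["localized"] * 5)
    _, sims1 = simulate_null(p_mut, states, config)
    _, sims2 = simulate_null(p_mut, states, config)
    np.testing.assert_array_equal(sims1, sims2)
    with pytest.raises(ValueError):
        simulate_null(np.array([0.5, 1.2]), np.array(["mCRPC", "localized"]),
                      config)
    with pytest.raises(ValueError):
        simulate_null(p_mut, np.array(["mCRPC"] * 10), config)


# ---------------------------------------------------------------------------
# empirical p-value


def test_pvalue_at_null_mean_is_one(rng):
    sims = rng.normal(0.1, 0.02, size=1000)
    assert empirical_pvalue(sims.mean(), sims, "SNV") == 1.0


def test_pvalue_floor_and_cna_halving(rng):
    sims = rng.normal(0.0, 0.01, size=100_000)
    extreme = 1.0
    # beyond every simulated value: flooring at 1/n_iter
    assert empirical_pvalue(extreme, sims, "SNV") == pytest.approx(1e-5)
    # halving happens before the floor, so the floor still binds
    assert empirical_pvalue(extreme, sims, "CNA_loss") == pytest.approx(1e-5)
    # a mid-tail observation is halved for copy-number classes
    mid = np.quantile(np.abs(sims - sims.mean()), 0.9) + sims.mean()
    p_snv = empirical_pvalue(mid, sims, "SNV")
    p_cna = empirical_pvalue(mid, sims, "CNA_loss")
    assert p_cna == pytest.approx(p_snv / 2, rel=1e-9)


# ---------------------------------------------------------------------------
# FDR and delta CI


def test_bh_hand_computation():
    q = adjust_fdr([0.01, 0.02, 0.03])
    assert np.allclose(q, [0.03, 0.03, 0.03])
    assert adjust_fdr([0.05]) == pytest.approx([0.05])
    # tied minima propagate the same minimal q
    q = adjust_fdr([1e-5, 1e-5, 1e-5, 0.5])
    assert q[0] == q[1] == q[2]
    assert adjust_fdr([]).size == 0
    with pytest.raises(ValueError):
        adjust_fdr([0.0, 0.5])


def test_delta_ci_yates_arithmetic():
    low, high = delta_ci_yates(0.5, 100, 0.5, 100)
    half = 1.96 * math.sqrt(2 * 0.25 / 100) + 0.5 * 0.02
    assert high == pytest.approx(half, abs=1e-6)
    assert high == pytest.approx(0.1486, abs=1e-4)
    assert low == pytest.approx(-half, abs=1e-6)
    # degenerate proportions leave only the continuity term
    low, high = delta_ci_yates(0.0, 50, 0.0, 25)
    assert high == pytest.approx(0.5 * (1 / 50 + 1 / 25))
    # width shrinks with sample size
    w = [delta_ci_yates(0.3, n, 0.2, n)[1] - delta_ci_yates(0.3, n, 0.2, n)[0]
         for n in (10, 100, 1000)]
    assert w[0] > w[1] > w[2]


# ---------------------------------------------------------------------------
# full differential table


def _small_cohort(seed=5, delta=None, n_loc=80, n_met=40, n_genes=6):
    cfg = syn.SyntheticConfig(
        seed=seed, n_genes=n_genes, n_localized=n_loc, n_mcrpc=n_met,
        planted_delta=delta or {},
        null_model=NullModelConfig(n_iter=2000, seed=seed),
    )
    catalog = syn.make_catalog(cfg)
    samples = syn.generate_samples(cfg)
    truth = syn.make_truth(samples, catalog, cfg)
    matrix = syn.plant_mutations(samples, catalog, truth, cfg)
    return cfg, catalog, samples, matrix


def test_planted_gene_has_largest_adjusted_delta():
    cfg, catalog, samples, matrix = _small_cohort(
        seed=5, delta={"G002": 0.3})  # G002 carries the SNV class
    results = differential_table(matrix, samples, catalog, cfg.null_model)
    by_delta = sorted(results, key=lambda r: r.adjusted_delta, reverse=True)
    assert by_delta[0].gene_id == "G002"
    assert by_delta[0].q_value < 0.05
    assert by_delta[0].direction == "enriched_mCRPC"


def test_adjusted_delta_identity_and_flagging():
    cfg, catalog, samples, matrix = _small_cohort(seed=9)
    results = differential_table(matrix, samples, catalog, cfg.null_model)
    for r in results:
        assert r.adjusted_delta == r.observed_delta - r.expected_delta
        assert r.p_value >= cfg.null_model.p_floor
    # drop all metastatic assays for one column -> flagged row
    col = results[0].mutation_type
    for s in samples:
        if s.state == "mCRPC":
            matrix.data.loc[s.sample_id, col] = np.nan
    flagged = differential_table(matrix, samples, catalog, cfg.null_model)
    row = next(r for r in flagged if r.mutation_type == col)
    assert row.flag == "missing_state"
    assert math.isnan(row.p_value)


def test_state_label_swap_negates_all_deltas_exactly():
    """Antisymmetry: relabeling the cohorts flips observed, expected and
    adjusted differences with no Monte-Carlo slack."""
    cfg, catalog, samples, matrix = _small_cohort(seed=13)
    results = differential_table(matrix, samples, catalog, cfg.null_model)
    flip = {"localized": "mCRPC", "mCRPC": "localized"}
    swapped = [dataclasses.replace(s, state=flip[s.state], outcomes=dict())
               for s in samples]
    swapped_results = differential_table(matrix, swapped, catalog,
                                         cfg.null_model)
    for a, b in zip(results, swapped_results):
        assert b.observed_delta == -a.observed_delta
        assert b.expected_delta == -a.expected_delta
        assert b.adjusted_delta == -a.adjusted_delta
        assert b.p_value == a.p_value


def test_empty_catalog_yields_empty_table():
    cfg, catalog, samples, matrix = _small_cohort(seed=3)
    assert differential_table(matrix, samples, [], cfg.null_model) == []


def test_results_order_independent_of_column_position():
    """Per-mutation substreams make each row independent of the others,
    so removing a column leaves the remaining rows unchanged."""
    cfg, catalog, samples, matrix = _small_cohort(seed=21, n_genes=4)
    full = differential_table(matrix, samples, catalog, cfg.null_model)
    reduced_matrix = matrix
    reduced_matrix.data = matrix.data.drop(columns=[full[0].mutation_type])
    reduced = differential_table(reduced_matrix, samples, catalog,
                                 cfg.null_model)
    full_by_type = {r.mutation_type: r for r in full}
    for r in reduced:
        assert r.expected_delta == full_by_type[r.mutation_type].expected_delta


def test_cna_halving_doubles_null_rejection_rate():
    """The printed halving rule for copy-number classes doubles their
    nominal type-I error relative to the plain exceedance (each CNA
    direction is treated as its own one-direction test)."""
    from driverdelta.validation import cna_halving_rate_study

    result = cna_halving_rate_study(seed=2, n_genes=100, n_iter=2000)
    se = math.sqrt(0.1 * 0.9 / result["n_genes"])
    assert abs(result["type_i_rate"] - 0.1) < 4 * se
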