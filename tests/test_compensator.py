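"""Deviation forecasting, grid search and uniform compensation."""

import numpy as np
import pytest

from pumptwin import synthdata
from pumptwin.compensator import (
    CompensationPlan,
    DeviationSeries,
    ModelSpec,
    apply_plan,
    chronological_split,
    default_grid,
    fit,
    grid_search,
    make_plan,
    mape,
    rmse,
)
from pumptwin.deviation import InfusionRecord, deviation_report


def make_series(per_infusion, dose=2.0) -> DeviationSeries:
    return DeviationSeries(
        per_infusion_deviation=tuple(per_infusion),
        cumulative_deviation=tuple(np.cumsum(per_infusion)),
        commanded_dose=dose,
    )


@pytest.mark.parametrize(
    "actual,predicted,expected",
    [([1, 2], [1, 2], 0.0), ([2, 4], [1, 5], 37.5)],
)
def test_mape_worked_values(actual, predicted, expected):
    assert mape(actual, predicted) == pytest.approx(expected)


def test_mape_relative_scaling():
    actual = np.array([0.5, 2.0, 7.0])
    assert mape(actual, 1.1 * actual) == pytest.approx(10.0)


def test_mape_excludes_zero_targets():
    assert mape([0.0, 2.0], [5.0, 2.2]) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        mape([0.0, 0.0], [1.0, 1.0])


@pytest.mark.parametrize(
    "actual,predicted,expected",
    [([1, 2], [1, 2], 0.0), ([5, 5], [6, 4], 1.0), ([0, 0], [3, 4], 3.5355339)],
)
def test_rmse_worked_values(actual, predicted, expected):
    assert rmse(actual, predicted) == pytest.approx(expected, rel=1e-6)


def test_chronological_split_boundary():
    series = make_series([0.07] * 120)
    train, test = chronological_split(series, 0.85)
    assert len(train) == 102 and len(test) == 18
    # partition property: order preserved, disjoint, complete
    assert train + test == series.cumulative_deviation


def test_chronological_split_rejects_degenerate_fraction():
    series = make_series([0.07] * 120)
    with pytest.raises(ValueError):
        chronological_split(series, 0.999, window_length=10)


def test_series_prefix_sum_integrity():
    with pytest.raises(ValueError):
        DeviationSeries(
            per_infusion_deviation=(0.1, 0.1),
            cumulative_deviation=(0.1, 0.3),  # not the prefix sum
            commanded_dose=2.0,
        )


def test_series_from_records_requires_constant_dose():
    recs = [InfusionRecord(0, 2.0, 1.9), InfusionRecord(1, 3.0, 2.9)]
    with pytest.raises(ValueError):
        DeviationSeries.from_records(recs)


def test_series_from_records_builds_running_sum():
    recs = [InfusionRecord(i, 2.0, 1.95) for i in range(12)]
    series = DeviationSeries.from_records(recs)
    assert series.per_infusion_deviation == pytest.approx((0.05,) * 12)
    assert series.cumulative_deviation[-1] == pytest.approx(0.6)


def test_fit_constant_series_learns_trivially():
    """A constant per-infusion deficit is predicted to well under 1% MAPE."""
    series = make_series([0.07] * 120)
    result = fit(series, ModelSpec(epochs=150, seed=0))
    assert result.mape < 1.0


def test_fit_zero_epochs_finite_metrics():
    series = make_series([0.07] * 120)
    result = fit(series, ModelSpec(epochs=0, seed=0))
    assert np.isfinite(result.mape) and np.isfinite(result.rmse)
    assert result.train_curve == () and result.test_curve == ()


def test_fit_deterministic_under_seed(biased_series_spec):
    series = DeviationSeries.from_records(synthdata.generate_infusions(biased_series_spec))
    r1 = fit(series, ModelSpec(epochs=40, seed=3))
    r2 = fit(series, ModelSpec(epochs=40, seed=3))
    assert r1 == r2


def test_fit_training_loss_plateaus(biased_series_spec):
    """Smoothed (window 10) training loss is nonincreasing — no divergence."""
    series = DeviationSeries.from_records(synthdata.generate_infusions(biased_series_spec))
    result = fit(series, ModelSpec(epochs=150, seed=0))
    curve = np.asarray(result.train_curve)
    smoothed = np.convolve(curve, np.ones(10) / 10, mode="valid")
    assert np.all(np.diff(smoothed) <= 1e-6)


def test_fit_curves_have_epoch_length(biased_series_spec):
    series = DeviationSeries.from_records(synthdata.generate_infusions(biased_series_spec))
    result = fit(series, ModelSpec(epochs=25, seed=0))
    assert len(result.train_curve) == 25
    assert len(result.test_curve) == 25
    assert len(result.test_accuracy) == 25


def test_fit_rejects_short_series():
    with pytest.raises(ValueError):
        fit(make_series([0.1] * 5), ModelSpec())


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(layer_pattern="LD")  # too short
    with pytest.raises(ValueError):
        ModelSpec(layer_pattern="LXD")
    with pytest.raises(ValueError):
        ModelSpec(train_fraction=1.0)


def test_default_grid_is_the_16_cell_lattice():
    grid = default_grid()
    assert len(grid) == 16
    assert {s.epochs for s in grid} == {100, 300, 500, 700}
    assert {s.batch_size for s in grid} == {128, 256}
    assert {s.hidden_units for s in grid} == {32, 64}


def test_grid_search_single_cell():
    series = make_series([0.07] * 120)
    cell = ModelSpec(epochs=10, seed=0)
    results = grid_search(series, [cell])
    assert len(results) == 1 and results[0].spec == cell


def test_grid_search_ranking(biased_series_spec):
    """Results come back sorted by MAPE, RMSE, then fewer epochs, with
    failed cells last."""
    series = DeviationSeries.from_records(synthdata.generate_infusions(biased_series_spec))
    grid = [
        ModelSpec(epochs=5, hidden_units=8, seed=0),
        ModelSpec(epochs=30, hidden_units=8, seed=0),
        ModelSpec(epochs=30, hidden_units=8, seed=0, train_fraction=0.99),  # infeasible split
    ]
    results = grid_search(series, grid)
    assert results[-1].failed
    keys = [(r.mape, r.rmse, r.spec.epochs) for r in results if not r.failed]
    assert keys == sorted(keys)


def test_make_plan_conservation():
    plan = make_plan(12.0, 120)
    assert plan.per_infusion_compensation == pytest.approx(0.1)
    assert plan.per_infusion_compensation * plan.n_infusions == plan.predicted_total_deviation
    zero = make_plan(0.0, 7)
    assert zero.per_infusion_compensation == 0.0


def test_apply_plan_zero_is_identity():
    recs = [InfusionRecord(i, 2.0, 1.9) for i in range(5)]
    assert apply_plan(recs, make_plan(0.0, 5)) == recs


def test_apply_plan_count_mismatch():
    recs = [InfusionRecord(i, 2.0, 1.9) for i in range(5)]
    with pytest.raises(ValueError):
        apply_plan(recs, make_plan(1.0, 6))


def test_bias_recovery_and_compensation_improves_accuracy(biased_series_spec):
    """End-to-end: on the seeded under-delivery run the plan recovers the
    per-infusion bias within two standard errors, and re-delivering with
    the raised commands cuts the mean deviation."""
    spec = biased_series_spec
    records = synthdata.generate_infusions(spec)
    series = DeviationSeries.from_records(records)
    result = fit(series, ModelSpec(epochs=150, seed=0))
    plan = make_plan(result.predicted_final_cumulative, spec.n_infusions)

    true_bias = spec.bias_fraction * spec.commanded_dose
    se = spec.noise_sd / np.sqrt(spec.n_infusions)
    assert plan.per_infusion_compensation == pytest.approx(true_bias, abs=2 * se)

    compensated = apply_plan(records, plan)
    redelivered = synthdata.simulate_delivery(
        [r.commanded_dose for r in compensated],
        synthdata.GeneratorSpec(
            n_infusions=spec.n_infusions, commanded_dose=spec.commanded_dose,
            bias_fraction=spec.bias_fraction, noise_sd=spec.noise_sd, seed=spec.seed + 1,
        ),
    )
    after = [
        InfusionRecord(i, spec.commanded_dose, float(d)) for i, d in enumerate(redelivered)
    ]
    assert (
        deviation_report(after).mean_deviation
        < deviation_report(records).mean_deviation
    )
    # compensation must not overshoot into a larger opposite-sign bias
    signed_after = np.mean(
        [spec.commanded_dose - r.delivered_dose for r in after]
    )
    noise_floor = spec.noise_sd + 2 * se
    assert signed_after > -noise_floor
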