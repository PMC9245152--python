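import numpy as np
import pandas as pd
import pytest

import survfunnel as sf


def test_no_losses_gives_zero_probabilities(make_cohort):
    cohort = make_cohort(seed=21, n_centers=3, size=30)
    df = cohort.data.copy()
    # everyone either dies or completes follow-up
    lost = (df["status"] == 0) & (df["time"] < cohort.horizon)
    df.loc[lost, "time"] = cohort.horizon
    cohort = sf.Cohort(df, ["x"], cohort.horizon)
    results, model, pooled = sf.followup_analysis(cohort)
    probs = sf.followup_probabilities(model, pooled, cohort)
    np.testing.assert_allclose(probs, 0.0, atol=1e-12)
    assert (results["O"] == 0).all()


def test_no_mortality_reduces_to_one_minus_G(make_cohort):
    cohort = make_cohort(seed=22, n_centers=3, size=40)
    pooled = sf.censoring_curves(cohort, pooled=True)
    # S identically 1: a model with no event hazard at all
    model = sf.import_benchmark({"x": 0.0}, [])
    probs = sf.followup_probabilities(model, pooled, cohort)
    expected = 1.0 - float(pooled.G(cohort.horizon))
    np.testing.assert_allclose(probs, expected, atol=1e-12)


def test_scalar_matches_vectorized(make_cohort):
    cohort = make_cohort(seed=23, n_centers=4, size=30)
    model = sf.fit_benchmark(cohort, stratify_by_center=True)
    pooled = sf.censoring_curves(cohort, pooled=True)
    probs = sf.followup_probabilities(model, pooled, cohort)
    for i in [0, 17, 55, 119]:
        row = cohort.data.iloc[i]
        p = sf.compute_followup_probability(
            model, pooled, [row["x"]], cohort.horizon, center=row["center"]
        )
        assert p == pytest.approx(probs[i], abs=1e-10)


def test_exponential_closed_form():
    """Exponential mortality h and loss hazard c on dense grids:
    p~ -> c/(h+c) (1 - exp(-(h+c) tau))."""
    h, c, tau = 0.08, 0.05, 12.0
    delta = 0.002
    grid = np.arange(delta, tau + delta / 2, delta)
    model = sf.import_benchmark(
        {"x": 0.0}, np.column_stack([grid, np.full(grid.size, h * delta)])
    )
    haz = 1 - np.exp(-c * delta)
    # offset the loss grid so survival and loss jumps never coincide
    cgrid = grid + delta / 2
    curve = sf.CensoringCurve(
        cgrid, np.full(grid.size, haz), np.cumprod(np.full(grid.size, 1 - haz)),
        horizon=tau,
    )
    p = sf.compute_followup_probability(model, curve, [0.0], tau)
    closed = c / (h + c) * (1 - np.exp(-(h + c) * tau))
    assert p == pytest.approx(closed, abs=2e-3)

    rng = np.random.default_rng(77)
    n = 500_000
    t_event = rng.exponential(1 / h, n)
    t_cens = rng.exponential(1 / c, n)
    mc = ((t_cens < t_event) & (t_cens < tau)).mean()
    se = np.sqrt(mc * (1 - mc) / n)
    assert abs(p - mc) < 3 * se + 2e-3


def test_conservation_of_probability():
    """p + p~ + P(alive and under follow-up at tau) = 1 exactly when the
    event and loss jump grids are disjoint (product-limit forms)."""
    model = sf.import_benchmark({"x": 0.3}, [[1.0, 0.05], [3.0, 0.1], [7.0, 0.2]])
    curve = sf.CensoringCurve(
        np.array([2.0, 5.0, 9.0]),
        np.array([0.1, 0.2, 0.15]),
        np.cumprod([0.9, 0.8, 0.85]),
        horizon=12.0,
    )
    for x in [[-1.0], [0.0], [2.0]]:
        tau = 12.0
        p = sf.compute_event_probability(model, curve, x, tau)
        pt = sf.compute_followup_probability(model, curve, x, tau)
        risk = np.exp(model.linear_predictor(np.asarray(x)))
        s_tau = np.prod(1 - np.minimum(1, risk * model.baseline_jumps))
        g_tau = float(curve.G(tau))
        assert p + pt + s_tau * g_tau == pytest.approx(1.0, abs=1e-12)


def test_role_reversal_symmetry(make_cohort):
    """With no covariate effect and no stratification, swapping the status
    codes turns the mortality funnel into the follow-up funnel."""
    cohort = make_cohort(seed=25, n_centers=4, size=50)
    config = sf.FunnelConfig(pooled_censoring=True)

    # follow-up funnel with an unstratified null event model
    null_model = sf.fit_benchmark(cohort, covariates=[])
    pooled = sf.censoring_curves(cohort, pooled=True)
    pt = sf.followup_probabilities(null_model, pooled, cohort)
    fu = sf.followup_center_summary(pt, cohort, config)

    # mortality funnel on the status-swapped cohort
    df = cohort.data.copy()
    swapped_status = np.where(
        (df["status"] == 0) & (df["time"] < cohort.horizon), 1, 0
    )
    df["status"] = swapped_status
    swapped = sf.Cohort(df, ["x"], cohort.horizon)
    model_sw = sf.fit_benchmark(swapped, covariates=[])
    curve_sw = sf.censoring_curves(swapped, pooled=True)
    p_sw = sf.event_probabilities(model_sw, curve_sw, swapped, config)
    mort = sf.center_summary(p_sw, swapped, config)

    merged = fu.merge(mort, on="center", suffixes=("_fu", "_sw"))
    np.testing.assert_array_equal(merged["O_fu"], merged["O_sw"])
    np.testing.assert_allclose(merged["E_fu"], merged["E_sw"], rtol=1e-7)
    np.testing.assert_allclose(merged["V_fu"], merged["V_sw"], rtol=1e-7)


def test_followup_counts_exclude_horizon_survivors():
    df = pd.DataFrame(
        {
            "center": ["A"] * 4,
            "time": [12.0, 12.0, 5.0, 3.0],
            "status": [0, 1, 0, 1],
            "x": [0.0, 0.1, -0.1, 0.2],
        }
    )
    cohort = sf.Cohort(df, ["x"], 12.0)
    results, _, _ = sf.followup_analysis(cohort)
    assert results["O"].iloc[0] == 1  # only the loss at t=5


def test_followup_center_summary_uses_loss_fraction_as_p0(make_cohort):
    cohort = make_cohort(seed=26, n_centers=3, size=40)
    results, _, _ = sf.followup_analysis(cohort)
    lost = (cohort.statuses == 0) & (cohort.times < cohort.horizon)
    assert results.attrs["p0"] == pytest.approx(lost.mean())
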