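import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import survfunnel as sf
from survfunnel.engine import _probs_dense, _probs_fast


# ---------------------------------------------------------------------------
# event probabilities
# ---------------------------------------------------------------------------

def test_no_censoring_telescoping_identity(sim_cohort):
    """With G identically 1 the product-limit sum telescopes exactly to
    1 - S_ij(tau)."""
    model = sf.fit_benchmark(sim_cohort)
    tau = sim_cohort.horizon
    for x in [[-1.0], [0.0], [1.3]]:
        p = sf.compute_event_probability(model, None, x, tau)
        risk = np.exp(model.linear_predictor(np.asarray(x)))
        keep = model.baseline_times <= tau
        s_tau = np.prod(1 - np.minimum(1, risk * model.baseline_jumps[keep]))
        assert p == pytest.approx(1 - s_tau, abs=1e-12)


def test_empty_baseline_or_zero_horizon_gives_zero():
    model = sf.import_benchmark({"x": 0.5}, [])
    assert sf.compute_event_probability(model, None, [1.0], tau=12.0) == 0.0
    model2 = sf.import_benchmark({"x": 0.5}, [[5.0, 0.1]])
    assert sf.compute_event_probability(model2, None, [1.0], tau=0.0) == 0.0


def test_exponential_closed_form_and_monte_carlo():
    """Exponential event hazard h and censoring hazard c on a dense grid:
    p -> h/(h+c) (1 - exp(-(h+c) tau)), also verified by simulation."""
    h, c, tau = 0.10, 0.05, 12.0
    delta = 0.002
    grid = np.arange(delta, tau + delta / 2, delta)
    model = sf.import_benchmark({"x": 0.0}, np.column_stack([grid, np.full(grid.size, h * delta)]))
    haz = 1 - np.exp(-c * delta)
    curve = sf.CensoringCurve(
        grid, np.full(grid.size, haz), np.cumprod(np.full(grid.size, 1 - haz)),
        horizon=tau,
    )
    p = sf.compute_event_probability(model, curve, [0.0], tau)
    closed = h / (h + c) * (1 - np.exp(-(h + c) * tau))
    assert p == pytest.approx(closed, abs=2e-3)

    rng = np.random.default_rng(2024)
    n = 1_000_000
    t_event = rng.exponential(1 / h, n)
    t_cens = rng.exponential(1 / c, n)
    mc = ((t_event < t_cens) & (t_event < tau)).mean()
    se = np.sqrt(mc * (1 - mc) / n)
    assert abs(p - mc) < 3 * se + 2e-3


def test_fast_path_matches_dense(make_cohort):
    # large enough that every per-jump hazard is small and the series
    # error bound admits the telescoped path
    cohort = make_cohort(seed=11, n_centers=4, size=600)
    model = sf.fit_benchmark(cohort)
    curves = sf.censoring_curves(cohort)
    tau = cohort.horizon
    keep = model.baseline_times <= tau
    bt, bj = model.baseline_times[keep], model.baseline_jumps[keep]
    lp = np.atleast_1d(model.linear_predictor(cohort.covariate_matrix()))
    centers = cohort.data["center"].to_numpy()
    for center, curve in curves.items():
        idx = centers == center
        fast = _probs_fast(bt, bj, lp[idx], curve, tau)
        dense = _probs_dense(bt, bj, lp[idx], curve, "product_limit")
        assert fast is not None
        ok = ~np.isnan(fast)
        assert ok.mean() > 0.9  # nearly every subject passes the error gate
        np.testing.assert_allclose(fast[ok], dense[ok], atol=1e-8)


def test_event_probabilities_bounds_and_order(sim_cohort):
    model = sf.fit_benchmark(sim_cohort)
    curves = sf.censoring_curves(sim_cohort)
    p = sf.event_probabilities(model, curves, sim_cohort)
    assert ((p >= 0) & (p <= 1)).all()
    # censoring can only remove probability mass relative to no censoring
    p_nocens = sf.event_probabilities(model, None, sim_cohort)
    assert (p <= p_nocens + 1e-12).all()


def test_survival_form_exp_cumhaz_close_to_product_limit(sim_cohort):
    model = sf.fit_benchmark(sim_cohort)
    curves = sf.censoring_curves(sim_cohort)
    p_pl = sf.event_probabilities(model, curves, sim_cohort, sf.FunnelConfig())
    p_ch = sf.event_probabilities(
        model, curves, sim_cohort, sf.FunnelConfig(survival_form="exp_cumhaz")
    )
    np.testing.assert_allclose(p_pl, p_ch, atol=0.02)


# ---------------------------------------------------------------------------
# Poisson-binomial inference
# ---------------------------------------------------------------------------

def test_poisson_binomial_examples():
    assert sf.poisson_binomial_pvalue([0.5, 0.5], 0) == pytest.approx(0.5)
    assert sf.poisson_binomial_pvalue([0.0, 0.0], 0) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sf.poisson_binomial_pvalue([0.5], 2)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_poisson_binomial_dp_equals_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 13))
    p = rng.uniform(0, 1, n)
    pmf = sf.poisson_binomial_pmf(p)
    brute = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        prob = np.prod(np.where(bits, p, 1 - p))
        brute[sum(bits)] += prob
    np.testing.assert_allclose(pmf, brute, atol=1e-12)


def test_poisson_binomial_matches_scipy():
    rng = np.random.default_rng(7)
    p = rng.uniform(0, 1, 40)
    pmf = sf.poisson_binomial_pmf(p)
    ref = stats.poisson_binom(p).pmf(np.arange(41))
    np.testing.assert_allclose(pmf, ref, atol=1e-12)


def test_exact_and_normal_pvalues_agree_for_large_centers():
    # close agreement in the decision-relevant tails; the doubled-tail
    # convention keeps a small discreteness gap near the center
    rng = np.random.default_rng(8)
    p = rng.uniform(0.1, 0.5, 400)  # E ~ 120
    E, sd = p.sum(), np.sqrt((p * (1 - p)).sum())
    for o in range(int(E - 3 * sd), int(E + 3 * sd)):
        exact = sf.poisson_binomial_pvalue(p, o)
        z = (o - E) / sd
        normal = 2 * stats.norm.sf(abs(z))
        # mid-range gap is discreteness: about one pmf mass ~ 1/sd
        tol = 0.01 if abs(z) >= 2 else 0.05
        assert abs(exact - normal) < tol


# ---------------------------------------------------------------------------
# effective sample size and funnel geometry
# ---------------------------------------------------------------------------

def test_effective_sample_size():
    assert sf.effective_sample_size(1.0, 0.5, 0.5) == pytest.approx(2.0)
    # homogeneous p_ij = p0 recovers the raw center size exactly
    n_i, p0 = 37, 0.3
    E, V = n_i * p0, n_i * p0 * (1 - p0)
    assert sf.effective_sample_size(E, V, p0) == pytest.approx(n_i)
    with pytest.raises(ValueError):
        sf.effective_sample_size(1.0, 0.5, 1.0)


def test_ess_additive_under_center_split():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.05, 0.6, 50)
    p0 = 0.25
    whole = sf.effective_sample_size(p.sum(), (p * (1 - p)).sum(), p0)
    e1, v1 = p[:20].sum(), (p[:20] * (1 - p[:20])).sum()
    e2, v2 = p[20:].sum(), (p[20:] * (1 - p[20:])).sum()
    # E and V are sums over subjects, so ESS recombines exactly
    recombined = sf.effective_sample_size(e1 + e2, v1 + v2, p0)
    assert recombined == pytest.approx(whole)


def test_funnel_limit_values_and_monotonicity():
    lim = sf.funnel_limits([1.96 ** 2], p0=0.5, alpha=0.05)
    assert lim["upper"].iloc[0] == pytest.approx(2.0, abs=1e-4)
    x = np.geomspace(1, 1e5, 50)
    lim = sf.funnel_limits(x, p0=0.3, alpha=0.05, alpha_adjusted=0.001)
    assert (np.diff(lim["upper"]) < 0).all() and (np.diff(lim["lower"]) > 0).all()
    assert lim["upper"].iloc[-1] == pytest.approx(1.0, abs=0.02)
    assert (lim["upper_adj"] >= lim["upper"]).all()


def test_classification_equals_funnel_geometry(sim_cohort):
    """|Z| > z_{1-a/2} iff the (ESS, O/E) point falls outside the curves —
    an exact algebraic equivalence."""
    results, _, _ = sf.funnel_analysis(sim_cohort)
    p0 = results.attrs["p0"]
    tested = results[results["tested"]]
    lim = sf.funnel_limits(tested["ess"].to_numpy(), p0, results.attrs["alpha"])
    outside = (tested["oe_ratio"].to_numpy() > lim["upper"].to_numpy() + 1e-12) | (
        tested["oe_ratio"].to_numpy() < lim["lower"].to_numpy() - 1e-12
    )
    flagged = (tested["class_alpha"] != "target").to_numpy()
    np.testing.assert_array_equal(outside, flagged)


# ---------------------------------------------------------------------------
# center summaries
# ---------------------------------------------------------------------------

def test_center_summary_arithmetic():
    df = pd.DataFrame(
        {"center": ["A", "A"], "time": [3.0, 5.0], "status": [1, 1],
         "x": [0.0, 0.0]}
    )
    cohort = sf.Cohort(df, ["x"], 12.0)
    res = sf.center_summary(np.array([0.5, 0.5]), cohort)
    row = res.iloc[0]
    assert row["O"] == 2 and row["E"] == pytest.approx(1.0)
    assert row["V"] == pytest.approx(0.5)
    assert row["Z"] == pytest.approx(np.sqrt(2.0))
    assert row["oe_ratio"] == pytest.approx(2.0)


def test_center_on_target(sim_cohort):
    results, _, _ = sf.funnel_analysis(sim_cohort)
    # O == E would give Z = 0; verify the classification rule directly
    near = results.loc[results["tested"]].iloc[0]
    assert near["class_alpha"] in {"over", "target", "under"}
    zero_z = results[results["Z"].abs() < 1e-9]
    assert (zero_z["class_alpha"] == "target").all()


def test_center_invariants(sim_cohort):
    results, _, _ = sf.funnel_analysis(sim_cohort)
    assert (results["O"] <= results["n"]).all()
    assert (results["V"] <= results["E"] + 1e-12).all()
    assert (results["E"] <= results["n"] + 1e-12).all()
    assert (results.loc[results["tested"], "exact_p"] > 0).all()
    assert (results.loc[results["tested"], "exact_p"] <= 1).all()


def test_null_coverage_about_95_percent():
    """On null-simulated multi-center data ~5% of centers exceed the
    unadjusted limits (within 3 binomial standard errors)."""
    spec = sf.scenario("base", n_centers=50, n_replications=4)
    summary = sf.run_scenario(spec, seed=123)
    frac_out = 100.0 - summary.pct_target
    se = 100 * np.sqrt(0.05 * 0.95 / summary.n_centers_total)
    assert abs(frac_out - 5.0) < 3 * se + 1e-9


def test_untested_center_flagged():
    df = pd.DataFrame(
        {"center": ["A", "B"], "time": [3.0, 4.0], "status": [1, 1], "x": [0.0, 0.0]}
    )
    cohort = sf.Cohort(df, ["x"], 12.0)
    res = sf.center_summary(np.array([0.5, 0.0]), cohort)
    assert not res.loc[res["center"] == "B", "tested"].iloc[0]
    assert res.loc[res["center"] == "B", "class_alpha"].iloc[0] == "untested"
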