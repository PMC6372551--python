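"""Cohort statistics: rank tests, correlations, OLS, effect size, power,
percentile exclusion."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pinealnorm import (
    PowerSpec,
    SimulationConfig,
    apply_exclusions,
    cohens_d,
    correlate,
    fit_linear_model,
    generate_cohort,
    mann_whitney,
    power,
    required_n,
)


def mw_enumeration_z(a, b):
    """Exact permutation oracle: the null mean and variance of U from
    exhaustive enumeration of all group-A assignments of the pooled
    midranks, and the resulting z of the observed U (sign: positive when
    b exceeds a)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n_a, n = len(a), len(a) + len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    offset = n_a * (n_a + 1) / 2.0
    us = np.array([ranks[list(idx)].sum() - offset for idx in combinations(range(n), n_a)])
    u_obs = ranks[:n_a].sum() - offset
    var = us.var()
    if var == 0:
        return us.mean(), 0.0, 0.0
    return us.mean(), var, (us.mean() - u_obs) / np.sqrt(var)


# -- Mann-Whitney -----------------------------------------------------------


def test_identical_samples_give_null_result():
    out = mann_whitney([1, 2, 3, 4], [4, 3, 2, 1])
    assert out.z == 0.0 and out.p == 1.0


def test_separated_samples_reference_value():
    out = mann_whitney([1, 2, 3], [4, 5, 6])
    assert out.u == 0.0
    assert abs(out.z) == pytest.approx(1.9640, abs=5e-5)
    # exhaustive enumeration over all 20 arrangements
    mu, var, z = mw_enumeration_z([1, 2, 3], [4, 5, 6])
    assert mu == pytest.approx(4.5) and var == pytest.approx(5.25)
    assert out.z == pytest.approx(z)
    assert out.z > 0  # b stochastically exceeds a


def test_all_tied_degenerates_gracefully():
    out = mann_whitney([5, 5, 5], [5, 5])
    assert out.z == 0.0 and out.p == 1.0


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 5), min_size=1, max_size=6),
    st.lists(st.integers(0, 5), min_size=1, max_size=6),
)
def test_mw_matches_exhaustive_enumeration(a, b):
    """The tie-corrected normal-approximation z equals the z formed from
    the exact permutation mean and variance of U, for all small samples
    (integer values force heavy ties)."""
    if len(a) + len(b) > 10:
        a, b = a[:5], b[:5]
    out = mann_whitney(a, b)
    _, _, z = mw_enumeration_z(a, b)
    assert out.z == pytest.approx(z, abs=1e-10)


def test_mw_agrees_with_scipy(rng):
    a = rng.normal(0, 1, 40)
    b = rng.normal(0.5, 1, 55)
    out = mann_whitney(a, b)
    ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    assert out.p == pytest.approx(ref.pvalue, rel=1e-9)


def test_mw_u_bounds(rng):
    a, b = rng.normal(size=12), rng.normal(size=9)
    out = mann_whitney(a, b)
    assert 0 <= out.u <= out.n_a * out.n_b
    assert 0 <= out.p <= 1


# -- correlations -----------------------------------------------------------


def test_perfect_linearity():
    x = np.arange(10.0)
    out = correlate(x, 2 * x + 1)
    assert out["r"] == pytest.approx(1.0)
    assert out["r_squared"] == pytest.approx(1.0)


def test_independent_samples_near_zero(rng):
    x, y = rng.normal(size=5000), rng.normal(size=5000)
    assert abs(correlate(x, y)["r"]) < 0.05  # ~2/sqrt(n) bound


def test_spearman_rank_invariance(rng):
    x = rng.uniform(0.1, 5, 50)
    assert correlate(x, np.exp(x), method="spearman")["r"] == pytest.approx(1.0)


def test_pearson_affine_invariance(rng):
    x, y = rng.normal(size=100), rng.normal(size=100)
    r1 = correlate(x, y)["r"]
    r2 = correlate(3 * x + 2, -0.5 * y + 7)["r"]
    assert r1 == pytest.approx(-r2, abs=1e-12)


def test_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        correlate([1, 1, 1], [1, 2, 3])


# -- linear model -----------------------------------------------------------


def _frame_with_outcome(rng, n=30):
    groups = rng.choice(["ASD", "relative", "control"], n)
    return pd.DataFrame({
        "id": [f"P{i}" for i in range(n)],
        "group": groups,
        "sex": rng.choice(["male", "female"], n),
        "age": rng.uniform(5, 60, n),
        "iq": rng.normal(100, 15, n),
        "srs": rng.normal(50, 10, n),
        "melatonin_nM": rng.lognormal(-2, 0.5, n),
        "pgv_mm3": rng.uniform(50, 180, n),
        "tbv_cm3": rng.normal(1150, 100, n),
    })


def test_single_regressor_exact():
    rng = np.random.default_rng(3)
    frame = _frame_with_outcome(rng)
    frame["melatonin_nM"] = np.exp(3.0 * frame["age"])  # log outcome = 3*age
    res = fit_linear_model(frame, terms={"main": ["age"]})
    assert res.params["age"] == pytest.approx(3.0, abs=1e-8)
    assert res.rsquared == pytest.approx(1.0)


def test_coefficients_match_pseudoinverse_oracle(rng):
    frame = _frame_with_outcome(rng, n=30)
    res = fit_linear_model(frame, terms={"main": ["group", "age", "iq", "tbv_cm3"]})
    X = res.design_matrix().to_numpy()
    y = np.log(frame["melatonin_nM"].to_numpy())
    beta = np.linalg.pinv(X) @ y
    assert np.allclose(res.params.to_numpy(), beta, atol=1e-8)


def test_planted_group_effect_detected(rng):
    # melatonin deficit planted per group, no PGV dependence (slope 0)
    cfg = SimulationConfig(seed=11, slope=0.0)
    cohort = generate_cohort(cfg)  # study-scale n = 215
    res = fit_linear_model(cohort, terms={"main": ["group", "pgv_mm3"]})
    pvals = {t: res.anova.loc[t, "PR(>F)"] for t in res.anova.index if t != "Residual"}
    group_term = next(t for t in pvals if "group" in t)
    assert pvals[group_term] < 0.01
    assert pvals["pgv_mm3"] > 0.05


def test_rank_deficient_design_named():
    rng = np.random.default_rng(5)
    frame = _frame_with_outcome(rng)
    frame["tbv_cm3"] = 2.0 * frame["age"]  # exact collinearity
    with pytest.raises(ValueError, match="collinear"):
        fit_linear_model(frame, terms={"main": ["age", "tbv_cm3"]})


def test_too_few_observations_rejected(rng):
    frame = _frame_with_outcome(rng, n=12)
    with pytest.raises(ValueError, match="observations"):
        fit_linear_model(frame)  # default terms need > 18 columns worth


def test_default_terms_run_at_study_scale(default_cohort):
    res = fit_linear_model(default_cohort)
    assert 0.0 <= res.rsquared <= 1.0
    assert res.df_num + res.df_den + 1 == len(default_cohort)


# -- effect size and power --------------------------------------------------


def test_cohens_d_zero_for_identical():
    assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0


def test_cohens_d_sign_and_magnitude(rng):
    a = rng.normal(0, 1, 20000)
    b = rng.normal(1, 1, 20000)
    assert cohens_d(a, b) == pytest.approx(-1.0, abs=0.05)


def test_cohens_d_degenerate():
    with pytest.raises(ValueError, match="pooled SD"):
        cohens_d([0, 0], [1, 1])


def test_required_n_textbook_value():
    assert required_n(PowerSpec(d=1.0)) == 17  # canonical two-sample value


def test_required_n_matches_statsmodels():
    from statsmodels.stats.power import TTestIndPower, TTestPower

    for d in (0.5, 0.8, 1.46):
        ref = int(np.ceil(TTestIndPower().solve_power(effect_size=d, alpha=0.05, power=0.8)))
        assert required_n(PowerSpec(d=d)) == ref
    ref1 = int(np.ceil(TTestPower().solve_power(effect_size=0.5, alpha=0.05, power=0.8)))
    assert required_n(PowerSpec(d=0.5, design="one_sample")) == ref1


def test_required_n_monotone():
    ns_by_d = [required_n(PowerSpec(d=d)) for d in (0.3, 0.6, 1.0, 1.5)]
    assert ns_by_d == sorted(ns_by_d, reverse=True)
    ns_by_power = [required_n(PowerSpec(d=0.8, power=p)) for p in (0.5, 0.8, 0.95)]
    assert ns_by_power == sorted(ns_by_power)


def test_required_n_floor_case():
    assert required_n(PowerSpec(d=2.0, power=0.05)) == 2  # minimum admissible df


def test_required_n_unreachable():
    with pytest.raises(ValueError, match="d = 0"):
        required_n(PowerSpec(d=0.0))


def test_unequal_allocation_needs_fewer_in_a():
    n_eq = required_n(PowerSpec(d=0.8))
    n_ratio = required_n(PowerSpec(d=0.8, design="two_sample_ratio", ratio=3.0))
    assert n_ratio < n_eq


# -- exclusions -------------------------------------------------------------


def test_extreme_record_excluded(rng):
    frame = _frame_with_outcome(rng, n=100)
    frame.loc[42, "pgv_mm3"] = 10 * frame["pgv_mm3"].median()
    out = apply_exclusions(frame)
    assert list(out["excluded"]["id"]) == [frame.loc[42, "id"]]
    assert len(out["kept"]) == 99
    assert "99th percentile" in out["reasons"][frame.loc[42, "id"]]


def test_all_equal_pgv_none_excluded(rng):
    frame = _frame_with_outcome(rng, n=50)
    frame["pgv_mm3"] = 100.0
    out = apply_exclusions(frame)
    assert len(out["excluded"]) == 0


def test_small_sample_skips_with_warning(rng):
    frame = _frame_with_outcome(rng, n=5)
    with pytest.warns(RuntimeWarning, match="skipped"):
        out = apply_exclusions(frame)
    assert len(out["kept"]) == 5


def test_exclusion_count_bounded(rng):
    frame = _frame_with_outcome(rng, n=500)
    out = apply_exclusions(frame)
    assert len(out["excluded"]) <= int(np.ceil(0.01 * 500)) + 1
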