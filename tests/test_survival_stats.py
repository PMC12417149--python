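import numpy as np
import pandas as pd
import pytest

from kirallo.survival_stats import (
    cox_fit,
    cumulative_incidence,
    grays_test,
    kaplan_meier,
    logrank,
)

# 30-subject two-group competing-risks fixture; the Gray chi-square below was
# computed with the cmprsk reference implementation (cuminc, rho=0).
FIX30_T1 = [33, 48, 61, 74, 85, 102, 110, 131, 144, 158, 170, 185, 199, 215, 230]
FIX30_E1 = [1, 2, 1, 0, 1, 2, 1, 0, 1, 1, 0, 2, 1, 0, 1]
FIX30_T2 = [37, 52, 66, 79, 93, 105, 118, 126, 140, 155, 168, 180, 196, 210, 225]
FIX30_E2 = [1, 1, 2, 1, 0, 1, 1, 2, 0, 1, 1, 0, 2, 1, 0]
FIX30_GRAY_STAT = 0.106553949072


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def test_km_no_censoring_is_empirical_survival():
    fit = kaplan_meier([1, 2, 3], [1, 1, 1])
    assert np.allclose(fit.surv, [2 / 3, 1 / 3, 0.0])


def test_km_all_censored_flat():
    with pytest.warns(UserWarning, match="censored"):
        fit = kaplan_meier([5, 8, 9], [0, 0, 0])
    assert np.all(fit.surv == 1.0)


def test_km_matches_hand_computed_product_limit():
    """8-subject fixture with censoring and a tie, against hand calculation."""
    t = [1, 2, 3, 4, 4, 5, 6, 7]
    e = [1, 0, 1, 1, 1, 0, 1, 1]
    fit = kaplan_meier(t, e)
    expected = {1: 7 / 8, 3: 35 / 48, 4: 7 / 16, 6: 7 / 32, 7: 0.0}
    for tt, s in expected.items():
        assert fit.value_at(tt)[0] == pytest.approx(s, abs=1e-12)
    assert np.all(np.diff(fit.surv) <= 1e-12)  # non-increasing from 1


def test_km_ci_bounds_order():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 60)
    e = rng.integers(0, 2, 60)
    fit = kaplan_meier(t, e)
    assert np.all(fit.ci_lower <= fit.surv + 1e-12)
    assert np.all(fit.surv <= fit.ci_upper + 1e-12)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------


def test_logrank_identical_groups():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 1]
    res = logrank([(t, e), (t, e)])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def test_logrank_label_symmetry(rng):
    g1 = (rng.exponential(10, 40), rng.integers(0, 2, 40))
    g2 = (rng.exponential(14, 35), rng.integers(0, 2, 35))
    a = logrank([g1, g2])
    b = logrank([g2, g1])
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_logrank_input_validation():
    with pytest.raises(ValueError):
        logrank([([1, 2], [1, 0])])
    with pytest.raises(ValueError):
        logrank([([1, 2], [0, 0]), ([], [])])


# ---------------------------------------------------------------------------
# cumulative incidence
# ---------------------------------------------------------------------------


def test_cif_complete_two_subject():
    fit = cumulative_incidence([1, 2], [1, 2])
    assert fit.cif_by_cause[1][-1] == pytest.approx(0.5)
    assert fit.cif_by_cause[2][-1] == pytest.approx(0.5)


def test_cif_reduces_to_one_minus_km_without_competing(rng):
    t = rng.exponential(20, 80).round(1) + 0.1
    e = rng.integers(0, 2, 80)
    if e.sum() == 0:
        e[0] = 1
    cif = cumulative_incidence(t, e)
    km = kaplan_meier(t, e)
    for tt in np.unique(t):
        f, _, _ = cif.value_at(tt, cause=1)
        s, _, _ = km.value_at(tt)
        assert f == pytest.approx(1.0 - s, abs=1e-12)


def test_cif_equals_empirical_subdistribution_without_censoring(rng):
    """20-subject fixture, no censoring: the Aalen-Johansen estimate equals
    the brute-force empirical fraction of cause-k events by each time."""
    t = rng.integers(1, 15, 20).astype(float)
    e = rng.choice([1, 2], 20)
    fit = cumulative_incidence(t, e)
    for tt in np.unique(t):
        for k in (1, 2):
            emp = np.mean((t <= tt) & (e == k))
            assert fit.value_at(tt, cause=k)[0] == pytest.approx(emp, abs=1e-12)


def test_cif_km_consistency_identity(rng):
    """1 - S_allcause(t) = CIF_1(t) + CIF_2(t) at every observed time."""
    t = rng.exponential(30, 150).round(1) + 0.1
    e = rng.choice([0, 1, 2], 150, p=[0.3, 0.4, 0.3])
    fit = cumulative_incidence(t, e)
    total = fit.cif_by_cause[1] + fit.cif_by_cause[2]
    assert np.max(np.abs((1.0 - fit.km_allcause) - total)) < 1e-9


def test_cif_monotone_from_zero(rng):
    t = rng.exponential(30, 100)
    e = rng.choice([0, 1, 2], 100)
    fit = cumulative_incidence(t, e)
    for k in (1, 2):
        assert fit.cif_by_cause[k][0] >= 0.0
        assert np.all(np.diff(fit.cif_by_cause[k]) >= -1e-12)


def test_cif_rejects_bad_codes():
    with pytest.raises(ValueError):
        cumulative_incidence([1, 2], [1, 5])


# ---------------------------------------------------------------------------
# Gray's test
# ---------------------------------------------------------------------------


def test_gray_identical_groups():
    t = [3.0, 5.0, 8.0, 11.0, 14.0]
    e = [1, 2, 1, 0, 1]
    res = grays_test([(t, e), (t, e)])
    assert res.statistic == pytest.approx(0.0, abs=1e-10)
    assert res.p_value == pytest.approx(1.0)
    assert res.method == "gray"


def test_gray_matches_reference_implementation():
    """Chi-square statistic agrees with cmprsk's cuminc to 1e-6 on a fixed
    30-subject fixture."""
    res = grays_test([(FIX30_T1, FIX30_E1), (FIX30_T2, FIX30_E2)])
    assert res.statistic == pytest.approx(FIX30_GRAY_STAT, abs=1e-6)
    assert res.df == 1


def test_gray_three_groups_df(rng):
    groups = [
        (rng.exponential(20, 30), rng.choice([0, 1, 2], 30, p=[0.2, 0.5, 0.3]))
        for _ in range(3)
    ]
    res = grays_test(groups)
    assert res.df == 2
    assert 0.0 <= res.p_value <= 1.0


def test_gray_requires_cause_events():
    with pytest.raises(ValueError):
        grays_test([([1, 2], [0, 2]), ([3, 4], [2, 0])], cause=1)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------


def _sim_cox(rng, n=200, beta=0.0):
    x = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.02 * np.exp(beta * x)))
    c = rng.uniform(0, 80, n)
    times = np.minimum(t, c) + 1e-9
    events = (t <= c).astype(int)
    return pd.DataFrame({"x": x}), times, events


def test_cox_null_recovery(rng):
    X, t, e = _sim_cox(rng, n=500, beta=0.0)
    fit = cox_fit(X, t, e)
    assert 0.85 <= float(fit.hr["x"]) <= 1.18
    assert float(fit.ci95.loc["x", "lower"]) < float(fit.hr["x"]) < float(
        fit.ci95.loc["x", "upper"]
    )


def test_cox_efron_breslow_agree_without_ties(rng):
    X, t, e = _sim_cox(rng, n=150, beta=0.7)
    assert len(np.unique(t[e == 1])) == e.sum()  # tie-free
    efron = cox_fit(X, t, e, ties="efron")
    breslow = cox_fit(X, t, e, ties="breslow")
    assert float(efron.coefficients["x"]) == pytest.approx(
        float(breslow.coefficients["x"]), abs=1e-6
    )


def test_cox_score_test_equals_logrank(rng):
    """With one binary covariate and no ties, the partial-likelihood score
    test at beta=0 equals the log-rank chi-square."""
    X, t, e = _sim_cox(rng, n=120, beta=0.5)
    x = X["x"].values
    order = np.argsort(-t)
    xs, ts, es = x[order], t[order], e[order]
    s0 = np.cumsum(np.ones_like(xs))
    s1 = np.cumsum(xs)
    U = np.sum((xs - s1 / s0)[es == 1])
    info = np.sum((s1 / s0 - (s1 / s0) ** 2)[es == 1])
    score_chi2 = U**2 / info
    lr = logrank([(t[x == 0], e[x == 0]), (t[x == 1], e[x == 1])])
    assert lr.statistic == pytest.approx(score_chi2, abs=1e-6)


def test_cox_refuses_bad_designs(rng):
    X, t, e = _sim_cox(rng, n=50)
    X["const"] = 1.0
    with pytest.raises(ValueError, match="constant"):
        cox_fit(X, t, e)
    X2 = pd.DataFrame({f"v{i}": rng.normal(size=6) for i in range(5)})
    with pytest.raises(ValueError, match="events"):
        cox_fit(X2, [1, 2, 3, 4, 5, 6], [1, 0, 0, 0, 0, 0])
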