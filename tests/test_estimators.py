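"""Estimators: balance diagnostics, IPW standardization, TMLE targeting,
double cross-fit aggregation."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from hdpsim import (LIB1, DoubleCrossFitTMLE, IPWRiskDifference, TMLE,
                    WeightSpec, classify_imbalanced, dc_tmle_rd,
                    fit_propensity, ipw_rd, tmle_rd, true_marginal_rd,
                    simulate_dataset, default_dgm)
from hdpsim._utils import child_seed
from hdpsim.estimators import (EstimateRecord, compute_weights,
                               standardized_mean_difference)


# --- balance ----------------------------------------------------------------

def test_smd_hand_formula_and_classification():
    rng = np.random.default_rng(0)
    a = np.repeat([1, 0], 500)
    x = np.concatenate([rng.normal(0.5, 1, 500), rng.normal(0.0, 1, 500)])
    smd = standardized_mean_difference(x, a)
    m1, m0 = x[:500].mean(), x[500:].mean()
    s1, s0 = x[:500].std(ddof=1), x[500:].std(ddof=1)
    assert smd == pytest.approx((m1 - m0) / np.sqrt((s1**2 + s0**2) / 2), abs=1e-12)

    X = pd.DataFrame({"balanced": np.tile(x[:500], 2), "shifted": x,
                      "is_exposed": a.astype(float)})
    out = classify_imbalanced(X, a, threshold=0.1)
    assert "balanced" not in out          # identical distribution by arm
    assert "shifted" in out               # SMD 0.5 > 0.1
    assert "is_exposed" in out            # maximal imbalance

    cat = pd.DataFrame({"lvl": np.where(a == 1, 2, 0)})
    assert classify_imbalanced(cat, a, categorical=["lvl"]) == ["lvl"]
    with pytest.raises(ValueError):
        standardized_mean_difference(x, np.ones_like(a))


# --- propensity -------------------------------------------------------------

def test_propensity_marginal_when_uninformative():
    rng = np.random.default_rng(1)
    n = 4000
    X = rng.standard_normal((n, 3))
    a = rng.integers(0, 2, n, endpoint=False) * 0  # start all 0
    a = (rng.random(n) < 0.3).astype(int)
    g, _ = fit_propensity(X, a, LIB1, seed=0, n_folds=5)
    assert abs(g.mean() - a.mean()) < 0.02
    assert np.all(np.abs(g - a.mean()) < 0.15)


def test_propensity_saturated_binary_covariate_matches_cell_rates():
    rng = np.random.default_rng(2)
    z = rng.integers(0, 2, 2000)
    a = (rng.random(2000) < np.where(z == 1, 0.6, 0.2)).astype(int)
    g, _ = fit_propensity(z.reshape(-1, 1).astype(float), a, LIB1, seed=0)
    for lev in (0, 1):
        emp = a[z == lev].mean()
        assert np.allclose(g[z == lev], emp, atol=1e-4)


def test_propensity_empty_covariates_gives_marginal():
    a = np.array([1, 0, 0, 1, 0])
    g, fit = fit_propensity(np.empty((5, 0)), a, LIB1)
    assert fit is None and np.allclose(g, 0.4)


def test_propensity_deterministic(dataset, investigator_design):
    g1, _ = fit_propensity(investigator_design, dataset.A, LIB1, seed=5, n_folds=5)
    g2, _ = fit_propensity(investigator_design, dataset.A, LIB1, seed=5, n_folds=5)
    assert np.array_equal(g1, g2)


# --- weights ----------------------------------------------------------------

def test_weights_truncation_and_nonfinite_detection():
    a = np.array([1, 0, 1, 0])
    g = np.array([0.001, 0.5, 0.9, 0.999])
    w, diag = compute_weights(a, g, WeightSpec(stabilized=False))
    assert diag["n_truncated"] == 2
    assert w.max() <= 1 / 0.025 + 1e-12
    with pytest.raises(ValueError, match="rows"):
        compute_weights(np.array([1, 0]), np.array([0.0, 0.5]),
                        WeightSpec(stabilized=False, truncation_bounds=(0.0, 1.0)))
    with pytest.raises(ValueError):
        WeightSpec(truncation_bounds=(0.5, 0.2))


# --- IPW --------------------------------------------------------------------

def test_ipw_constant_g_equals_difference_in_means():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 2, 500)
    y = rng.integers(0, 2, 500)
    rec = ipw_rd(y, a, np.full(500, 0.5), weight_spec=WeightSpec(stabilized=False))
    assert rec.rd_hat == pytest.approx(y[a == 1].mean() - y[a == 0].mean(), abs=1e-9)
    assert rec.ci_low <= rec.rd_hat <= rec.ci_high


def _stratified_toy():
    """Z=1: 100 rows, 50 exposed, risks 0.6/0.4; Z=0: 100 rows, 20 exposed,
    risks 0.3/0.1.  Standardization oracle: 0.5*0.2 + 0.5*0.2 = 0.20."""
    rows = []
    for z, n_t, r1, r0, n in [(1, 50, 0.6, 0.4, 100), (0, 20, 0.3, 0.1, 100)]:
        for i in range(n):
            a = 1 if i < n_t else 0
            n_arm = n_t if a else n - n_t
            pos = i if a else i - n_t
            risk = r1 if a else r0
            y = 1 if pos < round(risk * n_arm) else 0
            rows.append((z, a, y))
    df = pd.DataFrame(rows, columns=["z", "a", "y"])
    g = np.where(df.z == 1, 0.5, 0.2)
    return df, g


def test_ipw_matches_hand_standardization_oracle():
    df, g = _stratified_toy()
    rec = ipw_rd(df.y.to_numpy(), df.a.to_numpy(), g,
                 weight_spec=WeightSpec(stabilized=False,
                                        truncation_bounds=(0.0, 1.0)))
    assert rec.rd_hat == pytest.approx(0.20, abs=1e-9)


def test_ipw_stabilization_invariant_point_estimate():
    df, g = _stratified_toy()
    ws_u = WeightSpec(stabilized=False, truncation_bounds=(0.0, 1.0))
    ws_s = WeightSpec(stabilized=True, truncation_bounds=(0.0, 1.0))
    r_u = ipw_rd(df.y.to_numpy(), df.a.to_numpy(), g, weight_spec=ws_u)
    r_s = ipw_rd(df.y.to_numpy(), df.a.to_numpy(), g, weight_spec=ws_s)
    assert r_u.rd_hat == pytest.approx(r_s.rd_hat, abs=1e-9)
    assert r_u.diagnostics["weight_max"] != r_s.diagnostics["weight_max"]


def test_ipw_summary_exposes_estimate(dataset, investigator_design):
    g, _ = fit_propensity(investigator_design, dataset.A, LIB1, seed=1, n_folds=5)
    res = IPWRiskDifference(dataset.Y, dataset.A, g).fit()
    text = res.summary()
    assert "risk difference" in text and f"{res.rd: .6f}".strip() in text


# --- TMLE -------------------------------------------------------------------

def test_tmle_saturated_case_epsilon_zero():
    """Initial Q at the arm means and g at the empirical exposure rate solve
    the score equation already: epsilon 0, estimate = difference in means."""
    rng = np.random.default_rng(4)
    a = rng.integers(0, 2, 800)
    y = rng.integers(0, 2, 800)
    q1, q0 = y[a == 1].mean(), y[a == 0].mean()
    res = TMLE(y, a, g=np.full(800, a.mean()),
               Q0=np.full(800, q0), Q1=np.full(800, q1)).fit()
    assert abs(res.components.epsilon[0]) < 1e-8
    assert res.rd == pytest.approx(q1 - q0, abs=1e-8)


def test_tmle_matches_independent_newton_solver():
    """8 fixed rows with hand-specified nuisances: epsilon and the estimate
    must match a hand-coded 1-D Newton solve of the fluctuation score."""
    y = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
    a = np.array([1, 1, 1, 0, 0, 0, 1, 0], dtype=float)
    g = np.array([0.6, 0.55, 0.7, 0.3, 0.45, 0.35, 0.5, 0.4])
    Q1 = np.array([0.7, 0.4, 0.8, 0.6, 0.3, 0.2, 0.55, 0.35])
    Q0 = np.array([0.5, 0.3, 0.6, 0.5, 0.25, 0.15, 0.45, 0.3])
    res = TMLE(y, a, g=g, Q0=Q0, Q1=Q1,
               weight_spec=WeightSpec(truncation_bounds=(0.0, 1.0))).fit()

    H = a / g - (1 - a) / (1 - g)
    off = logit(a * Q1 + (1 - a) * Q0)
    eps = 0.0
    for _ in range(60):
        p = expit(off + eps * H)
        eps += np.sum(H * (y - p)) / np.sum(H * H * p * (1 - p))
    q1s, q0s = expit(logit(Q1) + eps / g), expit(logit(Q0) - eps / (1 - g))
    assert res.components.epsilon[0] == pytest.approx(eps, abs=1e-10)
    assert res.rd == pytest.approx(q1s.mean() - q0s.mean(), abs=1e-10)


def test_tmle_influence_function_mean_zero(dataset, investigator_design):
    _, comp = tmle_rd(dataset.Y, dataset.A, X_q=investigator_design,
                      X_g=investigator_design, q_library=LIB1,
                      g_library=LIB1, n_folds=5, seed=3)
    assert abs(comp.influence_values.mean()) < 1e-8


def test_tmle_double_robustness_desk_scale(base_cohort, dgm):
    """Either nuisance correctly specified keeps bias small even when the
    other omits the comorbidity score entirely."""
    truth = true_marginal_rd(dgm, base_cohort, 50_000, 0)
    K = 60
    biases = {"good_g": [], "good_q": []}
    for i in range(K):
        ds = simulate_dataset(base_cohort, dgm, 3000, child_seed(31, 1, i), i)
        g_true = base_cohort.true_propensity[ds.base_indices]
        X_oracle = dgm.oracle_design(ds.X_spec, ds.L, ds.C)
        X_bad = X_oracle[:, :-1]  # drop the comorbidity score
        r1, _ = tmle_rd(ds.Y, ds.A, X_q=X_bad, q_library=LIB1, g=g_true,
                        n_folds=5, seed=100 + i)
        r2, _ = tmle_rd(ds.Y, ds.A, X_q=X_oracle, q_library=LIB1,
                        g=np.full(ds.n, ds.A.mean()), n_folds=5, seed=200 + i)
        biases["good_g"].append(r1.rd_hat - truth)
        biases["good_q"].append(r2.rd_hat - truth)
    assert abs(np.mean(biases["good_g"])) < 0.01
    assert abs(np.mean(biases["good_q"])) < 0.01


# --- double cross-fit TMLE --------------------------------------------------

def test_dc_tmle_degenerate_mode_equals_tmle(dataset, investigator_design):
    X = investigator_design
    r1 = dc_tmle_rd(dataset.Y, dataset.A, X, X, LIB1, n_splits=1,
                    n_repeats=1, seed=42)
    r2, _ = tmle_rd(dataset.Y, dataset.A, X_q=X, X_g=X, q_library=LIB1,
                    g_library=LIB1, n_folds=5, seed=42)
    assert r1.rd_hat == pytest.approx(r2.rd_hat, abs=1e-12)
    assert r1.se_hat == pytest.approx(r2.se_hat, abs=1e-12)


def test_dc_tmle_rejects_two_splits():
    with pytest.raises(ValueError):
        DoubleCrossFitTMLE(np.zeros(10), np.zeros(10), np.zeros((10, 1)),
                           np.zeros((10, 1)), LIB1, n_splits=2)


def test_dc_tmle_single_exposed_row_cannot_partition():
    rng = np.random.default_rng(6)
    n = 60
    a = np.zeros(n); a[0] = 1
    y = rng.integers(0, 2, n).astype(float)
    X = rng.standard_normal((n, 2))
    with pytest.raises(RuntimeError, match="partition"):
        DoubleCrossFitTMLE(y, a, X, X, LIB1, n_splits=3, n_repeats=1).fit(seed=0)


def test_dc_tmle_nominal_under_randomized_exposure(randomized_cohort):
    """No confounding: the DC-TMLE interval contains 0 in nearly all reps."""
    dgm = default_dgm(randomized_cohort)
    from hdpsim.orchestrate import _investigator_matrix
    hits = 0
    K = 30
    for i in range(K):
        ds = simulate_dataset(randomized_cohort, dgm, 1500, child_seed(51, 1, i), i)
        X = _investigator_matrix(ds)
        rec = dc_tmle_rd(ds.Y, ds.A, X, X, LIB1, n_splits=3, n_repeats=2,
                         seed=300 + i, n_folds=4)
        hits += (rec.rd_hat - 2 * rec.se_hat <= 0 <= rec.rd_hat + 2 * rec.se_hat)
    assert hits >= int(0.8 * K)


# --- records ----------------------------------------------------------------

def test_estimate_record_validation():
    rec = EstimateRecord.from_point("x", 0.1, 0.02)
    assert rec.ci_low == pytest.approx(0.1 - 1.959963984540054 * 0.02)
    with pytest.raises(ValueError):
        EstimateRecord(method_tag="x", rd_hat=1.5, se_hat=0.1,
                       ci_low=1.3, ci_high=1.7)
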