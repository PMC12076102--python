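"""Risk-difference estimators: IPW, TMLE, and double cross-fit TMLE.

Organized as model objects in the statsmodels style: construct a model from
data, call ``fit()``, get a results object carrying the estimate, its
standard error, a Wald 95% interval and diagnostics, with a ``summary()``
table.  Thin functional wrappers (``ipw_rd``, ``tmle_rd``, ``dc_tmle_rd``)
expose the same computations for pipeline use.

Estimand: the marginal risk difference E[Y^1] - E[Y^0] for a binary outcome
under a binary exposure.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._utils import child_seed, expit, logit
from .learners import LearnerLibrary, StackFit, cv_stack, predict_stack

Z_95 = 1.959963984540054  # standard normal 97.5% quantile
_QBOUND = 1e-6            # bound on outcome probabilities before taking logits

ADJUSTMENT_STRATEGIES = ("none", "imbalanced_measured", "all_measured",
                         "imbalanced_plus_proxies", "all_measured_plus_proxies")


@dataclass(frozen=True)
class WeightSpec:
    """Propensity-weight options: stabilization and truncation bounds on the
    propensity scale (default (0.025, 0.975), the usual practical-positivity
    bound, essential under rare exposure)."""

    stabilized: bool = True
    truncation_bounds: tuple[float, float] = (0.025, 0.975)

    def __post_init__(self) -> None:
        lo, hi = self.truncation_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError(f"invalid truncation bounds {self.truncation_bounds}")

    def truncate(self, g: np.ndarray) -> tuple[np.ndarray, int]:
        lo, hi = self.truncation_bounds
        clipped = np.clip(g, lo, hi)
        return clipped, int(np.sum((g < lo) | (g > hi)))


@dataclass
class AdjustmentPlan:
    """Which covariates the weighted outcome model adjusts for."""

    strategy: str = "none"
    imbalance_threshold: float = 0.1
    proxy_set: object | None = None  # ProxySet or None

    def __post_init__(self) -> None:
        if self.strategy not in ADJUSTMENT_STRATEGIES:
            raise ValueError(f"strategy must be one of {ADJUSTMENT_STRATEGIES}")


@dataclass
class EstimateRecord:
    """One method's risk-difference estimate for one dataset."""

    method_tag: str
    rd_hat: float
    se_hat: float
    ci_low: float
    ci_high: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.rd_hat) and not -1.0 <= self.rd_hat <= 1.0:
            raise ValueError(f"risk difference {self.rd_hat} outside [-1, 1]")

    @classmethod
    def from_point(cls, method_tag: str, rd: float, se: float,
                   diagnostics: dict | None = None) -> "EstimateRecord":
        return cls(method_tag=method_tag, rd_hat=rd, se_hat=se,
                   ci_low=rd - Z_95 * se, ci_high=rd + Z_95 * se,
                   diagnostics=diagnostics or {})

    def to_row(self) -> dict:
        return {"method_tag": self.method_tag, "rd_hat": self.rd_hat,
                "se_hat": self.se_hat, "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "diagnostics": json.dumps(self.diagnostics, default=str)}


@dataclass
class TmleComponents:
    g_hat: np.ndarray
    Q0_hat: np.ndarray
    Q1_hat: np.ndarray
    epsilon: np.ndarray
    Q0_star: np.ndarray
    Q1_star: np.ndarray
    influence_values: np.ndarray


class RDResults:
    """Results container: point estimate, SE, Wald 95% CI, diagnostics."""

    def __init__(self, model, record: EstimateRecord,
                 components: TmleComponents | None = None):
        self.model = model
        self.record = record
        self.components = components

    rd = property(lambda self: self.record.rd_hat)
    se = property(lambda self: self.record.se_hat)
    conf_int = property(lambda self: (self.record.ci_low, self.record.ci_high))
    diagnostics = property(lambda self: self.record.diagnostics)

    def summary(self) -> str:
        r = self.record
        lines = [
            f"{type(self.model).__name__} risk-difference results",
            "=" * 48,
            f"method tag      : {r.method_tag}",
            f"risk difference : {r.rd_hat: .6f}",
            f"std. error      : {r.se_hat: .6f}",
            f"95% CI          : [{r.ci_low: .6f}, {r.ci_high: .6f}]",
        ]
        for k, v in r.diagnostics.items():
            lines.append(f"{k:<16}: {v}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<RDResults {self.record.method_tag}: rd={self.rd:.4f} "
                f"se={self.se:.4f}>")


# --- covariate balance ------------------------------------------------------

def standardized_mean_difference(x: np.ndarray, a: np.ndarray) -> float:
    """(m1 - m0) / sqrt((s1^2 + s0^2)/2) with arm-specific variances (ddof=1)."""
    x = np.asarray(x, dtype=float); a = np.asarray(a)
    x1, x0 = x[a == 1], x[a == 0]
    if len(x1) == 0 or len(x0) == 0:
        raise ValueError("both exposure arms are required to assess balance")
    pooled = np.sqrt((np.var(x1, ddof=1) + np.var(x0, ddof=1)) / 2.0)
    diff = x1.mean() - x0.mean()
    if pooled == 0:
        # degenerate arms: no difference is perfect balance, any difference
        # is maximal imbalance (e.g. a covariate identical to the exposure)
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / pooled)


def classify_imbalanced(X: pd.DataFrame, a: np.ndarray,
                        categorical: list[str] | None = None,
                        threshold: float = 0.1) -> list[str]:
    """Covariates whose |SMD| between exposure arms exceeds ``threshold``
    (default 0.1, the conventional cutoff), on the unweighted sample.
    Categorical covariates are assessed per level indicator and included if
    any level exceeds the threshold."""
    categorical = set(categorical or [])
    out = []
    for col in X.columns:
        x = X[col].to_numpy()
        if col in categorical:
            levels = np.unique(x)
            smds = [abs(standardized_mean_difference((x == l).astype(float), a))
                    for l in levels]
            if max(smds) > threshold:
                out.append(col)
        else:
            if abs(standardized_mean_difference(x, a)) > threshold:
                out.append(col)
    return out


# --- propensity -------------------------------------------------------------

def fit_propensity(X, a, library: LearnerLibrary, seed: int = 0,
                   n_folds: int = 10) -> tuple[np.ndarray, StackFit | None]:
    """P(A=1 | X) via the cross-validated stack; an empty covariate set
    (unadjusted-by-design) yields the marginal exposure rate."""
    a = np.asarray(a)
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return np.full(len(a), a.mean()), None
    fit = cv_stack(library, X, a, n_folds=n_folds, seed=seed)
    return predict_stack(fit, np.asarray(X, dtype=float)), fit


def compute_weights(a: np.ndarray, g: np.ndarray,
                    spec: WeightSpec) -> tuple[np.ndarray, dict]:
    """Inverse-probability-of-treatment weights, optionally stabilized by the
    marginal exposure probabilities, after truncating g."""
    a = np.asarray(a, dtype=float)
    g_t, n_trunc = spec.truncate(np.asarray(g, dtype=float))
    w = a / g_t + (1.0 - a) / (1.0 - g_t)
    if spec.stabilized:
        p1 = a.mean()
        w = w * (a * p1 + (1.0 - a) * (1.0 - p1))
    if not np.all(np.isfinite(w)):
        bad = np.flatnonzero(~np.isfinite(w))
        raise ValueError(f"non-finite weights at rows {bad[:10].tolist()}"
                         + ("..." if bad.size > 10 else ""))
    return w, {"weight_max": float(w.max()), "weight_min": float(w.min()),
               "n_truncated": n_trunc, "stabilized": spec.stabilized}


# --- IPW --------------------------------------------------------------------

class IPWRiskDifference:
    """IPW estimator of the marginal risk difference.

    A weighted logistic outcome regression of Y on A (plus any adjustment
    covariates) is fit with IPT weights; the marginal RD is recovered by
    g-computation on the weighted fit — predicted risk averaged over the
    sample with A set to 1 and then 0.  The SE is a robust sandwich treating
    the weights as fixed (conservative), propagated through the
    standardization step by the delta method.
    """

    def __init__(self, y, a, g, adjust: np.ndarray | None = None,
                 weight_spec: WeightSpec | None = None,
                 method_tag: str = "ipw"):
        self.y = np.asarray(y, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.g = np.asarray(g, dtype=float)
        self.adjust = None if adjust is None or np.size(adjust) == 0 \
            else np.asarray(adjust, dtype=float).reshape(len(self.y), -1)
        self.weight_spec = weight_spec or WeightSpec()
        self.method_tag = method_tag

    def fit(self) -> RDResults:
        n = len(self.y)
        w, wdiag = compute_weights(self.a, self.g, self.weight_spec)

        cols = [np.ones(n), self.a]
        if self.adjust is not None:
            cols.append(self.adjust)
        X = np.column_stack(cols)

        glm = sm.GLM(self.y, X, family=sm.families.Binomial(), var_weights=w)
        beta = glm.fit(maxiter=200, tol=1e-10).params

        X1, X0 = X.copy(), X.copy()
        X1[:, 1], X0[:, 1] = 1.0, 0.0
        p1, p0 = expit(X1 @ beta), expit(X0 @ beta)
        rd = float(p1.mean() - p0.mean())

        # sandwich for the weighted estimating equations, weights fixed
        p_fit = expit(X @ beta)
        W_info = w * p_fit * (1.0 - p_fit)
        A_mat = X.T @ (X * W_info[:, None])
        score = X * (w * (self.y - p_fit))[:, None]
        B_mat = score.T @ score
        A_inv = np.linalg.pinv(A_mat)
        V_beta = A_inv @ B_mat @ A_inv

        grad = (X1 * (p1 * (1.0 - p1))[:, None] -
                X0 * (p0 * (1.0 - p0))[:, None]).mean(axis=0)
        se = float(np.sqrt(grad @ V_beta @ grad))

        rec = EstimateRecord.from_point(self.method_tag, rd, se, wdiag)
        return RDResults(self, rec)


def ipw_rd(y, a, g, adjust=None, weight_spec: WeightSpec | None = None,
           method_tag: str = "ipw") -> EstimateRecord:
    return IPWRiskDifference(y, a, g, adjust=adjust, weight_spec=weight_spec,
                             method_tag=method_tag).fit().record


# --- TMLE -------------------------------------------------------------------

def _fluctuate(y: np.ndarray, H: np.ndarray, Q_a: np.ndarray) -> np.ndarray:
    """Logistic fluctuation: regress y on the clever covariate(s) H with
    offset logit(Q_a) and no intercept; returns epsilon."""
    Q_a = np.clip(Q_a, _QBOUND, 1.0 - _QBOUND)
    H = np.asarray(H, dtype=float)
    if H.ndim == 1:
        H = H.reshape(-1, 1)
    glm = sm.GLM(y, H, family=sm.families.Binomial(), offset=logit(Q_a))
    try:
        res = glm.fit(maxiter=200, tol=1e-12)
    except Exception as exc:
        raise RuntimeError(f"TMLE fluctuation failed to converge: {exc}") from exc
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"TMLE fluctuation diverged, epsilon trace {res.params}")
    return np.asarray(res.params)


def _target(y, a, g_t, Q0, Q1, two_epsilon: bool):
    """Run the targeting step; returns (Q0*, Q1*, epsilon, influence values, psi)."""
    a = np.asarray(a, dtype=float)
    Q0 = np.clip(Q0, _QBOUND, 1.0 - _QBOUND)
    Q1 = np.clip(Q1, _QBOUND, 1.0 - _QBOUND)
    Q_a = a * Q1 + (1.0 - a) * Q0
    H1_at_obs = a / g_t
    H0_at_obs = -(1.0 - a) / (1.0 - g_t)
    if two_epsilon:
        eps = _fluctuate(y, np.column_stack([H1_at_obs, H0_at_obs]), Q_a)
        Q1s = expit(logit(Q1) + eps[0] / g_t)
        Q0s = expit(logit(Q0) - eps[1] / (1.0 - g_t))
    else:
        H = H1_at_obs + H0_at_obs
        eps = _fluctuate(y, H, Q_a)
        Q1s = expit(logit(Q1) + eps[0] / g_t)
        Q0s = expit(logit(Q0) - eps[0] / (1.0 - g_t))
    psi = float(Q1s.mean() - Q0s.mean())
    Q_as = a * Q1s + (1.0 - a) * Q0s
    H_obs = a / g_t - (1.0 - a) / (1.0 - g_t)
    ic = H_obs * (y - Q_as) + (Q1s - Q0s) - psi
    return Q0s, Q1s, eps, ic, psi


class TMLE:
    """Targeted maximum likelihood estimation of the marginal risk difference.

    Initial outcome regressions Q(a, X) and the propensity g(X) come from
    cross-validated stacks (or may be supplied directly, e.g., by oracle
    analyses); a single-epsilon logistic fluctuation with the combined
    clever covariate A/g - (1-A)/(1-g) targets the initial fit so that the
    efficient-influence-function score equation is solved; the SE is the
    sample SD of the influence values over sqrt(n).
    """

    def __init__(self, y, a, X_q=None, X_g=None,
                 q_library: LearnerLibrary | None = None,
                 g_library: LearnerLibrary | None = None,
                 g=None, Q0=None, Q1=None,
                 weight_spec: WeightSpec | None = None,
                 two_epsilon: bool = False, n_folds: int = 10,
                 method_tag: str = "tmle"):
        self.y = np.asarray(y, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.X_q = None if X_q is None else np.asarray(X_q, dtype=float)
        self.X_g = None if X_g is None else np.asarray(X_g, dtype=float)
        self.q_library = q_library
        self.g_library = g_library
        self.g_given = None if g is None else np.asarray(g, dtype=float)
        self.Q0_given = None if Q0 is None else np.asarray(Q0, dtype=float)
        self.Q1_given = None if Q1 is None else np.asarray(Q1, dtype=float)
        self.weight_spec = weight_spec or WeightSpec()
        self.two_epsilon = two_epsilon
        self.n_folds = n_folds
        self.method_tag = method_tag

    def _nuisances(self, seed: int):
        if self.g_given is not None:
            g = self.g_given
        else:
            g, _ = fit_propensity(self.X_g, self.a, self.g_library,
                                  seed=seed, n_folds=self.n_folds)
        if self.Q0_given is not None and self.Q1_given is not None:
            Q0, Q1 = self.Q0_given, self.Q1_given
        else:
            n = len(self.y)
            base = self.X_q if self.X_q is not None else np.empty((n, 0))
            XA = np.column_stack([self.a, base])
            qfit = cv_stack(self.q_library, XA, self.y,
                            n_folds=self.n_folds, seed=seed + 1)
            Q1 = predict_stack(qfit, np.column_stack([np.ones(n), base]))
            Q0 = predict_stack(qfit, np.column_stack([np.zeros(n), base]))
        return g, Q0, Q1

    def fit(self, seed: int = 0) -> RDResults:
        g, Q0, Q1 = self._nuisances(seed)
        g_t, n_trunc = self.weight_spec.truncate(g)
        Q0s, Q1s, eps, ic, psi = _target(self.y, self.a, g_t, Q0, Q1,
                                         self.two_epsilon)
        n = len(self.y)
        se = float(np.std(ic, ddof=1) / np.sqrt(n))
        diag = {"epsilon": eps.tolist(), "n_truncated": n_trunc,
                "mean_ic": float(ic.mean()), "g_min": float(g_t.min()),
                "g_max": float(g_t.max())}
        rec = EstimateRecord.from_point(self.method_tag, psi, se, diag)
        comp = TmleComponents(g_hat=g_t, Q0_hat=Q0, Q1_hat=Q1, epsilon=eps,
                              Q0_star=Q0s, Q1_star=Q1s, influence_values=ic)
        return RDResults(self, rec, components=comp)


def tmle_rd(y, a, X_q=None, X_g=None, q_library=None, g_library=None,
            g=None, Q0=None, Q1=None, weight_spec=None, two_epsilon=False,
            n_folds: int = 10, seed: int = 0,
            method_tag: str = "tmle") -> tuple[EstimateRecord, TmleComponents]:
    res = TMLE(y, a, X_q=X_q, X_g=X_g, q_library=q_library,
               g_library=g_library, g=g, Q0=Q0, Q1=Q1,
               weight_spec=weight_spec, two_epsilon=two_epsilon,
               n_folds=n_folds, method_tag=method_tag).fit(seed=seed)
    return res.record, res.components


# --- double cross-fit TMLE --------------------------------------------------

class DoubleCrossFitTMLE:
    """Double cross-fit TMLE: the propensity model, the outcome model and the
    targeting/estimation step each use disjoint folds, rotated so every fold
    plays every role; rotation estimates are averaged into a partition
    estimate, the partitioning is repeated, and partition estimates are
    median-aggregated with the variance adjusted for between-partition
    spread.  The sample splitting relaxes the Donsker-class requirement on
    the nuisance learners.
    """

    def __init__(self, y, a, X_q, X_g, library: LearnerLibrary,
                 n_splits: int = 3, n_repeats: int = 20,
                 weight_spec: WeightSpec | None = None,
                 n_folds: int = 5, method_tag: str = "dc_tmle"):
        if n_splits != 1 and n_splits < 3:
            raise ValueError("n_splits must be >= 3 (or 1 for the degenerate "
                             "no-splitting mode)")
        self.y = np.asarray(y, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.X_q = np.asarray(X_q, dtype=float)
        self.X_g = np.asarray(X_g, dtype=float)
        self.library = library
        self.n_splits = n_splits
        self.n_repeats = n_repeats
        self.weight_spec = weight_spec or WeightSpec()
        self.n_folds = n_folds
        self.method_tag = method_tag

    def _partition(self, rng: np.random.Generator) -> np.ndarray:
        """Random fold labels; re-drawn (<= 10 attempts) until every fold
        holds both exposure levels."""
        n = len(self.y)
        for _ in range(10):
            labels = rng.permuted(np.arange(n) % self.n_splits)
            ok = all(len(np.unique(self.a[labels == f])) == 2
                     for f in range(self.n_splits))
            if ok:
                return labels
        raise RuntimeError("could not partition data with both exposure levels "
                           "in every fold after 10 attempts")

    def _rotation(self, labels: np.ndarray, s: int, seed: int):
        """One rotation: g on fold set I, Q on fold set II, targeting and
        estimation on fold set III."""
        k = self.n_splits
        est_f, q_f, g_f = s, (s + 1) % k, (s + 2) % k
        i_g = labels == g_f
        i_q = labels == q_f
        i_e = labels == est_f

        gfit = cv_stack(self.library, self.X_g[i_g], self.a[i_g],
                        n_folds=self.n_folds, seed=seed)
        g = predict_stack(gfit, self.X_g[i_e])

        XA_q = np.column_stack([self.a[i_q], self.X_q[i_q]])
        qfit = cv_stack(self.library, XA_q, self.y[i_q],
                        n_folds=self.n_folds, seed=seed + 1)
        n_e = int(i_e.sum())
        Q1 = predict_stack(qfit, np.column_stack([np.ones(n_e), self.X_q[i_e]]))
        Q0 = predict_stack(qfit, np.column_stack([np.zeros(n_e), self.X_q[i_e]]))

        g_t, _ = self.weight_spec.truncate(g)
        _, _, _, ic, psi = _target(self.y[i_e], self.a[i_e], g_t, Q0, Q1, False)
        var = float(np.var(ic, ddof=1) / n_e)
        return psi, var

    def fit(self, seed: int = 0) -> RDResults:
        if self.n_splits == 1:
            res = TMLE(self.y, self.a, X_q=self.X_q, X_g=self.X_g,
                       q_library=self.library, g_library=self.library,
                       weight_spec=self.weight_spec, n_folds=self.n_folds,
                       method_tag=self.method_tag).fit(seed=seed)
            res.record.diagnostics["n_splits"] = 1
            return res

        est_parts, var_parts = [], []
        for r in range(self.n_repeats):
            rng = np.random.default_rng(child_seed(seed, 17, r))
            labels = self._partition(rng)
            psis, vars_ = zip(*[self._rotation(labels, s, seed=seed + 1000 * r + s)
                                for s in range(self.n_splits)])
            est_parts.append(float(np.mean(psis)))
            var_parts.append(float(np.sum(vars_)) / self.n_splits ** 2)

        est_parts = np.asarray(est_parts)
        rd = float(np.median(est_parts))
        var = float(np.median(var_parts) + np.median((est_parts - rd) ** 2))
        se = float(np.sqrt(var))
        diag = {"n_splits": self.n_splits, "n_repeats": self.n_repeats,
                "partition_spread": float(est_parts.std(ddof=1)) if len(est_parts) > 1 else 0.0}
        rec = EstimateRecord.from_point(self.method_tag, rd, se, diag)
        return RDResults(self, rec)


def dc_tmle_rd(y, a, X_q, X_g, library, n_splits: int = 3, n_repeats: int = 20,
               weight_spec=None, seed: int = 0, n_folds: int = 5,
               method_tag: str = "dc_tmle") -> EstimateRecord:
    return DoubleCrossFitTMLE(y, a, X_q, X_g, library, n_splits=n_splits,
                              n_repeats=n_repeats, weight_spec=weight_spec,
                              n_folds=n_folds, method_tag=method_tag
                              ).fit(seed=seed).record
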