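"""Base learners and the cross-validated stacking ensemble (super learner).

The ensemble combines member probability predictions with convex weights
chosen to minimize the cross-validated negative Bernoulli log-likelihood —
a proper scoring rule, so a well-calibrated member is never down-weighted
in favor of a sharper but miscalibrated one.

Library presets follow the 1/3/4-learner convention:

* ``lib1`` — logistic regression;
* ``lib3`` — + L1-penalized logistic (LASSO) and an adaptive-spline learner;
* ``lib4`` — + gradient-boosted trees (XGBoost), a non-Donsker learner.

No adaptive-spline (MARS) backend is available as an installed package, so
the ``adaptive_splines`` member is a piecewise-linear hinge-basis expansion
at quantile knots followed by a ridge-penalized logistic fit; the
substitution is recorded in the stack metadata.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

# sklearn 1.8+ deprecates the long-standing `penalty=` spelling; the
# replacement (`l1_ratio`/`C=inf`) is not accepted by the older releases this
# package also supports, so keep the classic spelling and mute the notice.
warnings.filterwarnings("ignore", message=".*'penalty' was deprecated.*",
                        category=FutureWarning)
warnings.filterwarnings("ignore", message=".*fitted attributes of LogisticRegressionCV.*",
                        category=FutureWarning)
warnings.filterwarnings("ignore", message=".*default value for l1_ratios.*",
                        category=FutureWarning)
from scipy.optimize import minimize
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from xgboost import XGBClassifier

LEARNER_TAGS = ("logistic", "l1_logistic", "adaptive_splines", "gradient_boosted_trees")
_EPS = 1e-6


@dataclass(frozen=True)
class LearnerLibrary:
    """Ordered set of base-learner tags, optionally one of the named presets."""

    members: tuple[str, ...]
    preset: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("learner library must have at least one member")
        for m in self.members:
            if m not in LEARNER_TAGS:
                raise ValueError(f"unknown learner tag {m!r}; allowed: {LEARNER_TAGS}")

    @classmethod
    def from_preset(cls, name: str) -> "LearnerLibrary":
        presets = {
            "lib1": ("logistic",),
            "lib3": ("logistic", "l1_logistic", "adaptive_splines"),
            "lib4": ("logistic", "l1_logistic", "adaptive_splines",
                     "gradient_boosted_trees"),
        }
        if name not in presets:
            raise ValueError(f"unknown library preset {name!r}; allowed: {sorted(presets)}")
        return cls(members=presets[name], preset=name)


LIB1 = LearnerLibrary.from_preset("lib1")
LIB3 = LearnerLibrary.from_preset("lib3")
LIB4 = LearnerLibrary.from_preset("lib4")


# --- member implementations -------------------------------------------------

class _Member:
    tag = "base"

    def fit(self, X, y):  # pragma: no cover - interface
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class _Logistic(_Member):
    tag = "logistic"

    def __init__(self, seed: int = 0):
        self.model = LogisticRegression(penalty=None, max_iter=2000)

    def fit(self, X, y):
        self.model.fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict_proba(X)[:, 1]


class _L1Logistic(_Member):
    tag = "l1_logistic"

    def __init__(self, seed: int = 0):
        self.model = LogisticRegressionCV(penalty="l1", solver="liblinear",
                                          cv=3, Cs=5, scoring="neg_log_loss",
                                          random_state=seed, max_iter=2000)

    def fit(self, X, y):
        self.model.fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict_proba(X)[:, 1]


class _HingeSplineLogistic(_Member):
    """Piecewise-linear hinge basis (knots at the 25/50/75% quantiles of each
    continuous column) + ridge-logistic fit.  Stands in for an adaptive
    regression spline learner; tagged so outputs record the substitution."""

    tag = "adaptive_splines"
    substitution = "hinge_basis_ridge_logistic"

    def __init__(self, seed: int = 0, quantiles=(0.25, 0.50, 0.75)):
        self.quantiles = quantiles
        self.model = LogisticRegression(penalty="l2", C=1.0, max_iter=2000)
        self.knots_: list[tuple[int, np.ndarray]] = []

    def _expand(self, X: np.ndarray) -> np.ndarray:
        parts = [X]
        for j, knots in self.knots_:
            col = X[:, j]
            for t in knots:
                parts.append(np.maximum(col - t, 0.0).reshape(-1, 1))
        return np.hstack(parts)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.knots_ = []
        for j in range(X.shape[1]):
            uniq = np.unique(X[:, j])
            if uniq.size > 10:  # continuous column
                self.knots_.append((j, np.quantile(X[:, j], self.quantiles)))
        self.model.fit(self._expand(X), y)
        return self

    def predict(self, X):
        return self.model.predict_proba(self._expand(np.asarray(X, dtype=float)))[:, 1]


class _GradientBoostedTrees(_Member):
    """XGBoost with fixed, documented hyperparameters (depth 3, 200 rounds,
    learning rate 0.1, subsample 0.75), single thread for determinism."""

    tag = "gradient_boosted_trees"

    def __init__(self, seed: int = 0):
        self.model = XGBClassifier(max_depth=3, n_estimators=200,
                                   learning_rate=0.1, subsample=0.75,
                                   n_jobs=1, random_state=seed,
                                   tree_method="hist", eval_metric="logloss",
                                   verbosity=0)

    def fit(self, X, y):
        self.model.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return self.model.predict_proba(np.asarray(X, dtype=float))[:, 1]


_MEMBER_CLASSES = {
    "logistic": _Logistic,
    "l1_logistic": _L1Logistic,
    "adaptive_splines": _HingeSplineLogistic,
    "gradient_boosted_trees": _GradientBoostedTrees,
}


# --- stacking ---------------------------------------------------------------

@dataclass
class StackFit:
    """A fitted cross-validated stack."""

    library: LearnerLibrary
    weights: np.ndarray            # simplex weights, one per member (0 for failed)
    cv_risk: np.ndarray            # per-member CV negative log-likelihood
    fold_assignment: np.ndarray    # per-row fold id used for the CV predictions
    models: list                   # full-data refits (None for failed members)
    n_features: int
    metadata: dict = field(default_factory=dict)


def _neg_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _solve_simplex_weights(P: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimize CV negative log-likelihood of the convex combination P @ w
    over the probability simplex (SLSQP with uniform start)."""
    m = P.shape[1]
    if m == 1:
        return np.array([1.0])

    def obj(w):
        return _neg_loglik(P @ w, y)

    cons = ({"type": "eq", "fun": lambda w: np.sum(w) - 1.0},)
    res = minimize(obj, np.full(m, 1.0 / m), method="SLSQP",
                   bounds=[(0.0, 1.0)] * m, constraints=cons,
                   options={"maxiter": 500, "ftol": 1e-12})
    w = np.clip(res.x, 0.0, None)
    w = w / w.sum()
    # the discrete-best member is always a feasible point; never do worse
    candidates = [w] + [np.eye(m)[j] for j in range(m)]
    return min(candidates, key=obj)


def choose_n_folds(y: np.ndarray, requested: int = 10,
                   min_events_per_fold: int = 30) -> int:
    """Default 10 folds, dropped to 5 when the minority class would supply
    fewer than ``min_events_per_fold`` events per fold (rare outcomes),
    and never more folds than minority-class members."""
    minority = int(min(np.sum(y), np.sum(1 - y)))
    n = requested
    if minority / max(n, 1) < min_events_per_fold:
        n = min(n, 5)
    return max(2, min(n, minority)) if minority >= 2 else 2


def cv_stack(library: LearnerLibrary, X, y, n_folds: int = 10,
             seed: int = 0) -> StackFit:
    """Fit the cross-validated stack.

    Each member is fit on every training fold; ensemble weights minimize the
    out-of-fold negative log-likelihood over the simplex; members are then
    refit on the full data for prediction.  A member that raises during
    fitting gets weight 0 (with a warning); if every member fails, an error
    is raised.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_folds = min(n_folds, choose_n_folds(y, n_folds))

    m = len(library.members)
    n = len(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    P = np.full((n, m), np.nan)
    failed = np.zeros(m, dtype=bool)

    for f, (tr, te) in enumerate(skf.split(X, y)):
        fold_assignment[te] = f
        for j, tag in enumerate(library.members):
            if failed[j]:
                continue
            try:
                member = _MEMBER_CLASSES[tag](seed=seed + j)
                member.fit(X[tr], y[tr])
                P[te, j] = member.predict(X[te])
            except Exception as exc:  # noqa: BLE001 - member failure is recoverable
                warnings.warn(f"learner {tag!r} failed during CV ({exc}); weight set to 0")
                failed[j] = True

    alive = np.flatnonzero(~failed)
    if alive.size == 0:
        raise RuntimeError("all learners in the library failed to fit")

    cv_risk = np.full(m, np.inf)
    for j in alive:
        cv_risk[j] = _neg_loglik(P[:, j], y)

    weights = np.zeros(m)
    weights[alive] = _solve_simplex_weights(P[:, alive], y)

    models: list = [None] * m
    for j in alive:
        try:
            models[j] = _MEMBER_CLASSES[library.members[j]](seed=seed + j).fit(X, y)
        except Exception as exc:  # noqa: BLE001
            warnings.warn(f"learner {library.members[j]!r} failed on full data ({exc})")
            weights[j] = 0.0
            models[j] = None
    if weights.sum() == 0:
        raise RuntimeError("all learners in the library failed on the full data")
    weights = weights / weights.sum()

    metadata = {"n_folds": n_folds, "seed": seed,
                "failed_members": [library.members[j] for j in np.flatnonzero(failed)]}
    if "adaptive_splines" in library.members:
        metadata["adaptive_splines_substitution"] = _HingeSplineLogistic.substitution
    return StackFit(library=library, weights=weights, cv_risk=cv_risk,
                    fold_assignment=fold_assignment, models=models,
                    n_features=X.shape[1], metadata=metadata)


def predict_stack(fit: StackFit, X_new) -> np.ndarray:
    """Convex combination of the member probability predictions."""
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != fit.n_features:
        raise ValueError(f"expected {fit.n_features} features, got "
                         f"{X_new.shape[1] if X_new.ndim == 2 else 'non-2D input'}")
    out = np.zeros(len(X_new))
    for w, model in zip(fit.weights, fit.models):
        if w > 0 and model is not None:
            out += w * model.predict(X_new)
    return np.clip(out, 0.0, 1.0)
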