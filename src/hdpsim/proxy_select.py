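"""Proxy-covariate selection rules.

Three data-driven rules decide which of the high-dimensional binary proxies
enter the adjustment set (investigator-specified covariates are always
retained a priori and never subjected to selection):

* ``hdps``   — rank proxies by the Bross bias multiplier computed from their
               marginal exposure and outcome associations; keep the top k.
* ``lasso``  — L1-penalized logistic outcome regression; keep proxies with
               nonzero coefficients at the cross-validation-chosen penalty.
* ``hybrid`` — Bross ranking restricts to the top k, then the penalized
               regression shrinks within that subset.
* ``ks``     — "kitchen sink": all proxies; ``none`` — no proxies.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV

METHOD_TAGS = ("hdps", "lasso", "hybrid", "ks", "none")


@dataclass(frozen=True)
class ProxyAssociation:
    """Marginal associations of one binary proxy with exposure and outcome."""

    p_c1: float   # prevalence of the proxy among the exposed
    p_c0: float   # prevalence among the unexposed
    rr_cd: float  # outcome risk ratio, proxy=1 vs proxy=0
    bias_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_c1 <= 1.0 and 0.0 <= self.p_c0 <= 1.0):
            raise ValueError("proxy prevalences must lie in [0,1]")
        if self.rr_cd <= 0:
            raise ValueError("outcome risk ratio must be positive")


@dataclass
class ProxySet:
    """Result of one selection rule; JSON-serializable for audit trails."""

    selected_idx: np.ndarray
    method_tag: str
    scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.selected_idx = np.asarray(self.selected_idx, dtype=int)
        if self.method_tag not in METHOD_TAGS:
            raise ValueError(f"method_tag must be one of {METHOD_TAGS}")
        if len(np.unique(self.selected_idx)) != len(self.selected_idx):
            raise ValueError("selected_idx contains duplicates")

    def to_json(self) -> str:
        return json.dumps({"method_tag": self.method_tag,
                           "selected_idx": self.selected_idx.tolist(),
                           "scores": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                                      for k, v in self.scores.items()}})

    @classmethod
    def from_json(cls, s: str) -> "ProxySet":
        d = json.loads(s)
        return cls(selected_idx=np.asarray(d["selected_idx"], dtype=int),
                   method_tag=d["method_tag"], scores=d.get("scores", {}))


def bross_bias_score(p_c1: float, p_c0: float, rr_cd: float) -> float:
    """Absolute log of the Bross confounding-bias multiplier.

    |log[(p_c1 (RR-1) + 1) / (p_c0 (RR-1) + 1)]| — the bias a binary
    covariate with these marginal associations could induce in the exposure-
    outcome risk ratio; 0 whenever RR = 1 or the prevalences are equal.
    """
    if rr_cd <= 0:
        raise ValueError(f"rr_cd must be positive, got {rr_cd}")
    if not (0.0 <= p_c1 <= 1.0 and 0.0 <= p_c0 <= 1.0):
        raise ValueError("prevalences must lie in [0,1]")
    return abs(float(np.log((p_c1 * (rr_cd - 1.0) + 1.0) /
                            (p_c0 * (rr_cd - 1.0) + 1.0))))


def _rate(num: float, den: float) -> float:
    return num / den


def estimate_proxy_associations(A: np.ndarray, Y: np.ndarray,
                                c: np.ndarray) -> ProxyAssociation:
    """Empirical marginal associations of one proxy column.

    p_c1/p_c0 come from the exposure-by-proxy 2x2 table; rr_cd from the
    proxy-by-outcome table.  If any cell of a table is zero, 0.1 is added
    to every cell of that table (the standard continuity correction used by
    hdPS implementations) so rare proxies keep finite scores.
    """
    A = np.asarray(A); Y = np.asarray(Y); c = np.asarray(c)
    n1, n0 = A.sum(), (1 - A).sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("association undefined: all rows share one exposure level")

    # exposure x proxy table
    cells_ac = np.array([[(A * c).sum(), (A * (1 - c)).sum()],
                         [((1 - A) * c).sum(), ((1 - A) * (1 - c)).sum()]], dtype=float)
    if np.any(cells_ac == 0):
        cells_ac += 0.1
    p_c1 = _rate(cells_ac[0, 0], cells_ac[0].sum())
    p_c0 = _rate(cells_ac[1, 0], cells_ac[1].sum())

    # proxy x outcome table
    cells_cy = np.array([[(c * Y).sum(), (c * (1 - Y)).sum()],
                         [((1 - c) * Y).sum(), ((1 - c) * (1 - Y)).sum()]], dtype=float)
    if np.any(cells_cy == 0):
        cells_cy += 0.1
    risk1 = _rate(cells_cy[0, 0], cells_cy[0].sum())
    risk0 = _rate(cells_cy[1, 0], cells_cy[1].sum())
    rr_cd = risk1 / risk0

    return ProxyAssociation(p_c1=p_c1, p_c0=p_c0, rr_cd=rr_cd,
                            bias_score=bross_bias_score(p_c1, p_c0, rr_cd))


def rank_and_select_hdps(A: np.ndarray, Y: np.ndarray, C: pd.DataFrame | np.ndarray,
                         k: int = 100) -> ProxySet:
    """Bross-formula ranking: score every proxy, keep the top min(k, p).

    Ties broken deterministically toward the lower column index (stable sort
    on descending score).
    """
    M = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C)
    scores = np.array([estimate_proxy_associations(A, Y, M[:, j]).bias_score
                       for j in range(M.shape[1])])
    order = np.argsort(-scores, kind="stable")
    sel = order[: min(k, M.shape[1])]
    return ProxySet(selected_idx=sel, method_tag="hdps",
                    scores={"bias_score": scores})


def select_lasso(A: np.ndarray, Y: np.ndarray, C: pd.DataFrame | np.ndarray,
                 X_extra: np.ndarray | None = None, n_folds: int = 10,
                 Cs: int = 10, seed: int = 0) -> ProxySet:
    """L1-penalized logistic outcome regression; proxies with nonzero
    coefficients at the minimum-CV-deviance penalty are selected.

    Investigator covariates (``X_extra``) and the exposure are offered to
    the fit alongside the proxies, but only proxy columns are eligible for
    selection reporting — non-proxy columns are retained a priori downstream
    regardless of their coefficients here.
    """
    Y = np.asarray(Y)
    if len(np.unique(Y)) < 2:
        raise ValueError("degenerate outcome: all rows share one outcome level")
    M = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C)
    parts = [M, np.asarray(A, dtype=float).reshape(-1, 1)]
    if X_extra is not None and X_extra.size:
        parts.append(np.asarray(X_extra, dtype=float))
    X = np.column_stack(parts)

    n_folds_eff = min(n_folds, int(min(Y.sum(), (1 - Y).sum())))
    model = LogisticRegressionCV(
        penalty="l1", solver="liblinear", cv=max(2, n_folds_eff), Cs=Cs,
        scoring="neg_log_loss", random_state=seed, max_iter=2000)
    model.fit(X, Y)
    coef_proxies = model.coef_.ravel()[: M.shape[1]]
    sel = np.flatnonzero(coef_proxies != 0.0)
    return ProxySet(selected_idx=sel, method_tag="lasso",
                    scores={"coef": coef_proxies, "C_chosen": float(model.C_[0])})


def select_hybrid(A: np.ndarray, Y: np.ndarray, C: pd.DataFrame | np.ndarray,
                  k: int = 100, X_extra: np.ndarray | None = None,
                  n_folds: int = 10, Cs: int = 10, seed: int = 0) -> ProxySet:
    """Sequential hybrid: Bross ranking restricts to the top k, then the
    penalized outcome regression shrinks within the restricted subset; the
    final set is the nonzero-coefficient proxies of the restricted fit."""
    M = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C)
    stage1 = rank_and_select_hdps(A, Y, M, k=k)
    sub = M[:, stage1.selected_idx]
    stage2 = select_lasso(A, Y, sub, X_extra=X_extra, n_folds=n_folds, Cs=Cs, seed=seed)
    sel = stage1.selected_idx[stage2.selected_idx]
    return ProxySet(selected_idx=sel, method_tag="hybrid",
                    scores={"bias_score": stage1.scores["bias_score"],
                            "stage2_coef": stage2.scores["coef"]})


def all_proxies(C: pd.DataFrame | np.ndarray) -> ProxySet:
    """'Kitchen sink': every proxy column."""
    p = C.shape[1]
    return ProxySet(selected_idx=np.arange(p), method_tag="ks")


def no_proxies() -> ProxySet:
    return ProxySet(selected_idx=np.array([], dtype=int), method_tag="none")
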