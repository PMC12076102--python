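"""Plasmode simulation engine.

A plasmode simulation resamples *real* (here: synthetic base) covariate and
exposure rows without modification and generates the outcome from a known,
investigator-controlled model, so the causal truth is known while covariate
structure stays realistic.  The outcome model deliberately uses *transformed*
laboratory terms (log / exponential / square root / polynomial / pairwise
interactions) while analysts only ever see the raw labs — misspecification
of continuous terms is part of the challenge being simulated — plus a
comorbidity burden score equal to the sum of the signal proxies.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import expit, solve_intercept
from .cohort import BaseCohort, ConfigurationError, recalibrate_exposure

TRANSFORM_TAGS = ("log", "exp", "sqrt", "poly", "interaction")


@dataclass(frozen=True)
class Transform:
    """One recorded lab transformation: (function tag, input column(s), parameters)."""

    tag: str
    cols: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tag not in TRANSFORM_TAGS:
            raise ConfigurationError(f"unknown transform tag {self.tag!r}; "
                                     f"allowed: {TRANSFORM_TAGS}")

    def apply(self, L: pd.DataFrame) -> np.ndarray:
        v = L[self.cols[0]].to_numpy(dtype=float)
        if self.tag == "log":
            if np.any(v <= 0):
                raise ValueError(f"log transform of non-positive values in {self.cols[0]}")
            return np.log(v)
        if self.tag == "sqrt":
            if np.any(v < 0):
                raise ValueError(f"sqrt transform of negative values in {self.cols[0]}")
            return np.sqrt(v)
        if self.tag == "exp":
            out = np.exp(self.params.get("rate", -1.0) * v)
            if not np.all(np.isfinite(out)):
                raise ValueError(f"exp transform overflowed on {self.cols[0]}")
            return out
        if self.tag == "poly":
            return v ** self.params.get("degree", 2)
        # interaction
        return v * L[self.cols[1]].to_numpy(dtype=float)

    def to_dict(self) -> dict:
        return {"tag": self.tag, "cols": list(self.cols), "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Transform":
        return cls(tag=d["tag"], cols=tuple(d["cols"]), params=dict(d.get("params", {})))


@dataclass
class DgmSpec:
    """The outcome data-generating model.

    logit P(Y=1) = intercept + beta_A * A + beta_spec . D(X)
                   + beta_trans . T_std(L) + beta_score * score(C)

    where D(X) are non-reference category indicators, T_std the transformed
    lab terms standardized with the base-cohort moments stored here (so the
    correctly specified "oracle" design is reconstructible), and score(C)
    the comorbidity burden (sum of signal proxies).
    """

    beta_A: float
    beta_spec: np.ndarray
    beta_trans: np.ndarray
    transform_list: list[Transform]
    beta_score: float
    signal_idx: np.ndarray
    spec_level_counts: list[int]
    term_means: np.ndarray
    term_sds: np.ndarray
    intercept: float = 0.0
    target_outcome_prevalence: float | None = None

    @property
    def true_or(self) -> float:
        return float(np.exp(self.beta_A))

    # --- design pieces ------------------------------------------------------
    def spec_design(self, X_spec: pd.DataFrame) -> np.ndarray:
        """Category indicators with the level counts fixed at spec creation
        (stable across resamples even if a rare level is absent)."""
        blocks = []
        for col, k in zip(X_spec.columns, self.spec_level_counts):
            x = X_spec[col].to_numpy()
            for lev in range(1, k):
                blocks.append((x == lev).astype(float))
        return np.column_stack(blocks) if blocks else np.empty((len(X_spec), 0))

    def transformed_design(self, L: pd.DataFrame) -> np.ndarray:
        if not self.transform_list:
            return np.empty((len(L), 0))
        T = np.column_stack([t.apply(L) for t in self.transform_list])
        return (T - self.term_means) / self.term_sds

    def oracle_design(self, X_spec: pd.DataFrame, L: pd.DataFrame,
                      C: pd.DataFrame) -> np.ndarray:
        """The correctly specified confounder design (everything but A):
        category indicators, standardized transformed lab terms, comorbidity
        score.  Used by oracle-adjusted estimators in validation studies."""
        score = comorbidity_score(C, self.signal_idx).astype(float)
        return np.column_stack([self.spec_design(X_spec),
                                self.transformed_design(L), score])

    def linear_predictor(self, X_spec: pd.DataFrame, L: pd.DataFrame,
                         C: pd.DataFrame, A: np.ndarray) -> np.ndarray:
        score = comorbidity_score(C, self.signal_idx)
        return (self.intercept + self.beta_A * np.asarray(A, dtype=float)
                + self.spec_design(X_spec) @ self.beta_spec
                + self.transformed_design(L) @ self.beta_trans
                + self.beta_score * score)


def comorbidity_score(C: pd.DataFrame | np.ndarray, signal_idx: np.ndarray) -> np.ndarray:
    """Per-row sum of the signal proxy indicators (noise columns never count)."""
    M = C.to_numpy() if isinstance(C, pd.DataFrame) else np.asarray(C)
    signal_idx = np.asarray(signal_idx, dtype=int)
    if signal_idx.size and (signal_idx.min() < 0 or signal_idx.max() >= M.shape[1]):
        raise IndexError(f"signal index out of range for {M.shape[1]} proxy columns")
    return M[:, signal_idx].sum(axis=1)


def default_dgm(base: BaseCohort, true_or: float = 1.0,
                target_outcome_prevalence: float = 0.30,
                score_logodds_sd: float = 0.8,
                calibrate: bool = True) -> DgmSpec:
    """Default outcome model: moderate confounding.

    Transformed lab terms get alternating-sign coefficients with magnitudes
    0.2-0.4 on the standardized log-odds scale; the comorbidity score
    coefficient is chosen so the score term contributes ``score_logodds_sd``
    log-odds standard deviations over the base cohort (comparable to the lab
    block), which is what makes the latent comorbidity a real confounder.
    """
    lab_cols = list(base.L.columns)
    if len(lab_cols) < 2:
        raise ConfigurationError("default DGM needs at least 2 lab columns")

    def lc(i: int) -> str:
        return lab_cols[i % len(lab_cols)]

    transforms = [
        Transform("log", (lc(0),)),
        Transform("sqrt", (lc(1),)),
        Transform("exp", (lc(2),), {"rate": -1.0}),
        Transform("poly", (lc(3),), {"degree": 2}),
        Transform("interaction", (lc(4), lc(5))),
        Transform("log", (lc(6),)),
        Transform("poly", (lc(7),), {"degree": 3}),
        Transform("sqrt", (lc(8),)),
        Transform("interaction", (lc(9), lc(10))),
    ]
    mags = [0.30, -0.25, 0.35, -0.20, 0.40, -0.30, 0.25, -0.35, 0.20]
    T = np.column_stack([t.apply(base.L) for t in transforms])
    term_means, term_sds = T.mean(axis=0), T.std(axis=0, ddof=0)

    level_counts = [int(base.X_spec[c].max()) + 1 for c in base.X_spec.columns]
    n_ind = sum(k - 1 for k in level_counts)
    beta_spec = 0.15 * np.power(-1.0, np.arange(n_ind))

    score = comorbidity_score(base.C, base.signal_idx)
    sd_score = float(np.std(score, ddof=0))
    beta_score = score_logodds_sd / sd_score if sd_score > 0 else 0.0

    dgm = DgmSpec(beta_A=float(np.log(true_or)), beta_spec=beta_spec,
                  beta_trans=np.asarray(mags), transform_list=transforms,
                  beta_score=beta_score, signal_idx=np.asarray(base.signal_idx),
                  spec_level_counts=level_counts, term_means=term_means,
                  term_sds=term_sds, intercept=0.0,
                  target_outcome_prevalence=target_outcome_prevalence)
    if calibrate:
        dgm.intercept = calibrate_intercept(dgm, base, target_outcome_prevalence)
    return dgm


def calibrate_intercept(dgm: DgmSpec, base: BaseCohort, target: float,
                        tol: float = 1e-6) -> float:
    """Intercept such that the expected outcome prevalence over the base
    cohort (exposure at its observed values) hits ``target``; monotone
    bisection, error with the achievable range if the target is outside it."""
    if not 0.0 < target < 1.0:
        raise ConfigurationError(f"target outcome prevalence must be in (0,1), got {target}")
    fixed = (dgm.linear_predictor(base.X_spec, base.L, base.C, base.A) - dgm.intercept)
    return solve_intercept(fixed, target, tol=tol)


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: controlled exposure/outcome prevalence,
    true conditional odds ratio, dataset size and iteration count."""

    exposure_prevalence: float = 0.30
    outcome_prevalence: float = 0.30
    true_or: float = 1.0
    n_per_dataset: int = 3000
    n_iterations: int = 500
    label: str = "base"

    def __post_init__(self) -> None:
        for name in ("exposure_prevalence", "outcome_prevalence"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0,1)")
        if self.n_per_dataset < 1 or self.n_iterations < 1:
            raise ConfigurationError("n_per_dataset and n_iterations must be >= 1")
        if self.true_or <= 0:
            raise ConfigurationError("true_or must be positive")


#: presets for the three study scenarios plus a fast smoke configuration
SCENARIOS: dict[str, ScenarioConfig] = {
    "base": ScenarioConfig(0.30, 0.30, 1.0, 3000, 500, "base"),
    "rare_exposure": ScenarioConfig(0.05, 0.30, 1.0, 3000, 500, "rare_exposure"),
    "rare_outcome": ScenarioConfig(0.30, 0.05, 1.0, 3000, 500, "rare_outcome"),
    "smoke": ScenarioConfig(0.30, 0.30, 1.0, 500, 50, "smoke"),
}


def prepare_scenario(base: BaseCohort, scenario: ScenarioConfig,
                     seed: int = 0) -> tuple[BaseCohort, DgmSpec]:
    """Adapt a base cohort and build the calibrated DGM for one scenario.

    Exposure prevalence is changed by recalibrating the exposure-model
    intercept and redrawing A (covariate-exposure associations preserved),
    never by rejection sampling.
    """
    if abs(scenario.exposure_prevalence -
           (base.config.exposure_prevalence if base.config else np.mean(base.A))) > 1e-9:
        base = recalibrate_exposure(base, scenario.exposure_prevalence, seed)
    dgm = default_dgm(base, true_or=scenario.true_or,
                      target_outcome_prevalence=scenario.outcome_prevalence)
    return base, dgm


@dataclass
class SimulatedDataset:
    """One plasmode iteration: resampled rows plus generated outcome."""

    X_spec: pd.DataFrame
    L: pd.DataFrame
    C: pd.DataFrame
    A: np.ndarray
    Y: np.ndarray
    iteration_id: int = 0
    seed: int | None = None
    base_indices: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.A)

    def to_dataframe(self) -> pd.DataFrame:
        idx = self.X_spec.index
        return pd.concat([self.X_spec, self.L, self.C,
                          pd.Series(self.A, name="A", index=idx),
                          pd.Series(self.Y, name="Y", index=idx)], axis=1)


def resample_cohort(base: BaseCohort, n: int, seed) -> dict:
    """Sample n rows with replacement; covariates and exposure copied unmodified."""
    if n <= 0:
        raise ConfigurationError(f"resample size must be positive, got {n}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, base.n, size=n)
    return {
        "X_spec": base.X_spec.iloc[idx].reset_index(drop=True),
        "L": base.L.iloc[idx].reset_index(drop=True),
        "C": base.C.iloc[idx].reset_index(drop=True),
        "A": base.A[idx].copy(),
        "indices": idx,
    }


def generate_outcome(dgm: DgmSpec, X_spec: pd.DataFrame, L: pd.DataFrame,
                     C: pd.DataFrame, A: np.ndarray, seed) -> np.ndarray:
    """Bernoulli outcome draws from the calibrated model."""
    rng = np.random.default_rng(seed)
    p = expit(dgm.linear_predictor(X_spec, L, C, A))
    return (rng.random(len(p)) < p).astype(np.int64)


def simulate_dataset(base: BaseCohort, dgm: DgmSpec, n: int, seed,
                     iteration_id: int = 0) -> SimulatedDataset:
    """Resample + outcome generation for one iteration (one seed stream)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_rows, s_y = ss.spawn(2)
    rows = resample_cohort(base, n, s_rows)
    Y = generate_outcome(dgm, rows["X_spec"], rows["L"], rows["C"], rows["A"], s_y)
    return SimulatedDataset(X_spec=rows["X_spec"], L=rows["L"], C=rows["C"],
                            A=rows["A"], Y=Y, iteration_id=iteration_id,
                            base_indices=rows["indices"])


def true_marginal_rd(dgm: DgmSpec, base: BaseCohort, n_mc: int = 100_000,
                     seed=0) -> float:
    """E[Y^{a=1}] - E[Y^{a=0}] by counterfactual standardization: set A to 1
    then 0 for every resampled row and average the model probabilities (no
    Bernoulli noise needed).  Exactly 0 whenever beta_A = 0."""
    rows = resample_cohort(base, n_mc, seed)
    lp0 = dgm.linear_predictor(rows["X_spec"], rows["L"], rows["C"],
                               np.zeros(n_mc, dtype=float))
    p1 = expit(lp0 + dgm.beta_A)
    p0 = expit(lp0)
    return float(np.mean(p1) - np.mean(p0))
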