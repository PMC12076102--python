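"""Synthetic base-cohort generator.

Emulates the analytic structure of a survey-style epidemiological file
(NHANES-like): a modest set of investigator-specified categorical covariates,
a block of correlated continuous laboratory measurements, a large panel of
binary medication-indicator proxies, and a binary exposure.  A latent
comorbidity construct U drives both the signal proxies and the exposure, so
the proxies play exactly the role of proxies for an unmeasured confounder:
adjusting for them (or for their sum) removes confounding that the
investigator-specified covariates alone cannot.

Generative scheme (all one pass, single RNG):

* categorical covariates: independent multinomials with 2-4 levels,
  level probabilities proportional to (k, k-1, ..., 1);
* labs: lognormal, ``L_j = exp(0.4 Z_j)`` with Z ~ MVN(0, AR(1) rho=0.3);
* latent comorbidity: U ~ N(0, 1);
* signal proxies: Bernoulli(expit(a0_j + loading * U)), baseline logits
  spread over prevalences 0.08-0.35;
* noise proxies: independent Bernoulli, prevalences 0.05-0.35;
* exposure: logit-linear in category indicators, standardized log-labs and
  U, intercept solved by bisection to hit the target prevalence.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import expit, logit, rng_for, solve_intercept


class ConfigurationError(ValueError):
    """Raised when a cohort or scenario configuration is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic base population.

    Association-strength knobs (``proxy_loading``, ``exposure_latent_coef``,
    ``exposure_cov_scale``) are exposed rather than hard-coded because the
    strength of the proxy-exposure association is a study design choice,
    not a structural constant.
    """

    n_base: int = 25_000
    n_spec_cat: int = 14
    n_labs: int = 11
    n_proxies: int = 142
    n_signal_proxies: int = 94
    exposure_prevalence: float = 0.30
    seed: int = 0
    proxy_loading: float = 1.0        # U -> signal proxy log-odds slope
    exposure_latent_coef: float = 1.0  # U -> exposure log-odds slope
    exposure_cov_scale: float = 1.0    # multiplier on covariate -> exposure coefs

    def __post_init__(self) -> None:
        for name in ("n_base", "n_spec_cat", "n_labs", "n_proxies", "n_signal_proxies"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_signal_proxies > self.n_proxies:
            raise ConfigurationError(
                f"n_signal_proxies ({self.n_signal_proxies}) exceeds n_proxies ({self.n_proxies})")
        if not 0.0 < self.exposure_prevalence < 1.0:
            raise ConfigurationError(
                f"exposure_prevalence must be in (0,1), got {self.exposure_prevalence}")


@dataclass
class BaseCohort:
    """The population that plasmode iterations resample.

    ``latent``, ``exposure_eta`` and ``true_propensity`` are diagnostic
    fields available only for synthetically generated cohorts (None for
    cohorts loaded from a user CSV); estimators never see them.
    """

    X_spec: pd.DataFrame
    L: pd.DataFrame
    C: pd.DataFrame
    A: np.ndarray
    signal_idx: np.ndarray
    noise_idx: np.ndarray
    config: CohortConfig | None = None
    latent: np.ndarray | None = None
    exposure_eta: np.ndarray | None = None   # non-intercept exposure linear predictor
    true_propensity: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.intersect1d(self.signal_idx, self.noise_idx).size:
            raise ConfigurationError("signal_idx and noise_idx overlap")
        if len(self.signal_idx) + len(self.noise_idx) != self.C.shape[1]:
            raise ConfigurationError("signal_idx + noise_idx must partition the proxy columns")

    @property
    def n(self) -> int:
        return len(self.A)

    def to_dataframe(self) -> pd.DataFrame:
        """Analyst view: covariates, labs, proxies and exposure, one row per person."""
        return pd.concat(
            [self.X_spec, self.L, self.C,
             pd.Series(self.A, name="A", index=self.X_spec.index)], axis=1)

    # --- persistence: flat CSV + JSON sidecar -------------------------------
    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        self.to_dataframe().to_csv(csv_path, index=False)
        sidecar = {
            "spec_columns": list(self.X_spec.columns),
            "lab_columns": list(self.L.columns),
            "proxy_columns": list(self.C.columns),
            "exposure_column": "A",
            "signal_idx": [int(i) for i in self.signal_idx],
            "noise_idx": [int(i) for i in self.noise_idx],
            "seed": self.seed,
        }
        csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "BaseCohort":
        csv_path = Path(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        df = pd.read_csv(csv_path)
        return cls(
            X_spec=df[meta["spec_columns"]].astype(int),
            L=df[meta["lab_columns"]].astype(float),
            C=df[meta["proxy_columns"]].astype(int),
            A=df[meta["exposure_column"]].to_numpy(dtype=int),
            signal_idx=np.asarray(meta["signal_idx"], dtype=int),
            noise_idx=np.asarray(meta["noise_idx"], dtype=int),
            seed=meta.get("seed"),
        )


def _ar1_cov(p: int, rho: float) -> np.ndarray:
    idx = np.arange(p)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _category_sizes(n_cat: int) -> list[int]:
    # deterministic 2,3,4,2,3,4,... level counts
    return [2 + (j % 3) for j in range(n_cat)]


def _spec_indicator_matrix(X_spec: pd.DataFrame) -> np.ndarray:
    """Non-reference level indicators, fixed column order."""
    blocks = []
    for col in X_spec.columns:
        x = X_spec[col].to_numpy()
        for lev in range(1, int(x.max()) + 1):
            blocks.append((x == lev).astype(float))
    return np.column_stack(blocks) if blocks else np.empty((len(X_spec), 0))


def _exposure_linear_predictor(X_spec: pd.DataFrame, Z: np.ndarray, U: np.ndarray,
                               config: CohortConfig) -> np.ndarray:
    """Non-intercept part of the exposure logit (covariates + latent)."""
    D = _spec_indicator_matrix(X_spec)
    coef_spec = 0.25 * np.power(-1.0, np.arange(D.shape[1])) * config.exposure_cov_scale
    coef_lab = 0.15 * np.power(-1.0, np.arange(Z.shape[1])) * config.exposure_cov_scale
    return D @ coef_spec + Z @ coef_lab + config.exposure_latent_coef * U


def generate_base_cohort(config: CohortConfig) -> BaseCohort:
    """Draw a base population from the latent-comorbidity scheme above.

    Deterministic given ``config`` (including its seed): same config, same
    cohort, bit for bit.
    """
    rng = rng_for(config.seed, 0)
    n = config.n_base

    # categorical investigator covariates
    cols = {}
    for j, k in enumerate(_category_sizes(config.n_spec_cat)):
        p = np.arange(k, 0, -1, dtype=float)
        cols[f"x{j + 1}"] = rng.choice(k, size=n, p=p / p.sum())
    X_spec = pd.DataFrame(cols)

    # correlated labs (lognormal; Z is the standardized log scale)
    chol = np.linalg.cholesky(_ar1_cov(config.n_labs, 0.3))
    Z = rng.standard_normal((n, config.n_labs)) @ chol.T
    L = pd.DataFrame(np.exp(0.4 * Z), columns=[f"lab{j + 1}" for j in range(config.n_labs)])

    # latent comorbidity and proxies
    U = rng.standard_normal(n)
    n_sig, n_noise = config.n_signal_proxies, config.n_proxies - config.n_signal_proxies
    C = np.empty((n, config.n_proxies), dtype=np.int64)
    signal_idx = np.arange(n_sig)
    noise_idx = np.arange(n_sig, config.n_proxies)
    a0 = logit(np.linspace(0.08, 0.35, n_sig))
    for j in range(n_sig):
        C[:, j] = rng.random(n) < expit(a0[j] + config.proxy_loading * U)
    if n_noise:
        p_noise = np.linspace(0.05, 0.35, n_noise)
        for j, p in zip(noise_idx, p_noise):
            C[:, j] = rng.random(n) < p
    C = pd.DataFrame(C, columns=[f"proxy{j + 1}" for j in range(config.n_proxies)])

    # exposure: logit-linear, intercept calibrated by bisection
    eta = _exposure_linear_predictor(X_spec, Z, U, config)
    alpha0 = solve_intercept(eta, config.exposure_prevalence, tol=1e-4)
    g_true = expit(alpha0 + eta)
    A = (rng.random(n) < g_true).astype(np.int64)

    return BaseCohort(X_spec=X_spec, L=L, C=C, A=A,
                      signal_idx=signal_idx, noise_idx=noise_idx,
                      config=config, latent=U, exposure_eta=eta,
                      true_propensity=g_true, seed=config.seed)


def recalibrate_exposure(base: BaseCohort, target_prevalence: float, seed: int) -> BaseCohort:
    """Redraw exposure at a new target prevalence, keeping every covariate-
    exposure association (only the exposure-model intercept moves).

    Used for the rare-exposure scenario; requires a synthetically generated
    cohort (needs the stored linear predictor).
    """
    if base.exposure_eta is None:
        raise ConfigurationError("recalibrate_exposure needs a synthetic cohort "
                                 "(exposure linear predictor unavailable)")
    if not 0.0 < target_prevalence < 1.0:
        raise ConfigurationError(f"target_prevalence must be in (0,1), got {target_prevalence}")
    rng = rng_for(seed, 1)
    alpha0 = solve_intercept(base.exposure_eta, target_prevalence, tol=1e-4)
    g_true = expit(alpha0 + base.exposure_eta)
    A = (rng.random(base.n) < g_true).astype(np.int64)
    cfg = replace(base.config, exposure_prevalence=target_prevalence) if base.config else None
    return BaseCohort(X_spec=base.X_spec, L=base.L, C=base.C, A=A,
                      signal_idx=base.signal_idx, noise_idx=base.noise_idx,
                      config=cfg, latent=base.latent, exposure_eta=base.exposure_eta,
                      true_propensity=g_true, seed=seed)
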