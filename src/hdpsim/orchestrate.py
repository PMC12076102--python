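"""Scenario runner: wires base cohort -> plasmode iterations -> method grid
-> performance metrics, with deterministic seed streams.

Seed scheme (counter-based, documented): ``master_seed`` plus a stream key
identifies every random draw.  The dataset of iteration i depends only on
(master_seed, i), and method m's analysis of iteration i only on
(master_seed, i, m's fixed grid index) — so any single iteration can be
re-run in isolation and adding a method never changes another method's
estimates.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.linear_model import LogisticRegression

from ._utils import child_seed
from .cohort import BaseCohort, CohortConfig, generate_base_cohort
from .estimators import (EstimateRecord, WeightSpec, classify_imbalanced,
                         dc_tmle_rd, fit_propensity, ipw_rd, tmle_rd)
from .evaluate import PerformanceTable, compute_metrics
from .learners import LearnerLibrary
from .plasmode import (SCENARIOS, DgmSpec, ScenarioConfig, prepare_scenario,
                       simulate_dataset, true_marginal_rd)
from .proxy_select import (all_proxies, no_proxies, rank_and_select_hdps,
                           select_hybrid, select_lasso)

logger = logging.getLogger("hdpsim")


@dataclass(frozen=True)
class MethodSpec:
    """One cell of the method grid: selection rule x estimator x propensity
    learner x adjustment strategy x weight stabilization."""

    tag: str
    selection: str          # none | hdps | lasso | hybrid | ks
    estimator: str          # ipw | tmle | dc_tmle
    ps_learner: str         # "logistic" (plain fit) or "stack" (super learner)
    strategy: str = "none"  # outcome-model adjustment (IPW methods)
    stabilized: bool = True


#: Fixed method grid; the index of a tag in this order is its seed stream id.
METHOD_GRID: dict[str, MethodSpec] = {
    "PS.u": MethodSpec("PS.u", "none", "ipw", "logistic"),
    "SL.u": MethodSpec("SL.u", "none", "ipw", "stack"),
    "TMLE.u": MethodSpec("TMLE.u", "none", "tmle", "stack"),
    "PS.ks": MethodSpec("PS.ks", "ks", "ipw", "logistic"),
    "hdPS": MethodSpec("hdPS", "hdps", "ipw", "logistic"),
    "LASSO": MethodSpec("LASSO", "lasso", "ipw", "logistic"),
    "hdPS.LASSO": MethodSpec("hdPS.LASSO", "hybrid", "ipw", "logistic"),
    "hdPS.SL": MethodSpec("hdPS.SL", "hdps", "ipw", "stack"),
    "LASSO.SL": MethodSpec("LASSO.SL", "lasso", "ipw", "stack"),
    "hdPS.LASSO.SL": MethodSpec("hdPS.LASSO.SL", "hybrid", "ipw", "stack"),
    "SL.ks": MethodSpec("SL.ks", "ks", "ipw", "stack"),
    "hdPS.TMLE": MethodSpec("hdPS.TMLE", "hdps", "tmle", "stack"),
    "LASSO.TMLE": MethodSpec("LASSO.TMLE", "lasso", "tmle", "stack"),
    "hdPS.LASSO.TMLE": MethodSpec("hdPS.LASSO.TMLE", "hybrid", "tmle", "stack"),
    "TMLE.ks": MethodSpec("TMLE.ks", "ks", "tmle", "stack"),
    "DC.TMLE": MethodSpec("DC.TMLE", "ks", "dc_tmle", "stack"),
}
METHOD_ORDER = list(METHOD_GRID)


@dataclass
class RunConfig:
    """Everything a scenario run needs."""

    scenario: ScenarioConfig
    methods: list[str] = field(default_factory=lambda: ["PS.u", "PS.ks"])
    library: str = "lib1"
    master_seed: int = 0
    parallel_workers: int = 1
    output_dir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    weight_spec: WeightSpec = field(default_factory=WeightSpec)
    strategy: str | None = None   # override the outcome-model adjustment
    hdps_k: int = 100             # strategy of every non-TMLE method
    dc_n_splits: int = 3
    dc_n_repeats: int = 20
    n_iterations: int | None = None   # override scenario.n_iterations
    n_per_dataset: int | None = None  # override scenario.n_per_dataset

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in METHOD_GRID]
        if unknown:
            raise ValueError(f"unknown method tags {unknown}; "
                             f"allowed: {METHOD_ORDER}")
        LearnerLibrary.from_preset(self.library)  # validate
        from .estimators import ADJUSTMENT_STRATEGIES
        if self.strategy is not None and self.strategy not in ADJUSTMENT_STRATEGIES:
            raise ValueError(f"strategy must be one of {ADJUSTMENT_STRATEGIES}")


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _spec_dummies(X_spec: pd.DataFrame) -> np.ndarray:
    blocks = []
    for col in X_spec.columns:
        x = X_spec[col].to_numpy()
        for lev in range(1, int(x.max()) + 1):
            blocks.append((x == lev).astype(float))
    return np.column_stack(blocks) if blocks else np.empty((len(X_spec), 0))


def analyst_design(ds) -> np.ndarray:
    """Analyst view of the investigator-specified covariates: category
    indicators plus *raw* labs (the analyst never sees the DGM transforms)."""
    return np.column_stack([_spec_dummies(ds.X_spec), ds.L.to_numpy(dtype=float)])


_investigator_matrix = analyst_design


def _select_proxies(spec: MethodSpec, ds, k: int, seed: int):
    C = ds.C
    if spec.selection == "none":
        return no_proxies()
    if spec.selection == "ks":
        return all_proxies(C)
    if spec.selection == "hdps":
        return rank_and_select_hdps(ds.A, ds.Y, C, k=k)
    X_extra = _investigator_matrix(ds)
    if spec.selection == "lasso":
        return select_lasso(ds.A, ds.Y, C, X_extra=X_extra, seed=seed)
    return select_hybrid(ds.A, ds.Y, C, k=k, X_extra=X_extra, seed=seed)


def _logistic_propensity(X: np.ndarray, a: np.ndarray) -> np.ndarray:
    model = LogisticRegression(penalty=None, max_iter=2000)
    model.fit(X, a)
    return model.predict_proba(X)[:, 1]


def _outcome_adjustment(strategy: str, ds, Xc: np.ndarray,
                        proxies: np.ndarray,
                        imbalance_threshold: float = 0.1) -> np.ndarray | None:
    if strategy == "none":
        return None
    if strategy in ("imbalanced_measured", "imbalanced_plus_proxies"):
        covs = pd.DataFrame(Xc, columns=[f"c{j}" for j in range(Xc.shape[1])])
        keep = classify_imbalanced(covs, ds.A, threshold=imbalance_threshold)
        base = covs[keep].to_numpy() if keep else np.empty((len(ds.A), 0))
    else:
        base = Xc
    if strategy.endswith("plus_proxies"):
        base = np.column_stack([base, proxies]) if base.size else proxies
    return base if base.size else None


def run_method(spec: MethodSpec, ds, config: RunConfig,
               seed: int) -> EstimateRecord:
    """One method on one simulated dataset (isolated seed stream)."""
    library = LearnerLibrary.from_preset(config.library)
    wspec = WeightSpec(stabilized=spec.stabilized and config.weight_spec.stabilized,
                       truncation_bounds=config.weight_spec.truncation_bounds)
    Xc = _investigator_matrix(ds)
    pset = _select_proxies(spec, ds, config.hdps_k, seed)
    proxies = ds.C.to_numpy(dtype=float)[:, pset.selected_idx] \
        if len(pset.selected_idx) else np.empty((ds.n, 0))
    X_full = np.column_stack([Xc, proxies]) if proxies.size else Xc

    if spec.estimator == "ipw":
        if spec.ps_learner == "logistic":
            g = _logistic_propensity(X_full, ds.A)
        else:
            g, _ = fit_propensity(X_full, ds.A, library, seed=seed)
        strategy = config.strategy or spec.strategy
        adjust = _outcome_adjustment(strategy, ds, Xc, proxies)
        rec = ipw_rd(ds.Y, ds.A, g, adjust=adjust, weight_spec=wspec,
                     method_tag=spec.tag)
    elif spec.estimator == "tmle":
        rec, _ = tmle_rd(ds.Y, ds.A, X_q=X_full, X_g=X_full,
                         q_library=library, g_library=library,
                         weight_spec=wspec, seed=seed, method_tag=spec.tag)
    else:  # dc_tmle
        rec = dc_tmle_rd(ds.Y, ds.A, X_full, X_full, library,
                         n_splits=config.dc_n_splits,
                         n_repeats=config.dc_n_repeats,
                         weight_spec=wspec, seed=seed, method_tag=spec.tag)
    rec.diagnostics["n_proxies_selected"] = int(len(pset.selected_idx))
    rec.diagnostics["selection"] = pset.method_tag
    return rec


def run_iteration(base: BaseCohort, dgm: DgmSpec, config: RunConfig,
                  iteration: int) -> list[dict]:
    """One plasmode iteration: resample, generate outcome, run every method.

    Method failures are recorded (NaN estimate + error message), never
    propagated.
    """
    sc = config.scenario
    n = config.n_per_dataset or sc.n_per_dataset
    ds = simulate_dataset(base, dgm, n,
                          child_seed(config.master_seed, 1, iteration),
                          iteration_id=iteration)
    rows = []
    for tag in config.methods:
        spec = METHOD_GRID[tag]
        m_idx = METHOD_ORDER.index(tag)
        seed = _seed_int(child_seed(config.master_seed, 2, iteration, m_idx))
        t0 = time.perf_counter()
        try:
            rec = run_method(spec, ds, config, seed)
        except Exception as exc:  # noqa: BLE001 - per-method isolation
            rec = EstimateRecord(method_tag=tag, rd_hat=np.nan, se_hat=np.nan,
                                 ci_low=np.nan, ci_high=np.nan,
                                 diagnostics={"failure": str(exc)})
        logger.info("scenario=%s iteration=%d method=%s runtime_s=%.4f",
                    sc.label, iteration, tag, time.perf_counter() - t0)
        row = rec.to_row()
        row.update({"iteration": iteration, "scenario": sc.label,
                    "library": config.library,
                    "strategy": config.strategy or spec.strategy,
                    "stabilized": spec.stabilized})
        rows.append(row)
    return rows


def run_scenario(config: RunConfig,
                 base: BaseCohort | None = None
                 ) -> tuple[dict[str, PerformanceTable], pd.DataFrame]:
    """Full scenario run: returns per-method performance tables and the raw
    per-iteration estimate table (also written to ``output_dir`` if set)."""
    sc = config.scenario
    if base is None:
        from dataclasses import replace
        cfg = replace(config.cohort, seed=config.master_seed)
        base = generate_base_cohort(cfg)
    base, dgm = prepare_scenario(base, sc, seed=config.master_seed)
    truth = true_marginal_rd(dgm, base, n_mc=100_000,
                             seed=child_seed(config.master_seed, 3))

    n_iter = config.n_iterations or sc.n_iterations
    if config.parallel_workers > 1:
        chunks = Parallel(n_jobs=config.parallel_workers)(
            delayed(run_iteration)(base, dgm, config, i) for i in range(n_iter))
    else:
        chunks = [run_iteration(base, dgm, config, i) for i in range(n_iter)]
    raw = pd.DataFrame([r for chunk in chunks for r in chunk])

    tables: dict[str, PerformanceTable] = {}
    for tag in config.methods:
        sub = raw[raw["method_tag"] == tag]
        recs = [EstimateRecord(method_tag=tag, rd_hat=r.rd_hat, se_hat=r.se_hat,
                               ci_low=r.ci_low, ci_high=r.ci_high)
                for r in sub.itertuples()]
        tables[tag] = compute_metrics(recs, truth)

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        raw.to_csv(out / f"estimates_{sc.label}.csv", index=False)
        tidy = pd.concat([t.to_tidy() for t in tables.values()], ignore_index=True)
        tidy["scenario"] = sc.label
        tidy["library"] = config.library
        tidy.to_csv(out / f"metrics_{sc.label}.csv", index=False)
        (out / f"run_{sc.label}.json").write_text(json.dumps(
            {"truth": truth, "master_seed": config.master_seed,
             "methods": config.methods, "library": config.library,
             "n_iterations": n_iter}, indent=1))
    return tables, raw


def scenario_preset(name: str) -> ScenarioConfig:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario preset {name!r}; allowed: {sorted(SCENARIOS)}")
    return SCENARIOS[name]
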