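"""Simulation performance metrics with Monte-Carlo uncertainty.

Given the per-iteration risk-difference estimates of one method and the
known truth, computes the standard simulation-study metrics: bias, empirical
SE, average model-based SE, relative SE error, (R)MSE, coverage of the 95%
intervals, bias-corrected coverage (intervals containing the *mean* estimate
instead of the truth, isolating interval-width calibration from bias), plus
the Monte-Carlo SE of each metric, and the ranked table behind a zip plot.

Conventions: ``empirical_se`` uses the K-1 denominator; ``avg_model_se`` is
the arithmetic mean of the per-iteration SEs (a root-mean-variance variant
is reported alongside in the extended table); MSE uses the 1/K denominator,
so mse = bias^2 + empirical_se^2 (K-1)/K exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimators import EstimateRecord


@dataclass
class PerformanceTable:
    """Per-method metrics; ``metrics`` maps metric name -> value and
    ``mc_se`` maps metric name -> its Monte-Carlo SE."""

    method_tag: str
    n_valid_iterations: int
    n_total_iterations: int
    metrics: dict = field(default_factory=dict)
    mc_se: dict = field(default_factory=dict)
    flagged_unstable: bool = False

    def to_tidy(self) -> pd.DataFrame:
        rows = [{"method_tag": self.method_tag, "metric": k, "value": v,
                 "mc_se": self.mc_se.get(k, np.nan)}
                for k, v in self.metrics.items()]
        df = pd.DataFrame(rows)
        df["n_valid_iterations"] = self.n_valid_iterations
        return df


def _finite_records(estimates: list[EstimateRecord]) -> list[EstimateRecord]:
    return [e for e in estimates
            if np.isfinite(e.rd_hat) and np.isfinite(e.se_hat)]


def compute_metrics(estimates: list[EstimateRecord], truth: float,
                    failure_flag_rate: float = 0.05) -> PerformanceTable:
    """All performance metrics for one method.

    Non-finite iterations are excluded (never imputed) and counted via
    ``n_valid_iterations``; a method failing more than ``failure_flag_rate``
    of its iterations is flagged as unstable.
    """
    total = len(estimates)
    ok = _finite_records(estimates)
    K = len(ok)
    if K < 2:
        raise ValueError(f"need at least 2 finite estimates, got {K}")
    est = np.array([e.rd_hat for e in ok])
    ses = np.array([e.se_hat for e in ok])
    lo = np.array([e.ci_low for e in ok])
    hi = np.array([e.ci_high for e in ok])

    mean_est = est.mean()
    bias = mean_est - truth
    emp_se = est.std(ddof=1)
    avg_se = ses.mean()
    rmv_se = float(np.sqrt(np.mean(ses ** 2)))  # root-mean-variance variant
    rel_err = 100.0 * (avg_se / emp_se - 1.0) if emp_se > 0 else np.nan
    mse = float(np.mean((est - truth) ** 2))
    cover = float(np.mean((lo <= truth) & (truth <= hi)))
    bc_cover = float(np.mean((lo <= mean_est) & (mean_est <= hi)))

    # Monte-Carlo SEs: standard simulation-study formulas
    mc = {
        "bias": emp_se / np.sqrt(K),
        "empirical_se": emp_se / np.sqrt(2.0 * (K - 1)),
        "avg_model_se": ses.std(ddof=1) / np.sqrt(K),
        "mse": np.std((est - truth) ** 2, ddof=1) / np.sqrt(K),
        "coverage": np.sqrt(cover * (1.0 - cover) / K),
        "bias_corrected_coverage": np.sqrt(bc_cover * (1.0 - bc_cover) / K),
    }
    if emp_se > 0:
        # delta method on the ratio avg_se / emp_se
        var_ratio = (ses.var(ddof=1) / K) / avg_se ** 2 + 1.0 / (2.0 * (K - 1))
        mc["relative_se_error_pct"] = 100.0 * (avg_se / emp_se) * np.sqrt(var_ratio)
    mc["rmse"] = mc["mse"] / (2.0 * np.sqrt(mse)) if mse > 0 else np.nan

    metrics = {
        "bias": float(bias),
        "empirical_se": float(emp_se),
        "avg_model_se": float(avg_se),
        "rmv_model_se": rmv_se,
        "relative_se_error_pct": float(rel_err),
        "mse": mse,
        "rmse": float(np.sqrt(mse)),
        "coverage": cover,
        "bias_corrected_coverage": bc_cover,
        "mean_estimate": float(mean_est),
    }
    return PerformanceTable(
        method_tag=ok[0].method_tag if ok else "unknown",
        n_valid_iterations=K, n_total_iterations=total,
        metrics=metrics, mc_se={k: float(v) for k, v in mc.items()},
        flagged_unstable=(total - K) > failure_flag_rate * total)


def zip_plot_data(estimates: list[EstimateRecord], truth: float) -> pd.DataFrame:
    """Ranked-interval table sufficient to draw a zip plot.

    Rows are sorted by the centile of |(rd_hat - truth) / se_hat|; columns:
    rank fraction, CI bounds, and whether the interval covers the truth.
    Zero-SE rows are flagged and placed last.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    est = np.array([e.rd_hat for e in estimates])
    ses = np.array([e.se_hat for e in estimates])
    lo = np.array([e.ci_low for e in estimates])
    hi = np.array([e.ci_high for e in estimates])

    zero_se = ses <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs((est - truth) / ses)
    z[zero_se] = np.inf
    order = np.argsort(z, kind="stable")
    K = len(est)
    return pd.DataFrame({
        "rank_fraction": (np.arange(1, K + 1)) / K,
        "abs_z": z[order],
        "ci_low": lo[order],
        "ci_high": hi[order],
        "covers": ((lo <= truth) & (truth <= hi))[order],
        "zero_se_flag": zero_se[order],
    })
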