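"""Small numerical helpers shared across modules."""
from __future__ import annotations

import numpy as np
from scipy.special import expit, logit  # noqa: F401  (re-exported)


def child_seed(master_seed: int, *stream: int) -> np.random.SeedSequence:
    """Deterministic counter-based seed derivation.

    ``child_seed(m, i, j)`` always yields the same stream for the same
    (m, i, j) tuple, independent of how many other streams were spawned —
    this is what makes single iterations re-runnable in isolation.
    """
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(s) for s in stream))


def rng_for(master_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *stream))


def solve_intercept(fixed_logit: np.ndarray, target: float, tol: float = 1e-6,
                    lo: float = -40.0, hi: float = 40.0) -> float:
    """Bisection for c such that mean(expit(c + fixed_logit)) == target.

    The map c -> mean prevalence is strictly increasing, so bisection is
    safe whenever the target is bracketed.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(f"target prevalence must be in (0,1), got {target}")
    fixed_logit = np.asarray(fixed_logit, dtype=float)

    def prev(c: float) -> float:
        return float(np.mean(expit(c + fixed_logit)))

    p_lo, p_hi = prev(lo), prev(hi)
    if not (p_lo <= target <= p_hi):
        raise ValueError(
            f"target {target} outside achievable prevalence range [{p_lo:.4g}, {p_hi:.4g}]")
    while hi - lo > 1e-12:
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(prev(0.5 * (lo + hi)) - target) < tol and hi - lo < 1e-6:
            break
    return 0.5 * (lo + hi)
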