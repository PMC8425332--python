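"""Reliability-attenuated effect sizes and two-sample t-test power.

A planned population effect size delta assumes error-free measurement.
With single-occasion reliability r (the ratio of true-score to
observed-score variance, approximated by ICC(2,1)), the observable
standardized effect shrinks to

    d = delta * sqrt(r)

because measurement error inflates the observed standard deviation by
1/sqrt(r).  Power for the two-sided, two-sample, equal-n t-test is computed
exactly from the noncentral t distribution with df = 2n - 2 and
noncentrality d * sqrt(n/2); sample sizes are the smallest integer n
meeting the power target (a normal approximation can be off by one
participant per group and is not used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

_N_MAX = 10_000_000


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a reliability-aware power calculation."""

    delta: float
    reliability: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if not (0.0 <= self.reliability <= 1.0):
            raise ValueError("reliability must lie in [0, 1]")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.target_power < 1.0):
            raise ValueError("target_power must lie in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Attenuated effect size, minimal per-group n, and achieved power."""

    d_attenuated: float
    n_per_group: int
    achieved_power: float


def attenuate_effect(delta: float, reliability: float) -> float:
    """Observable effect size after attenuation by measurement error:
    delta * sqrt(reliability)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if not (0.0 <= reliability <= 1.0):
        raise ValueError("reliability must lie in [0, 1]")
    return delta * math.sqrt(reliability)


def power_two_sample_t(d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t-test at equal group sizes.

    Uses the noncentral t distribution with df = 2n - 2 and noncentrality
    d * sqrt(n/2).  At d = 0 the power equals alpha (the size of the test).
    """
    n = int(n_per_group)
    if n < 2:
        raise ValueError("n_per_group must be >= 2")
    df = 2 * n - 2
    ncp = d * math.sqrt(n / 2.0)
    tcrit = stats.t.isf(alpha / 2.0, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_n(d: float, alpha: float = 0.05, target_power: float = 0.80) -> int:
    """Smallest per-group n with two-sample t power >= ``target_power``.

    Always the ceiling integer, never a rounded one: the returned n meets
    the target and n - 1 does not.
    """
    if d <= 0:
        raise ValueError("d must be > 0 for a finite sample size")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if not (0.0 < target_power < 1.0):
        raise ValueError("target_power must lie in (0, 1)")
    # bracket by doubling, then bisect on the monotone power curve
    lo, hi = 2, 2
    while power_two_sample_t(d, hi, alpha) < target_power:
        lo, hi = hi, hi * 2
        if hi > _N_MAX:  # pragma: no cover - unreachable for d > 0
            raise ValueError("no attainable sample size below the search cap")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_two_sample_t(d, mid, alpha) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def solve(spec: PowerSpec) -> PowerResult:
    """Attenuate, size the study, and report achieved power for one spec."""
    d = attenuate_effect(spec.delta, spec.reliability)
    n = required_n(d, spec.alpha, spec.target_power)
    return PowerResult(
        d_attenuated=d,
        n_per_group=n,
        achieved_power=power_two_sample_t(d, n, spec.alpha),
    )


def power_curve(
    delta_grid,
    reliability_grid,
    alpha: float = 0.05,
    target_power: float = 0.80,
) -> pd.DataFrame:
    """Per-group n required across a grid of (delta, reliability) pairs.

    One row per combination with columns ``delta, reliability, d, n_per_group,
    achieved_power``; n is non-increasing along both grid axes.
    """
    deltas = list(np.atleast_1d(np.asarray(delta_grid, dtype=float)))
    rels = list(np.atleast_1d(np.asarray(reliability_grid, dtype=float)))
    if not deltas or not rels:
        raise ValueError("delta_grid and reliability_grid must be non-empty")
    rows = []
    for delta in deltas:
        for r in rels:
            res = solve(PowerSpec(delta=delta, reliability=r, alpha=alpha, target_power=target_power))
            rows.append(
                {
                    "delta": float(delta),
                    "reliability": float(r),
                    "d": res.d_attenuated,
                    "n_per_group": res.n_per_group,
                    "achieved_power": res.achieved_power,
                }
            )
    return pd.DataFrame(rows)
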