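"""Two-group sample-size and power arithmetic for a continuous outcome.

The machinery reproduces the standard frequentist calculations for a trial
whose primary outcome is a 0-100 quality-of-life pain score: smallest n per
group for a two-sided two-sample comparison of means, Bonferroni adjustment
of the family alpha across all pairwise comparisons, inflation of the
analysable total for expected attrition, and per-stratum power when the
cohort splits across prerandomisation strata.

Power is computed from the noncentral-t distribution of the two-sample
t statistic (df = 2n - 2, noncentrality delta / (sd * sqrt(2/n))).  The
cruder normal approximation is available behind ``method="normal"``; it
understates n by 1-2 per group at typical design points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError

__all__ = [
    "SampleSizeSpec",
    "bonferroni_alpha",
    "pairwise_comparisons",
    "n_per_group",
    "power_two_group",
    "inflate_for_attrition",
    "effect_size_sd",
    "stratified_power",
    "simulate_power_check",
]


def bonferroni_alpha(family_alpha: float, k: int, round_dp: Optional[int] = None) -> float:
    """Per-comparison alpha ``family_alpha / k``, optionally rounded half-up.

    ``round_dp=2`` reproduces the common reporting convention 0.05/6 -> 0.01.
    """
    if k < 1:
        raise ConfigurationError("number of comparisons k must be >= 1")
    if not 0 < family_alpha < 1:
        raise ConfigurationError("family_alpha must lie in (0, 1)")
    adj = family_alpha / k
    if round_dp is not None:
        adj = float(
            Decimal(repr(adj)).quantize(Decimal(1).scaleb(-round_dp), ROUND_HALF_UP)
        )
    return adj


def pairwise_comparisons(n_groups: int) -> int:
    """Number of all-against-all pairwise comparisons, n(n-1)/2."""
    if n_groups < 2:
        raise ConfigurationError("need >= 2 groups for pairwise comparisons")
    return n_groups * (n_groups - 1) // 2


def power_two_group(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float,
    method: str = "nct",
) -> float:
    """Power of the two-sided two-sample t test at equal group size n.

    Parameters
    ----------
    n_per_group : analysable participants per arm (>= 2).
    delta : true difference in means, outcome units.
    sd : common outcome standard deviation.
    alpha : two-sided type-I error.
    method : "nct" (noncentral t, default) or "normal" (z approximation).
    """
    if n_per_group < 2:
        raise ConfigurationError("n_per_group must be >= 2")
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    ncp = abs(delta) / (sd * math.sqrt(2.0 / n_per_group))
    if method == "normal":
        zc = stats.norm.ppf(1 - alpha / 2)
        return float(stats.norm.sf(zc - ncp) + stats.norm.cdf(-zc - ncp))
    if method != "nct":
        raise ConfigurationError(f"unknown power method {method!r}")
    df = 2 * n_per_group - 2
    tc = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tc, df, ncp) + stats.nct.cdf(-tc, df, ncp))


def n_per_group(
    delta: float,
    sd: float,
    alpha: float,
    power: float,
    method: str = "nct",
) -> int:
    """Smallest per-group n whose two-sided test achieves the target power.

    Starts from the closed-form normal-approximation solution and walks the
    (monotone) power function to the minimal integer.
    """
    if delta == 0:
        raise ConfigurationError("effect size zero: no finite sample size exists")
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ConfigurationError("alpha and power must lie in (0, 1)")
    za = stats.norm.ppf(1 - alpha / 2)
    zb = stats.norm.ppf(power)
    n = max(2, math.ceil(2.0 * ((za + zb) * sd / abs(delta)) ** 2))
    while n > 2 and power_two_group(n - 1, delta, sd, alpha, method) >= power:
        n -= 1
    while power_two_group(n, delta, sd, alpha, method) < power:
        n += 1
    return n


def inflate_for_attrition(n_total: int, attrition: float, round_to: int = 1) -> int:
    """Recruitment target: n / (1 - attrition), rounded up to a multiple.

    ``inflate_for_attrition(592, 0.20, round_to=50)`` gives 750 (592/0.8 = 740,
    rounded up to the next multiple of 50).
    """
    if not 0 <= attrition < 1:
        raise ConfigurationError("attrition must lie in [0, 1)")
    if round_to < 1:
        raise ConfigurationError("round_to must be >= 1")
    raw = math.ceil(n_total / (1.0 - attrition))
    return int(math.ceil(raw / round_to) * round_to)


def effect_size_sd(delta: float, sd: float) -> tuple[float, float]:
    """Standardised effect delta/sd: (full precision, 2-dp display value)."""
    if sd <= 0:
        raise ConfigurationError("sd must be positive")
    es = delta / sd
    disp = float(Decimal(repr(es)).quantize(Decimal("0.01"), ROUND_HALF_UP))
    return es, disp


def stratified_power(
    n_total: int,
    split: Sequence[float],
    delta: float,
    sd: float,
    alpha: float,
    method: str = "nct",
) -> list[Optional[float]]:
    """Per-stratum power when ``n_total`` splits across strata with 1:1 arms.

    Each stratum contributes floor(n_total * proportion / 2) per arm.  A
    stratum too small to analyse (fewer than 2 per arm) reports ``None``
    (not estimable).
    """
    if not math.isclose(sum(split), 1.0, abs_tol=1e-9):
        raise ConfigurationError("stratum proportions must sum to 1")
    out: list[Optional[float]] = []
    for prop in split:
        n_arm = int(n_total * prop) // 2
        out.append(
            power_two_group(n_arm, delta, sd, alpha, method) if n_arm >= 2 else None
        )
    return out


def simulate_power_check(
    n_per_group: int,
    delta: float,
    sd: float,
    alpha: float,
    n_reps: int,
    seed: int,
) -> float:
    """Empirical power: fraction of simulated two-sample t tests rejecting.

    Outcomes are independent normals with common SD; used as a Monte-Carlo
    cross-check of the analytic noncentral-t power.
    """
    if n_reps < 100:
        raise ConfigurationError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_reps, n_per_group))
    b = rng.normal(delta, sd, size=(n_reps, n_per_group))
    res = stats.ttest_ind(a, b, axis=1)
    return float(np.mean(res.pvalue < alpha))


@dataclass
class SampleSizeSpec:
    """Numeric design parameters for the sample-size block.

    Attributes
    ----------
    delta : minimum important difference, outcome units.
    sd : assumed outcome standard deviation.
    alpha : two-sided per-comparison type-I error (post adjustment).
    power : target power.
    n_groups : number of arms sharing the per-group n.
    attrition : expected loss to follow-up, proportion.
    round_to : recruitment targets round up to this multiple.
    method : power method, "nct" or "normal".
    """

    delta: float
    sd: float
    alpha: float = 0.05
    power: float = 0.80
    n_groups: int = 2
    attrition: float = 0.0
    round_to: int = 1
    method: str = "nct"

    def __post_init__(self):
        if self.delta <= 0 or self.sd <= 0:
            raise ConfigurationError("delta and sd must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ConfigurationError("alpha and power must lie in (0, 1)")
        if not 0 <= self.attrition < 1:
            raise ConfigurationError("attrition must lie in [0, 1)")

    def solve(self) -> dict:
        """Per-group n, analysable total and recruitment target as one block."""
        npg = n_per_group(self.delta, self.sd, self.alpha, self.power, self.method)
        total = npg * self.n_groups
        recruit = inflate_for_attrition(total, self.attrition, self.round_to)
        es_full, es_disp = effect_size_sd(self.delta, self.sd)
        return {
            "delta": self.delta,
            "sd": self.sd,
            "alpha": self.alpha,
            "power": self.power,
            "n_groups": self.n_groups,
            "n_per_group": npg,
            "n_total": total,
            "attrition": self.attrition,
            "recruitment_target": recruit,
            "effect_size_sd": es_full,
            "effect_size_sd_display": es_disp,
            "achieved_power": power_two_group(
                npg, self.delta, self.sd, self.alpha, self.method
            ),
        }
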