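"""Closed-form power and sample-size calculations for correlation effects.

The effect size of a multivariate association model is a prediction-outcome
correlation, so replication sample sizes follow from the classical power
analysis of a Pearson correlation.  Under the Fisher z transformation,
z = atanh(r) is approximately normal with mean atanh(rho) and standard error
1/sqrt(n - 3); power for a level-alpha significance test is then

    power(rho, n) = Phi(atanh(rho) * sqrt(n - 3) - z_{1 - alpha/2})

(two-sided; the vanishing opposite-tail term is included for completeness).
rho**2 is the fraction of outcome variance explained, the scale on which
effect sizes are usually quoted: a model explaining 1% of variance has
rho = 0.1 and reaches 80% power at alpha = 0.05 with 783 participants —
comfortably below a thousand.

A simulation-based check (:func:`simulated_power`) draws bivariate-normal
samples and reports the empirical rejection rate; the closed form agrees
with it to well within Monte-Carlo error for the n and rho ranges used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SizeError
from .inference import Sidedness, critical_r

__all__ = [
    "PowerQuery",
    "power_at_n",
    "required_n",
    "power_curve",
    "simulated_power",
]

N_CAP = 10**8


@dataclass(frozen=True)
class PowerQuery:
    """A sample-size question: how many participants for a target power?"""

    rho: float
    alpha: float = 0.05
    target_power: float = 0.8
    sidedness: Sidedness = "two_sided"

    def validate(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ConfigError(f"rho must lie in (0, 1), got {self.rho}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (0.0 < self.target_power < 1.0):
            raise ConfigError(f"target_power must lie in (0, 1), got {self.target_power}")
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ConfigError(f"unknown sidedness {self.sidedness!r}")


def power_at_n(
    rho: float, n: int, alpha: float = 0.05, sidedness: Sidedness = "two_sided"
) -> float:
    """Probability that a sample correlation at true rho is significant.

    Fisher-z approximation; monotone increasing in both rho and n.
    """
    if n < 4:
        raise SizeError(f"n must be at least 4, got {n}")
    if not (0.0 <= rho < 1.0):
        raise ConfigError(f"rho must lie in [0, 1), got {rho}")
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    mu = np.arctanh(rho) * np.sqrt(n - 3)
    if sidedness == "two_sided":
        za = stats.norm.isf(alpha / 2.0)
        # upper tail dominates for rho > 0; lower tail kept for exactness
        return float(stats.norm.sf(za - mu) + stats.norm.cdf(-za - mu))
    za = stats.norm.isf(alpha)
    return float(stats.norm.sf(za - mu))


def required_n(query: PowerQuery) -> int:
    """Smallest n at which power_at_n reaches the target power.

    Starts from the inverted Fisher-z expression
    ceil(((z_{1-alpha/2} + z_{power}) / atanh(rho))**2 + 3) and adjusts by
    direct evaluation, so minimality is guaranteed rather than approximate.
    """
    query.validate()
    za = stats.norm.isf(
        query.alpha / 2.0 if query.sidedness == "two_sided" else query.alpha
    )
    zp = stats.norm.ppf(query.target_power)
    n = int(np.ceil(((za + zp) / np.arctanh(query.rho)) ** 2 + 3))
    n = max(n, 4)
    if n > N_CAP:
        raise ConfigError(
            f"required sample size exceeds the configured cap {N_CAP}; rho too small"
        )
    while n > 4 and power_at_n(query.rho, n - 1, query.alpha, query.sidedness) >= query.target_power:
        n -= 1
    while power_at_n(query.rho, n, query.alpha, query.sidedness) < query.target_power:
        n += 1
        if n > N_CAP:
            raise ConfigError(
                f"required sample size exceeds the configured cap {N_CAP}; rho too small"
            )
    return n


def power_curve(
    rho_list: list[float],
    n_list: list[int],
    alpha: float = 0.05,
    sidedness: Sidedness = "two_sided",
) -> pd.DataFrame:
    """Cross-product power table with columns (rho, n, power)."""
    if not rho_list or not n_list:
        raise ConfigError("rho_list and n_list must be nonempty")
    rows = [
        {"rho": rho, "n": int(n), "power": power_at_n(rho, n, alpha, sidedness)}
        for rho in rho_list
        for n in n_list
    ]
    return pd.DataFrame(rows)


def simulated_power(
    rho: float,
    n: int,
    alpha: float = 0.05,
    sidedness: Sidedness = "two_sided",
    n_draws: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the correlation test at true rho.

    Independent oracle for :func:`power_at_n`: draws bivariate-normal samples
    of size n and tests each sample correlation against the exact critical r.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_draws, n))
    y = rho * x + np.sqrt(1.0 - rho**2) * rng.standard_normal((n_draws, n))
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    r = (xc * yc).sum(axis=1) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    rc = critical_r(n, alpha, sidedness)
    rejected = np.abs(r) >= rc if sidedness == "two_sided" else r >= rc
    return float(np.mean(rejected))
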