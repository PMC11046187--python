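"""Power analysis for the paired McNemar design.

The design's power depends on the number of pairs n, the probability psi
that a pair is discordant for exposure, and the discordant-pair odds ratio
theta: conditional on t discordant pairs, the case-only count b is
Binomial(t, theta/(1+theta)). Monte-Carlo simulation is the reference;
a conditional normal approximation provides a closed-form cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.stats import binom, norm

TestVariant = Literal["exact", "mid_p", "chi2_cc"]


@dataclass
class PowerSpec:
    n_pairs: int
    discordant_prob: float  # psi
    odds_ratio: float  # theta
    alpha: float = 0.01
    test_variant: TestVariant = "exact"
    n_reps: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.discordant_prob < 1:
            raise ValueError("discordant_prob must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds_ratio must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def _pvalues(b: np.ndarray, t: np.ndarray, variant: TestVariant) -> np.ndarray:
    """Vectorized two-sided p-values; replicates with t = 0 get p = 1."""
    from scipy.stats import chi2 as chi2_dist

    t = t.astype(float)
    k = np.minimum(b, t - b)
    safe_t = np.maximum(t, 1.0)
    if variant == "exact":
        p = 2.0 * binom.cdf(k, safe_t, 0.5)
    elif variant == "mid_p":
        p = 2.0 * (binom.cdf(k, safe_t, 0.5) - 0.5 * binom.pmf(k, safe_t, 0.5))
    elif variant == "chi2_cc":
        stat = np.maximum(np.abs(2 * b - t) - 1.0, 0.0) ** 2 / safe_t
        p = chi2_dist.sf(stat, df=1)
    else:
        raise ValueError(f"unknown test variant {variant!r}")
    p = np.minimum(p, 1.0)
    return np.where(t >= 1, p, 1.0)


def simulate_power(spec: PowerSpec) -> tuple[float, float]:
    """Monte-Carlo power with its standard error.

    Per replicate: t ~ Binomial(n_pairs, psi), b ~ Binomial(t, theta/(1+theta));
    the null is rejected when the chosen test's p-value is <= alpha.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p1 = spec.odds_ratio / (1.0 + spec.odds_ratio)
    t = rng.binomial(spec.n_pairs, spec.discordant_prob, size=spec.n_reps)
    b = rng.binomial(t, p1)
    pvals = _pvalues(b, t, spec.test_variant)
    reject = pvals <= spec.alpha
    power = float(reject.mean())
    mcse = float(np.sqrt(power * (1.0 - power) / spec.n_reps))
    return power, mcse


def approx_power(spec: PowerSpec) -> float:
    """Normal approximation conditional on the expected discordant count.

    With t = n * psi, p1 = theta/(1+theta), delta = |p1 - 1/2| and
    sigma = sqrt(p1 (1 - p1)), both rejection directions contribute, with a
    continuity correction of half a lattice cell that mirrors the exact
    test's discreteness:
    power ~= Phi((delta sqrt(t) - z/2 - 1/(2 sqrt(t))) / sigma)
           + Phi((-delta sqrt(t) - z/2 - 1/(2 sqrt(t))) / sigma),
    z = z_{1 - alpha/2}; at theta = 1 this is approximately alpha.
    """
    spec.validate()
    t = spec.n_pairs * spec.discordant_prob
    p1 = spec.odds_ratio / (1.0 + spec.odds_ratio)
    z = norm.ppf(1.0 - spec.alpha / 2.0)
    delta = abs(p1 - 0.5) * np.sqrt(t)
    sigma = np.sqrt(p1 * (1.0 - p1))
    corr = 0.5 / np.sqrt(t)
    return float(
        norm.cdf((delta - 0.5 * z - corr) / sigma)
        + norm.cdf((-delta - 0.5 * z - corr) / sigma)
    )


def power_grid(
    n_pairs: int,
    psis: list[float],
    thetas: list[float],
    alpha: float = 0.01,
    test_variant: TestVariant = "exact",
    n_reps: int = 20_000,
    seed: int = 0,
):
    """Simulated and approximate power over a (psi, theta) grid as a DataFrame."""
    import pandas as pd

    rows = []
    for i, psi in enumerate(psis):
        for j, theta in enumerate(thetas):
            spec = PowerSpec(
                n_pairs=n_pairs,
                discordant_prob=psi,
                odds_ratio=theta,
                alpha=alpha,
                test_variant=test_variant,
                n_reps=n_reps,
                seed=seed + 1000 * i + j,
            )
            power, mcse = simulate_power(spec)
            rows.append(
                {
                    "n_pairs": n_pairs,
                    "psi": psi,
                    "theta": theta,
                    "alpha": alpha,
                    "test": test_variant,
                    "power_sim": power,
                    "mcse": mcse,
                    "power_approx": approx_power(spec),
                }
            )
    return pd.DataFrame(rows)
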