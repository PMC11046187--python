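"""Genome-wide significance control for discrete p-values.

McNemar p-values live on a per-SNP lattice determined by the discordant-pair
total t = b + c, so the usual uniform-null assumptions behind FDR machinery
need care. This module provides the Bonferroni threshold, Storey q-values
with two pi0 estimators (the Storey-Tibshirani bootstrap and a cubic
polynomial fit in the tuning parameter lambda), and the lattice-aware
expected p-value distribution used for Q-Q plots: each test with support t
assigns null probability f(k; t, 1/2) to the p-value achieved at k = 0..t,
and the per-SNP supports are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mcnemar_core import mcnemar_mid_p


def bonferroni_threshold(alpha: float, m_tests: int) -> tuple[float, float]:
    """Genome-wide threshold alpha/m; returns (threshold, -log10 threshold)."""
    if not 0 < alpha < 1 or m_tests < 1:
        raise ValueError("need alpha in (0,1) and m_tests >= 1")
    thr = alpha / m_tests
    return thr, float(-np.log10(thr))


DEFAULT_LAMBDA_GRID = np.round(np.arange(0.0, 0.951, 0.01), 4)


def _pi0_of_lambda(p: np.ndarray, grid: np.ndarray) -> np.ndarray:
    m = p.size
    p_sorted = np.sort(p)
    n_above = m - np.searchsorted(p_sorted, grid, side="right")
    return n_above / (m * (1.0 - grid))


def estimate_pi0(
    p_values: np.ndarray,
    method: str = "bootstrap",
    lambda_grid: np.ndarray | None = None,
    n_boot: int = 100,
    seed: int = 0,
) -> tuple[float, dict]:
    """Estimate the null proportion pi0 from a p-value vector.

    ``bootstrap``: Storey-Tibshirani (2003) — pick the lambda whose bootstrap
    mean squared error against the plug-in minimum over the grid is smallest.
    ``polynomial``: fit a cubic in lambda to pi0(lambda) and evaluate the fit
    at the grid maximum. Either way the estimate is clamped to (0, 1].

    Returns (pi0, diagnostics) with the grid, the raw pi0(lambda) curve, and
    the method-specific selection details.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    pi0_lam = _pi0_of_lambda(p, grid)
    diagnostics: dict = {"lambda_grid": grid, "pi0_lambda": pi0_lam}

    if np.all(p == p[0]):
        import warnings

        warnings.warn("all p-values identical; pi0 set to 1")
        return 1.0, diagnostics

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        target = pi0_lam.min()
        m = p.size
        mse = np.zeros(grid.size)
        for _ in range(n_boot):
            pb = p[rng.integers(0, m, m)]
            mse += (_pi0_of_lambda(pb, grid) - target) ** 2
        mse /= n_boot
        lam_best = int(np.argmin(mse))
        pi0 = pi0_lam[lam_best]
        diagnostics.update(bootstrap_mse=mse, lambda_selected=grid[lam_best])
    elif method == "polynomial":
        coef = np.polyfit(grid, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, grid.max()))
        ss_res = np.sum((pi0_lam - np.polyval(coef, grid)) ** 2)
        ss_tot = np.sum((pi0_lam - pi0_lam.mean()) ** 2)
        diagnostics.update(
            poly_coef=coef,
            r2=1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan"),
            eval_lambda=grid.max(),
        )
    else:
        raise ValueError(f"unknown pi0 method {method!r}")

    return float(min(1.0, max(pi0, 1.0 / p.size))), diagnostics


def q_values(p_values: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Storey q-values: q = pi0 * m * p / rank, monotonized from the top.

    With pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    Output is aligned to the input order.
    """
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    raw = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


@dataclass
class QValueSet:
    """q-values for one p-value vector under one pi0 estimation method."""

    p_values: np.ndarray
    pi0: float
    pi0_method: str
    lambda_grid: np.ndarray
    q_values: np.ndarray

    @classmethod
    def from_p_values(
        cls,
        p_values: np.ndarray,
        method: str = "bootstrap",
        lambda_grid: np.ndarray | None = None,
        seed: int = 0,
    ) -> "QValueSet":
        pi0, diag = estimate_pi0(p_values, method=method, lambda_grid=lambda_grid, seed=seed)
        return cls(
            p_values=np.asarray(p_values, float),
            pi0=pi0,
            pi0_method=method,
            lambda_grid=diag["lambda_grid"],
            q_values=q_values(p_values, pi0),
        )


@dataclass
class DiscreteNull:
    """Pooled null distribution of achievable McNemar p-values.

    For a test with t = b + c discordant pairs the null puts probability
    f(k; t, 1/2) on the p-value realized by each split k = 0..t. ``supports``
    is the vector of per-SNP t values from a scan; ``variant`` selects which
    p-value's lattice is enumerated (it must match the observed statistic).
    """

    supports: np.ndarray
    variant: str = "mid_p"

    def pooled_pvalues(self) -> tuple[np.ndarray, np.ndarray]:
        """All achievable p-values with their pooled null weights.

        Each SNP contributes total weight 1; weights are normalized so they
        sum to the number of SNPs. Returns (p sorted ascending, weights).
        """
        from scipy.stats import binom

        from .mcnemar_core import mcnemar_exact_p

        pfun = {"mid_p": mcnemar_mid_p, "exact": mcnemar_exact_p}[self.variant]
        supports = np.asarray(self.supports, dtype=int)
        if supports.size == 0:
            raise ValueError("empty scan: no discordant-pair supports")
        ps: list[np.ndarray] = []
        ws: list[np.ndarray] = []
        for t, count in zip(*np.unique(supports, return_counts=True)):
            if t < 1:
                continue
            k = np.arange(t + 1)
            pmf = binom.pmf(k, t, 0.5)
            pvals = np.array([pfun(int(b), int(t - b)) for b in k])
            ps.append(pvals)
            ws.append(pmf * count)
        p = np.concatenate(ps)
        w = np.concatenate(ws)
        order = np.argsort(p, kind="stable")
        return p[order], w[order]


def qq_expected(discrete_null: DiscreteNull, n_points: int) -> np.ndarray:
    """Expected sorted -log10 p under the pooled lattice null.

    Deterministic quantiles of the pooled distribution at the plotting
    positions (i - 1/2)/n, i = 1..n_points, returned in ascending p order
    (descending -log10) to pair with observed sorted p-values.
    """
    p, w = discrete_null.pooled_pvalues()
    cdf = np.cumsum(w) / np.sum(w)
    probs = (np.arange(1, n_points + 1) - 0.5) / n_points
    idx = np.searchsorted(cdf, probs, side="left")
    idx = np.clip(idx, 0, p.size - 1)
    expected_p = p[idx]
    return -np.log10(expected_p)
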