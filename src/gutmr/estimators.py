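"""Causal-effect estimators for two-sample MR.

All estimators consume a list of :class:`~gutmr.sumstats.HarmonizedInstrument`
and return an :class:`MREstimate` on the log-odds scale with the odds ratio
and a 95% Wald confidence interval attached.

* ``wald_ratio`` — single-variant ratio estimate.
* ``ivw`` — inverse-variance-weighted mean of the Wald ratios, identical to a
  weighted regression of outcome on exposure effects with the intercept
  constrained to zero.  Default is multiplicative random effects (the SE is
  inflated by sqrt(Q/(J−1)) when heterogeneity exceeds its expectation, never
  deflated).
* ``egger`` — weighted regression with a free intercept; the intercept
  estimates average directional pleiotropy and the slope the causal effect
  under the InSIDE assumption.
* ``weighted_median`` — the 50% point of the weight-ordered ratio
  distribution; consistent when at least half the weight is on valid
  instruments.
* ``weighted_mode`` — Gaussian-kernel weighted density argmax over ratios;
  consistent when the largest cluster of instruments is valid.

Bootstrap standard errors (weighted median / mode) resample the exposure and
outcome effects from their reported normal errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from gutmr.sumstats import HarmonizedInstrument

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the estimator requires."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate for one exposure-outcome pair."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.beta - Z95 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.beta + Z95 * self.se))


def _arrays(hs: Sequence[HarmonizedInstrument]):
    bx = np.array([h.beta_exp for h in hs])
    sx = np.array([h.se_exp for h in hs])
    by = np.array([h.beta_out for h in hs])
    sy = np.array([h.se_out for h in hs])
    return bx, sx, by, sy


def _normal_p(beta: float, se: float) -> float:
    if se == 0.0:
        return 1.0 if beta == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def wald_ratio(h: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate: beta_out / beta_exp."""
    beta = h.ratio
    se = h.ratio_se
    return MREstimate("wald", beta, se, _normal_p(beta, se), 1)


def _ivw_beta_se(ratios: np.ndarray, weights: np.ndarray,
                 re_mode: str) -> tuple[float, float, float]:
    """Weighted mean, SE and Cochran Q used by ivw and the diagnostics."""
    sw = weights.sum()
    beta = float((weights * ratios).sum() / sw)
    q = float((weights * (ratios - beta) ** 2).sum())
    se = float(sw ** -0.5)
    j = ratios.size
    if re_mode == "multiplicative" and j > 1:
        se *= max(1.0, np.sqrt(q / (j - 1)))
    return beta, se, q


def ivw(hs: Sequence[HarmonizedInstrument],
        re_mode: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate over the Wald ratios.

    Weights are 1/ratio_se² = beta_exp²/se_out².  ``re_mode`` is
    ``"multiplicative"`` (random-effects SE, scale-up only; default) or
    ``"fixed"``.
    """
    if re_mode not in ("fixed", "multiplicative"):
        raise ValueError(f"unknown re_mode {re_mode!r}")
    if len(hs) < 2:
        raise InsufficientInstrumentsError(
            "ivw needs >= 2 instruments; use wald_ratio for a single one"
        )
    ratios = np.array([h.ratio for h in hs])
    weights = np.array([h.ratio_se for h in hs]) ** -2.0
    beta, se, _ = _ivw_beta_se(ratios, weights, re_mode)
    return MREstimate("ivw", beta, se, _normal_p(beta, se), len(hs))


def egger(hs: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with a free
    intercept.

    Instruments are first oriented so that every exposure effect is positive
    (both betas of an instrument are negated together, which leaves the Wald
    ratio unchanged).  Weights are 1/se_out².  The residual scale is
    multiplicative random effects (scale-up only) and p-values use the t
    distribution with J−2 degrees of freedom.
    """
    j = len(hs)
    if j < 3:
        raise InsufficientInstrumentsError("egger needs >= 3 instruments")
    bx, _, by, sy = _arrays(hs)
    flip = np.sign(bx)
    bx, by = bx * flip, by * flip
    w = sy ** -2.0

    # weighted normal equations for [intercept, slope]
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    rss = float(w @ resid ** 2)
    scale2 = max(1.0, rss / (j - 2))
    cov = np.linalg.inv(xtwx) * scale2
    inter, slope = float(coef[0]), float(coef[1])
    se_inter, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))

    def t_p(b, se):
        if se == 0.0:
            return 1.0 if b == 0.0 else 0.0
        return float(2.0 * stats.t.sf(abs(b) / se, df=j - 2))

    return MREstimate(
        "egger", slope, se_slope, t_p(slope, se_slope), j,
        intercept=inter, intercept_se=se_inter,
        intercept_pvalue=t_p(inter, se_inter),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: the 0.5 point of the standardized
    cumulative weight s_j = (cumsum(w)_j − w_j/2) / sum(w)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / w.sum()
    if 0.5 <= s[0]:
        return float(r[0])
    if 0.5 >= s[-1]:
        return float(r[-1])
    return float(np.interp(0.5, s, r))


def _bootstrap_se(
    hs: Sequence[HarmonizedInstrument],
    point_fn,
    n_boot: int,
    seed: int,
) -> float:
    """Parametric bootstrap: resample effects from their normal errors and
    recompute the point estimate."""
    bx, sx, by, sy = _arrays(hs)
    rng = np.random.default_rng(seed)
    j = bx.size
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    # guard: a resampled exposure effect of exactly zero has measure zero
    bx_star[bx_star == 0.0] = np.finfo(float).tiny
    ratios = by_star / bx_star
    weights = (sy / np.abs(bx_star)) ** -2.0
    ests = np.array([
        point_fn(ratios[b], weights[b]) for b in range(n_boot)
    ])
    return float(ests.std(ddof=1))


def weighted_median(
    hs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE."""
    if len(hs) < 3:
        raise InsufficientInstrumentsError("weighted_median needs >= 3 instruments")
    ratios = np.array([h.ratio for h in hs])
    weights = np.array([h.ratio_se for h in hs]) ** -2.0
    beta = _weighted_median_point(ratios, weights)
    se = _bootstrap_se(hs, _weighted_median_point, n_boot, seed)
    return MREstimate("weighted_median", beta, se, _normal_p(beta, se), len(hs))


def mode_bandwidth(ratios: np.ndarray, bandwidth_factor: float = 1.0) -> float:
    """Modified-Silverman bandwidth over the ratio estimates.

    h = factor · 0.9 · min(sd, MAD/0.6745) · J^(−1/5), with fallbacks so the
    bandwidth is strictly positive even for (near-)constant input.
    """
    if bandwidth_factor <= 0.0:
        raise ValueError("bandwidth_factor must be positive")
    j = ratios.size
    sd = float(ratios.std(ddof=1)) if j > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    spread = min(x for x in (sd, mad) if x > 0.0) if max(sd, mad) > 0.0 else 0.0
    if spread == 0.0:
        spread = max(abs(float(np.mean(ratios))), 1.0) * 1e-3
    return bandwidth_factor * 0.9 * spread * j ** (-0.2)


def _weighted_mode_point(
    ratios: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float = 1.0,
    grid_points: int = 4096,
    refine: bool = True,
) -> float:
    """Argmax of the weighted Gaussian-kernel density over the ratios.

    The argmax is located on a dense grid and (by default) polished with a
    bounded scalar optimization; the bootstrap uses a coarser grid without
    polishing since only the spread of the estimates matters there.
    """
    h = mode_bandwidth(ratios, bandwidth_factor)

    def neg_density(x: np.ndarray) -> np.ndarray:
        z = (np.atleast_2d(x).T - ratios) / h
        return -(weights * np.exp(-0.5 * z ** 2)).sum(axis=1)

    lo, hi = ratios.min() - 3.0 * h, ratios.max() + 3.0 * h
    grid = np.linspace(lo, hi, grid_points)
    dens = -neg_density(grid)
    k = int(np.argmax(dens))
    if not refine:
        return float(grid[k])
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda x: float(neg_density(np.array([x]))[0]),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def weighted_mode(
    hs: Sequence[HarmonizedInstrument],
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted-mode causal estimate with parametric-bootstrap SE."""
    if len(hs) < 3:
        raise InsufficientInstrumentsError("weighted_mode needs >= 3 instruments")
    ratios = np.array([h.ratio for h in hs])
    weights = np.array([h.ratio_se for h in hs]) ** -2.0
    beta = _weighted_mode_point(ratios, weights, bandwidth_factor)

    def point(r, w):
        return _weighted_mode_point(r, w, bandwidth_factor,
                                    grid_points=512, refine=False)

    se = _bootstrap_se(hs, point, n_boot, seed)
    return MREstimate("weighted_mode", beta, se, _normal_p(beta, se), len(hs))
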