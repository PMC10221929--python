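"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

* :func:`cochran_q` — weighted heterogeneity statistic over the per-variant
  Wald ratios, chi-square with J−1 df under homogeneity.
* :func:`presso_global` / :func:`presso_outlier_and_distortion` — a
  residual-sum-of-squares pleiotropy test in the MR-PRESSO style: the
  observed RSS (with leave-one-out fitted values) is compared against a
  parametric-bootstrap null, per-variant residuals yield Bonferroni-adjusted
  outlier p-values, and a distortion test compares the estimate shift after
  outlier removal against random same-size removals.
* :func:`leave_one_out` — IVW re-estimates excluding each instrument in
  turn, flagging influential variants.
* :func:`funnel_table` — per-instrument (ratio, precision) pairs for funnel
  plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from gutmr.estimators import (
    MREstimate,
    _ivw_beta_se,
    _normal_p,
    ivw,
)
from gutmr.sumstats import HarmonizedInstrument


class AllOutliersError(ValueError):
    """Every instrument was flagged; no corrected estimate is possible."""


@dataclass
class SensitivityReport:
    """Diagnostics for one exposure-outcome pair."""

    q_stat: float
    q_df: int
    q_pvalue: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso_global_p: float | None = None
    presso_outliers: list[tuple[str, float]] = field(default_factory=list)
    presso_distortion_p: float | None = None
    loo: list[tuple[str, MREstimate]] = field(default_factory=list)
    loo_flags: list[bool] = field(default_factory=list)


def cochran_q(
    hs: Sequence[HarmonizedInstrument], theta: float
) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test around a causal estimate ``theta``.

    Q = Σ w_j (ratio_j − theta)² with w_j = 1/ratio_se_j²; the p-value is the
    upper chi-square tail with J−1 degrees of freedom.
    """
    if len(hs) < 2:
        raise ValueError("cochran_q needs >= 2 instruments")
    ratios = np.array([h.ratio for h in hs])
    w = np.array([h.ratio_se for h in hs]) ** -2.0
    q = float((w * (ratios - theta) ** 2).sum())
    df = len(hs) - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_ivw_matrix(ratios: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates for every instrument, vectorized.

    Works on a 1-D instance or on a (n_sim, J) batch.
    """
    sw = weights.sum(axis=-1, keepdims=True)
    swr = (weights * ratios).sum(axis=-1, keepdims=True)
    return (swr - weights * ratios) / (sw - weights)


def _presso_rss(
    bx: np.ndarray, by: np.ndarray, w_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument weighted squared residuals against leave-one-out IVW
    fits, and their sum.  Accepts 1-D or (n_sim, J) batches."""
    ratios = by / bx
    w_ratio = w_out * bx ** 2  # 1/ratio_se^2 on the ratio scale
    theta_minus = _loo_ivw_matrix(ratios, w_ratio)
    resid2 = w_out * (by - theta_minus * bx) ** 2
    return resid2, resid2.sum(axis=-1)


def _presso_simulate(
    hs: Sequence[HarmonizedInstrument], n_sim: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Observed per-variant residuals/RSS plus their parametric-bootstrap
    null distributions."""
    bx = np.array([h.beta_exp for h in hs])
    sx = np.array([h.se_exp for h in hs])
    by = np.array([h.beta_out for h in hs])
    sy = np.array([h.se_out for h in hs])
    w_out = sy ** -2.0

    obs_resid2, obs_rss = _presso_rss(bx, by, w_out)

    # expected outcome effects under the no-pleiotropy model, per instrument
    ratios = by / bx
    w_ratio = w_out * bx ** 2
    theta_minus = _loo_ivw_matrix(ratios, w_ratio)

    rng = np.random.default_rng(seed)
    j = bx.size
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_minus * bx, sy, size=(n_sim, j))
    bx_star[bx_star == 0.0] = np.finfo(float).tiny
    sim_resid2, sim_rss = _presso_rss(bx_star, by_star, np.broadcast_to(w_out, (n_sim, j)))
    return obs_resid2, obs_rss, sim_resid2, sim_rss


def presso_global(
    hs: Sequence[HarmonizedInstrument], n_sim: int = 1000, seed: int = 0
) -> float:
    """Global pleiotropy test p-value (add-one empirical tail probability)."""
    if len(hs) < 4:
        raise ValueError("presso_global needs >= 4 instruments")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives an unstable empirical p-value")
    _, obs_rss, _, sim_rss = _presso_simulate(hs, n_sim, seed)
    return float((1 + (sim_rss >= obs_rss).sum()) / (n_sim + 1))


def presso_outlier_and_distortion(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[list[tuple[str, float]], float | None, MREstimate]:
    """Per-instrument outlier test, distortion test and corrected estimate.

    Each instrument's observed weighted squared residual is compared with its
    simulated null distribution; the empirical p-value is Bonferroni-adjusted
    by J and instruments below ``alpha`` are flagged.  The distortion p-value
    compares the IVW shift after removing the flagged set against shifts from
    removing random subsets of the same size, and is only computed when at
    least one outlier is found.

    Returns ``(outliers, distortion_p, corrected_estimate)`` where
    ``outliers`` is a list of (variant_id, adjusted p).
    """
    if len(hs) < 4:
        raise ValueError("presso outlier test needs >= 4 instruments")
    j = len(hs)
    obs_resid2, _, sim_resid2, _ = _presso_simulate(hs, n_sim, seed)
    raw_p = (1 + (sim_resid2 >= obs_resid2).sum(axis=0)) / (n_sim + 1)
    adj_p = np.minimum(1.0, raw_p * j)
    # alpha >= 1 means every p-value qualifies (adjusted p is capped at 1)
    flagged = [i for i in range(j) if alpha >= 1.0 or adj_p[i] < alpha]
    outliers = [(hs[i].variant_id, float(adj_p[i])) for i in flagged]

    if len(flagged) == j:
        raise AllOutliersError("every instrument flagged as an outlier")
    if not flagged:
        full = ivw(hs)
        return [], None, full

    retained = [h for i, h in enumerate(hs) if i not in set(flagged)]
    full = ivw(hs)
    if len(retained) >= 2:
        corrected = ivw(retained)
    else:
        from gutmr.estimators import wald_ratio

        corrected = wald_ratio(retained[0])
    d_obs = corrected.beta - full.beta

    # null shifts: remove random subsets of the same size
    rng = np.random.default_rng(seed + 1)
    ratios = np.array([h.ratio for h in hs])
    w = np.array([h.ratio_se for h in hs]) ** -2.0
    m = len(flagged)
    n_draw = min(n_sim, 1000)
    shifts = np.empty(n_draw)
    for b in range(n_draw):
        drop = rng.choice(j, size=m, replace=False)
        keep = np.ones(j, dtype=bool)
        keep[drop] = False
        beta_b, _, _ = _ivw_beta_se(ratios[keep], w[keep], "fixed")
        shifts[b] = beta_b - full.beta
    distortion_p = float((1 + (np.abs(shifts) >= abs(d_obs)).sum()) / (n_draw + 1))
    return outliers, distortion_p, corrected


def leave_one_out(
    hs: Sequence[HarmonizedInstrument], alpha: float = 0.05
) -> tuple[list[tuple[str, MREstimate]], list[bool]]:
    """IVW re-estimate excluding each instrument in turn.

    A row is flagged when dropping that instrument changes the sign of the
    estimate or makes a nominally significant full estimate lose
    significance.
    """
    if len(hs) < 3:
        raise ValueError("leave_one_out needs >= 3 instruments")
    full = ivw(hs)
    rows: list[tuple[str, MREstimate]] = []
    flags: list[bool] = []
    for i, h in enumerate(hs):
        rest = [x for k, x in enumerate(hs) if k != i]
        est = ivw(rest) if len(rest) >= 2 else None
        rows.append((h.variant_id, est))
        sign_change = est.beta * full.beta < 0
        lost_sig = full.pvalue < alpha <= est.pvalue
        flags.append(bool(sign_change or lost_sig))
    return rows, flags


def funnel_table(
    hs: Sequence[HarmonizedInstrument],
    full_estimates: Sequence[MREstimate] = (),
) -> pd.DataFrame:
    """Plot-ready funnel table: per-instrument Wald ratio against precision.

    ``full_estimates`` adds method reference lines (columns method/beta with
    empty instrument fields) after the per-variant rows.
    """
    rows = [
        {
            "variant_id": h.variant_id,
            "ratio": h.ratio,
            "precision": 1.0 / h.ratio_se,
            "method": "",
            "reference_beta": np.nan,
        }
        for h in hs
    ]
    for est in full_estimates:
        rows.append(
            {
                "variant_id": "",
                "ratio": np.nan,
                "precision": np.nan,
                "method": est.method,
                "reference_beta": est.beta,
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "ratio", "precision", "method", "reference_beta"]
    )


def sensitivity_report(
    hs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Run the full diagnostic battery for one instrument set."""
    from gutmr.estimators import egger

    theta_fixed, _, _ = _ivw_beta_se(
        np.array([h.ratio for h in hs]),
        np.array([h.ratio_se for h in hs]) ** -2.0,
        "fixed",
    )
    q, df, q_p = cochran_q(hs, theta_fixed)
    report = SensitivityReport(q_stat=q, q_df=df, q_pvalue=q_p)
    if len(hs) >= 3:
        eg = egger(hs)
        report.egger_intercept = eg.intercept
        report.egger_intercept_se = eg.intercept_se
        report.egger_intercept_p = eg.intercept_pvalue
        loo, flags = leave_one_out(hs, alpha=alpha)
        report.loo = loo
        report.loo_flags = flags
    if len(hs) >= 4:
        report.presso_global_p = presso_global(hs, n_sim=n_sim, seed=seed)
        if report.presso_global_p < alpha:
            try:
                outliers, dist_p, _ = presso_outlier_and_distortion(
                    hs, n_sim=n_sim, seed=seed, alpha=alpha
                )
                report.presso_outliers = outliers
                report.presso_distortion_p = dist_p
            except AllOutliersError:
                report.presso_outliers = [(h.variant_id, 0.0) for h in hs]
    return report
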