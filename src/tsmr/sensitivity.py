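"""Heterogeneity and pleiotropy diagnostics.

Covers the standard two-sample MR sensitivity suite: Cochran's Q on the
IVW model and Rücker's Q on the MR-Egger model (Rücker's can only be
smaller — the intercept absorbs weighted residual), the Egger-intercept
test for directional pleiotropy, the simulation-based MR-PRESSO global /
outlier / distortion tests, leave-one-variant-out re-estimation with
IVW-RE, and funnel-plot coordinates (symmetry is assessed visually; no
statistic is computed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    EggerIntercept,
    MRResult,
    RatioEstimate,
    egger,
    ivw,
    wald_ratio,
)
from .harmonize import HarmonizedSet, orient_positive

__all__ = [
    "HeterogeneityResult",
    "PressoResult",
    "LOOResult",
    "cochran_q",
    "rucker_q",
    "egger_intercept_test",
    "mr_presso",
    "leave_one_out",
    "funnel_data",
    "HETEROGENEITY_ALPHA",
]

HETEROGENEITY_ALPHA = 0.05  # p below this flags heterogeneity


@dataclass(frozen=True)
class HeterogeneityResult:
    """Weighted heterogeneity statistic with chi-square upper-tail p."""

    statistic: str  # cochran_ivw | rucker_egger
    q: float
    df: int
    pval: float

    @property
    def heterogeneous(self) -> bool:
        return self.pval < HETEROGENEITY_ALPHA


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test outputs.

    Empirical p-values use (count + 1)/(n_sim + 1) smoothing, so the floor
    is 1/(n_sim + 1) and zero is never reported.  ``estimate_after`` and
    ``distortion_pval`` are None when no outliers were flagged.
    """

    rss_obs: float
    global_pval: float
    outlier_pvals: dict[str, float]
    outlier_indices: list[str]
    distortion_pval: float | None
    estimate_before: float
    estimate_after: float | None
    n_sim: int
    seed: int


@dataclass(frozen=True)
class LOOResult:
    """Leave-one-out IVW-RE estimates, one entry per excluded instrument.

    ``influential`` lists excluded rsids whose removal changes the
    qualitative conclusion (the sign-and-significance reading of the 95% CI)
    relative to the full-set estimate.
    """

    entries: list[tuple[str, MRResult]]
    full: MRResult
    influential: list[str]


def cochran_q(ratios: list[RatioEstimate]) -> HeterogeneityResult:
    """Cochran's Q = Σ w_j (θ_j − θ_IVW)², df = J − 1."""
    j = len(ratios)
    if j < 2:
        raise ValueError("Cochran's Q needs at least 2 ratios")
    theta = np.array([r.ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = np.sum(w * theta) / np.sum(w)
    q = float(np.sum(w * (theta - est) ** 2))
    return HeterogeneityResult("cochran_ivw", q, j - 1, float(stats.chi2.sf(q, j - 1)))


def q_contributions(ratios: list[RatioEstimate]) -> np.ndarray:
    """Per-SNP terms w_j (θ_j − θ_IVW)²; they sum exactly to Cochran's Q."""
    theta = np.array([r.ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = np.sum(w * theta) / np.sum(w)
    return w * (theta - est) ** 2


def rucker_q(records: HarmonizedSet) -> HeterogeneityResult:
    """Rücker's Q: weighted residual sum about the Egger fit, df = J − 2."""
    kept = orient_positive(records).kept
    j = len(kept)
    if j < 3:
        raise ValueError("Rücker's Q needs at least 3 instruments")
    x = np.array([r.beta_x for r in kept])
    y = np.array([r.beta_y for r in kept])
    w = np.array([1.0 / r.se_y**2 for r in kept])
    slope_res, icpt = egger(records)
    resid = y - icpt.intercept - slope_res.estimate * x
    q = float(np.sum(w * resid**2))
    return HeterogeneityResult("rucker_egger", q, j - 2, float(stats.chi2.sf(q, j - 2)))


def egger_intercept_test(records: HarmonizedSet) -> EggerIntercept:
    """Directional-pleiotropy test: the Egger intercept with t-based p."""
    _, icpt = egger(records)
    return icpt


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """IVW (weighted through-origin) slope leaving each SNP out, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def _ivw_estimate(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * bx * by) / np.sum(w * bx * bx))


def mr_presso(
    records: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int | None = None,
) -> PressoResult:
    """MR-PRESSO: detect and remove pleiotropic outlier instruments.

    The observed statistic is the inverse-variance-weighted residual sum of
    squares where each SNP's expected outcome effect comes from the IVW
    slope fitted without it.  The null distribution is built by simulating
    ``n_sim`` datasets with beta_x drawn around its observed value and
    beta_y around its no-pleiotropy expectation (each with the observed
    SEs), and recomputing the same statistic.  The global test is the
    empirical exceedance probability; per-SNP outlier tests compare each
    observed squared residual with its simulated distribution, flagged at a
    Bonferroni-adjusted ``outlier_alpha``; the distortion test compares the
    IVW shift after removing the flagged set against shifts from removing
    equally many randomly chosen instruments.  Identical seed and inputs
    give identical results.
    """
    kept = records.kept
    j = len(kept)
    if j < 4:
        raise ValueError(f"MR-PRESSO requires at least 4 instruments, got {j}")
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    if seed is None:
        raise ValueError("mr_presso requires an explicit seed")

    bx = np.array([r.beta_x for r in kept])
    sx = np.array([r.se_x for r in kept])
    by = np.array([r.beta_y for r in kept])
    sy = np.array([r.se_y for r in kept])
    w = 1.0 / sy**2
    rsids = [r.rsid for r in kept]

    slopes_loo = _loo_slopes(bx, by, w)
    resid_obs = by - slopes_loo * bx
    wr2_obs = w * resid_obs**2
    rss_obs = float(np.sum(wr2_obs))

    rng = np.random.default_rng(seed)
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, j))

    # leave-one-out slopes per simulated dataset, vectorized over sims
    wxy = w * bx_sim * by_sim
    wxx = w * bx_sim * bx_sim
    slopes_sim = (wxy.sum(axis=1, keepdims=True) - wxy) / (wxx.sum(axis=1, keepdims=True) - wxx)
    resid_sim = by_sim - slopes_sim * bx_sim
    wr2_sim = w * resid_sim**2
    rss_sim = wr2_sim.sum(axis=1)

    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))
    outlier_p = (np.sum(wr2_sim >= wr2_obs, axis=0) + 1) / (n_sim + 1)
    outlier_pvals = dict(zip(rsids, outlier_p.astype(float)))
    bonferroni = outlier_alpha / j
    flagged = [rsids[i] for i in range(j) if outlier_p[i] < bonferroni]

    estimate_before = _ivw_estimate(bx, by, w)
    estimate_after = None
    distortion_pval = None
    if flagged:
        keep_mask = np.array([r not in flagged for r in rsids])
        if keep_mask.sum() >= 1:
            estimate_after = _ivw_estimate(bx[keep_mask], by[keep_mask], w[keep_mask])
            d_obs = abs(estimate_after - estimate_before)
            k = len(flagged)
            shifts = np.empty(n_sim)
            for i in range(n_sim):
                drop = rng.choice(j, size=k, replace=False)
                mask = np.ones(j, dtype=bool)
                mask[drop] = False
                shifts[i] = _ivw_estimate(bx[mask], by[mask], w[mask]) - estimate_before
            distortion_pval = float((np.sum(np.abs(shifts) >= d_obs) + 1) / (n_sim + 1))

    return PressoResult(
        rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=outlier_pvals,
        outlier_indices=flagged,
        distortion_pval=distortion_pval,
        estimate_before=estimate_before,
        estimate_after=estimate_after,
        n_sim=n_sim,
        seed=seed,
    )


def leave_one_out(records: HarmonizedSet) -> LOOResult:
    """Leave-one-variant-out IVW-RE re-estimation.

    One entry per kept instrument, fitted on the remaining J − 1.  Entries
    whose 95% CI reading (sign and whether it excludes zero) disagrees with
    the full-set IVW-RE estimate are flagged as influential.
    """
    kept = records.kept
    j = len(kept)
    if j < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    full_ratios = [wald_ratio(r) for r in kept]
    full = ivw(full_ratios, mode="random")

    def conclusion(res: MRResult) -> tuple[bool, int]:
        significant = res.ci_low > 0 or res.ci_high < 0
        return significant, int(np.sign(res.estimate)) if significant else 0

    full_conc = conclusion(full)
    entries: list[tuple[str, MRResult]] = []
    influential: list[str] = []
    for i, rec in enumerate(kept):
        sub = full_ratios[:i] + full_ratios[i + 1:]
        res = ivw(sub, mode="random")
        entries.append((rec.rsid, res))
        if conclusion(res) != full_conc:
            influential.append(rec.rsid)
    return LOOResult(entries=entries, full=full, influential=influential)


def funnel_data(ratios: list[RatioEstimate], combined: MRResult) -> pd.DataFrame:
    """Funnel-plot coordinates: per-SNP ratio, precision 1/se, combined line."""
    if not ratios:
        raise ValueError("funnel_data needs at least one ratio")
    return pd.DataFrame(
        {
            "SNP": [r.rsid for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "precision": [1.0 / r.se for r in ratios],
            "combined_estimate": combined.estimate,
        }
    )
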