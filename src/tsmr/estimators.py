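"""Causal-effect estimators for two-sample MR.

All estimators combine per-SNP Wald ratios (outcome effect over exposure
effect) or regress outcome on exposure effects across instruments:

* ``wald_ratio`` — one instrument's ratio with first-order delta-method SE
  (se_y / |beta_x|, exposure-side uncertainty ignored).
* ``ivw`` — inverse-variance weighted meta-analysis of the ratios; under
  first-order SEs this equals weighted least squares of beta_y on beta_x
  through the origin with weights 1/se_y².  The fixed-effects SE assumes
  homogeneity; the multiplicative random-effects SE inflates it by
  sqrt(Q/(J-1)), floored at 1, with Q Cochran's statistic.
* ``egger`` — the same regression with a free intercept; the slope is the
  pleiotropy-adjusted causal estimate and the intercept the average
  directional pleiotropy.  Residual dispersion is floored at 1 and p-values
  use t with J-2 degrees of freedom.
* ``weighted_median`` — the cumulative-inverse-variance-weight median of the
  ratios, consistent when valid instruments carry at least half the weight;
  SE from a seeded parametric bootstrap.
* ``ivw_penalized`` — IVW with each weight multiplied by min(1, 20·p_j),
  p_j the chi-square(1) upper-tail probability of the SNP's heterogeneity
  contribution; used when Cochran's Q signals heterogeneity.

Binary outcomes are analysed on the log-odds scale; ``with_or_scale``
exponentiates estimate and CI to odds ratios for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .harmonize import HarmonizedRecord, HarmonizedSet, orient_positive

__all__ = [
    "RatioEstimate",
    "MRResult",
    "EggerIntercept",
    "wald_ratio",
    "ratio_estimates",
    "ivw",
    "egger",
    "weighted_median",
    "ivw_penalized",
    "with_or_scale",
]

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass(frozen=True)
class RatioEstimate:
    """Single-SNP Wald ratio with delta-method SE and IVW weight (1/se²)."""

    rsid: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.rsid}: ratio SE must be positive")

    @property
    def weight(self) -> float:
        return 1.0 / self.se**2


@dataclass(frozen=True)
class MRResult:
    """One method's causal estimate on the outcome's linear scale.

    For binary outcomes the linear scale is log-odds and ``or_scale`` holds
    the exponentiated (estimate, ci_low, ci_high).
    """

    method: str
    n_snp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_scale: tuple[float, float, float] | None = None


@dataclass(frozen=True)
class EggerIntercept:
    """MR-Egger intercept: the average directional-pleiotropy estimate."""

    intercept: float
    se: float
    pval: float


def _normal_result(method: str, n_snp: int, estimate: float, se: float) -> MRResult:
    p = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else np.nan
    return MRResult(method, n_snp, estimate, se,
                    estimate - Z_95 * se, estimate + Z_95 * se, float(p))


def with_or_scale(result: MRResult) -> MRResult:
    """Populate the odds-ratio triple by exponentiating the linear scale."""
    return replace(result, or_scale=(np.exp(result.estimate),
                                     np.exp(result.ci_low),
                                     np.exp(result.ci_high)))


def wald_ratio(record: HarmonizedRecord) -> RatioEstimate:
    """Per-SNP causal estimate beta_y/beta_x with SE se_y/|beta_x|."""
    if record.beta_x == 0:
        raise ValueError(f"{record.rsid}: beta_x = 0, Wald ratio undefined")
    return RatioEstimate(record.rsid, record.beta_y / record.beta_x,
                         record.se_y / abs(record.beta_x))


def ratio_estimates(records: HarmonizedSet) -> list[RatioEstimate]:
    """Wald ratios for every kept record of a harmonized set."""
    return [wald_ratio(r) for r in records.kept]


def wald_result(record: HarmonizedRecord) -> MRResult:
    r = wald_ratio(record)
    return _normal_result("wald", 1, r.ratio, r.se)


def _ivw_point(ratios: list[RatioEstimate]) -> tuple[float, float, np.ndarray, np.ndarray]:
    theta = np.array([r.ratio for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = float(np.sum(w * theta) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    return est, se_fixed, theta, w


def cochran_q_statistic(ratios: list[RatioEstimate]) -> float:
    """Cochran's Q = Σ w_j (θ_j − θ_IVW)² over the ratio estimates."""
    est, _, theta, w = _ivw_point(ratios)
    return float(np.sum(w * (theta - est) ** 2))


def ivw(ratios: list[RatioEstimate], mode: str = "fixed") -> MRResult:
    """Inverse-variance weighted causal estimate.

    ``mode`` 'fixed' or 'random'.  Point estimates are identical; the
    random-effects (multiplicative) SE is the fixed SE times
    max(1, sqrt(Q/(J−1))), so it can only be larger.  p-values use the
    standard normal.  A single ratio is permitted with a warning and
    collapses to the Wald result.
    """
    if mode not in ("fixed", "random"):
        raise ValueError(f"mode must be fixed or random, got {mode!r}")
    if not ratios:
        raise ValueError("ivw requires at least one ratio")
    method = "ivw_fe" if mode == "fixed" else "ivw_re"
    if len(ratios) == 1:
        warnings.warn("single instrument: IVW collapses to the Wald estimator")
        r = ratios[0]
        return _normal_result(method, 1, r.ratio, r.se)
    est, se_fixed, theta, w = _ivw_point(ratios)
    se = se_fixed
    if mode == "random":
        q = float(np.sum(w * (theta - est) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (len(ratios) - 1)))
    return _normal_result(method, len(ratios), est, se)


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray, intercept: bool):
    """Closed-form weighted least squares; returns coefs, cov (unit dispersion), rss_w."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coefs = np.linalg.solve(xtwx, WX.T @ y)
    resid = y - X @ coefs
    rss_w = float(np.sum(w * resid**2))
    cov_unit = np.linalg.inv(xtwx)
    return coefs, cov_unit, rss_w


def egger(records: HarmonizedSet, intercept: bool = True) -> tuple[MRResult, EggerIntercept | None]:
    """MR-Egger regression of outcome on exposure effects.

    Instruments are first oriented to positive exposure effects (the
    regression is not orientation-invariant).  Weights are 1/se_y²; the
    dispersion parameter is max(1, weighted RSS/(J−2)) — no
    super-efficiency — and p-values use t with J−2 df.  With
    ``intercept=False`` (diagnostic mode) the slope reproduces the IVW-FE
    point estimate and no intercept is returned.
    """
    kept = orient_positive(records).kept
    j = len(kept)
    if j < 3:
        raise ValueError(f"MR-Egger requires at least 3 instruments, got {j}")
    x = np.array([r.beta_x for r in kept])
    y = np.array([r.beta_y for r in kept])
    w = np.array([1.0 / r.se_y**2 for r in kept])
    coefs, cov_unit, rss_w = _wls(x, y, w, intercept=intercept)
    df = j - 2 if intercept else j - 1
    dispersion = max(1.0, rss_w / df)
    ses = np.sqrt(dispersion * np.diag(cov_unit))

    def t_result(method: str, est: float, se: float) -> MRResult:
        tq = stats.t.ppf(0.975, df)
        p = 2.0 * stats.t.sf(abs(est) / se, df)
        return MRResult(method, j, float(est), float(se),
                        float(est - tq * se), float(est + tq * se), float(p))

    if intercept:
        slope_res = t_result("egger", coefs[1], ses[1])
        icpt = EggerIntercept(float(coefs[0]), float(ses[0]),
                              float(2.0 * stats.t.sf(abs(coefs[0]) / ses[0], df)))
        return slope_res, icpt
    return t_result("egger_no_intercept", coefs[0], ses[0]), None


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta_s, w_s = theta[order], w[order]
    w_s = w_s / w_s.sum()
    s = np.cumsum(w_s) - 0.5 * w_s
    k = int(np.searchsorted(s, 0.5))
    if k == 0:
        return float(theta_s[0])
    if k == len(theta_s):
        return float(theta_s[-1])
    # linear interpolation between the bracketing ratios
    return float(theta_s[k - 1] + (theta_s[k] - theta_s[k - 1])
                 * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def weighted_median(ratios: list[RatioEstimate], n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    Ratios are sorted and the estimate interpolates where the cumulative
    inverse-variance weight crosses one half.  The SE is the standard
    deviation of the estimate over ``n_boot`` replicates in which each
    ratio is redrawn from a normal with its own mean and SE (weights held
    fixed); ``seed`` is required for reproducibility.
    """
    if len(ratios) < 3:
        raise ValueError(f"weighted median requires at least 3 ratios, got {len(ratios)}")
    if seed is None:
        raise ValueError("weighted_median requires an explicit seed")
    theta = np.array([r.ratio for r in ratios])
    se = np.array([r.se for r in ratios])
    w = 1.0 / se**2
    est = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se, size=(n_boot, len(ratios)))
    boot = np.array([_weighted_median_point(d, w) for d in draws])
    boot_se = float(boot.std(ddof=1))
    return _normal_result("weighted_median", len(ratios), est, boot_se)


PENALTY_SCALE = 20.0


def ivw_penalized(ratios: list[RatioEstimate]) -> MRResult:
    """IVW with heterogeneity-penalized weights.

    Each SNP's heterogeneity contribution q_j = w_j(θ_j − θ_IVW)² is
    referred to chi-square(1); its upper-tail probability p_j down-weights
    the SNP via w_j* = w_j · min(1, 20·p_j).  Homogeneous sets are
    unchanged (all penalties 1); penalized weights never exceed the
    originals.
    """
    if not ratios:
        raise ValueError("ivw_penalized requires at least one ratio")
    est, _, theta, w = _ivw_point(ratios)
    q_j = w * (theta - est) ** 2
    pen = np.minimum(1.0, PENALTY_SCALE * stats.chi2.sf(q_j, df=1))
    w_star = w * pen
    est_p = float(np.sum(w_star * theta) / np.sum(w_star))
    se_p = float(np.sum(w_star) ** -0.5)
    return _normal_result("ivw_penalized", len(ratios), est_p, se_p)
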