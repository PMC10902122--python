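"""Two-sample MR estimators and sensitivity analyses.

All estimators consume a :class:`~drugmr.sumstats.HarmonizedSet` and work
on the per-variant exposure/outcome effect pairs (betaX_j, betaY_j) with
first-order Wald-ratio weights ``w_j = 1 / se_outcome_j^2`` (exposure
uncertainty is ignored in the weights, matching the convention of the
standard two-sample MR software).

The headline estimator is the multiplicative random-effects IVW: weighted
regression of betaY on betaX through the origin, with the slope standard
error inflated by ``sqrt(phi)`` where ``phi = max(1, Q / (J - 1))`` and Q
is Cochran's heterogeneity statistic.  Sensitivity estimators: MR-Egger
(free intercept; a nonzero intercept estimates directional pleiotropy
under the InSIDE assumption), weighted median, weighted mode, and
leave-one-out IVW.  P-values are two-sided standard normal throughout.

Effects are estimated per 1-unit exposure *increase*; the reporting
fields ``or_decrease``/``ci_low``/``ci_high`` give ``exp(-b)`` with its
95% interval, i.e. the odds ratio per 1-unit exposure *decrease* (the
convention for lipid-lowering drug-target studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from drugmr.sumstats import HarmonizedSet

Z975 = float(stats.norm.ppf(0.975))


class UndefinedRatioError(ZeroDivisionError):
    """Wald ratio is undefined because the exposure beta is zero."""


class InsufficientInstrumentsError(ValueError):
    """Too few instruments for the requested method."""


@dataclass
class MREstimate:
    """One method's causal estimate on both the slope and OR-decrease scales."""

    method: str
    b: float
    se: float
    pval: float
    n_snps: int
    q: float | None = None
    q_pval: float | None = None
    phi: float | None = None
    or_decrease: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self) -> None:
        if math.isnan(self.or_decrease):
            self.or_decrease = math.exp(-self.b)
            self.ci_low = math.exp(-(self.b + Z975 * self.se))
            self.ci_high = math.exp(-(self.b - Z975 * self.se))


@dataclass(frozen=True)
class EggerExtras:
    """MR-Egger intercept: the average directional pleiotropic effect per variant."""

    intercept: float
    intercept_se: float
    intercept_pval: float


def _two_sided_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([r.beta_exposure for r in hset.records], dtype=float)
    sx = np.array([r.se_exposure for r in hset.records], dtype=float)
    by = np.array([r.beta_outcome for r in hset.records], dtype=float)
    sy = np.array([r.se_outcome for r in hset.records], dtype=float)
    return bx, sx, by, sy


def wald_ratio(bx: float, sex: float, by: float, sey: float) -> tuple[float, float]:
    """Single-instrument causal estimate: theta = by/bx, se = sey/|bx|.

    First-order approximation: the exposure-side uncertainty ``sex`` does
    not enter the standard error.
    """
    if bx == 0:
        raise UndefinedRatioError("wald ratio undefined for bx = 0")
    return by / bx, sey / abs(bx)


def ivw_mre(hset: HarmonizedSet) -> MREstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights ``1/se_outcome^2``; the fixed-effect slope SE is
    scaled by ``sqrt(max(1, Q/(J-1)))`` so heterogeneity widens the
    interval but can never narrow it.  With a single instrument this
    reduces exactly to the Wald ratio.
    """
    if len(hset) == 0:
        raise InsufficientInstrumentsError("ivw_mre requires at least 1 instrument")
    bx, _, by, sy = _arrays(hset)
    if np.all(bx == 0):
        raise ValueError("degenerate design: all exposure betas are zero")
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx * bx))
    b = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx ** -0.5
    j = len(hset)
    if j >= 2:
        q = float(np.sum(w * (by - b * bx) ** 2))
        phi = max(1.0, q / (j - 1))
        q_pval = float(stats.chi2.sf(q, j - 1))
    else:
        q, q_pval, phi = None, None, 1.0
    se = se_fixed * math.sqrt(phi)
    return MREstimate(
        method="ivw_mre", b=b, se=se, pval=_two_sided_p(b / se), n_snps=j,
        q=q, q_pval=q_pval, phi=phi,
    )


def egger(hset: HarmonizedSet) -> tuple[MREstimate, EggerExtras]:
    """MR-Egger: weighted regression of betaY on betaX with a free intercept.

    Instruments are first oriented so every exposure beta is non-negative
    (joint sign flips leave ratio estimates unchanged).  Both coefficient
    SEs are inflated by ``sqrt(max(1, s^2))`` where ``s^2`` is the weighted
    residual mean square on ``J - 2`` degrees of freedom.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("egger requires at least 3 instruments")
    bx, _, by, sy = _arrays(hset)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    x = np.column_stack([np.ones_like(bx), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    j = len(hset)
    s2 = float(np.sum(w * resid**2)) / (j - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, s2)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    est = MREstimate(
        method="egger", b=slope, se=se_slope, pval=_two_sided_p(slope / se_slope), n_snps=j,
    )
    extras = EggerExtras(
        intercept=intercept, intercept_se=se_int, intercept_pval=_two_sided_p(intercept / se_int),
    )
    return est, extras


def _ratios_and_weights(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = by / bx
    w = bx**2 / sy**2
    return theta, w / w.sum()


def _weighted_median_point(theta: np.ndarray, w_norm: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    w = w_norm[order]
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, th))


def weighted_median(hset: HarmonizedSet, n_boot: int = 5000, seed: int | None = 0) -> MREstimate:
    """Weighted-median estimator: consistent when valid instruments carry
    more than half the weight.

    Ratio estimates ``theta_j = betaY_j / betaX_j`` are combined at the
    point where the cumulative (midpoint-adjusted) normalized weights
    cross one half; the SE comes from a parametric bootstrap that redraws
    both betas from normals centred at their estimates.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("weighted_median requires at least 3 instruments")
    bx, sx, by, sy = _arrays(hset)
    theta, w_norm = _ratios_and_weights(bx, by, sy)
    b = _weighted_median_point(theta, w_norm)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        th, wn = _ratios_and_weights(bx_b, by_b, sy)
        boots[i] = _weighted_median_point(th, wn)
    se = float(boots.std(ddof=1))
    return MREstimate(
        method="weighted_median", b=b, se=se, pval=_two_sided_p(b / se), n_snps=len(hset),
    )


def _mode_point(theta: np.ndarray, w_norm: np.ndarray, bandwidth_factor: float, grid_size: int = 1024) -> float:
    mad = float(np.median(np.abs(theta - np.median(theta))))
    scale = 1.4826 * mad
    if scale == 0.0:
        return float(np.median(theta))
    h = bandwidth_factor * 0.9 * scale * len(theta) ** (-1 / 5)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    dens = (w_norm[:, None] * np.exp(-0.5 * ((grid[None, :] - theta[:, None]) / h) ** 2)).sum(axis=0)
    return float(grid[int(np.argmax(dens))])


def weighted_mode(
    hset: HarmonizedSet,
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int | None = 0,
) -> MREstimate:
    """Weighted-mode estimator: consistent when the largest group of
    instruments sharing a ratio value is valid.

    The estimate is the argmax of a normal-kernel weighted density over
    the per-instrument ratios, with bandwidth ``bandwidth_factor`` times a
    median-absolute-deviation scale (Silverman-style ``0.9 s J^{-1/5}``);
    SE by parametric bootstrap.  When all ratios coincide the common value
    is returned directly.
    """
    if len(hset) < 3:
        raise InsufficientInstrumentsError("weighted_mode requires at least 3 instruments")
    bx, sx, by, sy = _arrays(hset)
    theta, w_norm = _ratios_and_weights(bx, by, sy)
    b = _mode_point(theta, w_norm, bandwidth_factor)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_b = rng.normal(bx, sx)
        by_b = rng.normal(by, sy)
        th, wn = _ratios_and_weights(bx_b, by_b, sy)
        boots[i] = _mode_point(th, wn, bandwidth_factor)
    se = float(boots.std(ddof=1))
    return MREstimate(
        method="weighted_mode", b=b, se=se, pval=_two_sided_p(b / se), n_snps=len(hset),
    )


@dataclass(frozen=True)
class LeaveOneOutResult:
    excluded_variant: str
    estimate: MREstimate
    flagged: bool


def leave_one_out(hset: HarmonizedSet) -> list[LeaveOneOutResult]:
    """Re-run IVW J times, omitting one instrument each time.

    An omission is flagged when it flips the sign of the slope or moves the
    p-value across 0.05 relative to the full-set estimate — evidence that a
    single variant drives the result.
    """
    if len(hset) < 2:
        raise InsufficientInstrumentsError("leave_one_out requires at least 2 instruments")
    full = ivw_mre(hset)
    out: list[LeaveOneOutResult] = []
    for i, rec in enumerate(hset.records):
        sub = HarmonizedSet(records=hset.records[:i] + hset.records[i + 1:])
        est = ivw_mre(sub)
        flagged = (np.sign(est.b) != np.sign(full.b)) or ((est.pval < 0.05) != (full.pval < 0.05))
        out.append(LeaveOneOutResult(excluded_variant=rec.variant_id, estimate=est, flagged=bool(flagged)))
    return out


def _power_from_ncp(ncp: float, alpha: float) -> float:
    z = stats.norm.ppf(1 - alpha / 2)
    # both rejection tails, so size is exactly alpha at the null
    return float(stats.norm.cdf(ncp - z) + stats.norm.cdf(-ncp - z))


def mr_power_binary(n: float, r2: float, k: float, or_alt: float, alpha: float = 0.05) -> float:
    """Approximate power of two-sample MR with a binary outcome.

    Uses the non-centrality approximation behind the standard online MR
    power calculator: the test statistic is approximately normal with mean
    ``|log(or_alt)| * sqrt(n * r2 * k * (1 - k))`` where ``n`` is the
    outcome sample size, ``r2`` the variance in the exposure explained by
    the instruments and ``k`` the case fraction.
    """
    if not (0 < k < 1) or not (0 < r2 < 1) or n <= 0 or or_alt <= 0 or not (0 < alpha < 1):
        raise ValueError("require n > 0, 0 < r2 < 1, 0 < k < 1, or_alt > 0, 0 < alpha < 1")
    ncp = abs(math.log(or_alt)) * math.sqrt(n * r2 * k * (1 - k))
    return _power_from_ncp(ncp, alpha)


def mr_power_continuous(n: float, r2: float, b_alt: float, alpha: float = 0.05) -> float:
    """As :func:`mr_power_binary` for a continuous standardized outcome
    (the case-fraction factor drops out)."""
    if not (0 < r2 < 1) or n <= 0 or not (0 < alpha < 1):
        raise ValueError("require n > 0, 0 < r2 < 1, 0 < alpha < 1")
    ncp = abs(b_alt) * math.sqrt(n * r2)
    return _power_from_ncp(ncp, alpha)
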