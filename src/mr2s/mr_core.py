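"""Causal estimators for two-sample Mendelian randomization.

All estimators consume harmonized per-variant effect pairs. With ratio
estimates r_j = beta_out,j / beta_exp,j and first-order weights
w_j = (beta_exp,j / se_out,j)^2 (the inverse of the delta-method ratio
variance, exposure effects treated as known):

* Wald ratio — a single instrument's r with se = se_out / |beta_exp|.
* IVW — the w-weighted mean of the r_j, equivalently weighted regression of
  beta_out on beta_exp through the origin. The fixed-effects variant uses
  se = 1/sqrt(sum w); the multiplicative random-effects variant scales that
  se by max(1, sqrt(Q / (k - 1))) where Q is Cochran's heterogeneity
  statistic at the IVW estimate.
* MR-Egger — weighted regression of beta_out on beta_exp *with* an
  intercept (weights 1/se_out^2, exposure effects oriented non-negative).
  The slope is the causal estimate under InSIDE; the intercept estimates
  average directional pleiotropy. Inference uses t(k-2) with multiplicative
  overdispersion max(1, sqrt(RSS_w / (k-2))).
* Weighted median — consistent when instruments carrying >50% of the
  weight are valid; se by seeded parametric bootstrap.
* Weighted mode — the maximum of a weighted Gaussian kernel density over
  the ratio estimates; robust when the largest cluster of instruments is
  valid; se by the same bootstrap.

Confidence intervals are beta +/- 1.96 se throughout; p-values are
two-sided normal except MR-Egger's, which use t(k-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (DegenerateInstrumentError, DomainError,
                     InsufficientDataError)
from .harmonize import HarmonizedDataset, HarmonizedPair

Z_CI = 1.96  # reporting convention: printed CIs reconstruct with 1.96 exactly

METHOD_LABELS = ("wald_ratio", "ivw_fe", "ivw_mre", "egger_slope",
                 "egger_intercept", "weighted_median", "weighted_mode")


@dataclass(frozen=True)
class MREstimate:
    """A causal-effect estimate with its diagnostics.

    ``beta`` is a log odds ratio per SD of exposure for binary outcomes, or
    an SD difference per SD of exposure for continuous outcomes.
    """

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    q_stat: float | None = None
    q_pval: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHOD_LABELS:
            raise DomainError(f"unknown method label {self.method!r}")
        if not (self.se > 0 or math.isnan(self.se)):
            raise DomainError(f"se must be positive, got {self.se!r}")

    @property
    def ci_low(self) -> float:
        return self.beta - Z_CI * self.se

    @property
    def ci_high(self) -> float:
        return self.beta + Z_CI * self.se

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


def _pairs(data: HarmonizedDataset | Sequence[HarmonizedPair],
           ) -> list[HarmonizedPair]:
    return list(data.pairs) if isinstance(data, HarmonizedDataset) else list(data)


def _ratio_arrays(pairs: Sequence[HarmonizedPair],
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ratios, weights, ratio-se) with w_j = (beta_exp_j / se_out_j)^2."""
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    for p in pairs:
        if p.beta_exp == 0:
            raise DegenerateInstrumentError(
                f"instrument {p.variant_id} has zero exposure effect")
    r = by / bx
    se_r = sy / np.abs(bx)
    return r, 1.0 / se_r**2, se_r


def _norm_p(z: float) -> float:
    return 2.0 * stats.norm.sf(abs(z))


def wald_ratio(pair: HarmonizedPair) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp.

    The standard error is first-order delta method using outcome noise only,
    se_out / |beta_exp|, the usual two-sample convention.
    """
    if pair.beta_exp == 0:
        raise DegenerateInstrumentError(
            f"instrument {pair.variant_id} has zero exposure effect")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return MREstimate("wald_ratio", beta, se, _norm_p(beta / se), 1)


def cochrans_q(data: HarmonizedDataset | Sequence[HarmonizedPair],
               center: float) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q of the per-variant ratios about ``center``.

    Q = sum w_j (r_j - center)^2 with w_j = (beta_exp_j/se_out_j)^2;
    df = k - 1; p from the chi-square(df) upper tail.
    """
    pairs = _pairs(data)
    k = len(pairs)
    if k < 2:
        raise InsufficientDataError(f"Cochran's Q needs >= 2 instruments, got {k}")
    r, w, _ = _ratio_arrays(pairs)
    q = float(np.sum(w * (r - center) ** 2))
    df = k - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(data: HarmonizedDataset | Sequence[HarmonizedPair],
        variant: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate over the per-variant ratios.

    ``variant`` is ``"fixed"`` or ``"multiplicative_random"``; the latter
    inflates the fixed-effects se by max(1, sqrt(Q/(k-1))). With a single
    instrument the fixed-effects IVW reduces exactly to the Wald ratio.
    """
    if variant not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown IVW variant {variant!r}")
    pairs = _pairs(data)
    k = len(pairs)
    if k < 1:
        raise InsufficientDataError("IVW needs >= 1 instrument")
    if variant == "multiplicative_random" and k < 2:
        raise InsufficientDataError(
            "multiplicative random-effects IVW needs >= 2 instruments")
    if k == 1:
        est = wald_ratio(pairs[0])
        return replace(est, method="ivw_fe")
    r, w, _ = _ratio_arrays(pairs)
    beta = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q, df, q_p = cochrans_q(pairs, beta)
    label = "ivw_fe"
    if variant == "multiplicative_random":
        se *= max(1.0, math.sqrt(q / df))
        label = "ivw_mre"
    return MREstimate(label, beta, se, _norm_p(beta / se), k,
                      q_stat=q, q_pval=q_p)


def mr_egger(data: HarmonizedDataset | Sequence[HarmonizedPair],
             ) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Pairs with negative exposure effect are flipped (both betas negated)
    before fitting so the intercept is identified. Fitted by weighted least
    squares of beta_out on beta_exp with weights 1/se_out^2; standard errors
    carry a multiplicative overdispersion factor max(1, sqrt(RSS_w/(k-2)))
    and p-values come from t(k-2).
    """
    pairs = _pairs(data)
    k = len(pairs)
    if k < 3:
        raise InsufficientDataError(f"MR-Egger needs >= 3 instruments, got {k}")
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.ptp(bx) == 0:
        raise DomainError("exposure effects are constant; Egger slope is "
                          "unidentified (collinearity)")
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # statsmodels scale = weighted RSS / (k-2); rescale to multiplicative
    # overdispersion with a floor of 1 (never deflate below the fixed model)
    dispersion = max(1.0, math.sqrt(fit.scale))
    # unit-scale SEs from (X'WX)^{-1}; robust to RSS == 0 on an exact line
    base_se = np.sqrt(np.diag(fit.normalized_cov_params))
    inter_b, slope_b = float(fit.params[0]), float(fit.params[1])
    inter_se = float(base_se[0]) * dispersion
    slope_se = float(base_se[1]) * dispersion
    df = k - 2
    slope_p = 2.0 * float(stats.t.sf(abs(slope_b / slope_se), df))
    inter_p = 2.0 * float(stats.t.sf(abs(inter_b / inter_se), df))
    slope = MREstimate("egger_slope", slope_b, slope_se, slope_p, k)
    intercept = MREstimate("egger_intercept", inter_b, inter_se, inter_p, k)
    return slope, intercept


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r_s, w_s = r[order], w[order] / np.sum(w)
    s = np.cumsum(w_s) - 0.5 * w_s
    return float(np.interp(0.5, s, r_s))


def _bootstrap_se(pairs: Sequence[HarmonizedPair], point_fn, n_boot: int,
                  rng: np.random.Generator) -> float:
    """Parametric bootstrap: perturb each pair's betas by its SEs, re-estimate."""
    bx = np.array([p.beta_exp for p in pairs])
    by = np.array([p.beta_out for p in pairs])
    sx = np.array([p.se_exp for p in pairs])
    sy = np.array([p.se_out for p in pairs])
    ests = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + rng.normal(0.0, sx)
        by_b = by + rng.normal(0.0, sy)
        bx_b[bx_b == 0] = np.finfo(float).tiny
        r = by_b / bx_b
        w = (bx_b / sy) ** 2
        ests[b] = point_fn(r, w)
    return float(np.std(ests, ddof=1))


def weighted_median(data: HarmonizedDataset | Sequence[HarmonizedPair],
                    n_boot: int = 5000,
                    seed: int | np.random.Generator | None = None,
                    ) -> MREstimate:
    """Weighted median of the per-variant ratio estimates.

    Consistent when valid instruments carry more than half of the
    inverse-variance weight. The point estimate interpolates the ordered
    ratios at cumulative weight 0.5; the standard error is the spread of
    the estimate over ``n_boot`` seeded parametric-bootstrap resamples.
    """
    pairs = _pairs(data)
    k = len(pairs)
    if k < 3:
        raise InsufficientDataError(f"weighted median needs >= 3 instruments, got {k}")
    r, w, _ = _ratio_arrays(pairs)
    beta = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(pairs, _weighted_median_point, n_boot, rng)
    if se == 0:
        se = np.finfo(float).tiny
    return MREstimate("weighted_median", beta, se, _norm_p(beta / se), k)


def _weighted_mode_point(r: np.ndarray, w: np.ndarray,
                         bandwidth_factor: float = 1.0) -> float:
    w = w / np.sum(w)
    mad = float(np.median(np.abs(r - np.median(r))))
    h = bandwidth_factor * 1.4826 * mad
    if h == 0:  # all (or half of) ratios identical: fall back to weighted median
        return _weighted_median_point(r, w)
    lo, hi = float(np.min(r)) - 3 * h, float(np.max(r)) + 3 * h
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2) @ w
    # np.argmax returns the first maximum -> ties break to the smaller mode
    return float(grid[np.argmax(dens)])


def weighted_mode(data: HarmonizedDataset | Sequence[HarmonizedPair],
                  bandwidth_factor: float = 1.0, n_boot: int = 5000,
                  seed: int | np.random.Generator | None = None,
                  ) -> MREstimate:
    """Mode of the weighted kernel density over the per-variant ratios.

    Bandwidth is ``bandwidth_factor`` times the MAD-based robust spread
    (1.4826 * median absolute deviation) of the ratios. Exact ties between
    modes break deterministically to the smaller mode value. The standard
    error uses the same seeded parametric bootstrap as the weighted median.
    """
    pairs = _pairs(data)
    k = len(pairs)
    if k < 3:
        raise InsufficientDataError(f"weighted mode needs >= 3 instruments, got {k}")
    r, w, _ = _ratio_arrays(pairs)
    beta = _weighted_mode_point(r, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    se = _bootstrap_se(
        pairs, lambda rr, ww: _weighted_mode_point(rr, ww, bandwidth_factor),
        n_boot, rng)
    if se == 0:
        se = np.finfo(float).tiny
    return MREstimate("weighted_mode", beta, se, _norm_p(beta / se), k)


@dataclass(frozen=True)
class MethodPlan:
    """Which estimator leads the analysis and which sensitivity checks run."""

    main: str                       # "wald_ratio", "ivw_fe" or "ivw_mre"
    sensitivity: tuple[str, ...]    # () or ("weighted_median", "mr_egger")


def select_main_method(k: int, outcome_mode: str = "binary_primary") -> MethodPlan:
    """Method-selection rule keyed to the instrument count.

    One instrument -> Wald ratio; two or three -> fixed-effects IVW; four or
    more -> multiplicative random-effects IVW with weighted-median and
    MR-Egger sensitivity analyses attached. The same rule applies to binary
    and continuous outcomes; ``outcome_mode`` ("binary_primary" or
    "continuous_pdff") controls only reporting scale downstream.
    """
    if outcome_mode not in ("binary_primary", "continuous_pdff"):
        raise DomainError(f"unknown outcome mode {outcome_mode!r}")
    if k < 1:
        raise InsufficientDataError("no instruments available")
    if k == 1:
        return MethodPlan("wald_ratio", ())
    if k <= 3:
        return MethodPlan("ivw_fe", ())
    return MethodPlan("ivw_mre", ("weighted_median", "mr_egger"))
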