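"""Summary-level causal-effect estimators for two-sample MR.

Given harmonized instruments (β̂_Xj, β̂_Yj with standard errors), the causal
effect θ of the exposure on the outcome is estimated by:

* Wald ratio — β̂_Yj / β̂_Xj for a single SNP (delta-method SE);
* IVW — inverse-variance-weighted combination of Wald ratios, equivalent to
  zero-intercept weighted regression of β̂_Y on β̂_X with weights 1/SE_Yj²;
  the default multiplicative random-effects model inflates the fixed-effect
  SE by max(1, √(Q/(k−1))) under heterogeneity;
* MR-Egger — the same regression with a free intercept; the slope remains a
  consistent causal estimate under InSIDE and the intercept measures
  directional pleiotropy (t inference with k−2 df);
* weighted median — interpolated median of the Wald ratios under
  inverse-variance weights; consistent when ≥50% of weight is valid;
* simple / weighted mode — the mode of a kernel-smoothed density of Wald
  ratios; consistent when the largest homogeneous cluster is valid (ZEMPA).

Bootstrap SEs (median, mode) use a parametric bootstrap drawing β̂* around
the observed effects with the observed SEs, seeded for reproducibility.

All estimators first orient instruments so β̂_X ≥ 0; estimates are invariant
to jointly re-signing any instrument's effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateDesignError, DomainError
from .instruments import HarmonizedInstrument

Z975 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One estimator's causal effect with normal/t inference.

    ``beta`` is on the log-odds scale for binary outcomes; ``or_`` and its
    CI are the exponentiated twins. ``extra`` carries method-specific fields
    (Egger intercept and its SE/p, residual scale, bootstrap settings).
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    nsnp: int
    extra: dict = dc_field(default_factory=dict)

    @property
    def or_(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_low(self) -> float:
        return float(np.exp(self.ci_low))

    @property
    def or_high(self) -> float:
        return float(np.exp(self.ci_high))


def _arrays(instrs: Sequence[HarmonizedInstrument]):
    """Extract (bx, sx, by, sy) arrays, oriented so bx >= 0."""
    bx = np.asarray([i.beta_exp for i in instrs], dtype=float)
    sx = np.asarray([i.se_exp for i in instrs], dtype=float)
    by = np.asarray([i.beta_out for i in instrs], dtype=float)
    sy = np.asarray([i.se_out for i in instrs], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, sx, by * sign, sy


def _normal_estimate(method: str, beta: float, se: float, nsnp: int, extra=None) -> MREstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta) if beta else 0.0
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return MREstimate(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(beta - Z975 * se), ci_high=float(beta + Z975 * se),
        pvalue=p, nsnp=nsnp, extra=extra or {},
    )


def wald_ratio(instr: HarmonizedInstrument) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X with first-order delta SE."""
    if instr.beta_exp == 0:
        raise DomainError("Wald ratio undefined for beta_exp = 0")
    beta = instr.beta_out / instr.beta_exp
    se = instr.se_out / abs(instr.beta_exp)
    return _normal_estimate("wald", beta, se, 1)


def _ivw_core(bx, by, w):
    s2 = float(np.sum(w * bx * bx))
    if s2 <= 0:
        raise DegenerateDesignError("IVW needs at least one nonzero exposure effect")
    beta = float(np.sum(w * bx * by)) / s2
    se_fixed = 1.0 / np.sqrt(s2)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(
    instrs: Sequence[HarmonizedInstrument],
    model: str = "multiplicative_random",
) -> MREstimate:
    """Inverse-variance-weighted estimate (zero-intercept WLS).

    With weights w_j = 1/SE_Yj², β̂ = Σw β_X β_Y / Σw β_X². ``model`` is
    ``fixed`` or ``multiplicative_random`` (default); the random-effects SE
    is the fixed SE scaled by max(1, √(Q/(k−1))), conservative under
    heterogeneity and never tighter than fixed.
    """
    if len(instrs) == 0:
        raise DomainError("ivw needs at least one instrument")
    if len(instrs) == 1:
        est = wald_ratio(instrs[0])
        return MREstimate(method="ivw", beta=est.beta, se=est.se, ci_low=est.ci_low,
                          ci_high=est.ci_high, pvalue=est.pvalue, nsnp=1,
                          extra={"model": "wald_fallback", "q": 0.0})
    if model not in ("fixed", "multiplicative_random"):
        raise DomainError(f"unknown IVW model {model!r}")
    bx, _, by, sy = _arrays(instrs)
    w = 1.0 / sy**2
    beta, se_fixed, q = _ivw_core(bx, by, w)
    k = len(instrs)
    scale = max(1.0, np.sqrt(q / (k - 1))) if model == "multiplicative_random" else 1.0
    est = _normal_estimate("ivw", beta, se_fixed * scale, k,
                           extra={"model": model, "q": q, "se_fixed": se_fixed})
    return est


def egger(instrs: Sequence[HarmonizedInstrument]) -> MREstimate:
    """MR-Egger regression: intercept-included WLS of β_Y on β_X.

    The slope is the causal estimate; the intercept estimates the average
    directional pleiotropic effect, and its two-sided t test (k−2 df) below
    0.05 flags horizontal pleiotropy. SEs use a multiplicative
    random-effects scale max(1, √(RSS_w/(k−2))); CIs and p-values use the t
    distribution with k−2 df.
    """
    k = len(instrs)
    if k < 3:
        raise DomainError("MR-Egger needs at least 3 instruments")
    bx, _, by, sy = _arrays(instrs)
    w = 1.0 / sy**2
    sw = np.sum(w)
    mx = np.sum(w * bx) / sw
    sxx = np.sum(w * (bx - mx) ** 2)
    if sxx <= 0 or np.allclose(bx, bx[0]):
        raise DegenerateDesignError("all exposure effects identical: Egger design has no leverage")
    my = np.sum(w * by) / sw
    slope = float(np.sum(w * (bx - mx) * (by - my)) / sxx)
    intercept = float(my - slope * mx)
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    sigma2 = max(1.0, rss_w / (k - 2))
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_int = float(np.sqrt(sigma2 * (1.0 / sw + mx**2 / sxx)))
    tdist = stats.t(k - 2)
    tcrit = tdist.ppf(0.975)
    p_slope = float(2.0 * tdist.sf(abs(slope / se_slope)))
    p_int = float(2.0 * tdist.sf(abs(intercept / se_int))) if se_int > 0 else 1.0
    return MREstimate(
        method="egger", beta=slope, se=se_slope,
        ci_low=slope - tcrit * se_slope, ci_high=slope + tcrit * se_slope,
        pvalue=p_slope, nsnp=k,
        extra={
            "intercept": intercept, "intercept_se": se_int, "intercept_pvalue": p_int,
            "residual_scale": float(np.sqrt(sigma2)), "df": k - 2,
        },
    )


def _interp_weighted_median(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    t, ww = theta[order], w[order]
    cum = np.cumsum(ww)
    s = (cum - 0.5 * ww) / cum[-1]
    return float(np.interp(0.5, s, t))


def weighted_median(
    instrs: Sequence[HarmonizedInstrument],
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Weighted median of the per-SNP Wald ratios.

    Ratios θ_j = β_Yj/β_Xj carry inverse-variance weights
    w_j = β_Xj²/SE_Yj² (the first-order precision of θ_j). The estimate
    interpolates θ across standardized cumulative weights at 0.5, so it is
    consistent whenever valid instruments carry more than half the weight.
    The SE is the SD of the estimate over ``n_boot`` parametric bootstrap
    replicates (seeded).
    """
    k = len(instrs)
    if k < 3:
        raise DomainError("weighted median needs at least 3 instruments")
    bx, sx, by, sy = _arrays(instrs)
    if np.any(bx == 0):
        raise DomainError("weighted median undefined with beta_exp = 0")
    theta = by / bx
    w = bx**2 / sy**2
    beta = _interp_weighted_median(theta, w)
    se = _bootstrap_se(_interp_weighted_median, bx, sx, by, sy, n_boot, seed)
    return _normal_estimate("weighted_median", beta, se, k,
                            extra={"n_boot": n_boot, "seed": seed})


def _silverman_bandwidth(theta: np.ndarray, factor: float) -> float:
    n = theta.size
    sd = float(np.std(theta, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread <= 0:
        return 0.0
    return factor * 0.9 * spread * n ** (-0.2)


def _kde_mode(theta: np.ndarray, w: np.ndarray, h: float, grid_size: int = 512) -> float:
    if h <= 0:  # degenerate spread: weighted consensus value
        return float(theta[np.argmax(w)]) if not np.allclose(theta, theta[0]) else float(theta[0])
    lo, hi = theta.min() - 3 * h, theta.max() + 3 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid_size - 1)]

    def neg_dens(x):
        return -(w * np.exp(-0.5 * ((x - theta) / h) ** 2)).sum()

    res = optimize.minimize_scalar(neg_dens, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def mode_estimate(
    instrs: Sequence[HarmonizedInstrument],
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode of the smoothed density of Wald ratios (simple/weighted mode).

    A normal kernel with Silverman-type bandwidth (0.9·min(sd, IQR/1.349)·
    k^(−1/5), scaled by ``bandwidth_factor``) smooths the ratio estimates;
    the estimate is the density maximizer. Weights are 1 for the simple
    mode and the ratios' inverse variances for the weighted mode. The SE is
    a seeded parametric-bootstrap SD, as for the weighted median.
    """
    k = len(instrs)
    if k < 3:
        raise DomainError("mode estimator needs at least 3 instruments")
    if bandwidth_factor <= 0:
        raise DomainError("bandwidth_factor must be positive")
    bx, sx, by, sy = _arrays(instrs)
    if np.any(bx == 0):
        raise DomainError("mode estimator undefined with beta_exp = 0")
    theta = by / bx
    w = bx**2 / sy**2 if weighted else np.ones_like(theta)
    h = _silverman_bandwidth(theta, bandwidth_factor)
    beta = _kde_mode(theta, w, h)
    se = _bootstrap_se(
        lambda t, ww: _kde_mode(t, ww, _silverman_bandwidth(t, bandwidth_factor), grid_size=256),
        bx, sx, by, sy, n_boot, seed,
        weights="ivw" if weighted else "unit",
    )
    method = "weighted_mode" if weighted else "simple_mode"
    return _normal_estimate(method, beta, se, k,
                            extra={"bandwidth": h, "n_boot": n_boot, "seed": seed})


def _bootstrap_se(statistic, bx, sx, by, sy, n_boot, seed, weights="ivw"):
    """Parametric-bootstrap SD of a ratio statistic.

    Draws β_X* ~ N(β_X, SE_X) and β_Y* ~ N(β_Y, SE_Y), recomputes the
    statistic on (θ*, w*) per replicate. ``statistic`` takes (theta, w).
    """
    if n_boot < 2:
        return float("nan")
    rng = np.random.default_rng(seed)
    k = bx.size
    bxs = rng.normal(bx, sx, size=(n_boot, k))
    bys = rng.normal(by, sy, size=(n_boot, k))
    # guard exact zeros in the denominator (probability-zero event)
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    theta = bys / bxs
    if weights == "ivw":
        w = bxs**2 / sy[None, :] ** 2
    else:
        w = np.ones_like(theta)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        vals[b] = statistic(theta[b], w[b])
    return float(np.std(vals, ddof=1))
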