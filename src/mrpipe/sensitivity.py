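"""Heterogeneity, pleiotropy, and influence diagnostics.

* Cochran's Q over the per-SNP Wald ratios (the IVW companion form),
  referred to a chi-square with k−1 df;
* the MR-Egger intercept test for directional pleiotropy;
* leave-one-out IVW, flagging SNPs whose omission flips the estimate's
  sign or moves it outside the full-set confidence interval;
* MR-PRESSO: a parametric-simulation residual-sum-of-squares global test,
  per-SNP outlier flagging (Bonferroni), a distortion test comparing the
  all-SNP and outlier-removed IVW estimates, and the corrected estimate.

All stochastic procedures are bit-reproducible given (seed, n_sim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .estimators import MREstimate, _arrays, ivw
from .instruments import HarmonizedInstrument


def cochran_q(
    instrs: Sequence[HarmonizedInstrument], method: str = "ivw"
) -> tuple[float, int, float]:
    """Cochran's Q over per-SNP ratio estimates.

    Q = Σ w_j (θ_j − θ̂_fixed)² with θ_j = β_Yj/β_Xj. The default weights
    w_j = β_Xj²/SE_Yj² are the first-order precisions of θ_j (equivalently
    Q is the weighted RSS of the fixed-effect IVW fit); ``method="delta"``
    adds the exposure-side variance to the denominator. The p-value refers
    Q to chi-square with k−1 df.
    """
    k = len(instrs)
    if k < 2:
        raise DomainError("Cochran's Q needs at least 2 instruments")
    bx, sx, by, sy = _arrays(instrs)
    theta = by / bx
    if method == "ivw":
        w = bx**2 / sy**2
    elif method == "delta":
        w = 1.0 / (sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    else:
        raise DomainError(f"unknown Q method {method!r}")
    theta_fixed = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - theta_fixed) ** 2))
    p = float(stats.chi2.sf(q, k - 1))
    return q, k - 1, p


def egger_intercept_test(instrs: Sequence[HarmonizedInstrument]) -> tuple[float, float, float]:
    """(intercept, SE, p) from the MR-Egger regression (t test, k−2 df)."""
    from .estimators import egger

    est = egger(instrs)
    return est.extra["intercept"], est.extra["intercept_se"], est.extra["intercept_pvalue"]


def leave_one_out(instrs: Sequence[HarmonizedInstrument]) -> pd.DataFrame:
    """IVW re-estimated with each SNP omitted in turn.

    Returns one row per left-out SNP (rsid, beta, se, ci_low, ci_high,
    pvalue) plus ``influential``: True when omitting the SNP flips the
    estimate's sign or moves it outside the full-set 95% CI.
    """
    k = len(instrs)
    if k < 2:
        raise DomainError("leave-one-out needs at least 2 instruments")
    full = ivw(instrs)
    rows = []
    for j, left_out in enumerate(instrs):
        subset = [ins for i, ins in enumerate(instrs) if i != j]
        est = ivw(subset)
        influential = (
            np.sign(est.beta) != np.sign(full.beta)
            or not (full.ci_low <= est.beta <= full.ci_high)
        )
        rows.append({
            "rsid": left_out.rsid, "beta": est.beta, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "pvalue": est.pvalue, "influential": bool(influential),
        })
    return pd.DataFrame(rows)


@dataclass
class PressoResult:
    global_p: float
    rss_obs: float
    outliers: list[str]
    outlier_pvalues: dict[str, float]
    distortion_p: float | None
    corrected: MREstimate | None
    n_sim: int
    seed: int


def _loo_slopes(bx, by, w):
    """Leave-one-out fixed-effect IVW slopes, computed from running sums."""
    s1 = np.sum(w * bx * by)
    s2 = np.sum(w * bx * bx)
    return (s1 - w * bx * by) / (s2 - w * bx * bx)


def mr_presso(
    instrs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    outlier_alpha: float = 0.05,
) -> PressoResult:
    """MR-PRESSO global, outlier, and distortion tests.

    The observed statistic is the leave-one-out weighted residual sum of
    squares RSS = Σ_j w_j (β_Yj − θ̂₍₋ⱼ₎ β_Xj)² with w_j = 1/SE_Yj². Its
    null distribution is built from ``n_sim`` parametric draws
    β_X* ~ N(β_X, SE_X), β_Y* ~ N(θ̂₍₋ⱼ₎ β_X, SE_Y), each re-fitted with
    leave-one-out slopes. The global p uses the add-one Monte-Carlo
    estimator, so it lies in (0, 1] and is never exactly zero. Per-SNP
    residual terms are compared with their simulated distributions and
    flagged at the Bonferroni level ``outlier_alpha``/k. When outliers
    exist, the distortion test compares the observed shift between the
    all-SNP and outlier-free IVW estimates with shifts from removing random
    subsets of the same size, and the corrected estimate is IVW on the
    outlier-free set.
    """
    k = len(instrs)
    if k < 4:
        raise DomainError("MR-PRESSO needs at least 4 instruments")
    if not (0 < outlier_alpha < 1):
        raise DomainError("outlier_alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    bx, sx, by, sy = _arrays(instrs)
    w = 1.0 / sy**2
    theta_loo = _loo_slopes(bx, by, w)
    res_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(np.sum(res_obs))

    bx_star = rng.normal(bx, sx, size=(n_sim, k))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, k))
    s1 = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    s2 = np.sum(w * bx_star**2, axis=1, keepdims=True)
    theta_star = (s1 - w * bx_star * by_star) / (s2 - w * bx_star**2)
    res_star = w * (by_star - theta_star * bx_star) ** 2
    rss_star = res_star.sum(axis=1)

    global_p = float((1 + np.sum(rss_star >= rss_obs)) / (1 + n_sim))
    per_snp_p = (1 + np.sum(res_star >= res_obs[None, :], axis=0)) / (1 + n_sim)
    threshold = outlier_alpha / k
    flagged = [instrs[j].rsid for j in range(k) if per_snp_p[j] < threshold]
    outlier_pvalues = {instrs[j].rsid: float(per_snp_p[j]) for j in range(k)}

    distortion_p = None
    corrected = None
    if flagged:
        keep = [ins for ins in instrs if ins.rsid not in flagged]
        if len(keep) >= 1:
            corrected = ivw(keep)
            full = ivw(list(instrs))
            d_obs = corrected.beta - full.beta
            n_rm = k - len(keep)
            d_null = np.empty(n_sim)
            for b in range(n_sim):
                rm = rng.choice(k, size=n_rm, replace=False)
                mask = np.ones(k, dtype=bool)
                mask[rm] = False
                beta_b = float(
                    np.sum(w[mask] * bx[mask] * by[mask]) / np.sum(w[mask] * bx[mask] ** 2)
                )
                d_null[b] = beta_b - full.beta
            distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_sim))
    return PressoResult(
        global_p=global_p, rss_obs=rss_obs, outliers=flagged,
        outlier_pvalues=outlier_pvalues, distortion_p=distortion_p,
        corrected=corrected, n_sim=n_sim, seed=seed,
    )


@dataclass
class SensitivityReport:
    """Q, Egger-intercept, leave-one-out, and MR-PRESSO results for one pair.

    Components that need more instruments than are available are left None
    (Q and leave-one-out need ≥2, the Egger intercept ≥3, MR-PRESSO ≥4).
    ``flags`` holds the α = 0.05 heterogeneity / pleiotropy booleans driven
    by the Q and intercept p-values.
    """

    nsnp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None
    presso: PressoResult | None = None
    loo: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)

    @property
    def presso_global_p(self):
        return None if self.presso is None else self.presso.global_p

    @property
    def presso_outliers(self):
        return [] if self.presso is None else self.presso.outliers


def sensitivity_report(
    instrs: Sequence[HarmonizedInstrument],
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    outlier_alpha: float = 0.05,
    run_presso: bool = True,
) -> SensitivityReport:
    """Run every diagnostic the instrument count permits."""
    k = len(instrs)
    rep = SensitivityReport(nsnp=k)
    if k >= 2:
        rep.q_stat, rep.q_df, rep.q_pvalue = cochran_q(instrs)
        rep.loo = leave_one_out(instrs)
    if k >= 3:
        rep.egger_intercept, rep.egger_intercept_se, rep.egger_intercept_p = (
            egger_intercept_test(instrs)
        )
    if k >= 4 and run_presso:
        rep.presso = mr_presso(instrs, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    rep.flags = {
        "heterogeneity": bool(rep.q_pvalue is not None and rep.q_pvalue < alpha),
        "pleiotropy": bool(rep.egger_intercept_p is not None and rep.egger_intercept_p < alpha),
    }
    return rep
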