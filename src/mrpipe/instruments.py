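"""Instrument selection, strength filtering, proxy search, and harmonization.

The workflow implemented here mirrors standard two-sample MR practice on
summary statistics:

1. keep exposure SNPs below a p-value threshold (default 1e-5, the usual
   relaxed threshold for microbiome exposures with few genome-wide hits);
2. greedily clump them so retained instruments are approximately independent
   (r² < 0.01 within a 1,000 kb window);
3. substitute SNPs absent from the outcome study with LD proxies (r² > 0.8);
4. align outcome alleles to the exposure (swap / strand-complement), resolve
   palindromic SNPs by allele frequency or drop them;
5. attach per-SNP variance explained R² and the F statistic
   F = R²(N − 2)/(1 − R²), dropping weak instruments (F ≤ 10).

Retained instruments are re-signed so the exposure effect is non-negative;
all downstream estimators are invariant to this orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .gwas_io import GwasDataset, LDReference

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection and harmonization.

    Defaults follow common two-sample MR practice for microbiome exposures:
    a relaxed association threshold (1e-5), strict independence (r² < 0.01
    within 1,000 kb), proxies at r² > 0.8, and the conventional F > 10
    weak-instrument cutoff. ``palindrome_eaf_window`` is the "intermediate
    allele frequency" band inside which palindromic SNPs cannot be oriented
    and are removed.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.01
    clump_kb: float = 1000.0
    proxy_r2_min: float = 0.8
    f_min: float = 10.0
    palindrome_eaf_window: tuple[float, float] = (0.42, 0.58)

    def __post_init__(self):
        if not (0 < self.p_threshold <= 1):
            raise DomainError("p_threshold must be in (0, 1]")
        if not (0 <= self.clump_r2 <= 1) or not (0 <= self.proxy_r2_min <= 1):
            raise DomainError("r2 thresholds must be in [0, 1]")
        if self.clump_kb < 0 or self.f_min < 0:
            raise DomainError("clump_kb and f_min must be non-negative")
        lo, hi = self.palindrome_eaf_window
        if not (0 <= lo <= hi <= 1):
            raise DomainError("palindrome_eaf_window must be an interval within [0, 1]")


@dataclass
class HarmonizedInstrument:
    """An exposure/outcome-aligned SNP with instrument-strength metrics.

    After harmonization both studies' effects refer to the same
    ``effect_allele``; ``beta_exp`` is oriented non-negative. ``r2`` is the
    exposure variance explained by the SNP and ``f_stat`` the corresponding
    F statistic. ``is_proxy`` marks instruments where an LD proxy stood in
    for an exposure SNP missing from the outcome study (``proxy_r2`` gives
    the LD between them).
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    eaf_exp: float
    n_exp: int
    r2: float
    f_stat: float
    is_proxy: bool = False
    proxy_r2: float = float("nan")
    source_rsid: str | None = None  # original exposure SNP when proxied


@dataclass
class HarmonizationResult:
    """Harmonized instruments plus machine-readable drop reasons."""

    instruments: list[HarmonizedInstrument]
    dropped: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.instruments)

    def __len__(self):
        return len(self.instruments)

    def __getitem__(self, i):
        return self.instruments[i]


def compute_r2_f(beta: float, se: float, eaf: float, n: float) -> tuple[float, float]:
    """Per-SNP variance explained and instrument F statistic.

    R² = [2β²·EAF(1−EAF)] / [2β²·EAF(1−EAF) + 2·SE²·N·EAF(1−EAF)] and
    F = R²(N − 2)/(1 − R²). The 2·EAF(1−EAF) factor cancels algebraically,
    so R² = β²/(β² + N·SE²): the full form is evaluated and the cancellation
    asserted, making the result exactly EAF-invariant.
    """
    if n <= 2:
        raise DomainError(f"sample size must exceed 2, got {n}")
    if se <= 0:
        raise DomainError(f"se must be positive, got {se}")
    if not (0.0 < eaf < 1.0):
        raise DomainError(f"eaf must be in (0, 1), got {eaf}")
    var_term = 2.0 * beta * beta * eaf * (1.0 - eaf)
    noise_term = 2.0 * se * se * n * eaf * (1.0 - eaf)
    r2 = var_term / (var_term + noise_term)
    reduced = beta * beta / (beta * beta + n * se * se)
    if not math.isclose(r2, reduced, rel_tol=1e-12, abs_tol=1e-300):
        raise AssertionError("EAF cancellation violated — numeric inconsistency")
    f_stat = r2 * (n - 2.0) / (1.0 - r2)
    return r2, f_stat


def _chrom_key(chrom: str):
    return (0, int(chrom)) if str(chrom).isdigit() else (1, str(chrom))


def select_instruments(
    exposure: GwasDataset, ld: LDReference, cfg: SelectionConfig | None = None
) -> list[str]:
    """Greedy LD clumping of sub-threshold exposure SNPs.

    Candidates with p < ``p_threshold`` are sorted by ascending p (ties by
    chromosome, position, rsid); the best is kept and any remaining SNP on
    the same chromosome within ``clump_kb`` kilobases *and* with
    r² ≥ ``clump_r2`` to a kept SNP is discarded. The output order is the
    keep order, independent of input row order.
    """
    cfg = cfg or SelectionConfig()
    t = exposure.table
    cand = t.loc[t["pval"] < cfg.p_threshold]
    if len(cand) == 0:
        log.warning("select_instruments: no SNP passes p < %g for %s",
                    cfg.p_threshold, exposure.trait_name)
        return []
    rows = sorted(
        cand[["rsid", "chrom", "pos", "pval"]].itertuples(index=False),
        key=lambda r: (r.pval, _chrom_key(r.chrom), r.pos, r.rsid),
    )
    kept: list = []
    window = cfg.clump_kb * 1000.0
    for row in rows:
        clash = False
        for k in kept:
            if (
                row.chrom == k.chrom
                and abs(row.pos - k.pos) <= window
                and ld.r2(row.rsid, k.rsid) >= cfg.clump_r2
            ):
                clash = True
                break
        if not clash:
            kept.append(row)
    return [k.rsid for k in kept]


def find_proxy(
    rsid: str, outcome: GwasDataset, ld: LDReference, cfg: SelectionConfig | None = None
) -> str | None:
    """Best LD proxy present in the outcome study, or None.

    Among outcome SNPs with r² > ``proxy_r2_min`` to ``rsid``, returns the
    one with maximal r²; ties go to the nearest position, then the
    lexicographically smallest rsid. Absence of a proxy is a valid result.
    """
    cfg = cfg or SelectionConfig()
    here = ld.position(rsid)
    best = None
    for cand, r2 in ld.partners(rsid).items():
        if r2 <= cfg.proxy_r2_min or cand not in outcome:
            continue
        pos = ld.position(cand)
        dist = abs(pos[1] - here[1]) if (pos and here) else float("inf")
        key = (-r2, dist, cand)
        if best is None or key < best[0]:
            best = (key, cand)
    return None if best is None else best[1]


def is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT.get(a1) == a2


def align_alleles(
    ea_exp: str, oa_exp: str, ea_out: str, oa_out: str,
    eaf_exp: float, eaf_out: float,
    window: tuple[float, float] = (0.42, 0.58),
) -> str:
    """Classify the outcome orientation relative to the exposure alleles.

    Returns one of ``keep`` (alleles already aligned), ``flip`` (outcome
    effect/other swapped: negate beta_out), ``drop_palindromic`` (strand
    ambiguous and frequencies intermediate/missing), or
    ``drop_incompatible`` (allele sets irreconcilable).

    Non-palindromic SNPs are matched directly, after swapping, or after
    strand complementing (then swapping). Palindromic SNPs carry the same
    allele set on both strands, so orientation is inferred by comparing
    effect-allele frequencies — only when both lie outside ``window``.
    """
    exp_set = {ea_exp, oa_exp}
    out_set = {ea_out, oa_out}
    comp_out = {COMPLEMENT[a] for a in out_set if a in COMPLEMENT}
    if is_palindromic(ea_exp, oa_exp):
        if out_set != exp_set:
            return "drop_incompatible"
        if not (np.isfinite(eaf_exp) and np.isfinite(eaf_out)):
            return "drop_palindromic"
        lo, hi = window
        if lo <= eaf_exp <= hi or lo <= eaf_out <= hi:
            return "drop_palindromic"
        # tentative orientation from allele labels, then check frequency concordance
        tentative = "keep" if ea_out == ea_exp else "flip"
        eaf_out_aligned = eaf_out if tentative == "keep" else 1.0 - eaf_out
        if (eaf_exp < 0.5) == (eaf_out_aligned < 0.5):
            return tentative
        # frequencies disagree: the outcome is reported on the other strand,
        # which for a palindrome inverts the label-based orientation
        return "flip" if tentative == "keep" else "keep"
    if out_set == exp_set:
        return "keep" if ea_out == ea_exp else "flip"
    if comp_out == exp_set:
        return "keep" if COMPLEMENT[ea_out] == ea_exp else "flip"
    return "drop_incompatible"


def harmonize(
    exposure: GwasDataset,
    outcome: GwasDataset,
    snps: list[str],
    cfg: SelectionConfig | None = None,
    proxies: dict[str, str] | None = None,
    ld: LDReference | None = None,
) -> HarmonizationResult:
    """Align outcome effects to exposure alleles and attach strength metrics.

    ``proxies`` maps an exposure rsid absent from the outcome to the outcome
    rsid standing in for it (see :func:`find_proxy`); when the proxy is also
    present in the exposure study its own association is used throughout.
    SNPs are dropped (with a reason code) when palindromic at intermediate
    frequency, allele-incompatible, missing from the outcome, missing EAF
    (needed for orientation and R²), or weak (F ≤ ``f_min``).
    """
    cfg = cfg or SelectionConfig()
    proxies = proxies or {}
    out: list[HarmonizedInstrument] = []
    dropped: dict[str, str] = {}
    for rsid in snps:
        exp_rsid, out_rsid = rsid, rsid
        is_proxy, proxy_r2, source = False, float("nan"), None
        if rsid not in outcome:
            proxy = proxies.get(rsid)
            if proxy is None or proxy not in outcome:
                dropped[rsid] = "missing-outcome"
                continue
            out_rsid, is_proxy, source = proxy, True, rsid
            proxy_r2 = ld.r2(rsid, proxy) if ld is not None else float("nan")
            if proxy in exposure:
                exp_rsid = proxy
        e = exposure.record(exp_rsid)
        o = outcome.record(out_rsid)
        # for a proxy the exposure-side record is the proxy's own when it is
        # genotyped in the exposure study; alignment always uses the alleles
        # each record actually carries (no haplotype phasing)
        action = align_alleles(
            e.effect_allele, e.other_allele, o.effect_allele, o.other_allele,
            e.eaf, o.eaf, cfg.palindrome_eaf_window,
        )
        if action == "drop_palindromic":
            dropped[rsid] = "palindromic"
            continue
        if action == "drop_incompatible":
            dropped[rsid] = "incompatible"
            continue
        beta_out = o.beta if action == "keep" else -o.beta
        if not np.isfinite(e.eaf):
            dropped[rsid] = "missing-eaf"
            continue
        r2, f_stat = compute_r2_f(e.beta, e.se, e.eaf, e.n)
        if f_stat <= cfg.f_min:
            dropped[rsid] = "weak-F"
            continue
        ea, oa, beta_exp, eaf_exp = e.effect_allele, e.other_allele, e.beta, e.eaf
        if beta_exp < 0:  # exposure-increasing orientation
            ea, oa = oa, ea
            beta_exp, beta_out, eaf_exp = -beta_exp, -beta_out, 1.0 - eaf_exp
        out.append(HarmonizedInstrument(
            rsid=out_rsid if is_proxy else rsid,
            effect_allele=ea, other_allele=oa,
            beta_exp=beta_exp, se_exp=e.se, pval_exp=e.pval,
            beta_out=beta_out, se_out=o.se, pval_out=o.pval,
            eaf_exp=eaf_exp, n_exp=e.n, r2=r2, f_stat=f_stat,
            is_proxy=is_proxy, proxy_r2=proxy_r2, source_rsid=source,
        ))
    if dropped:
        log.info("harmonize: dropped %d SNPs (%s)", len(dropped),
                 ", ".join(f"{k}:{v}" for k, v in list(dropped.items())[:8]))
    return HarmonizationResult(instruments=out, dropped=dropped)


def instruments_frame(instrs) -> "pd.DataFrame":
    """Tabular export of harmonized instruments (one row per SNP)."""
    import pandas as pd

    rows = [vars(i).copy() for i in instrs]
    return pd.DataFrame(rows)
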