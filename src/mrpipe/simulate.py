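"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works directly on the summary-statistic scale (no
individual-level genotypes): for SNP j with minor-allele frequency p_j,

* exposure: true effect γ_j ~ N(0, gamma_sd²) for causal SNPs (else 0),
  sampling SE  SE_Xj = 1/√(2·N_exp·p_j(1−p_j)),  β̂_Xj ~ N(γ_j, SE_Xj²);
* outcome (binary, log-odds approximation with case fraction K):
  SE_Yj = 1/√(2·N_out·K(1−K)·p_j(1−p_j)),  β̂_Yj ~ N(θ·γ_j + α_j, SE_Yj²),

where θ is the causal effect and α_j a direct (pleiotropic) effect drawn
per regime: none (0), balanced (mean-zero), directional (nonzero mean,
independent of γ — InSIDE holds), or correlated (corr(α, γ) = 0.5,
violating InSIDE). Wald p-values, block-exchangeable LD, and realistic
allele coding (random effect/other order, strand flips, a tunable fraction
of palindromic SNPs) complete the two datasets, so every pipeline stage —
clumping, proxy search, harmonization, estimation, diagnostics — can be
exercised against the stored truth record.

Default cohort sizes mirror the study setting this emulates: a microbiome
exposure GWAS of 18,340 individuals and a disease outcome GWAS of 598
cases / 218,194 controls (case fraction ≈ 0.00273).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .gwas_io import GwasDataset, LDReference
from .instruments import SelectionConfig, harmonize

#: outcome-study shape used throughout: 598 cases / 218,194 controls
DEFAULT_N_OUT = 598 + 218_194
DEFAULT_CASE_FRACTION = 598 / DEFAULT_N_OUT

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for one simulated exposure/outcome pair.

    ``theta`` is the true causal effect on the log-odds scale;
    ``gamma_sd`` sets instrument strength (at the default exposure N,
    gamma_sd = 0.05 yields the sparse 3–22 instruments-per-trait regime of
    microbiome GWAS, gamma_sd = 0.1 gives uniformly strong instruments,
    mean F ≈ 70). ``ld_block_size`` > 1 groups SNPs into blocks sharing
    exchangeable within-block r² = ``ld_block_r2``; blocks are placed 2 Mb
    apart so clumping should retain one SNP per block.
    """

    m_snps: int = 200
    m_causal: int = 30
    theta: float = 0.0
    gamma_sd: float = 0.05
    pleiotropy_mode: str = "none"  # none | balanced | directional | correlated
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    n_exp: int = 18_340
    n_out: int = DEFAULT_N_OUT
    case_fraction: float = DEFAULT_CASE_FRACTION
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_block_r2: float = 0.0
    palindrome_fraction: float = 0.15
    trait_name: str = "synthetic_exposure"
    outcome_name: str = "synthetic_outcome"
    rsid_prefix: str = "rs"
    seed: int = 0

    def validate(self) -> None:
        if self.m_causal > self.m_snps or self.m_snps < 1:
            raise DomainError("need 0 <= m_causal <= m_snps and m_snps >= 1")
        if self.gamma_sd < 0 or self.alpha_sd < 0:
            raise DomainError("standard deviations must be non-negative")
        if not (0.0 < self.case_fraction < 1.0):
            raise DomainError("case_fraction must be in (0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise DomainError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "correlated"):
            raise DomainError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.ld_block_size < 1 or not (0.0 <= self.ld_block_r2 <= 1.0):
            raise DomainError("bad LD block specification")
        if not (0.0 <= self.palindrome_fraction <= 1.0):
            raise DomainError("palindrome_fraction must be in [0, 1]")
        if self.n_exp <= 2 or self.n_out <= 2:
            raise DomainError("cohort sizes must exceed 2")


@dataclass
class SimulatedPair:
    """A simulated exposure/outcome dataset pair plus its ground truth.

    ``truth`` has one row per SNP (rsid, maf, gamma, alpha, causal,
    planted_outlier) and carries the scenario in ``truth.attrs``.
    """

    exposure: GwasDataset
    outcome: GwasDataset
    ld: LDReference
    truth: pd.DataFrame


def _draw_pleiotropy(rng, sc: SyntheticScenario, gamma: np.ndarray) -> np.ndarray:
    """Direct (pleiotropic) outcome effects per regime.

    Directional pleiotropy is defined relative to the exposure-increasing
    allele — the orientation every estimator works in after harmonization —
    so the nonzero mean is applied along sign(γ) (treating γ = 0 as +).
    A fixed mean in the arbitrary generator coding would be scrambled into
    balanced pleiotropy by the re-orientation and would be undetectable by
    construction.
    """
    m = gamma.size
    if sc.pleiotropy_mode == "none":
        return np.zeros(m)
    if sc.pleiotropy_mode == "balanced":
        return rng.normal(0.0, sc.alpha_sd, m)
    sgn = np.where(gamma < 0, -1.0, 1.0)
    if sc.pleiotropy_mode == "directional":
        return sgn * rng.normal(sc.alpha_mean, sc.alpha_sd, m)
    # correlated: corr(alpha, gamma) = 0.5, violating InSIDE
    z = rng.normal(0.0, 1.0, m)
    g_std = gamma / sc.gamma_sd if sc.gamma_sd > 0 else np.zeros(m)
    return sgn * sc.alpha_mean + sc.alpha_sd * (0.5 * g_std + np.sqrt(0.75) * z)


def simulate_pair(sc: SyntheticScenario) -> SimulatedPair:
    """Generate one exposure/outcome pair with LD reference and truth record."""
    sc.validate()
    rng = np.random.default_rng(sc.seed)
    m = sc.m_snps
    rsids = np.array([f"{sc.rsid_prefix}{i + 1}" for i in range(m)])
    maf = rng.uniform(*sc.maf_range, m)

    block = np.arange(m) // sc.ld_block_size
    chrom = (block % 22 + 1).astype(int)
    block_on_chrom = block // 22
    within = np.arange(m) % sc.ld_block_size
    pos = 1_000_000 + block_on_chrom * 2_000_000 + within * 5_000

    gamma = np.zeros(m)
    causal = np.zeros(m, dtype=bool)
    causal[: sc.m_causal] = True
    gamma[causal] = rng.normal(0.0, sc.gamma_sd, sc.m_causal)
    alpha = _draw_pleiotropy(rng, sc, gamma)

    se_exp = 1.0 / np.sqrt(2.0 * sc.n_exp * maf * (1.0 - maf))
    beta_exp = rng.normal(gamma, se_exp)
    kk = sc.case_fraction * (1.0 - sc.case_fraction)
    se_out = 1.0 / np.sqrt(2.0 * sc.n_out * kk * maf * (1.0 - maf))
    beta_out = rng.normal(sc.theta * gamma + alpha, se_out)

    from scipy import stats

    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out / se_out))

    pal = rng.random(m) < sc.palindrome_fraction
    pair_idx = rng.integers(0, len(_NONPALINDROMIC), m)
    pal_idx = rng.integers(0, len(_PALINDROMIC), m)
    ea = np.where(pal, np.array([_PALINDROMIC[i][0] for i in pal_idx]),
                  np.array([_NONPALINDROMIC[i][0] for i in pair_idx]))
    oa = np.where(pal, np.array([_PALINDROMIC[i][1] for i in pal_idx]),
                  np.array([_NONPALINDROMIC[i][1] for i in pair_idx]))

    def frame(beta, se, pval, eaf, n):
        return pd.DataFrame({
            "rsid": rsids, "chrom": chrom.astype(str), "pos": pos,
            "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se, "pval": np.clip(pval, np.finfo(float).tiny, 1.0),
            "eaf": eaf, "n": n,
        })

    exp_df = frame(beta_exp, se_exp, p_exp, maf, sc.n_exp)

    # outcome allele coding: random effect/other swaps and, for
    # non-palindromic SNPs, random strand flips — harmonization must undo both
    swap = rng.random(m) < 0.5
    strand = (rng.random(m) < 0.5) & ~pal
    ea_o, oa_o = ea.copy(), oa.copy()
    flip_to = np.vectorize(_COMP.get)
    ea_o = np.where(strand, flip_to(ea_o), ea_o)
    oa_o = np.where(strand, flip_to(oa_o), oa_o)
    ea_o, oa_o = np.where(swap, oa_o, ea_o), np.where(swap, ea_o, oa_o)
    beta_out_coded = np.where(swap, -beta_out, beta_out)
    eaf_out = np.where(swap, 1.0 - maf, maf)

    out_df = frame(beta_out_coded, se_out, p_out, eaf_out, sc.n_out)
    out_df["effect_allele"], out_df["other_allele"] = ea_o, oa_o

    exposure = GwasDataset(trait_name=sc.trait_name, table=exp_df,
                           trait_type="quantitative", provenance="synthetic")
    outcome = GwasDataset(trait_name=sc.outcome_name, table=out_df, trait_type="binary",
                          case_fraction=sc.case_fraction, provenance="synthetic")

    panel = pd.DataFrame({"rsid": rsids, "chrom": chrom.astype(str), "pos": pos})
    ld = LDReference(panel=panel)
    if sc.ld_block_size > 1 and sc.ld_block_r2 > 0:
        for b in np.unique(block):
            members = rsids[block == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld.add_pair(members[i], members[j], sc.ld_block_r2)

    truth = pd.DataFrame({
        "rsid": rsids, "maf": maf, "gamma": gamma, "alpha": alpha,
        "causal": causal, "planted_outlier": np.zeros(m, dtype=bool),
    })
    truth.attrs["theta"] = sc.theta
    truth.attrs["scenario"] = sc
    return SimulatedPair(exposure=exposure, outcome=outcome, ld=ld, truth=truth)


def plant_outlier(pair: SimulatedPair, rsid: str, offset_in_se: float) -> SimulatedPair:
    """Shift one SNP's outcome effect by ``offset_in_se`` outcome SEs.

    Returns a new pair (the input is not modified) with the truth record
    marking the planted outlier.
    """
    if rsid not in pair.outcome:
        raise DomainError(f"unknown rsid {rsid!r}")
    out_table = pair.outcome.table.copy()
    se = float(out_table.loc[rsid, "se"])
    out_table.loc[rsid, "beta"] = float(out_table.loc[rsid, "beta"]) + offset_in_se * se
    outcome = GwasDataset(
        trait_name=pair.outcome.trait_name, table=out_table.reset_index(drop=True),
        trait_type=pair.outcome.trait_type, case_fraction=pair.outcome.case_fraction,
        provenance=pair.outcome.provenance,
    )
    truth = pair.truth.copy()
    if offset_in_se != 0:
        truth.loc[truth["rsid"] == rsid, "planted_outlier"] = True
    truth.attrs.update(pair.truth.attrs)
    return SimulatedPair(exposure=pair.exposure, outcome=outcome, ld=pair.ld, truth=truth)


@dataclass
class SimulatedBatch:
    """Many exposures sharing one outcome study, emulating a taxa panel."""

    exposures: list[GwasDataset]
    outcome: GwasDataset
    ld: LDReference
    manifest: pd.DataFrame  # taxon, theta, m_causal
    truths: dict[str, pd.DataFrame] = field(default_factory=dict)


def simulate_batch(
    base: SyntheticScenario,
    n_taxa: int,
    causal_taxa: Mapping[str, float] | None = None,
    taxon_names: Sequence[str] | None = None,
) -> SimulatedBatch:
    """Simulate ``n_taxa`` exposures against one shared outcome study.

    Each taxon gets its own SNP panel (disjoint rsid ranges) and its own
    draw of exposure effects; ``causal_taxa`` maps taxon name -> true θ
    (taxa not listed are null). The outcome study is the union of the
    per-taxon outcome records, so all taxa are tested against the same
    outcome cohort, as when a single disease GWAS serves every exposure.
    """
    if taxon_names is None:
        taxon_names = [f"taxon_{i + 1:03d}" for i in range(n_taxa)]
    if len(taxon_names) != n_taxa:
        raise DomainError("taxon_names length must equal n_taxa")
    causal_taxa = dict(causal_taxa or {})
    unknown = set(causal_taxa) - set(taxon_names)
    if unknown:
        raise DomainError(f"causal_taxa keys not in taxa: {sorted(unknown)}")
    ss = np.random.SeedSequence(base.seed)
    child_seeds = ss.generate_state(n_taxa) % (2**31)
    exposures, out_tables, panels, truths, rows = [], [], [], {}, []
    ld_pairs = []
    for i, name in enumerate(taxon_names):
        sc = replace(
            base,
            theta=float(causal_taxa.get(name, 0.0)),
            trait_name=name,
            rsid_prefix=f"rs{i + 1}_",
            seed=int(child_seeds[i]),
        )
        pair = simulate_pair(sc)
        exposures.append(pair.exposure)
        out_tables.append(pair.outcome.table.reset_index(drop=True))
        panels.append(pair.ld.panel)
        for a, nbrs in pair.ld._adj.items():
            for b, r2 in nbrs.items():
                if a < b:
                    ld_pairs.append((a, b, r2))
        truths[name] = pair.truth
        rows.append({"taxon": name, "theta": sc.theta, "m_causal": sc.m_causal})
    outcome_table = pd.concat(out_tables, ignore_index=True)
    outcome = GwasDataset(
        trait_name=base.outcome_name, table=outcome_table, trait_type="binary",
        case_fraction=base.case_fraction, provenance="synthetic",
    )
    ld = LDReference.from_pairs(pd.concat(panels, ignore_index=True), ld_pairs)
    manifest = pd.DataFrame(rows)
    return SimulatedBatch(exposures=exposures, outcome=outcome, ld=ld,
                          manifest=manifest, truths=truths)


def as_instruments(
    pair: SimulatedPair,
    snps: Sequence[str] | None = None,
    f_min: float = 0.0,
    p_threshold: float = 1.0,
):
    """Harmonized instruments straight from a simulated pair.

    Convenience for estimator studies that want a fixed instrument set
    without the selection step: harmonizes the requested SNPs (default:
    the causal ones) with no strength filter unless ``f_min`` is raised.
    """
    if snps is None:
        snps = pair.truth.loc[pair.truth["causal"], "rsid"].tolist()
    cfg = SelectionConfig(p_threshold=p_threshold, f_min=f_min)
    return harmonize(pair.exposure, pair.outcome, list(snps), cfg).instruments
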