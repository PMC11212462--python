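"""End-to-end orchestration: estimation across many exposures, FDR control,
significance classification, power, and confounder exclusion.

For each exposure (e.g. each bacterial taxon) against one outcome study the
pipeline selects instruments, substitutes proxies, harmonizes, applies an
optional confounder blocklist, runs every estimator the instrument count
permits, and computes the sensitivity diagnostics. Across exposures the IVW
p-values are converted to Benjamini–Hochberg q-values, and each trait is
classified:

* ``significant`` — p < α and q < q-threshold (default 0.05 / 0.1);
* ``nominal`` — p < α but q ≥ q-threshold (an "indicative" association);
* ``null`` — otherwise;
* ``not_evaluable`` — no valid instruments survived.

Post-hoc power for a binary outcome uses the non-centrality approximation
power = Φ(−z_{1−α/2} + |log OR|·√(N·R²·K(1−K))) + Φ(−z_{1−α/2} − ...),
with N the outcome sample size, K the case fraction, and R² the summed
variance explained by the instruments.

Reverse-direction analyses reuse the same machinery with exposure and
outcome roles swapped and a relaxed instrument threshold (default 1e-4).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import estimators as est_mod
from .errors import DomainError, MrpipeError
from .estimators import MREstimate, ivw, wald_ratio
from .gwas_io import GwasDataset, LDReference
from .instruments import (
    HarmonizedInstrument, SelectionConfig, find_proxy, harmonize,
    instruments_frame, select_instruments,
)
from .sensitivity import SensitivityReport, sensitivity_report

log = logging.getLogger(__name__)

ALL_METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable the pipeline exposes, with field-standard defaults."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    methods: tuple[str, ...] = ALL_METHODS
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    run_presso: bool = True
    fdr_q_threshold: float = 0.1
    alpha: float = 0.05
    power_threshold: float = 0.8
    blocklist: frozenset[str] = frozenset()
    reverse_p_threshold: float = 1e-4
    rerun_on_sign_conflict: bool = False
    strict_p_threshold: float = 5e-8
    seed: int = 0

    def __post_init__(self):
        for name in ("fdr_q_threshold", "alpha", "power_threshold",
                     "reverse_p_threshold", "strict_p_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise DomainError(f"{name} must be in (0, 1), got {v}")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise DomainError(f"unknown methods: {sorted(unknown)}")


@dataclass
class TaxonResult:
    """One exposure's full result: estimates, diagnostics, classification."""

    exposure: str
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    instruments: list[HarmonizedInstrument] = field(default_factory=list)
    nsnp: int = 0
    pvalue: float | None = None  # primary (IVW) p
    q_value: float | None = None
    classification: str = "not_evaluable"
    power: float | None = None
    reason: str = ""
    drop_log: dict[str, str] = field(default_factory=dict)

    @property
    def primary(self) -> MREstimate | None:
        return self.estimates.get("ivw") or self.estimates.get("wald")


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j ≥ i} (m · p_(j) / j) over the ascending order, mapped
    back to input order; monotone non-decreasing in p and invariant to the
    input ordering.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise DomainError("bh_qvalues needs a non-empty 1-d collection")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify(pvalue: float, q_value: float, cfg: PipelineConfig) -> str:
    """Apply the p/q decision rule (pure function of its arguments)."""
    if pvalue is None or q_value is None:
        return "not_evaluable"
    if pvalue < cfg.alpha and q_value < cfg.fdr_q_threshold:
        return "significant"
    if pvalue < cfg.alpha and q_value >= cfg.fdr_q_threshold:
        return "nominal"
    return "null"


def mr_power(
    n_outcome: float,
    case_fraction: float,
    r2_sum: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Approximate power of the Wald test for a binary-outcome MR estimate.

    Non-centrality b·√v with b = |log OR| and v = N·R²·K(1−K); power =
    1 − Φ(z_{1−α/2} − b√v) + Φ(−z_{1−α/2} − b√v). At OR = 1 this equals α.
    """
    if r2_sum <= 0:
        raise DomainError("r2_sum must be positive")
    if not (0 < case_fraction < 1) or n_outcome <= 0 or or_alt <= 0:
        raise DomainError("inputs outside natural ranges")
    if not (0 < alpha < 1):
        raise DomainError("alpha must be in (0, 1)")
    b = abs(np.log(or_alt))
    ncp = b * np.sqrt(n_outcome * r2_sum * case_fraction * (1.0 - case_fraction))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.sf(z - ncp) + stats.norm.cdf(-z - ncp))


def apply_blocklist(
    instrs: Sequence[HarmonizedInstrument], blocklist: Iterable[str]
) -> list[HarmonizedInstrument]:
    """Remove instruments whose rsid (or source rsid) is blocklisted.

    The blocklist stands in for an external confounder screen: SNPs known
    to act on the outcome through other risk factors are excluded and the
    causal effects re-estimated downstream.
    """
    block = set(blocklist)
    if not block:
        return list(instrs)
    kept = [i for i in instrs
            if i.rsid not in block and (i.source_rsid or i.rsid) not in block]
    removed = len(instrs) - len(kept)
    if removed:
        log.info("apply_blocklist: removed %d blocklisted instruments", removed)
    return kept


def _estimate_all(
    instrs: list[HarmonizedInstrument], cfg: PipelineConfig, seed: int
) -> dict[str, MREstimate]:
    k = len(instrs)
    out: dict[str, MREstimate] = {}
    if k == 1:
        out["wald"] = wald_ratio(instrs[0])
        return out
    if "ivw" in cfg.methods:
        out["ivw"] = ivw(instrs)
    if k >= 3:
        if "egger" in cfg.methods:
            try:
                out["egger"] = est_mod.egger(instrs)
            except MrpipeError as exc:
                log.warning("egger failed: %s", exc)
        if "weighted_median" in cfg.methods:
            out["weighted_median"] = est_mod.weighted_median(
                instrs, n_boot=cfg.n_boot, seed=seed)
        if "simple_mode" in cfg.methods:
            out["simple_mode"] = est_mod.mode_estimate(
                instrs, weighted=False, n_boot=cfg.n_boot, seed=seed + 1)
        if "weighted_mode" in cfg.methods:
            out["weighted_mode"] = est_mod.mode_estimate(
                instrs, weighted=True, n_boot=cfg.n_boot, seed=seed + 2)
    return out


def analyze_pair(
    exposure: GwasDataset,
    outcome: GwasDataset,
    ld: LDReference,
    cfg: PipelineConfig | None = None,
    seed: int | None = None,
    p_threshold: float | None = None,
) -> TaxonResult:
    """Full single-pair analysis (no cross-exposure FDR).

    Selection → proxy substitution → harmonization → blocklist → all
    applicable estimators → sensitivity diagnostics → power. Failures
    yield a ``not_evaluable`` result with a reason, never an exception.
    """
    cfg = cfg or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    sel = cfg.selection if p_threshold is None else replace(cfg.selection, p_threshold=p_threshold)
    res = TaxonResult(exposure=exposure.trait_name)
    try:
        snps = select_instruments(exposure, ld, sel)
        if not snps:
            res.reason = "below-threshold"
            return res
        proxies = {s: find_proxy(s, outcome, ld, sel) for s in snps if s not in outcome}
        proxies = {s: p for s, p in proxies.items() if p is not None}
        harm = harmonize(exposure, outcome, snps, sel, proxies=proxies, ld=ld)
        res.drop_log = dict(harm.dropped)
        instrs = apply_blocklist(harm.instruments, cfg.blocklist)
        n_blocked = len(harm.instruments) - len(instrs)
        if n_blocked:
            res.drop_log.update({i.rsid: "blocklisted" for i in harm.instruments
                                 if i not in instrs})
        if not instrs:
            res.reason = "no-valid-instruments"
            return res
        ests = _estimate_all(instrs, cfg, seed)
        if cfg.rerun_on_sign_conflict and "ivw" in ests and "weighted_median" in ests:
            if np.sign(ests["ivw"].beta) != np.sign(ests["weighted_median"].beta):
                log.info("%s: IVW / weighted-median sign conflict, re-selecting at p < %g",
                         exposure.trait_name, cfg.strict_p_threshold)
                return analyze_pair(exposure, outcome, ld, cfg, seed,
                                    p_threshold=cfg.strict_p_threshold)
        res.instruments = instrs
        res.nsnp = len(instrs)
        res.estimates = ests
        primary = res.primary
        res.pvalue = primary.pvalue if primary is not None else None
        if len(instrs) >= 2:
            res.sensitivity = sensitivity_report(
                instrs, n_sim=cfg.presso_n_sim, seed=seed, alpha=cfg.alpha,
                outlier_alpha=cfg.presso_outlier_alpha, run_presso=cfg.run_presso)
        else:
            res.reason = "insufficient for sensitivity analyses"
        if outcome.trait_type == "binary" and primary is not None:
            r2_sum = float(sum(i.r2 for i in instrs))
            res.power = mr_power(
                n_outcome=float(outcome.table["n"].max()),
                case_fraction=outcome.case_fraction,
                r2_sum=r2_sum, or_alt=float(np.exp(primary.beta)), alpha=cfg.alpha)
    except MrpipeError as exc:
        res.reason = f"error: {exc}"
        res.classification = "not_evaluable"
    return res


def _finalize(results: list[TaxonResult], cfg: PipelineConfig) -> list[TaxonResult]:
    """Attach BH q-values and classifications across one batch."""
    idx = [i for i, r in enumerate(results) if r.pvalue is not None]
    if idx:
        q = bh_qvalues([results[i].pvalue for i in idx])
        for j, i in enumerate(idx):
            results[i].q_value = float(q[j])
            results[i].classification = classify(results[i].pvalue, results[i].q_value, cfg)
    return results


def run_forward(
    exposures: Sequence[GwasDataset],
    outcome: GwasDataset,
    ld: LDReference,
    cfg: PipelineConfig | None = None,
) -> list[TaxonResult]:
    """Analyze every exposure against one outcome, with FDR across exposures.

    Per-taxon seeds are spawned deterministically from ``cfg.seed``, so a
    re-run with the same configuration is byte-identical. Per-taxon errors
    are recorded, never aborting the batch.
    """
    cfg = cfg or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed).generate_state(max(len(exposures), 1)) % (2**31)
    results = [
        analyze_pair(exp, outcome, ld, cfg, seed=int(seeds[i]))
        for i, exp in enumerate(exposures)
    ]
    return _finalize(results, cfg)


def run_reverse(
    outcome_as_exposure: GwasDataset,
    exposures_as_outcomes: Sequence[GwasDataset],
    ld: LDReference,
    cfg: PipelineConfig | None = None,
) -> list[TaxonResult]:
    """Reverse-direction MR: the disease as exposure, each taxon as outcome.

    Instruments are selected at ``cfg.reverse_p_threshold`` (default 1e-4).
    Results are labelled ``<exposure> -> <outcome>``; use
    :func:`no_reverse_signal` for the batch-level summary flag.
    """
    cfg = cfg or PipelineConfig()
    seeds = np.random.SeedSequence(cfg.seed + 1).generate_state(
        max(len(exposures_as_outcomes), 1)) % (2**31)
    results = []
    for i, out in enumerate(exposures_as_outcomes):
        r = analyze_pair(outcome_as_exposure, out, ld, cfg, seed=int(seeds[i]),
                         p_threshold=cfg.reverse_p_threshold)
        r.exposure = f"{outcome_as_exposure.trait_name} -> {out.trait_name}"
        results.append(r)
    return _finalize(results, cfg)


def no_reverse_signal(results: Sequence[TaxonResult]) -> bool:
    """True when no reverse-direction result reaches significance."""
    return not any(r.classification == "significant" for r in results)


def results_table(results: Sequence[TaxonResult]) -> pd.DataFrame:
    """Long-format estimates table (one row per exposure × method)."""
    rows = []
    for r in results:
        if not r.estimates:
            rows.append({"exposure": r.exposure, "method": None, "nsnp": 0,
                         "beta": np.nan, "se": np.nan, "or": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "pvalue": np.nan,
                         "q_value": np.nan, "classification": r.classification,
                         "power": np.nan, "reason": r.reason})
            continue
        for method, e in r.estimates.items():
            rows.append({
                "exposure": r.exposure, "method": method, "nsnp": e.nsnp,
                "beta": e.beta, "se": e.se, "or": e.or_,
                "ci_low": e.or_low, "ci_high": e.or_high, "pvalue": e.pvalue,
                "q_value": r.q_value if method in ("ivw", "wald") else np.nan,
                "classification": r.classification if method in ("ivw", "wald") else "",
                "power": r.power if method in ("ivw", "wald") else np.nan,
                "reason": r.reason,
            })
    return pd.DataFrame(rows)


def sensitivity_table(results: Sequence[TaxonResult]) -> pd.DataFrame:
    """Per-exposure diagnostics: Egger intercept/p, Q/p, PRESSO global p."""
    rows = []
    for r in results:
        s = r.sensitivity
        rows.append({
            "exposure": r.exposure,
            "egger_intercept": None if s is None else s.egger_intercept,
            "egger_intercept_p": None if s is None else s.egger_intercept_p,
            "q_stat": None if s is None else s.q_stat,
            "q_pvalue": None if s is None else s.q_pvalue,
            "presso_global_p": None if s is None else s.presso_global_p,
            "presso_outliers": "" if s is None else ";".join(s.presso_outliers),
        })
    return pd.DataFrame(rows)


def volcano_table(results: Sequence[TaxonResult]) -> pd.DataFrame:
    """(beta, −log10 p) per exposure — the volcano-plot-ready export."""
    rows = []
    for r in results:
        if r.primary is None:
            continue
        rows.append({"exposure": r.exposure, "beta": r.primary.beta,
                     "neg_log10_p": -np.log10(r.primary.pvalue),
                     "classification": r.classification})
    return pd.DataFrame(rows)


def run_manifest(results: Sequence[TaxonResult], cfg: PipelineConfig) -> dict:
    """JSON-serializable record of a run: config, seeds, and counts."""
    counts: dict[str, int] = {}
    for r in results:
        counts[r.classification] = counts.get(r.classification, 0) + 1
    return {
        "n_exposures": len(results),
        "classification_counts": counts,
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "fdr_q_threshold": cfg.fdr_q_threshold,
        "selection": {
            "p_threshold": cfg.selection.p_threshold,
            "clump_r2": cfg.selection.clump_r2,
            "clump_kb": cfg.selection.clump_kb,
            "proxy_r2_min": cfg.selection.proxy_r2_min,
            "f_min": cfg.selection.f_min,
        },
        "methods": list(cfg.methods),
    }


def load_config(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file mirroring its fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sel = SelectionConfig(**{
        k: (tuple(v) if k == "palindrome_eaf_window" else v)
        for k, v in (raw.pop("selection", {}) or {}).items()
    })
    if "blocklist" in raw and raw["blocklist"] is not None:
        raw["blocklist"] = frozenset(raw["blocklist"])
    if "methods" in raw and raw["methods"] is not None:
        raw["methods"] = tuple(raw["methods"])
    return PipelineConfig(selection=sel, **raw)


def save_outputs(results: Sequence[TaxonResult], cfg: PipelineConfig, out_dir) -> None:
    """Write estimates/sensitivity/instrument TSVs and the run manifest."""
    from pathlib import Path

    from .gwas_io import write_results_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_results_table(results_table(results), out / "estimates.tsv")
    write_results_table(sensitivity_table(results), out / "sensitivity.tsv")
    vt = volcano_table(results)
    if len(vt):
        write_results_table(vt, out / "volcano.tsv")
    inst_dir = out / "instruments"
    inst_dir.mkdir(exist_ok=True)
    for r in results:
        if r.instruments:
            safe = r.exposure.replace("/", "_").replace(" ", "_").replace(":", "")
            instruments_frame(r.instruments).to_csv(
                inst_dir / f"{safe}.tsv", sep="\t", index=False, float_format="%.12g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(run_manifest(results, cfg), fh, indent=2)
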