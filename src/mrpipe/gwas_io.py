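"""Read, validate, and write GWAS summary statistics and LD references.

The shared in-memory containers for the whole package live here:

* :class:`GwasDataset` — one study's per-SNP association estimates, held as a
  :class:`pandas.DataFrame` with canonical column names, keyed by rsID.
* :class:`LDReference` — a sparse pairwise r² lookup over a SNP panel with
  chromosome/position metadata, used for clumping and proxy search.

Summary statistics travel as delimited text (tab or comma, auto-detected);
output is always tab-delimited. Foreign headers (consortium exports) are
adapted through an explicit column map rather than guessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

log = logging.getLogger(__name__)

#: canonical internal column order for summary statistics
CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval", "eaf", "n",
]

#: canonical on-disk header (short names used by the TSV interchange format)
TSV_COLUMNS = {
    "rsid": "rsid", "chrom": "chr", "pos": "pos",
    "effect_allele": "ea", "other_allele": "oa",
    "beta": "beta", "se": "se", "pval": "pval", "eaf": "eaf", "n": "n",
}

VALID_ALLELES = frozenset("ACGT")


class SummaryStatRecord(NamedTuple):
    """One SNP's association estimate in one GWAS.

    ``beta`` is the additive effect per copy of ``effect_allele`` (log-odds
    for binary traits); ``eaf`` is the effect-allele frequency and may be
    missing (NaN).
    """

    rsid: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float
    n: int


@dataclass
class GwasDataset:
    """One study's summary statistics with trait metadata.

    ``table`` holds one row per SNP with the canonical columns; rsIDs are
    unique and mirrored in the index. ``case_fraction`` is required for
    binary traits (cases / total) and used by the power calculation.
    """

    trait_name: str
    table: pd.DataFrame
    trait_type: str = "quantitative"
    case_fraction: float | None = None
    n_dropped: int = 0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ConfigError(f"trait_type must be quantitative|binary, got {self.trait_type!r}")
        if self.trait_type == "binary":
            if self.case_fraction is None or not (0.0 < self.case_fraction < 1.0):
                raise ConfigError("binary traits need case_fraction in (0, 1)")
        t = self.table
        missing = [c for c in CANONICAL_COLUMNS if c not in t.columns]
        if missing:
            raise ConfigError(f"summary table missing columns: {missing}")
        if t["rsid"].duplicated().any():
            dups = t.loc[t["rsid"].duplicated(), "rsid"].tolist()[:5]
            raise InputError(f"duplicate rsids in {self.trait_name!r}: {dups}")
        self.table = t.set_index(t["rsid"].rename(None), drop=False)

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.table.index

    def record(self, rsid: str) -> SummaryStatRecord:
        row = self.table.loc[rsid]
        return SummaryStatRecord(
            rsid=row["rsid"], chrom=row["chrom"], pos=int(row["pos"]),
            effect_allele=row["effect_allele"], other_allele=row["other_allele"],
            beta=float(row["beta"]), se=float(row["se"]), pval=float(row["pval"]),
            eaf=float(row["eaf"]), n=int(row["n"]),
        )


def validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Enforce per-record invariants, dropping (and counting) bad rows.

    Validation is total: every input row either yields a record satisfying
    all invariants or is counted as dropped. Alleles are upper-cased before
    checking. Missing EAF is tolerated (stored as NaN); everything else must
    be present and in range.
    """
    df = df.copy()
    n_in = len(df)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(str)
    num = {}
    for col in ("pos", "beta", "se", "pval", "eaf", "n"):
        num[col] = pd.to_numeric(df[col], errors="coerce")
        df[col] = num[col]
    eaf = num["eaf"]
    ok = (
        df["effect_allele"].isin(VALID_ALLELES)
        & df["other_allele"].isin(VALID_ALLELES)
        & (df["effect_allele"] != df["other_allele"])
        & (num["pos"] > 0)
        & np.isfinite(num["beta"])
        & (num["se"] > 0)
        & (num["pval"] > 0) & (num["pval"] <= 1)
        & (eaf.isna() | ((eaf > 0) & (eaf < 1)))
        & (num["n"] > 0)
    )
    ok = ok.fillna(False)
    clean = df.loc[ok].copy()
    clean["pos"] = clean["pos"].astype(np.int64)
    clean["n"] = clean["n"].astype(np.int64)
    n_dropped = n_in - len(clean)
    if n_dropped:
        log.info("validate_table: dropped %d of %d rows failing record invariants", n_dropped, n_in)
    return clean[CANONICAL_COLUMNS], n_dropped


def read_summary_stats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str = "",
    trait_type: str = "quantitative",
    case_fraction: float | None = None,
    provenance: str = "",
) -> GwasDataset:
    """Read a delimited summary-statistics file into a validated dataset.

    Parameters
    ----------
    path
        Tab- or comma-delimited text with a header row.
    column_map
        Mapping from canonical names (``rsid``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pval``,
        ``eaf``, ``n``) to the file's column names. Defaults to the package
        TSV header (rsid, chr, pos, ea, oa, beta, se, pval, eaf, n).
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    cmap = dict(TSV_COLUMNS if column_map is None else column_map)
    missing = [src for src in cmap.values() if src not in raw.columns]
    if missing:
        raise ConfigError(f"mapped columns absent from {path}: {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    if "eaf" not in df.columns:
        df["eaf"] = np.nan
    clean, n_dropped = validate_table(df)
    if len(clean) == 0:
        raise InputError(f"no valid summary-statistic rows in {path}")
    return GwasDataset(
        trait_name=trait_name or str(path), table=clean, trait_type=trait_type,
        case_fraction=case_fraction, n_dropped=n_dropped, provenance=provenance,
    )


def write_summary_stats(dataset: GwasDataset, path) -> None:
    """Write a dataset in the canonical tab-delimited interchange format."""
    out = dataset.table[CANONICAL_COLUMNS].rename(columns=TSV_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_results_table(results: pd.DataFrame, path) -> None:
    """Write a results table (estimates or sensitivity) as TSV.

    Column order is preserved deterministically; numeric values are printed
    with 12 significant digits so a round-trip read recovers them.
    """
    if results is None or len(results) == 0:
        raise InputError("refusing to write an empty results table")
    results.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


@dataclass
class LDReference:
    """Pairwise LD (r²) lookup over a SNP panel.

    Absent pairs default to r² = 0; the diagonal is 1. Storage is a sparse
    per-SNP adjacency map, symmetric by construction.
    """

    panel: pd.DataFrame  # columns: rsid, chrom, pos
    _adj: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"rsid", "chrom", "pos"}
        if not need.issubset(self.panel.columns):
            raise ConfigError(f"LD panel needs columns {sorted(need)}")
        self.panel = self.panel.reset_index(drop=True)
        self.panel["rsid"] = self.panel["rsid"].astype(str)
        self.panel["chrom"] = self.panel["chrom"].astype(str)
        self._pos = dict(zip(self.panel["rsid"], zip(self.panel["chrom"], self.panel["pos"])))

    @classmethod
    def from_pairs(cls, panel: pd.DataFrame, pairs: Iterable[tuple[str, str, float]]) -> "LDReference":
        ref = cls(panel=panel)
        for a, b, r2 in pairs:
            ref.add_pair(str(a), str(b), float(r2))
        return ref

    def add_pair(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r2({a},{b}) = {r2} outside [0, 1]")
        if a == b:
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def partners(self, rsid: str) -> dict[str, float]:
        """All SNPs with a recorded nonzero r² to ``rsid``."""
        return dict(self._adj.get(rsid, {}))

    def position(self, rsid: str) -> tuple[str, int] | None:
        return self._pos.get(rsid)


def read_ld_reference(pairs_path, panel_path) -> LDReference:
    """Read a long-format LD file (rsid_a, rsid_b, r2) plus a panel file.

    The panel file carries (rsid, chr, pos). Symmetric closure is applied;
    unlisted pairs default to r² = 0.
    """
    panel = pd.read_csv(panel_path, sep=None, engine="python")
    panel = panel.rename(columns={"chr": "chrom"})
    pairs = pd.read_csv(pairs_path, sep=None, engine="python")
    cols = list(pairs.columns[:3])
    ref = LDReference(panel=panel[["rsid", "chrom", "pos"]])
    for a, b, r2 in pairs[cols].itertuples(index=False):
        ref.add_pair(str(a), str(b), float(r2))
    return ref


def write_ld_reference(ref: LDReference, pairs_path, panel_path) -> None:
    panel = ref.panel.rename(columns={"chrom": "chr"})
    panel.to_csv(panel_path, sep="\t", index=False)
    seen = set()
    rows = []
    for a, nbrs in ref._adj.items():
        for b, r2 in nbrs.items():
            key = (a, b) if a < b else (b, a)
            if key in seen:
                continue
            seen.add(key)
            rows.append((key[0], key[1], r2))
    pd.DataFrame(rows, columns=["rsid_a", "rsid_b", "r2"]).to_csv(
        pairs_path, sep="\t", index=False, float_format="%.12g"
    )
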