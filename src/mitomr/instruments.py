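"""Instrumental-variable selection for one protein exposure.

The selection pipeline applies, in order: a genome-wide significance filter
(5e-8, relaxed to 5e-6 when nothing survives), removal of SNPs on a
confounder blocklist, greedy LD clumping (r^2 > 0.01 within 10,000 kb), and
an instrument-strength filter based on the F statistic
``F = R^2 (n - k - 1) / (k (1 - R^2))`` with weak sets (F < 10) pruned by
iteratively dropping the variant explaining the least exposure variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .gwas_io import SummaryStatsTable

__all__ = [
    "LDTable",
    "SelectionConfig",
    "InstrumentSet",
    "filter_by_pvalue",
    "clump",
    "variant_r2",
    "f_statistic",
    "select_instruments",
    "read_ld_table",
    "read_blocklist",
]


@dataclass
class LDTable:
    """Pairwise r-squared values plus genomic positions.

    ``entries`` maps an unordered rsid pair (frozenset) to r^2 in [0, 1];
    a missing pair is treated as r^2 = 0. ``positions`` maps rsid to
    ``(chrom, pos)`` with 1-based positions.
    """

    entries: Dict[FrozenSet[str], float] = field(default_factory=dict)
    positions: Dict[str, Tuple[str, int]] = field(default_factory=dict)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.entries.get(frozenset((a, b)), 0.0)

    def set_r2(self, a: str, b: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValidationError(f"r2 must be in [0,1], got {value}")
        self.entries[frozenset((a, b))] = float(value)

    def distance_bp(self, a: str, b: str) -> Optional[int]:
        """|pos_a - pos_b| in bp, or None when on different chromosomes."""
        if a not in self.positions or b not in self.positions:
            raise ConfigurationError(
                f"position unknown for {'%s' % (a if a not in self.positions else b)}"
            )
        (ca, pa), (cb, pb) = self.positions[a], self.positions[b]
        if str(ca) != str(cb):
            return None
        return abs(int(pa) - int(pb))


def read_ld_table(path, positions: Optional[Dict[str, Tuple[str, int]]] = None) -> LDTable:
    """Read a 3-column TSV (rsid_a, rsid_b, r2)."""
    df = pd.read_csv(path, sep="\t")
    table = LDTable(positions=dict(positions or {}))
    for _, row in df.iterrows():
        table.set_r2(str(row.iloc[0]), str(row.iloc[1]), float(row.iloc[2]))
    return table


def read_blocklist(path) -> frozenset:
    """One rsid per line; blank lines and '#' comments ignored."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh
            if line.strip() and not line.startswith("#")
        )


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds governing instrument selection.

    ``r2_method`` chooses the per-variant variance-explained formula:
    ``"se"`` uses t^2/(t^2 + n - 2) (needs no allele frequency), ``"eaf"``
    uses 2*eaf*(1-eaf)*beta^2 and assumes a standardized exposure.
    ``per_variant_f`` switches the weak-instrument filter from the set-level
    F to per-variant F thresholds.
    """

    p_primary: float = 5e-8
    p_relaxed: float = 5e-6
    r2_max: float = 0.01
    clump_window_kb: float = 10_000.0
    f_min: float = 10.0
    confounder_rsids: frozenset = frozenset()
    r2_method: str = "se"
    per_variant_f: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_primary <= self.p_relaxed < 1.0):
            raise ValidationError("need 0 < p_primary <= p_relaxed < 1")
        if not (0.0 < self.r2_max < 1.0):
            raise ValidationError("r2_max must be in (0,1)")
        if self.f_min <= 0:
            raise ValidationError("f_min must be > 0")
        if self.r2_method not in ("se", "eaf"):
            raise ValidationError("r2_method must be 'se' or 'eaf'")


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure, with a removal audit."""

    exposure_id: str
    rsids: list
    r2_by_rsid: Dict[str, float]
    F: float
    n: int
    audit: Dict[str, str]
    p_threshold_used: Optional[float] = None

    @property
    def k(self) -> int:
        return len(self.rsids)

    @property
    def R2(self) -> float:
        return min(sum(self.r2_by_rsid[r] for r in self.rsids), 0.999)


def filter_by_pvalue(
    table: SummaryStatsTable, cfg: SelectionConfig
) -> Tuple[SummaryStatsTable, float, Dict[str, str]]:
    """Keep genome-wide significant records, falling back to the relaxed tier.

    Returns ``(filtered table, threshold used, audit)`` where the audit maps
    removed rsids to ``"above_p"``.
    """
    df = table.records
    threshold = cfg.p_primary
    keep = df["pval"] < threshold
    if not keep.any():
        threshold = cfg.p_relaxed
        keep = df["pval"] < threshold
    audit = {r: "above_p" for r in df.loc[~keep, "rsid"]}
    return table.subset(df.loc[keep, "rsid"]), threshold, audit


def clump(
    records: pd.DataFrame, ld: LDTable, cfg: SelectionConfig
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Greedy LD clumping: lowest-p SNP indexes a clump, correlated
    neighbours within the window are removed.

    Ties on p are broken by (chrom, pos, rsid); missing chrom/pos sort last.
    Returns the retained records and an audit mapping removed rsids to
    ``"clumped_by:<index rsid>"``.
    """
    def sort_key(row):
        chrom = str(row["chrom"]) if pd.notna(row["chrom"]) else "~"
        pos = float(row["pos"]) if pd.notna(row["pos"]) else np.inf
        return (row["pval"], chrom, pos, row["rsid"])

    order = sorted(records.to_dict("records"), key=sort_key)
    kept: list[str] = []
    audit: Dict[str, str] = {}
    removed: set[str] = set()
    for row in order:
        rsid = row["rsid"]
        if rsid in removed:
            continue
        kept.append(rsid)
        for other in order:
            rid = other["rsid"]
            if rid == rsid or rid in removed or rid in kept:
                continue
            r2 = ld.r2(rsid, rid)
            if r2 > cfg.r2_max:
                dist = ld.distance_bp(rsid, rid)
                if dist is not None and dist < cfg.clump_window_kb * 1000.0:
                    removed.add(rid)
                    audit[rid] = f"clumped_by:{rsid}"
    out = records[records["rsid"].isin(kept)].reset_index(drop=True)
    return out, audit


def variant_r2(beta: float, se: float, n: float, eaf: float = np.nan,
               method: str = "se") -> float:
    """Variance of the exposure explained by one variant.

    ``"se"``: r2 = t^2 / (t^2 + n - 2) with t = beta/se.
    ``"eaf"``: r2 = 2*eaf*(1-eaf)*beta^2 (standardized exposure).
    """
    if method == "se":
        if se <= 0:
            raise ValidationError("se must be > 0")
        if n < 3:
            raise ValidationError("variant_r2 needs n >= 3")
        t2 = (beta / se) ** 2
        return t2 / (t2 + n - 2.0)
    if method == "eaf":
        if np.isnan(eaf):
            raise ValidationError("eaf required for the 'eaf' r2 method")
        return float(2.0 * eaf * (1.0 - eaf) * beta**2)
    raise ValidationError(f"unknown r2 method {method!r}")


def f_statistic(R2: float, n: float, k: int) -> float:
    """F = R^2 (n - k - 1) / (k (1 - R^2))."""
    if not (0.0 <= R2 < 1.0):
        raise ValidationError("R2 must be in [0,1)")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n <= k + 1:
        raise ValidationError("f_statistic requires n > k + 1")
    return R2 * (n - k - 1.0) / (k * (1.0 - R2))


def select_instruments(
    exposure: SummaryStatsTable, ld: LDTable, cfg: SelectionConfig
) -> InstrumentSet:
    """Full instrument-selection pipeline for one exposure table.

    Order: p-value filter -> confounder blocklist -> LD clumping ->
    weak-instrument (F) filter. Every removed rsid appears in the audit with
    its reason; the empty set is a legal result.
    """
    filtered, threshold, audit = filter_by_pvalue(exposure, cfg)
    df = filtered.records
    conf = df["rsid"].isin(cfg.confounder_rsids)
    for rsid in df.loc[conf, "rsid"]:
        audit[rsid] = "confounder"
    df = df[~conf].reset_index(drop=True)
    df, clump_audit = clump(df, ld, cfg)
    audit.update(clump_audit)

    r2_by_rsid = {
        row["rsid"]: variant_r2(
            row["beta"], row["se"], row["n"], row["eaf"], cfg.r2_method
        )
        for _, row in df.iterrows()
    }
    rsids = list(df["rsid"])
    n = int(np.median(df["n"])) if len(df) else 0

    if cfg.per_variant_f:
        for rsid in list(rsids):
            r2 = r2_by_rsid[rsid]
            if n <= 2 or f_statistic(r2, n, 1) < cfg.f_min:
                rsids.remove(rsid)
                audit[rsid] = "low_F"
    else:
        # enforce set-level F >= f_min by dropping the weakest variant
        while rsids:
            R2 = min(sum(r2_by_rsid[r] for r in rsids), 0.999)
            k = len(rsids)
            if n > k + 1 and f_statistic(R2, n, k) >= cfg.f_min:
                break
            weakest = min(rsids, key=lambda r: (r2_by_rsid[r], r))
            rsids.remove(weakest)
            audit[weakest] = "low_F"

    if rsids:
        R2 = min(sum(r2_by_rsid[r] for r in rsids), 0.999)
        F = f_statistic(R2, n, len(rsids))
    else:
        F = 0.0
    return InstrumentSet(
        exposure_id=exposure.trait_id,
        rsids=rsids,
        r2_by_rsid={r: r2_by_rsid[r] for r in rsids},
        F=F,
        n=n,
        audit=audit,
        p_threshold_used=threshold,
    )
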