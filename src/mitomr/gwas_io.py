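"""Reading, validation, and harmonization of GWAS summary statistics.

Two-sample Mendelian randomization needs exposure and outcome effects
expressed per copy of the *same* effect allele. This module reads
tab-delimited summary-statistics tables (GWAS-SSF-like column names are
accepted), validates the per-variant records, and aligns an outcome table to
an exposure table: allele swaps flip the outcome beta, strand flips are
resolved by base complement, and palindromic (A/T, C/G) variants are either
aligned by allele frequency or dropped when the frequency is uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, ValidationError

__all__ = [
    "SummaryStatsTable",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "kept_pairs",
    "KEEP_ACTIONS",
    "DROP_ACTIONS",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical internal column order
COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

# GWAS-SSF-style aliases accepted on input; the writer emits the long names.
_ALIASES = {
    "variant_id": "rsid",
    "chromosome": "chrom",
    "base_pair_location": "pos",
    "effect_allele_frequency": "eaf",
    "standard_error": "se",
    "p_value": "pval",
    "sample_size": "n",
}
_MANDATORY = ["rsid", "effect_allele", "other_allele", "beta", "se", "pval", "n"]

#: harmonization actions that keep a pair usable downstream
KEEP_ACTIONS = ("none", "sign_flip", "strand_flip")
DROP_ACTIONS = ("dropped_palindromic", "dropped_mismatch")


@dataclass
class SummaryStatsTable:
    """A validated per-trait table of per-SNP association records.

    Parameters
    ----------
    trait_id:
        Trait label, e.g. a protein symbol for exposures or a GWAS accession
        for outcomes.
    trait_role:
        ``"exposure"`` or ``"outcome"``.
    records:
        DataFrame with columns ``rsid, chrom, pos, effect_allele,
        other_allele, eaf, beta, se, pval, n``; ``chrom``/``pos``/``eaf``
        may be missing (NaN).
    outcome_category:
        ``"egfr"``, ``"uae"`` or ``"creatinine"`` for outcome tables; must be
        ``None`` for exposures.
    """

    trait_id: str
    trait_role: str
    records: pd.DataFrame
    outcome_category: Optional[str] = None

    def __post_init__(self) -> None:
        if self.trait_role not in ("exposure", "outcome"):
            raise ValidationError(f"unknown trait_role {self.trait_role!r}")
        if self.trait_role == "outcome" and self.outcome_category not in (
            "egfr", "uae", "creatinine",
        ):
            raise ValidationError(
                f"outcome table {self.trait_id!r} needs an outcome_category"
            )
        if self.trait_role == "exposure" and self.outcome_category is not None:
            raise ValidationError("exposure tables carry no outcome_category")
        self.records = _coerce_columns(self.records)
        _validate_records(self.records, trait_id=self.trait_id)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, rsids: Iterable[str]) -> "SummaryStatsTable":
        """Restrict to the given rsids (order preserved)."""
        keep = self.records[self.records["rsid"].isin(set(rsids))]
        return SummaryStatsTable(
            self.trait_id, self.trait_role, keep.reset_index(drop=True),
            self.outcome_category,
        )


def _coerce_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.rename(columns=_ALIASES).copy()
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("chrom", "pos", "eaf"):
        if col not in df.columns:
            df[col] = np.nan
    df["rsid"] = df["rsid"].astype(str)
    df["chrom"] = df["chrom"].astype(object)
    notna = df["chrom"].notna()
    df.loc[notna, "chrom"] = df.loc[notna, "chrom"].astype(str)
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df[COLUMNS].reset_index(drop=True)


def _validate_records(
    df: pd.DataFrame, trait_id: str = "", check_p_consistency: bool = True
) -> None:
    """Raise :class:`ValidationError` with row-numbered diagnostics.

    Row numbers are 1-based over data rows (header excluded).
    """
    problems: list[str] = []
    dup = df["rsid"][df["rsid"].duplicated()]
    if not dup.empty:
        names = ", ".join(sorted(set(dup)))
        raise ValidationError(f"{trait_id}: duplicate rsid(s): {names}")
    for i, row in df.iterrows():
        rowno = i + 1
        ea, oa = row["effect_allele"], row["other_allele"]
        if ea not in VALID_BASES or oa not in VALID_BASES:
            problems.append(f"row {rowno}: alleles must be A/C/G/T, got {ea}/{oa}")
            continue
        if ea == oa:
            problems.append(f"row {rowno}: effect_allele equals other_allele")
        if not np.isnan(row["pos"]) and row["pos"] < 1:
            problems.append(f"row {rowno}: pos must be >= 1")
        if not np.isnan(row["eaf"]) and not (0.0 < row["eaf"] < 1.0):
            problems.append(f"row {rowno}: eaf outside (0,1)")
        if not (row["se"] > 0):
            problems.append(f"row {rowno}: se must be > 0")
        if not (0.0 < row["pval"] <= 1.0):
            problems.append(f"row {rowno}: pval outside (0,1]")
        elif check_p_consistency and row["se"] > 0:
            # reported p should agree with 2*Phi(-|beta/se|) within factor 2;
            # both sides floored at 1e-300 so underflow never trips the check
            floor = np.log(1e-300)
            logp = max(stats.norm.logsf(abs(row["beta"] / row["se"])) + np.log(2.0), floor)
            if abs(max(np.log(row["pval"]), floor) - logp) > np.log(2.0) + 1e-9:
                problems.append(
                    f"row {rowno}: pval {row['pval']:.3g} inconsistent with "
                    f"|beta/se| (implied {np.exp(logp):.3g})"
                )
        if not (row["n"] >= 2):
            problems.append(f"row {rowno}: n must be >= 2")
    if problems:
        raise ValidationError(f"{trait_id}: " + "; ".join(problems))


def read_summary_stats(
    path,
    trait_role: str,
    outcome_category: Optional[str] = None,
    trait_id: Optional[str] = None,
    check_p_consistency: bool = True,
) -> SummaryStatsTable:
    """Read a tab-delimited summary-statistics file into a validated table."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "variant_id": str})
    df = _coerce_columns(df)
    _validate_records(df, trait_id=str(path), check_p_consistency=check_p_consistency)
    if trait_id is None:
        import os

        trait_id = os.path.splitext(os.path.basename(str(path)))[0]
    return SummaryStatsTable(trait_id, trait_role, df, outcome_category)


def write_summary_stats(table: SummaryStatsTable, path) -> None:
    """Write a table in the GWAS-SSF-like dialect the reader accepts."""
    out = table.records.rename(
        columns={
            "chrom": "chromosome",
            "pos": "base_pair_location",
            "eaf": "effect_allele_frequency",
            "se": "standard_error",
            "pval": "p_value",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _is_palindromic(ea: str, oa: str) -> bool:
    return COMPLEMENT[ea] == oa


def harmonize(
    exposure: SummaryStatsTable,
    outcome: SummaryStatsTable,
    palindrome_eaf_band: float = 0.08,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Returns one row per rsid in the intersection of the two tables with
    columns ``rsid, beta_exp, se_exp, p_exp, n_exp, eaf_exp, beta_out,
    se_out, p_out, n_out, eaf_out, action``. Rows with a ``dropped_*``
    action must not be used downstream (:func:`kept_pairs` filters them).

    Alignment rules, applied per variant:

    * identical alleles -> ``none``;
    * swapped alleles -> outcome beta negated, eaf reflected (``sign_flip``);
    * alleles matching only after base complement -> strand flip, then the
      swap rule (net action ``strand_flip`` when no sign change);
    * palindromic variants (A/T, C/G): dropped when either eaf is missing or
      within ``0.5 +/- palindrome_eaf_band``, otherwise aligned so both
      frequencies sit on the same side of 0.5;
    * anything else -> ``dropped_mismatch``.
    """
    if len(exposure) == 0 or len(outcome) == 0:
        raise ValidationError("harmonize requires nonempty exposure and outcome")
    out_by_rsid = outcome.records.set_index("rsid")
    rows = []
    for _, ex in exposure.records.iterrows():
        rsid = ex["rsid"]
        if rsid not in out_by_rsid.index:
            continue
        oy = out_by_rsid.loc[rsid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        ea_y, oa_y = oy["effect_allele"], oy["other_allele"]
        beta_out, eaf_out = float(oy["beta"]), float(oy["eaf"])
        action = None
        if _is_palindromic(ea_x, oa_x):
            if {ea_y, oa_y} != {ea_x, oa_x}:
                action = "dropped_mismatch"
            else:
                eaf_x = float(ex["eaf"])
                flipped = ea_y != ea_x
                if flipped:  # letter swap first: track frequency of ea_x
                    beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                ambiguous = (
                    np.isnan(eaf_x)
                    or np.isnan(eaf_out)
                    or abs(eaf_x - 0.5) <= palindrome_eaf_band
                    or abs(eaf_out - 0.5) <= palindrome_eaf_band
                )
                if ambiguous:
                    action = "dropped_palindromic"
                else:
                    if (eaf_x - 0.5) * (eaf_out - 0.5) < 0:
                        # strand mismatch: the stated allele is really its
                        # complement on the exposure strand
                        beta_out, eaf_out = -beta_out, 1.0 - eaf_out
                        flipped = not flipped
                    action = "sign_flip" if flipped else "none"
        elif (ea_y, oa_y) == (ea_x, oa_x):
            action = "none"
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "sign_flip"
        elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (ea_x, oa_x):
            action = "strand_flip"
        elif (COMPLEMENT[ea_y], COMPLEMENT[oa_y]) == (oa_x, ea_x):
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
            action = "sign_flip"
        else:
            action = "dropped_mismatch"
        rows.append(
            {
                "rsid": rsid,
                "beta_exp": float(ex["beta"]),
                "se_exp": float(ex["se"]),
                "p_exp": float(ex["pval"]),
                "n_exp": float(ex["n"]),
                "eaf_exp": float(ex["eaf"]),
                "beta_out": beta_out,
                "se_out": float(oy["se"]),
                "p_out": float(oy["pval"]),
                "n_out": float(oy["n"]),
                "eaf_out": eaf_out,
                "action": action,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "beta_exp", "se_exp", "p_exp", "n_exp", "eaf_exp",
            "beta_out", "se_out", "p_out", "n_out", "eaf_out", "action",
        ],
    )


def kept_pairs(harmonized: pd.DataFrame) -> pd.DataFrame:
    """Rows of a harmonized frame that survive alignment."""
    return harmonized[harmonized["action"].isin(KEEP_ACTIONS)].reset_index(drop=True)
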