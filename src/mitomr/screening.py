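"""Evidence tiers, cross-outcome intersection, and direction-of-effect
classification of candidate drug targets.

The screen tests each protein against nine renal outcome datasets, three per
outcome category (eGFR, urinary albumin excretion, serum creatinine).
Benjamini-Hochberg q-values are computed per outcome dataset across
proteins. A protein is a *candidate* when every category shows at least one
significant dataset, and *core* when at least two categories are significant
with a consistent direction of effect. Direction follows the kidney-damage
convention: a positive effect on creatinine or urinary albumin, or a
negative effect on eGFR, votes "risk"; the opposite signs vote
"resistance"; mixed votes are a "conflict" and are excluded from the core
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "CATEGORIES", "ScreeningConfig", "bh_adjust", "adjust_by_dataset",
    "assign_tier", "direction_classify", "candidate_filter", "core_filter",
    "classify_targets", "risk_resistance_sets", "venn_counts",
    "load_printed_estimates", "headline_calls", "classify_printed",
]

CATEGORIES = ("egfr", "uae", "creatinine")

#: categories where a positive beta means more kidney damage
_POSITIVE_IS_RISK = {"creatinine", "uae"}


@dataclass(frozen=True)
class ScreeningConfig:
    """Voting rules for candidate/core status.

    ``alpha`` is the per-call significance level on raw p (``strict_q``
    switches voting to the BH q-value). A candidate needs at least
    ``min_datasets_per_category`` significant datasets in *every* category;
    core status needs ``min_categories_core`` significant categories and a
    conflict-free direction. ``min_total_datasets`` optionally adds a floor
    on the total number of significant datasets.
    """

    alpha: float = 0.05
    strict_q: bool = False
    min_datasets_per_category: int = 1
    min_categories_core: int = 2
    min_total_datasets: int = 0
    bh_family: str = "per_dataset"  # or "global"


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values for one family."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_by_dataset(calls: pd.DataFrame, cfg: ScreeningConfig = ScreeningConfig()) -> pd.DataFrame:
    """Attach a ``q`` column, BH-adjusted within each outcome dataset
    (or globally when ``cfg.bh_family == "global"``)."""
    out = calls.copy()
    if cfg.bh_family == "global":
        out["q"] = bh_adjust(out["p"].to_numpy())
    else:
        out["q"] = (
            out.groupby("dataset_id")["p"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    return out


def assign_tier(p: float, q: float) -> str:
    """Evidence tier from (p, q): none / suggestive / strong."""
    if p >= 0.05:
        return "none"
    if q >= 0.05:
        return "suggestive"
    return "strong"


def _significant(calls: pd.DataFrame, cfg: ScreeningConfig) -> pd.DataFrame:
    col = "q" if cfg.strict_q else "p"
    return calls[calls[col] < cfg.alpha]


def direction_classify(calls: pd.DataFrame,
                       cfg: ScreeningConfig = ScreeningConfig()) -> str:
    """Direction of effect for one exposure from its significant calls.

    Risk votes: beta > 0 on creatinine/UAE datasets, beta < 0 on eGFR.
    Resistance votes: the opposite signs. Unanimous votes give the
    direction; mixed votes give ``"conflict"``; no significant call gives
    ``"indeterminate"``. Zero betas cast no vote.
    """
    sig = _significant(calls, cfg)
    votes: Set[str] = set()
    for _, row in sig.iterrows():
        if row["beta"] == 0:
            continue
        positive = row["beta"] > 0
        if row["outcome_category"] in _POSITIVE_IS_RISK:
            votes.add("risk" if positive else "resistance")
        else:  # egfr: lower is worse
            votes.add("resistance" if positive else "risk")
    if not votes:
        return "indeterminate"
    if len(votes) > 1:
        return "conflict"
    return votes.pop()


def candidate_filter(calls: pd.DataFrame,
                     cfg: ScreeningConfig = ScreeningConfig()) -> Set[str]:
    """Exposures significant in every outcome category.

    Requires at least ``cfg.min_datasets_per_category`` significant datasets
    in each of the three categories (and ``cfg.min_total_datasets`` overall).
    """
    sig = _significant(calls, cfg)
    counts = (
        sig.groupby(["exposure", "outcome_category"])["dataset_id"]
        .nunique()
        .unstack(fill_value=0)
    )
    candidates: Set[str] = set()
    for exposure, row in counts.iterrows():
        per_cat = [row.get(cat, 0) for cat in CATEGORIES]
        if all(c >= cfg.min_datasets_per_category for c in per_cat) and (
            sum(per_cat) >= cfg.min_total_datasets
        ):
            candidates.add(exposure)
    return candidates


def core_filter(calls: pd.DataFrame, candidates: Iterable[str],
                cfg: ScreeningConfig = ScreeningConfig()) -> Set[str]:
    """Candidates significant in >= ``min_categories_core`` categories with
    a conflict-free direction."""
    core: Set[str] = set()
    for exposure in candidates:
        sub = calls[calls["exposure"] == exposure]
        sig = _significant(sub, cfg)
        n_cat = sig["outcome_category"].nunique()
        if n_cat < cfg.min_categories_core:
            continue
        if direction_classify(sub, cfg) in ("risk", "resistance"):
            core.add(exposure)
    return core


def classify_targets(calls: pd.DataFrame,
                     cfg: ScreeningConfig = ScreeningConfig(),
                     assume_candidates: bool = False) -> pd.DataFrame:
    """Per-exposure candidate/core status and direction.

    ``assume_candidates=True`` treats every exposure as already having
    passed the candidate stage (used when replaying printed estimates whose
    candidate screen ran on the full upstream results).

    Returns a frame with columns ``exposure, is_candidate, is_core,
    direction, supporting_categories, n_significant_datasets``.
    """
    exposures = sorted(calls["exposure"].unique())
    candidates = (
        set(exposures) if assume_candidates else candidate_filter(calls, cfg)
    )
    core = core_filter(calls, candidates, cfg)
    rows = []
    for exposure in exposures:
        sub = calls[calls["exposure"] == exposure]
        sig = _significant(sub, cfg)
        cats = sorted(sig["outcome_category"].unique())
        rows.append(
            {
                "exposure": exposure,
                "is_candidate": exposure in candidates,
                "is_core": exposure in core,
                "direction": direction_classify(sub, cfg),
                "supporting_categories": ",".join(cats),
                "n_significant_datasets": int(sig["dataset_id"].nunique()),
            }
        )
    return pd.DataFrame(rows)


def risk_resistance_sets(classification: pd.DataFrame) -> Tuple[List[str], List[str]]:
    """Partition core exposures by direction -> (risk, resistance)."""
    core = classification[classification["is_core"]]
    risk = sorted(core.loc[core["direction"] == "risk", "exposure"])
    resistance = sorted(core.loc[core["direction"] == "resistance", "exposure"])
    return risk, resistance


def venn_counts(calls: pd.DataFrame,
                cfg: ScreeningConfig = ScreeningConfig()) -> Dict[str, object]:
    """Per-category significant exposure sets and their intersections."""
    sig = _significant(calls, cfg)
    sets = {
        cat: set(sig.loc[sig["outcome_category"] == cat, "exposure"])
        for cat in CATEGORIES
    }
    out: Dict[str, object] = {cat: sorted(s) for cat, s in sets.items()}
    out["egfr_uae"] = sorted(sets["egfr"] & sets["uae"])
    out["egfr_creatinine"] = sorted(sets["egfr"] & sets["creatinine"])
    out["uae_creatinine"] = sorted(sets["uae"] & sets["creatinine"])
    out["all_three"] = sorted(sets["egfr"] & sets["uae"] & sets["creatinine"])
    return out


# ---------------------------------------------------------------------------
# printed-estimate fixtures (the published report tables, shipped verbatim)
# ---------------------------------------------------------------------------

_FIXTURES = {
    "core": "printed_mr_core.tsv",
    "excluded": "printed_mr_excluded.tsv",
}


def _parse_printed(token: str) -> float:
    """Printed p/q tokens: plain numbers or '<0.001' upper bounds."""
    token = str(token).strip()
    if token.startswith("<"):
        return float(token[1:])
    return float(token)


def load_printed_estimates(which: str = "core") -> pd.DataFrame:
    """Load a packaged printed-estimate table.

    ``which`` is ``"core"`` (28 retained proteins) or ``"excluded"`` (the
    conflicted proteins). Columns: ``exposure, dataset_id,
    outcome_category, nsnp, method, beta, p, q, or_, or_ci_low, or_ci_high``
    with p/q parsed from the printed tokens ('<0.001' -> 0.001 upper bound).
    """
    if which not in _FIXTURES:
        raise ValidationError(f"unknown fixture {which!r}")
    ref = resources.files("mitomr").joinpath("data", _FIXTURES[which])
    with ref.open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, sep="\t")
    df["p"] = df["p_value"].map(_parse_printed)
    df["q"] = df["q_value"].map(_parse_printed)
    df = df.rename(columns={"or": "or_"})
    return df[
        ["exposure", "dataset_id", "outcome_category", "nsnp", "method",
         "beta", "p", "q", "or_", "or_ci_low", "or_ci_high"]
    ]


_METHOD_PRIORITY = {"Inverse variance weighted": 0, "Wald ratio": 1}


def headline_calls(printed: pd.DataFrame) -> pd.DataFrame:
    """One call per (exposure, dataset): the IVW row when present, else the
    Wald-ratio row (sensitivity methods are never the headline)."""
    ranked = printed.assign(
        _rank=printed["method"].map(lambda m: _METHOD_PRIORITY.get(m, 9))
    )
    idx = (
        ranked.sort_values(["exposure", "dataset_id", "_rank"])
        .groupby(["exposure", "dataset_id"], sort=False)
        .head(1)
        .index
    )
    return printed.loc[idx].reset_index(drop=True)


def classify_printed(printed: pd.DataFrame,
                     cfg: ScreeningConfig = ScreeningConfig()) -> pd.DataFrame:
    """Replay the screening stage on printed estimates.

    The printed tables already passed the upstream candidate screen, so
    every exposure is treated as a candidate and only the core/direction
    rules are applied.
    """
    calls = headline_calls(printed)
    return classify_targets(calls, cfg, assume_candidates=True)
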