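"""Synthetic inputs with known ground truth.

Three generators stand in for the study's downloads:

* :func:`simulate_summary_stats` - two-sample GWAS summary statistics for
  one protein exposure against one or more outcomes, with finite-sample
  standard errors ``se = 1/sqrt(2 maf (1-maf) n)``, an optional directional
  pleiotropy component, and block-diagonal LD;
* :func:`simulate_screen_panel` - a panel of proteins with risk /
  resistance / null truth classes driving the sign pattern of the causal
  effect across the three renal outcome categories, three replicate
  datasets per category;
* :func:`simulate_expression` - log2 expression matrices with additive /
  multiplicative batch effects and a high-risk diabetic-nephropathy
  subgroup carrying opposite shifts on the risk and resistance gene sets.

Every generator is a pure function of its config (which includes the seed):
identical configs give identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .expression import ExpressionMatrix
from .gwas_io import SummaryStatsTable
from .instruments import LDTable

__all__ = [
    "MRSimConfig", "PanelSimConfig", "ExprSimConfig",
    "MRSimResult", "PanelSimResult", "ExprSimResult",
    "simulate_summary_stats", "simulate_screen_panel", "simulate_expression",
]

# non-palindromic ordered allele pairs to sidestep strand ambiguity
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def _se_from_maf(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _pvals(beta_hat: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    return np.clip(p, 1e-300, 1.0)


@dataclass(frozen=True)
class MRSimConfig:
    """Study conditions for one exposure's two-sample MR simulation.

    ``theta`` maps outcome dataset ids to (category, true causal effect);
    a bare float simulates a single creatinine-like outcome. Exposure
    effects are N(0, sigma_beta_exp^2); ``prop_null_snps`` zeroes a
    fraction of them. Pleiotropy adds alpha_j ~ N(mu, sd^2) to each SNP's
    direct outcome effect. SNPs within an LD block share effects with
    correlation r2 and are entered in the LD table at that r2.
    """

    J: int = 4
    n_exp: float = 50_000.0
    n_out: float = 200_000.0
    maf_range: Tuple[float, float] = (0.05, 0.5)
    theta: object = 0.1
    sigma_beta_exp: float = 0.15
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    prop_null_snps: float = 0.0
    ld_block_size: int = 1
    ld_r2: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must sit inside (0, 0.5]")
        if self.pleiotropy_sd < 0 or self.sigma_beta_exp < 0:
            raise ValidationError("variances must be >= 0")
        if not (0.0 <= self.ld_r2 <= 1.0):
            raise ValidationError("ld_r2 must be in [0,1]")

    def outcomes(self) -> Dict[str, Tuple[str, float]]:
        if isinstance(self.theta, Mapping):
            return dict(self.theta)
        return {"sim_outcome": ("creatinine", float(self.theta))}


@dataclass
class MRSimResult:
    exposure: SummaryStatsTable
    outcomes: Dict[str, SummaryStatsTable]
    ld: LDTable
    truth: Dict[str, object]

    def truth_json(self) -> str:
        return json.dumps(self.truth, sort_keys=True)


def simulate_summary_stats(cfg: MRSimConfig,
                           exposure_id: str = "sim_protein") -> MRSimResult:
    """Generate exposure and outcome summary statistics with known truth."""
    rng = np.random.default_rng(cfg.seed)
    J = cfg.J
    maf = rng.uniform(*cfg.maf_range, size=J)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=J)
    rsids = [f"rs{cfg.seed % 1000}{j:04d}" for j in range(J)]
    pos = 1_000_000 + 1_000_000 * np.arange(J)

    # true exposure effects, block-correlated when ld_block_size > 1
    blocks = np.arange(J) // max(cfg.ld_block_size, 1)
    latent = rng.normal(0.0, cfg.sigma_beta_exp, size=blocks.max() + 1)
    own = rng.normal(0.0, cfg.sigma_beta_exp, size=J)
    r = np.sqrt(cfg.ld_r2)
    beta_x = r * latent[blocks] + np.sqrt(1.0 - cfg.ld_r2) * own
    # effect alleles are coded as the exposure-increasing alleles (the usual
    # convention for protein-QTL instruments), so directional pleiotropy has
    # a well-defined sign
    beta_x = np.abs(beta_x)
    n_null = int(round(cfg.prop_null_snps * J))
    if n_null:
        null_idx = rng.choice(J, size=n_null, replace=False)
        beta_x[null_idx] = 0.0

    se_x = _se_from_maf(maf, cfg.n_exp)
    beta_x_hat = beta_x + rng.normal(0.0, se_x)

    def table(trait_id, role, category, beta_hat, se, n):
        df = pd.DataFrame(
            {
                "rsid": rsids,
                "chrom": "1",
                "pos": pos,
                "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
                "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
                "eaf": maf,
                "beta": beta_hat,
                "se": se,
                "pval": _pvals(beta_hat, se),
                "n": float(n),
            }
        )
        return SummaryStatsTable(trait_id, role, df, category)

    exposure = table(exposure_id, "exposure", None, beta_x_hat, se_x, cfg.n_exp)

    outcomes: Dict[str, SummaryStatsTable] = {}
    truth_alpha: Dict[str, List[float]] = {}
    se_y = _se_from_maf(maf, cfg.n_out)
    for out_id, (category, theta) in cfg.outcomes().items():
        alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=J) \
            if (cfg.pleiotropy_sd > 0 or cfg.pleiotropy_mean != 0) else np.zeros(J)
        beta_y_hat = theta * beta_x + alpha + rng.normal(0.0, se_y)
        outcomes[out_id] = table(out_id, "outcome", category, beta_y_hat,
                                 se_y, cfg.n_out)
        truth_alpha[out_id] = alpha.tolist()

    ld = LDTable(positions={r_: ("1", int(p)) for r_, p in zip(rsids, pos)})
    if cfg.ld_block_size > 1 and cfg.ld_r2 > 0:
        for b in range(blocks.max() + 1):
            members = [rsids[j] for j in range(J) if blocks[j] == b]
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ld.set_r2(members[i], members[j], cfg.ld_r2)

    truth = {
        "theta": {k: v[1] for k, v in cfg.outcomes().items()},
        "beta_x": beta_x.tolist(),
        "alpha": truth_alpha,
        "maf": maf.tolist(),
        "rsids": rsids,
        "seed": cfg.seed,
    }
    return MRSimResult(exposure, outcomes, ld, truth)


@dataclass(frozen=True)
class PanelSimConfig:
    """A protein panel emulating the proteome-wide screen.

    Each protein draws a truth class. Risk proteins raise creatinine and
    urinary albumin and lower eGFR (positive ``effect_size`` on
    creatinine/UAE, negative on eGFR); resistance proteins show the mirror
    pattern; null proteins have no causal effect anywhere. Three replicate
    outcome datasets per category carry independent sampling noise.
    """

    n_proteins: int = 50
    fraction_risk: float = 0.2
    fraction_resistance: float = 0.2
    fraction_null: float = 0.6
    effect_size: float = 0.1
    replicates_per_category: int = 3
    mr: MRSimConfig = field(default_factory=MRSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.fraction_risk + self.fraction_resistance + self.fraction_null
        if abs(total - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")


@dataclass
class ProteinSim:
    exposure: SummaryStatsTable
    outcomes: Dict[str, SummaryStatsTable]
    ld: LDTable


@dataclass
class PanelSimResult:
    proteins: Dict[str, ProteinSim]
    truth: Dict[str, str]  # protein -> risk | resistance | null
    dataset_ids: List[str]


def _theta_pattern(cls: str, effect: float) -> Dict[str, float]:
    sign = {"risk": 1.0, "resistance": -1.0, "null": 0.0}[cls]
    return {"creatinine": sign * effect, "uae": sign * effect,
            "egfr": -sign * effect}


def simulate_screen_panel(cfg: PanelSimConfig) -> PanelSimResult:
    """Generate exposure/outcome tables for a labelled protein panel."""
    rng = np.random.default_rng(cfg.seed)
    n_risk = int(round(cfg.fraction_risk * cfg.n_proteins))
    n_res = int(round(cfg.fraction_resistance * cfg.n_proteins))
    classes = (["risk"] * n_risk + ["resistance"] * n_res
               + ["null"] * (cfg.n_proteins - n_risk - n_res))
    rng.shuffle(classes)

    dataset_ids = [
        f"{cat}_{i + 1}"
        for cat in ("egfr", "uae", "creatinine")
        for i in range(cfg.replicates_per_category)
    ]
    proteins: Dict[str, ProteinSim] = {}
    truth: Dict[str, str] = {}
    for p, cls in enumerate(classes):
        name = f"protein_{p:03d}"
        pattern = _theta_pattern(cls, cfg.effect_size)
        theta = {
            ds: (ds.rsplit("_", 1)[0], pattern[ds.rsplit("_", 1)[0]])
            for ds in dataset_ids
        }
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_cfg = MRSimConfig(
            J=cfg.mr.J, n_exp=cfg.mr.n_exp, n_out=cfg.mr.n_out,
            maf_range=cfg.mr.maf_range, theta=theta,
            sigma_beta_exp=cfg.mr.sigma_beta_exp,
            pleiotropy_mean=cfg.mr.pleiotropy_mean,
            pleiotropy_sd=cfg.mr.pleiotropy_sd,
            prop_null_snps=cfg.mr.prop_null_snps,
            ld_block_size=cfg.mr.ld_block_size, ld_r2=cfg.mr.ld_r2,
            seed=sub_seed,
        )
        sim = simulate_summary_stats(sub_cfg, exposure_id=name)
        proteins[name] = ProteinSim(sim.exposure, sim.outcomes, sim.ld)
        truth[name] = cls
    return PanelSimResult(proteins, truth, dataset_ids)


@dataclass(frozen=True)
class ExprSimConfig:
    """Log2 expression matrices with batch structure and group signal.

    Baseline expression is N(8, 1) on the log2 scale. Each batch b applies
    ``batch_shift * b`` additively and ``batch_scale ** b``
    multiplicatively (around the baseline mean). Within the DN group, a
    designated high-risk subgroup (half the DN samples per batch) gains
    ``effect_size`` on risk-set genes and loses it on resistance-set genes.
    """

    n_genes: int = 1000
    n_per_group_per_batch: int = 10
    n_batches: int = 2
    batch_shift: float = 2.0
    batch_scale: float = 1.0
    n_risk_genes: int = 30
    n_resistance_genes: int = 30
    effect_size: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_risk_genes + self.n_resistance_genes > self.n_genes:
            raise ValidationError("gene-set sizes exceed n_genes")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")


@dataclass
class ExprSimResult:
    matrix: ExpressionMatrix
    risk_genes: List[str]
    resistance_genes: List[str]
    high_risk_samples: List[str]
    de_genes: List[str]


def simulate_expression(cfg: ExprSimConfig) -> ExprSimResult:
    """Generate a batched expression matrix with a high-risk DN subgroup."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{g:04d}" for g in range(cfg.n_genes)]
    risk_genes = genes[: cfg.n_risk_genes]
    resistance_genes = genes[cfg.n_risk_genes: cfg.n_risk_genes + cfg.n_resistance_genes]

    columns: List[str] = []
    batch: Dict[str, str] = {}
    group: Dict[str, str] = {}
    high_risk: List[str] = []
    blocks: List[np.ndarray] = []
    base_mean = 8.0
    for b in range(cfg.n_batches):
        for grp in ("control", "DN"):
            for i in range(cfg.n_per_group_per_batch):
                sid = f"b{b}_{grp}_{i:02d}"
                columns.append(sid)
                batch[sid] = f"batch{b}"
                group[sid] = grp
                x = base_mean + rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
                if grp == "DN" and i < cfg.n_per_group_per_batch // 2:
                    high_risk.append(sid)
                    x[: cfg.n_risk_genes] += cfg.effect_size
                    x[cfg.n_risk_genes: cfg.n_risk_genes + cfg.n_resistance_genes] -= cfg.effect_size
                # batch effects: additive shift and multiplicative scale
                x = base_mean + (x - base_mean) * (cfg.batch_scale ** b)
                x = x + cfg.batch_shift * b
                blocks.append(x)
    values = pd.DataFrame(np.column_stack(blocks), index=genes, columns=columns)
    matrix = ExpressionMatrix(values, pd.Series(batch), pd.Series(group))
    return ExprSimResult(matrix, risk_genes, resistance_genes, high_risk,
                         risk_genes + resistance_genes)
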