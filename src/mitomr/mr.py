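"""Causal-effect estimators for one exposure-outcome pair.

Given harmonized instrument-level effects, this module computes the Wald
ratio, inverse-variance-weighted (IVW), MR-Egger, weighted-median and
mode-based estimates, together with Cochran's Q heterogeneity statistic and
the Egger-intercept test for directional pleiotropy. Estimates are reported
as log odds/trait-unit effects with 95% CIs and exponentiated ORs.

Per-SNP Wald ratios use the first-order delta approximation
``theta_j = beta_out / beta_exp``, ``se_j = se_out / |beta_exp|`` so IVW
weights are ``w_j = 1/se_j^2 = beta_exp^2 / se_out^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientInstrumentsError, ValidationError

__all__ = [
    "METHOD_WALD", "METHOD_IVW", "METHOD_EGGER", "METHOD_WMEDIAN",
    "METHOD_WMODE", "METHOD_SMODE",
    "MRConfig", "MREstimate", "HeterogeneityResult", "PleiotropyResult",
    "MRReport", "ratio_estimates", "wald_ratio", "ivw", "egger_regression",
    "weighted_median", "mode_estimate", "cochran_q", "or_from_beta", "run_mr",
]

# method labels as printed in the report tables
METHOD_WALD = "Wald ratio"
METHOD_IVW = "Inverse variance weighted"
METHOD_EGGER = "MR Egger"
METHOD_WMEDIAN = "Weighted median"
METHOD_WMODE = "Weighted mode"
METHOD_SMODE = "Simple mode"

Z95 = 1.96


@dataclass(frozen=True)
class MRConfig:
    """Estimation options.

    ``ivw_mode``: ``"auto"`` uses a fixed-effect model for k <= 3 and
    multiplicative random effects for k >= 4; ``"fixed"`` /
    ``"multiplicative_re"`` force one model. Outlier pruning removes, while
    the Cochran-Q p-value is below ``outlier_q_alpha`` and k > 2, the variant
    whose removal most reduces Q.
    """

    ivw_mode: str = "auto"
    outlier_q_alpha: float = 0.05
    prune_outliers: bool = True
    n_boot: int = 1000
    bandwidth_factor: float = 1.0
    seed: int = 0
    second_order_wald_se: bool = False


@dataclass
class MREstimate:
    exposure_id: str
    outcome_id: str
    method: str
    nsnp: int
    beta: float
    se: float
    p: float
    q: Optional[float] = None  # BH-adjusted p, filled by the screening stage

    @property
    def ci95(self) -> Tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def or_ci(self) -> Tuple[float, float]:
        lo, hi = self.ci95
        return (math.exp(lo), math.exp(hi))


@dataclass
class HeterogeneityResult:
    Q: float
    df: int
    p: float


@dataclass
class PleiotropyResult:
    intercept: float
    intercept_se: float
    intercept_p: float


@dataclass
class MRReport:
    """All estimates and diagnostics for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    estimates: List[MREstimate]
    heterogeneity: Optional[HeterogeneityResult] = None
    pleiotropy: Optional[PleiotropyResult] = None
    removed_outliers: List[str] = field(default_factory=list)
    seed: Optional[int] = None


def _norm_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0


def ratio_estimates(pairs: pd.DataFrame,
                    second_order_se: bool = False) -> pd.DataFrame:
    """Per-SNP Wald ratios from a harmonized-pairs frame.

    Returns columns ``rsid, theta, se, w`` with ``w = 1/se^2``.
    """
    if (pairs["beta_exp"] == 0).any():
        raise ValidationError("beta_exp = 0 gives an undefined ratio")
    theta = pairs["beta_out"] / pairs["beta_exp"]
    se = pairs["se_out"] / pairs["beta_exp"].abs()
    if second_order_se:
        se = np.sqrt(
            se**2
            + pairs["beta_out"] ** 2 * pairs["se_exp"] ** 2 / pairs["beta_exp"] ** 4
        )
    return pd.DataFrame(
        {"rsid": pairs["rsid"], "theta": theta, "se": se, "w": 1.0 / se**2}
    ).reset_index(drop=True)


def wald_ratio(pair, exposure_id: str = "", outcome_id: str = "",
               second_order_se: bool = False) -> MREstimate:
    """Single-instrument causal estimate beta_out / beta_exp."""
    if pair["beta_exp"] == 0:
        raise ValidationError("beta_exp = 0 gives an undefined ratio")
    beta = pair["beta_out"] / pair["beta_exp"]
    se = pair["se_out"] / abs(pair["beta_exp"])
    if second_order_se:
        se = math.sqrt(
            se**2 + pair["beta_out"] ** 2 * pair["se_exp"] ** 2 / pair["beta_exp"] ** 4
        )
    return MREstimate(exposure_id, outcome_id, METHOD_WALD, 1,
                      float(beta), float(se), _norm_p(beta / se))


def ivw(ratios: pd.DataFrame, mode: str = "fixed",
        exposure_id: str = "", outcome_id: str = "") -> MREstimate:
    """Inverse-variance-weighted mean of the per-SNP ratios.

    ``multiplicative_re`` inflates the fixed-effect SE by
    ``max(1, sqrt(Q/(k-1)))``.
    """
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError("ivw requires >= 2 instruments")
    w, theta = ratios["w"].to_numpy(), ratios["theta"].to_numpy()
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    if mode == "multiplicative_re":
        Q = float(np.sum(w * (theta - beta) ** 2))
        se *= max(1.0, math.sqrt(Q / (k - 1)))
    elif mode != "fixed":
        raise ValidationError(f"unknown IVW mode {mode!r}")
    return MREstimate(exposure_id, outcome_id, METHOD_IVW, k, beta, se,
                      _norm_p(beta / se))


def egger_regression(pairs: pd.DataFrame, exposure_id: str = "",
                     outcome_id: str = "") -> Tuple[MREstimate, PleiotropyResult]:
    """MR-Egger: WLS of beta_out on beta_exp with an intercept.

    Pairs are first oriented so beta_exp >= 0; weights are 1/se_out^2;
    p-values use the t distribution with k - 2 df.
    """
    k = len(pairs)
    if k < 3:
        raise InsufficientInstrumentsError("MR-Egger requires >= 3 instruments")
    sign = np.sign(pairs["beta_exp"].to_numpy())
    bx = pairs["beta_exp"].to_numpy() * sign
    by = pairs["beta_out"].to_numpy() * sign
    w = 1.0 / pairs["se_out"].to_numpy() ** 2
    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    slope, slope_se = float(fit.params[1]), float(fit.bse[1])
    icpt, icpt_se = float(fit.params[0]), float(fit.bse[0])
    df = k - 2
    slope_p = float(2.0 * stats.t.sf(abs(slope / slope_se), df))
    icpt_p = float(2.0 * stats.t.sf(abs(icpt / icpt_se), df))
    est = MREstimate(exposure_id, outcome_id, METHOD_EGGER, k, slope,
                     slope_se, slope_p)
    return est, PleiotropyResult(icpt, icpt_se, icpt_p)


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta)
    theta, w = theta[order], w[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, theta))


def weighted_median(ratios: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                    exposure_id: str = "", outcome_id: str = "") -> MREstimate:
    """Bowden weighted-median estimator with a parametric-bootstrap SE."""
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError("weighted median requires >= 3 instruments")
    theta = ratios["theta"].to_numpy()
    w = ratios["w"].to_numpy()
    se_j = ratios["se"].to_numpy()
    beta = _weighted_median_point(theta, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_j, size=(n_boot, k))
    boots = np.array([_weighted_median_point(d, w) for d in draws])
    se = float(np.std(boots, ddof=1))
    return MREstimate(exposure_id, outcome_id, METHOD_WMEDIAN, k, beta, se,
                      _norm_p(beta / se) if se > 0 else 1.0)


def _silverman_bandwidths(theta: np.ndarray) -> np.ndarray:
    """Row-wise Silverman bandwidths for a (B, k) matrix of ratios."""
    n = theta.shape[1]
    sd = theta.std(axis=1, ddof=1)
    q75, q25 = np.quantile(theta, [0.75, 0.25], axis=1)
    iqr = q75 - q25
    spread = np.where(iqr > 0, np.minimum(sd, iqr / 1.34), sd)
    return 0.9 * spread * n ** (-0.2)


_KDE_GRID = 512
_KDE_GRID_BOOT = 128  # coarser grid for bootstrap replicates (SE only)


def _kde_modes(theta: np.ndarray, w: np.ndarray, h: np.ndarray,
               n_grid: int = _KDE_GRID) -> np.ndarray:
    """Row-wise Gaussian-kernel density modes for a (B, k) matrix."""
    B = theta.shape[0]
    modes = np.empty(B)
    degen = h <= 0  # all ratios (effectively) identical
    if degen.any():
        modes[degen] = np.average(theta[degen], axis=1, weights=w)
    live = ~degen
    if live.any():
        th, hh = theta[live], h[live]
        lo = th.min(axis=1) - 3 * hh
        hi = th.max(axis=1) + 3 * hh
        step = (hi - lo) / (n_grid - 1)
        grid = lo[:, None] + step[:, None] * np.arange(n_grid)[None, :]
        z = (grid[:, :, None] - th[:, None, :]) / hh[:, None, None]
        dens = (w[None, None, :] * np.exp(-0.5 * z**2)).sum(axis=2)
        modes[live] = np.take_along_axis(
            grid, dens.argmax(axis=1)[:, None], axis=1
        ).ravel()
    return modes


def mode_estimate(ratios: pd.DataFrame, weighted: bool = True,
                  bandwidth_factor: float = 1.0, n_boot: int = 1000,
                  seed: int = 0, exposure_id: str = "",
                  outcome_id: str = "") -> MREstimate:
    """Mode of the per-SNP ratio density (Gaussian kernel, Silverman rule).

    ``weighted=True`` weights each ratio by its IVW weight (the "weighted
    mode"); ``weighted=False`` is the "simple mode".
    """
    k = len(ratios)
    if k < 3:
        raise InsufficientInstrumentsError("mode estimators require >= 3 instruments")
    theta = ratios["theta"].to_numpy()
    se_j = ratios["se"].to_numpy()
    w = ratios["w"].to_numpy() if weighted else np.ones(k)
    point = theta[None, :]
    beta = float(_kde_modes(point, w, bandwidth_factor * _silverman_bandwidths(point))[0])
    rng = np.random.default_rng(seed)
    draws = rng.normal(theta, se_j, size=(n_boot, k))
    boots = _kde_modes(draws, w, bandwidth_factor * _silverman_bandwidths(draws),
                       n_grid=_KDE_GRID_BOOT)
    se = float(np.std(boots, ddof=1))
    method = METHOD_WMODE if weighted else METHOD_SMODE
    return MREstimate(exposure_id, outcome_id, method, k, beta, se,
                      _norm_p(beta / se) if se > 0 else 1.0)


def cochran_q(ratios: pd.DataFrame, ivw_beta: float) -> HeterogeneityResult:
    """Q = sum w_j (theta_j - beta_IVW)^2, chi-square with k - 1 df."""
    k = len(ratios)
    if k < 2:
        raise InsufficientInstrumentsError("Cochran's Q requires >= 2 instruments")
    Q = float(np.sum(ratios["w"] * (ratios["theta"] - ivw_beta) ** 2))
    df = k - 1
    return HeterogeneityResult(Q, df, float(stats.chi2.sf(Q, df)))


def or_from_beta(beta: float, se: float) -> Tuple[float, float, float]:
    """(OR, 95% CI low, 95% CI high) on the exponentiated scale."""
    if se < 0:
        raise ValidationError("se must be >= 0")
    return (math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))


def _prune_outliers(ratios: pd.DataFrame, alpha: float) -> Tuple[pd.DataFrame, List[str]]:
    """Leave-one-out Q minimization while heterogeneity is significant."""
    removed: List[str] = []
    while len(ratios) > 2:
        beta = float(np.sum(ratios["w"] * ratios["theta"]) / np.sum(ratios["w"]))
        het = cochran_q(ratios, beta)
        if het.p >= alpha:
            break
        best_q, best_idx = np.inf, None
        for idx in ratios.index:
            sub = ratios.drop(index=idx)
            b = float(np.sum(sub["w"] * sub["theta"]) / np.sum(sub["w"]))
            q = float(np.sum(sub["w"] * (sub["theta"] - b) ** 2))
            if q < best_q:
                best_q, best_idx = q, idx
        removed.append(str(ratios.loc[best_idx, "rsid"]))
        ratios = ratios.drop(index=best_idx)
    return ratios, removed


def run_mr(pairs: pd.DataFrame, exposure_id: str, outcome_id: str,
           cfg: MRConfig = MRConfig()) -> MRReport:
    """Dispatch estimators by instrument count.

    k = 1: Wald ratio. k in {2..4}: IVW plus Cochran's Q. k >= 5: IVW,
    MR-Egger, weighted median, weighted mode and simple mode, plus Q and the
    Egger-intercept pleiotropy test. Heterogeneity outliers are pruned first
    (leave-one-out Q minimization) when ``cfg.prune_outliers``.
    """
    if len(pairs) == 0:
        return MRReport(exposure_id, outcome_id, [], seed=cfg.seed)
    if len(pairs) == 1:
        est = wald_ratio(pairs.iloc[0], exposure_id, outcome_id,
                         cfg.second_order_wald_se)
        return MRReport(exposure_id, outcome_id, [est], seed=cfg.seed)

    ratios = ratio_estimates(pairs, cfg.second_order_wald_se)
    removed: List[str] = []
    if cfg.prune_outliers:
        ratios, removed = _prune_outliers(ratios, cfg.outlier_q_alpha)
        pairs = pairs[~pairs["rsid"].isin(removed)].reset_index(drop=True)
    k = len(ratios)
    if k == 1:
        est = wald_ratio(pairs.iloc[0], exposure_id, outcome_id,
                         cfg.second_order_wald_se)
        return MRReport(exposure_id, outcome_id, [est],
                        removed_outliers=removed, seed=cfg.seed)

    if cfg.ivw_mode == "auto":
        mode = "fixed" if k <= 3 else "multiplicative_re"
    else:
        mode = cfg.ivw_mode
    main = ivw(ratios, mode, exposure_id, outcome_id)
    het = cochran_q(ratios, ivw(ratios, "fixed").beta)
    estimates = [main]
    pleio = None
    if k >= 5:
        egger_est, pleio = egger_regression(pairs, exposure_id, outcome_id)
        estimates.append(egger_est)
        estimates.append(weighted_median(ratios, cfg.n_boot, cfg.seed,
                                         exposure_id, outcome_id))
        estimates.append(mode_estimate(ratios, True, cfg.bandwidth_factor,
                                       cfg.n_boot, cfg.seed + 1,
                                       exposure_id, outcome_id))
        estimates.append(mode_estimate(ratios, False, cfg.bandwidth_factor,
                                       cfg.n_boot, cfg.seed + 2,
                                       exposure_id, outcome_id))
    return MRReport(exposure_id, outcome_id, estimates, heterogeneity=het,
                    pleiotropy=pleio, removed_outliers=removed, seed=cfg.seed)
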