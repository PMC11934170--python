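"""Expression-based validation of the screened targets.

The validation stage merges log2 expression matrices from several
microarray series, removes batch effects with a parametric empirical-Bayes
location-scale adjustment (the ComBat model), scores every sample against
the risk and resistance gene sets with a rank-based single-sample
enrichment statistic (GSVA-inspired: Gaussian-kernel CDF normalization
followed by a weighted Kolmogorov-Smirnov walk; not bit-compatible with the
R gsva package), splits the diabetic-nephropathy samples at the median of
``risk score - resistance score``, and tests genes between the high and low
halves with an empirical-Bayes moderated t-statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import MergeError, ScoringError, ValidationError

__all__ = [
    "ExpressionMatrix", "GeneSet", "merge_batches", "combat_adjust",
    "set_score", "risk_enrichment", "median_split", "moderated_t_de",
    "read_expression_tsv", "read_gmt", "write_gmt",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with batch and group labels.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    ``batch`` and ``group`` are Series indexed by sample id, ``group``
    taking values ``"control"`` / ``"DN"``.
    """

    values: pd.DataFrame
    batch: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        samples = list(self.values.columns)
        for name, series in (("batch", self.batch), ("group", self.group)):
            missing = [s for s in samples if s not in series.index]
            if missing:
                raise ValidationError(f"{name} labels missing for {missing[:3]}...")
        self.batch = self.batch.loc[samples]
        self.group = self.group.loc[samples]
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene symbols")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        bad = set(self.group) - {"control", "DN"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def genes(self) -> List[str]:
        return list(self.values.index)

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    def restrict_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(samples)], self.batch.loc[list(samples)],
            self.group.loc[list(samples)],
        )


@dataclass
class GeneSet:
    name: str
    members: frozenset

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")


def merge_batches(matrices: Sequence[ExpressionMatrix]) -> ExpressionMatrix:
    """Join matrices on the intersection of their gene symbols.

    Samples are concatenated; batch and group labels are preserved. Raises
    :class:`MergeError` when the gene intersection is empty.
    """
    if len(matrices) < 2:
        raise ValidationError("merge_batches needs >= 2 matrices")
    common: Optional[set] = None
    for m in matrices:
        common = set(m.genes) if common is None else common & set(m.genes)
    if not common:
        raise MergeError("no genes shared across all matrices")
    genes = [g for g in matrices[0].genes if g in common]
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    if values.columns.duplicated().any():
        raise ValidationError("duplicate sample ids across matrices")
    batch = pd.concat([m.batch for m in matrices])
    group = pd.concat([m.group for m in matrices])
    return ExpressionMatrix(values, batch, group)


# ---------------------------------------------------------------------------
# parametric empirical-Bayes batch adjustment (ComBat location-scale model)
# ---------------------------------------------------------------------------

def _combat_priors(gamma_hat: np.ndarray, delta_hat: np.ndarray):
    gamma_bar = gamma_hat.mean()
    tau2 = gamma_hat.var(ddof=1)
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    a = (2.0 * s2 + m**2) / s2
    b = (m * s2 + m**3) / s2
    return gamma_bar, tau2, a, b


def _combat_itsol(Z: np.ndarray, gamma_hat: np.ndarray, delta_hat: np.ndarray,
                  gamma_bar: float, tau2: float, a: float, b: float,
                  tol: float = 1e-4, max_iter: int = 100):
    n = Z.shape[1]
    g_old, d_old = gamma_hat.copy(), delta_hat.copy()
    for _ in range(max_iter):
        g_new = (n * tau2 * gamma_hat + d_old * gamma_bar) / (n * tau2 + d_old)
        sum2 = ((Z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max() if np.abs(g_old).max() else 0.0,
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def combat_adjust(m: ExpressionMatrix, parametric: bool = True) -> ExpressionMatrix:
    """Remove batch effects with the parametric empirical-Bayes model.

    Per gene, fit a location-scale model with batch indicators and the
    control/DN group as a biological covariate; shrink the per-batch
    location (normal prior) and scale (inverse-gamma prior) estimates
    toward their batch-wide means; subtract the shrunken batch effects and
    restore the covariate fit. A single batch is returned unchanged with a
    warning; a batch with fewer than two samples raises.
    """
    if not parametric:
        raise NotImplementedError("only the parametric adjustment is provided")
    batches = list(dict.fromkeys(m.batch))
    if len(batches) < 2:
        warnings.warn("single batch: combat_adjust is a no-op")
        return ExpressionMatrix(m.values.copy(), m.batch, m.group)
    counts = m.batch.value_counts()
    small = counts[counts < 2]
    if not small.empty:
        raise ValidationError(
            f"batch scale inestimable with a single sample: {list(small.index)}"
        )

    Y = m.values.to_numpy(dtype=float)
    G, N = Y.shape
    batch_idx = [np.flatnonzero((m.batch == b).to_numpy()) for b in batches]
    n_b = np.array([len(ix) for ix in batch_idx], dtype=float)

    # design: batch indicators + group covariate (control/DN)
    Xb = np.zeros((N, len(batches)))
    for j, ix in enumerate(batch_idx):
        Xb[ix, j] = 1.0
    grp = (m.group == "DN").to_numpy(dtype=float)[:, None]
    X = np.hstack([Xb, grp])
    B_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (len(batches)+1, G)

    weights = n_b / N
    grand_mean = weights @ B_hat[: len(batches)]  # per gene
    resid = Y - (X @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] + np.outer(B_hat[len(batches)], grp.ravel())
    Z = (Y - stand_mean) / np.sqrt(var_pooled)[:, None]

    adjusted = Y.astype(float).copy()
    for j, ix in enumerate(batch_idx):
        Zb = Z[:, ix]
        gamma_hat = Zb.mean(axis=1)
        delta_hat = Zb.var(axis=1, ddof=1)
        delta_hat = np.maximum(delta_hat, 1e-12)
        gamma_bar, tau2, a, b = _combat_priors(gamma_hat, delta_hat)
        gamma_star, delta_star = _combat_itsol(
            Zb, gamma_hat, delta_hat, gamma_bar, tau2, a, b
        )
        adj = (Zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]
        adjusted[:, ix] = adj * np.sqrt(var_pooled)[:, None] + stand_mean[:, ix]

    values = pd.DataFrame(adjusted, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, m.batch, m.group)


# ---------------------------------------------------------------------------
# single-sample gene-set enrichment
# ---------------------------------------------------------------------------

def _kernel_cdf_stat(values: np.ndarray) -> np.ndarray:
    """Cross-sample Gaussian-kernel CDF per gene (bandwidth = sd/4)."""
    G, N = values.shape
    out = np.empty_like(values, dtype=float)
    sds = values.std(axis=1, ddof=1)
    for g in range(G):
        h = sds[g] / 4.0
        row = values[g]
        if h <= 0:
            out[g] = 0.5  # constant gene: uninformative
            continue
        out[g] = special.ndtr((row[:, None] - row[None, :]) / h).mean(axis=1)
    return out


def set_score(m: ExpressionMatrix, gs: GeneSet, tau: float = 1.0) -> pd.Series:
    """Per-sample enrichment score of one gene set.

    Genes are normalized across samples with a Gaussian-kernel CDF, ranked
    within each sample, and scored with a weighted KS walk: set genes add
    ``|G/2 - rank + 1/2|^tau`` (normalized over the set), non-set genes
    subtract ``1/(G - |set|)``; the score is the maximum positive plus the
    minimum negative running deviation.
    """
    genes = m.genes
    members = gs.members & set(genes)
    if not members:
        raise ScoringError(f"gene set {gs.name!r} shares no genes with the matrix")
    G = len(genes)
    S = len(members)
    if S == G:
        warnings.warn(f"gene set {gs.name!r} covers every gene; score is 0")
        return pd.Series(0.0, index=m.samples, name=gs.name)
    if len(m.samples) < 2:
        raise ScoringError("set_score needs >= 2 samples for normalization")

    z = _kernel_cdf_stat(m.values.to_numpy(dtype=float))
    in_set = np.array([g in members for g in genes])
    scores = np.empty(len(m.samples))
    for j in range(len(m.samples)):
        order = np.argsort(-z[:, j], kind="stable")
        pos = np.arange(1, G + 1)
        rank_weight = np.abs(G / 2.0 - pos + 0.5) ** tau
        set_mask = in_set[order]
        inc = np.where(set_mask, rank_weight, 0.0)
        denom = inc.sum()
        steps = inc / denom - (~set_mask) / (G - S)
        walk = np.cumsum(steps)
        scores[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.Series(scores, index=m.samples, name=gs.name)


def risk_enrichment(m: ExpressionMatrix, risk: GeneSet,
                    resistance: GeneSet, tau: float = 1.0) -> pd.DataFrame:
    """Per-sample ``es_risk - es_resistance`` scores."""
    es_risk = set_score(m, risk, tau)
    es_res = set_score(m, resistance, tau)
    return pd.DataFrame(
        {
            "es_risk": es_risk,
            "es_resistance": es_res,
            "risk_enrichment": es_risk - es_res,
        }
    )


def median_split(scores: pd.Series) -> pd.Series:
    """Split at the median: above -> ``"high"``, at or below -> ``"low"``."""
    if len(scores) < 2:
        raise ValidationError("median_split needs >= 2 samples")
    med = scores.median()
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="split"
    )


# ---------------------------------------------------------------------------
# moderated-t differential expression
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df1: float) -> Tuple[float, float]:
    """Moment-match a scaled F prior to the sample variances.

    Returns ``(d0, s0^2)``: the prior df (may be inf) and prior variance.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    z = z - special.digamma(df1 / 2.0) + np.log(df1 / 2.0)
    emean = z.mean()
    evar = z.var(ddof=1) - special.polygamma(1, df1 / 2.0)
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_t_de(m: ExpressionMatrix, labels: pd.Series,
                   prior_df: Optional[float] = None) -> pd.DataFrame:
    """Two-group moderated-t differential expression (high vs low).

    Per gene, the pooled two-sample variance ``s_g^2`` (``d_g`` residual df)
    is shrunk toward a prior ``s_0^2`` whose df ``d_0`` is estimated by
    moment-matching on ``log s_g^2``; the moderated t uses the posterior
    variance and ``d_0 + d_g`` df. ``prior_df`` overrides the estimated
    ``d_0`` (0 disables shrinkage and recovers the ordinary t). Returns a
    frame with columns ``gene, logFC, t, p, q`` where ``logFC`` is
    high minus low and ``q`` is the BH adjustment over all genes.
    """
    labels = labels.loc[m.samples]
    hi = m.values.loc[:, (labels == "high").to_numpy()].to_numpy(dtype=float)
    lo = m.values.loc[:, (labels == "low").to_numpy()].to_numpy(dtype=float)
    n1, n2 = hi.shape[1], lo.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need >= 2 samples per group")
    d_g = n1 + n2 - 2
    logfc = hi.mean(axis=1) - lo.mean(axis=1)
    s2 = (hi.var(axis=1, ddof=1) * (n1 - 1) + lo.var(axis=1, ddof=1) * (n2 - 1)) / d_g

    if prior_df is None:
        d0, s02 = _fit_f_dist(s2, d_g)
    else:
        d0 = float(prior_df)
        s02 = float(np.median(s2)) if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s02 + d_g * s2) / (d0 + d_g)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    df_total = d0 + d_g
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.nextafter(0, 1), 1.0)
    from .screening import bh_adjust

    return pd.DataFrame(
        {"gene": m.genes, "logFC": logfc, "t": t, "p": p, "q": bh_adjust(p)}
    )


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def read_expression_tsv(values_path, annotation_path) -> ExpressionMatrix:
    """Genes-as-rows TSV plus a (sample, batch, group) annotation TSV."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
    for col in ("batch", "group"):
        if col not in ann.columns:
            raise ValidationError(f"annotation file lacks a {col!r} column")
    return ExpressionMatrix(values, ann["batch"], ann["group"])


def write_expression_tsv(m: ExpressionMatrix, values_path, annotation_path) -> None:
    m.values.to_csv(values_path, sep="\t")
    pd.DataFrame({"batch": m.batch, "group": m.group}).rename_axis("sample").to_csv(
        annotation_path, sep="\t"
    )


def read_gmt(path) -> Dict[str, GeneSet]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: Dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = GeneSet(parts[0], frozenset(parts[2:]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path, description: str = "mitomr") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description] + sorted(gs.members)) + "\n")
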