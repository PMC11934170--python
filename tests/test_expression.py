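import subprocess

import numpy as np
import pandas as pd
import pytest

from mitomr.errors import MergeError, ScoringError, ValidationError
from mitomr.expression import (
    ExpressionMatrix, GeneSet, combat_adjust, median_split, merge_batches,
    moderated_t_de, risk_enrichment, set_score,
)


def _matrix(values, batch=None, group=None, prefix="s"):
    values = np.asarray(values, float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    cols = [f"{prefix}{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=cols)
    batch = pd.Series(batch or "b0", index=cols)
    group = pd.Series(group or "DN", index=cols)
    return ExpressionMatrix(df, batch, group)


def _two_batch(G=400, n=8, shift=2.0, group_effect=0.0, seed=0):
    """Two batches, balanced control/DN groups, known injected effects."""
    rng = np.random.default_rng(seed)
    vals = rng.normal(8, 1, size=(G, 2 * n))
    vals[:, n:] += shift
    grp = np.array(["control"] * (n // 2) + ["DN"] * (n // 2))
    groups = list(grp) * 2
    if group_effect:
        dn = np.array([g == "DN" for g in groups])
        vals[:50, dn] += group_effect
    cols = [f"s{j}" for j in range(2 * n)]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=[f"G{i}" for i in range(G)], columns=cols),
        pd.Series(["b0"] * n + ["b1"] * n, index=cols),
        pd.Series(groups, index=cols),
    )


class TestMergeBatches:
    def test_intersection_join(self):
        a = _matrix(np.zeros((5, 2)), prefix="a")
        b = _matrix(np.zeros((5, 2)), prefix="b")
        b.values.index = ["G2", "G3", "G4", "G5", "G6"]
        b.values = b.values  # reindex applied above
        merged = merge_batches([a, b])
        assert merged.genes == ["G2", "G3", "G4"]
        assert len(merged.samples) == 4

    def test_disjoint_genes_error(self):
        a = _matrix(np.zeros((2, 2)), prefix="a")
        b = _matrix(np.zeros((2, 2)), prefix="b")
        b.values.index = ["H0", "H1"]
        with pytest.raises(MergeError):
            merge_batches([a, b])

    def test_column_concatenation(self):
        a = _matrix(np.ones((3, 2)), prefix="a")
        b = _matrix(np.ones((3, 3)), prefix="b")
        merged = merge_batches([a, b])
        assert merged.samples == ["a0", "a1", "b0", "b1", "b2"]


class TestCombatAdjust:
    def test_removes_injected_shift(self):
        m = _two_batch(shift=2.0, seed=1)
        adj = combat_adjust(m)

        def signed_shift(mat):
            b0 = mat.values.loc[:, (mat.batch == "b0").to_numpy()].mean(axis=1)
            b1 = mat.values.loc[:, (mat.batch == "b1").to_numpy()].mean(axis=1)
            return float((b1 - b0).mean())

        before, after = signed_shift(m), signed_shift(adj)
        assert before == pytest.approx(2.0, abs=0.2)
        assert abs(after) < 0.1 * abs(before)
        # per-gene mean differences also shrink
        def per_gene(mat):
            b0 = mat.values.loc[:, (mat.batch == "b0").to_numpy()].mean(axis=1)
            b1 = mat.values.loc[:, (mat.batch == "b1").to_numpy()].mean(axis=1)
            return (b1 - b0).abs().mean()

        assert per_gene(adj) < per_gene(m)

    def test_preserves_group_effect(self):
        m = _two_batch(shift=2.0, group_effect=1.0, seed=2)
        adj = combat_adjust(m)
        dn = (adj.group == "DN").to_numpy()
        effect = (
            adj.values.iloc[:50, dn].mean(axis=1)
            - adj.values.iloc[:50, ~dn].mean(axis=1)
        ).mean()
        assert effect == pytest.approx(1.0, abs=0.1)

    def test_single_batch_noop_with_warning(self):
        m = _matrix(np.random.default_rng(0).normal(8, 1, (10, 6)))
        with pytest.warns(UserWarning):
            adj = combat_adjust(m)
        pd.testing.assert_frame_equal(adj.values, m.values)

    def test_singleton_batch_rejected(self):
        vals = np.random.default_rng(0).normal(8, 1, (10, 5))
        m = _matrix(vals, batch=["b0"] * 4 + ["b1"])
        with pytest.raises(ValidationError, match="single sample"):
            combat_adjust(m)

    def test_matches_bioconductor_reference(self, tmp_path):
        """Adjusted values agree with the Bioconductor empirical-Bayes
        reference implementation to numerical precision."""
        m = _two_batch(G=120, n=8, shift=2.0, group_effect=1.0, seed=11)
        path = tmp_path / "expr.tsv"
        m.values.to_csv(path, sep="\t")
        grp_r = ",".join(f'"{g}"' for g in m.group)
        r_code = f"""
        suppressMessages(library(sva))
        x <- as.matrix(read.delim("{path}", row.names=1))
        batch <- c(rep("b0",8), rep("b1",8))
        mod <- model.matrix(~factor(c({grp_r})))
        adj <- ComBat(dat=x, batch=batch, mod=mod, par.prior=TRUE)
        write.table(adj, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", r_code], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t").to_numpy()
        mine = combat_adjust(m).values.to_numpy()
        assert np.abs(mine - ref).max() < 1e-8


class TestSetScore:
    def test_top_expressed_set_scores_positive(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(100, 6))
        vals[:10, 0] += 4.0  # set genes top-ranked in sample 0
        m = _matrix(vals)
        gs = GeneSet("top", frozenset(f"G{i}" for i in range(10)))
        scores = set_score(m, gs)
        assert scores.iloc[0] > 0

    def test_all_genes_degenerate(self):
        m = _matrix(np.random.default_rng(0).normal(8, 1, (10, 4)))
        gs = GeneSet("all", frozenset(m.genes))
        with pytest.warns(UserWarning):
            scores = set_score(m, gs)
        assert (scores == 0).all()

    def test_unknown_genes_error(self):
        m = _matrix(np.random.default_rng(0).normal(8, 1, (10, 4)))
        with pytest.raises(ScoringError):
            set_score(m, GeneSet("none", frozenset({"ZZZ"})))

    def test_storage_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 1, (50, 5))
        m = _matrix(vals)
        gs = GeneSet("s", frozenset(f"G{i}" for i in range(0, 50, 7)))
        base = set_score(m, gs)
        perm = rng.permutation(50)
        m2 = ExpressionMatrix(m.values.iloc[perm], m.batch, m.group)
        assert set_score(m2, gs).to_numpy() == pytest.approx(base.to_numpy(), abs=1e-12)

    def test_affine_rescaling_invariance(self):
        """Per-gene positive affine transforms keep cross-sample ranks and
        (with bandwidth proportional to the SD) the kernel-CDF statistic."""
        rng = np.random.default_rng(2)
        vals = rng.normal(8, 1, (50, 6))
        m = _matrix(vals)
        gs = GeneSet("s", frozenset(f"G{i}" for i in range(12)))
        base = set_score(m, gs)
        a = rng.uniform(0.5, 3.0, 50)[:, None]
        b = rng.uniform(-2, 2, 50)[:, None]
        m2 = _matrix(vals * a + b)
        assert set_score(m2, gs).to_numpy() == pytest.approx(base.to_numpy(), abs=1e-9)


class TestRiskEnrichment:
    def test_antisymmetry_exact(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.normal(8, 1, (60, 8)))
        risk = GeneSet("risk", frozenset(f"G{i}" for i in range(10)))
        res = GeneSet("resistance", frozenset(f"G{i}" for i in range(20, 30)))
        fwd = risk_enrichment(m, risk, res)["risk_enrichment"]
        rev = risk_enrichment(m, res, risk)["risk_enrichment"]
        assert (fwd + rev == 0).all()

    def test_identical_sets_zero(self):
        m = _matrix(np.random.default_rng(4).normal(8, 1, (30, 5)))
        gs = GeneSet("risk", frozenset(f"G{i}" for i in range(8)))
        out = risk_enrichment(m, gs, GeneSet("resistance", gs.members))
        assert (out["risk_enrichment"] == 0).all()


class TestMedianSplit:
    @pytest.mark.parametrize(
        "scores, high",
        [
            ([1, 2, 3, 4], ["s2", "s3"]),
            ([1, 2, 2, 3], ["s3"]),  # ties at the median go low
            ([0, 1], ["s1"]),
        ],
    )
    def test_examples(self, scores, high):
        s = pd.Series(scores, index=[f"s{i}" for i in range(len(scores))],
                      dtype=float)
        labels = median_split(s)
        assert sorted(labels[labels == "high"].index) == high
        assert set(labels) <= {"high", "low"}
        assert len(labels) == len(s)


class TestModeratedT:
    def _labels(self, n1, n2):
        cols = [f"s{j}" for j in range(n1 + n2)]
        return pd.Series(["high"] * n1 + ["low"] * n2, index=cols)

    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(5)
        m = _matrix(rng.normal(8, 1, (100, 12)))
        labels = self._labels(6, 6)
        out = moderated_t_de(m, labels, prior_df=0.0)
        hi = m.values.iloc[:, :6].to_numpy()
        lo = m.values.iloc[:, 6:].to_numpy()
        s2 = (hi.var(1, ddof=1) + lo.var(1, ddof=1)) / 2
        t_ref = (hi.mean(1) - lo.mean(1)) / np.sqrt(s2 * (2 / 6))
        assert out["t"].to_numpy() == pytest.approx(t_ref, abs=1e-9)

    def test_large_prior_df_pools_variances(self):
        rng = np.random.default_rng(6)
        m = _matrix(rng.normal(8, 1, (100, 12)))
        out = moderated_t_de(m, self._labels(6, 6), prior_df=1e9)
        # posterior variances collapse to a single pooled value
        hi = m.values.iloc[:, :6].to_numpy()
        lo = m.values.iloc[:, 6:].to_numpy()
        logfc = hi.mean(1) - lo.mean(1)
        ratio = (out["t"] / logfc).to_numpy()
        assert np.ptp(ratio) < 1e-6

    def test_power_and_fdr_on_known_truth(self):
        rng = np.random.default_rng(7)
        G, n = 2000, 10
        vals = rng.normal(8, 1, size=(G, 2 * n))
        vals[:100, :n] += 2.0  # 100 true DE genes at 2 SD
        m = _matrix(vals)
        out = moderated_t_de(m, self._labels(n, n))
        called = set(out.loc[out["q"] < 0.05, "gene"])
        truth = {f"G{i}" for i in range(100)}
        fdr = len(called - truth) / max(len(called), 1)
        sensitivity = len(called & truth) / 100
        assert fdr <= 0.10
        assert sensitivity >= 0.6

    def test_matches_bioconductor_reference(self, tmp_path):
        """Moderated t, p and the estimated prior agree with the
        Bioconductor reference implementation."""
        rng = np.random.default_rng(8)
        G, n = 200, 6
        sd = rng.uniform(0.3, 2.0, G)
        vals = rng.normal(8, 1, (G, 2 * n)) * sd[:, None]
        vals[:20, :n] += 1.5
        m = _matrix(vals)
        path = tmp_path / "expr.tsv"
        m.values.to_csv(path, sep="\t")
        r_code = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{path}", row.names=1))
        design <- cbind(Intercept=1, hi=c(rep(1,{n}), rep(0,{n})))
        fit <- eBayes(lmFit(x, design))
        out <- data.frame(gene=rownames(x), t=fit$t[,"hi"],
                          p=fit$p.value[,"hi"])
        write.table(out, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE,
                    row.names=FALSE)
        """
        subprocess.run(["Rscript", "-e", r_code], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t")
        mine = moderated_t_de(m, self._labels(n, n))
        merged = mine.merge(ref, on="gene", suffixes=("_py", "_r"))
        assert np.abs(merged["t_py"] - merged["t_r"]).max() < 1e-8
        assert np.abs(merged["p_py"] - merged["p_r"]).max() < 1e-8

    def test_null_simulation_controls_fdr(self):
        rates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m = _matrix(rng.normal(8, 1, size=(500, 12)))
            out = moderated_t_de(m, self._labels(6, 6))
            rates.append((out["q"] < 0.05).mean())
        assert np.mean(rates) <= 0.01
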