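import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitomr.errors import InsufficientInstrumentsError, ValidationError
from mitomr.mr import (
    METHOD_EGGER, METHOD_IVW, METHOD_SMODE, METHOD_WALD, METHOD_WMEDIAN,
    METHOD_WMODE, MRConfig, cochran_q, egger_regression, ivw, mode_estimate,
    or_from_beta, ratio_estimates, run_mr, wald_ratio, weighted_median,
)


def _ratios(theta, se):
    theta, se = np.asarray(theta, float), np.asarray(se, float)
    return pd.DataFrame(
        {"rsid": [f"rs{i}" for i in range(len(theta))], "theta": theta,
         "se": se, "w": 1.0 / se**2}
    )


def _pairs(beta_exp, beta_out, se_out, se_exp=None):
    beta_exp = np.asarray(beta_exp, float)
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(len(beta_exp))],
            "beta_exp": beta_exp,
            "se_exp": se_exp if se_exp is not None else np.full(len(beta_exp), 0.01),
            "beta_out": np.asarray(beta_out, float),
            "se_out": np.asarray(se_out, float),
        }
    )


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01,
                          "beta_out": 0.02, "se_out": 0.01})
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_outcome_effect(self):
        est = wald_ratio({"beta_exp": 0.1, "se_exp": 0.01,
                          "beta_out": 0.0, "se_out": 0.01})
        assert est.beta == 0.0
        assert est.or_ == 1.0

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValidationError):
            wald_ratio({"beta_exp": 0.0, "se_exp": 0.01,
                        "beta_out": 0.1, "se_out": 0.01})

    def test_published_or_aco2(self):
        # a creatinine association reported as beta -0.1236, OR 0.884
        assert math.exp(-0.1236) == pytest.approx(0.884, abs=5e-4)


class TestIVW:
    def test_closed_form_two_snps(self):
        est = ivw(_ratios([0.2, 0.3], [0.1, 0.1]))
        assert est.beta == pytest.approx(0.25)
        assert est.se == pytest.approx(1 / math.sqrt(200))

    def test_homogeneous_ratios(self):
        fixed = ivw(_ratios([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]))
        re = ivw(_ratios([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]),
                 mode="multiplicative_re")
        assert fixed.beta == pytest.approx(0.2)
        assert re.se == fixed.se  # RE scale floored at 1

    def test_single_ratio_rejected(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(_ratios([0.2], [0.1]))

    @given(data=st.data())
    def test_equals_wls_through_origin(self, data):
        """IVW is weighted least squares of beta_out on beta_exp without
        intercept, weights 1/se_out^2."""
        n = data.draw(st.integers(2, 10))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**20)))
        bx = rng.uniform(0.05, 0.5, n) * rng.choice([-1, 1], n)
        by = rng.normal(0.1 * bx, 0.05)
        sy = rng.uniform(0.01, 0.2, n)
        est = ivw(ratio_estimates(_pairs(bx, by, sy)))
        w = 1.0 / sy**2
        wls = np.sum(w * bx * by) / np.sum(w * bx**2)
        assert est.beta == pytest.approx(wls, abs=1e-10)


class TestEgger:
    def test_exact_linear_fit(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est, pleio = egger_regression(
            _pairs(bx, 0.01 + 0.3 * bx, np.full(4, 0.05))
        )
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert pleio.intercept == pytest.approx(0.01, abs=1e-10)

    def test_orients_negative_exposure_effects(self):
        bx = np.array([0.1, -0.2, 0.3, -0.4])
        est, pleio = egger_regression(
            _pairs(bx, 0.01 * np.sign(bx) + 0.3 * bx, np.full(4, 0.05))
        )
        assert est.beta == pytest.approx(0.3, abs=1e-10)
        assert pleio.intercept == pytest.approx(0.01, abs=1e-10)

    def test_proportional_data_null_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        rng = np.random.default_rng(0)
        by = 0.3 * bx + rng.normal(0, 1e-9, 4)
        _, pleio = egger_regression(_pairs(bx, by, np.full(4, 0.05)))
        assert abs(pleio.intercept) < 1e-8
        assert pleio.intercept_p > 0.5

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger_regression(_pairs([0.1, 0.2], [0.03, 0.06], [0.05, 0.05]))

    def test_published_or_fuca1(self):
        # an Egger slope reported as beta 0.0197, OR 1.02
        assert math.exp(0.0197) == pytest.approx(1.02, abs=5e-3)


class TestWeightedMedian:
    def test_equal_weights_interpolation(self):
        est = weighted_median(_ratios([0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))
        assert est.beta == pytest.approx(0.2)

    def test_constant_ratios(self):
        est = weighted_median(_ratios([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]),
                              n_boot=200, seed=1)
        again = weighted_median(_ratios([0.2, 0.2, 0.2], [0.1, 0.1, 0.1]),
                                n_boot=200, seed=1)
        assert est.beta == 0.2
        assert est.se == again.se  # seeded bootstrap reproducible
        assert est.se < 0.1  # ~ se_j / sqrt(k)

    def test_robust_to_outlier(self):
        # hand check: w = (100, 100, 69.4); cumulative standardized weights
        # (0.186, 0.557, 0.871) cross 0.5 between 0.1 and 0.2, so the
        # estimate interpolates to ~0.185 despite the huge outlier ratio
        est = weighted_median(_ratios([0.1, 0.2, 100.0], [0.1, 0.1, 0.12]))
        assert est.beta == pytest.approx(0.185, abs=0.01)
        assert est.beta < 1.0


class TestModeEstimators:
    def test_constant_ratios(self):
        est = mode_estimate(_ratios([0.2] * 4, [0.1] * 4), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-6)

    def test_majority_cluster_wins_unweighted(self):
        est = mode_estimate(
            _ratios([0.2, 0.2, 0.2, 0.9], [0.05] * 4),
            weighted=False, n_boot=100, seed=0,
        )
        assert est.beta == pytest.approx(0.2, abs=0.05)
        assert est.method == METHOD_SMODE

    def test_seeded_determinism(self):
        a = mode_estimate(_ratios([0.1, 0.25, 0.3, 0.35], [0.1] * 4), seed=42)
        b = mode_estimate(_ratios([0.1, 0.25, 0.3, 0.35], [0.1] * 4), seed=42)
        assert (a.beta, a.se, a.p) == (b.beta, b.se, b.p)


class TestCochranQ:
    def test_hand_computation(self):
        het = cochran_q(_ratios([0.2, 0.3], [0.1, 0.1]), ivw_beta=0.25)
        assert het.Q == pytest.approx(0.5)
        assert het.df == 1

    def test_homogeneous(self):
        het = cochran_q(_ratios([0.2, 0.2, 0.2], [0.1] * 3), ivw_beta=0.2)
        assert het.Q == pytest.approx(0.0, abs=1e-12)
        assert het.p == pytest.approx(1.0)

    def test_monotone_in_divergence(self):
        qs = [
            cochran_q(_ratios([0.2, 0.2 + d], [0.1, 0.1]),
                      ivw_beta=0.2 + d / 2).Q
            for d in (0.0, 0.1, 0.2, 0.4)
        ]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestORReporting:
    @pytest.mark.parametrize(
        "beta, expected",
        [(0.0, 1.0), (-0.1666, 0.847), (0.1931, 1.213)],
    )
    def test_published_rows(self, beta, expected):
        or_, lo, hi = or_from_beta(beta, 0.0)
        assert or_ == pytest.approx(expected, abs=5e-4)

    def test_roundtrip(self):
        or_, lo, hi = or_from_beta(0.1931, 0.023)
        assert math.log(or_) == pytest.approx(0.1931, abs=1e-12)
        assert lo < or_ < hi


class TestRunMR:
    def test_single_instrument_dispatch(self):
        report = run_mr(_pairs([0.1], [0.02], [0.01]), "X", "Y")
        assert [e.method for e in report.estimates] == [METHOD_WALD]
        assert report.estimates[0].nsnp == 1

    def test_two_instruments_dispatch(self):
        report = run_mr(_pairs([0.1, 0.2], [0.02, 0.04], [0.01, 0.01]),
                        "X", "Y")
        assert [e.method for e in report.estimates] == [METHOD_IVW]
        assert report.estimates[0].nsnp == 2
        assert report.heterogeneity is not None

    def test_five_method_tier(self):
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.1, 0.3, 8)
        by = 0.2 * bx + rng.normal(0, 0.002, 8)
        report = run_mr(_pairs(bx, by, np.full(8, 0.01)), "X", "Y",
                        MRConfig(n_boot=100))
        methods = {e.method for e in report.estimates}
        assert methods == {METHOD_IVW, METHOD_EGGER, METHOD_WMEDIAN,
                           METHOD_WMODE, METHOD_SMODE}
        assert report.pleiotropy is not None

    def test_outlier_pruning_logged(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.3, 6)
        by = 0.2 * bx + rng.normal(0, 0.002, 6)
        by[0] += 0.5  # gross heterogeneity from one variant
        report = run_mr(_pairs(bx, by, np.full(6, 0.01)), "X", "Y",
                        MRConfig(n_boot=100))
        assert "rs0" in report.removed_outliers

    def test_empty_pairs_skipped(self):
        report = run_mr(_pairs([], [], []), "X", "Y")
        assert report.estimates == []
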