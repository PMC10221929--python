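"""Causal estimators: worked examples, oracle equivalence, equivariance."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from gutmr.estimators import (
    InsufficientInstrumentsError,
    _ivw_beta_se,
    _weighted_median_point,
    _weighted_mode_point,
    egger,
    ivw,
    mode_bandwidth,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from tests.conftest import make_instrument


class TestWaldRatio:
    def test_direct_division(self):
        est = wald_ratio(make_instrument(beta_exp=0.1, beta_out=0.02, se_out=0.01))
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        est = wald_ratio(make_instrument(beta_out=0.0))
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_sign_convention(self):
        est = wald_ratio(make_instrument(beta_exp=-0.1, beta_out=0.02))
        assert est.beta == pytest.approx(-0.2)

    def test_confidence_interval_brackets_or(self):
        est = wald_ratio(make_instrument())
        assert est.ci_low < est.or_ < est.ci_high


class TestIVW:
    def test_derived_weighted_mean(self):
        hs = [
            make_instrument("rs1", 0.10, 0.020, 0.010),
            make_instrument("rs2", 0.20, 0.044, 0.010),
            make_instrument("rs3", 0.15, 0.033, 0.010),
        ]
        est = ivw(hs)
        # brute-force weighted mean with w = (bx/se_y)^2:
        # (100*0.2 + 400*0.22 + 225*0.22) / 725
        assert est.beta == pytest.approx(157.5 / 725, abs=1e-12)
        assert est.beta == pytest.approx(0.21724, abs=1e-5)

    def test_two_identical_instruments_give_common_ratio(self):
        hs = [make_instrument("rs1"), make_instrument("rs2")]
        assert ivw(hs).beta == pytest.approx(hs[0].ratio)

    def test_equal_weights_give_arithmetic_mean(self):
        hs = [
            make_instrument("rs1", 0.1, 0.01, 0.01),
            make_instrument("rs2", 0.1, 0.02, 0.01),
            make_instrument("rs3", 0.1, 0.03, 0.01),
        ]
        ratios = [h.ratio for h in hs]
        assert ivw(hs).beta == pytest.approx(np.mean(ratios))

    def test_single_instrument_redirects_to_wald(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw([make_instrument()])

    def test_single_ratio_limit_matches_wald(self):
        h = make_instrument()
        beta, _, _ = _ivw_beta_se(
            np.array([h.ratio]), np.array([h.ratio_se]) ** -2.0, "fixed"
        )
        assert beta == pytest.approx(wald_ratio(h).beta)

    def test_multiplicative_se_never_below_fixed(self, random_instruments):
        fixed = ivw(random_instruments, re_mode="fixed")
        mre = ivw(random_instruments, re_mode="multiplicative")
        assert mre.se >= fixed.se
        assert mre.beta == pytest.approx(fixed.beta)


class TestEgger:
    def test_exact_line_recovered(self):
        hs = [
            make_instrument(f"rs{i}", bx, 0.05 + 0.2 * bx, 0.01)
            for i, bx in enumerate([0.1, 0.2, 0.3])
        ]
        est = egger(hs)
        assert est.beta == pytest.approx(0.2, abs=1e-12)
        assert est.intercept == pytest.approx(0.05, abs=1e-12)

    def test_all_zero_outcome(self):
        hs = [make_instrument(f"rs{i}", 0.1 * (i + 1), 0.0, 0.01)
              for i in range(4)]
        est = egger(hs)
        assert est.beta == pytest.approx(0.0, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger([make_instrument("rs1"), make_instrument("rs2")])

    def test_orientation_invariance(self, random_instruments):
        """Negating both betas of any instrument leaves the fit unchanged."""
        flipped = [
            make_instrument(h.variant_id, -h.beta_exp, -h.beta_out,
                            h.se_out, h.se_exp, h.eaf_exp)
            for h in random_instruments
        ]
        a, b = egger(random_instruments), egger(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-10)


class TestOracleEquivalence:
    """IVW and Egger must agree with statsmodels WLS normal-equation
    solutions to 1e-10 on random instances."""

    def _random_set(self, rng, j=8):
        return [
            make_instrument(
                f"rs{i}",
                beta_exp=float(rng.uniform(0.05, 0.5) * rng.choice([-1, 1])),
                beta_out=float(rng.normal(0, 0.05)),
                se_out=float(rng.uniform(0.005, 0.05)),
            )
            for i in range(j)
        ]

    def test_ivw_matches_origin_constrained_wls(self, rng):
        for _ in range(100):
            hs = self._random_set(rng)
            bx = np.array([h.beta_exp for h in hs])
            by = np.array([h.beta_out for h in hs])
            sy = np.array([h.se_out for h in hs])
            fit = sm.WLS(by, bx, weights=sy**-2.0).fit()
            assert ivw(hs).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_egger_matches_free_intercept_wls(self, rng):
        for _ in range(100):
            hs = self._random_set(rng)
            flip = np.sign([h.beta_exp for h in hs])
            bx = np.array([h.beta_exp for h in hs]) * flip
            by = np.array([h.beta_out for h in hs]) * flip
            sy = np.array([h.se_out for h in hs])
            x = sm.add_constant(bx)
            fit = sm.WLS(by, x, weights=sy**-2.0).fit()
            est = egger(hs)
            assert est.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert est.beta == pytest.approx(fit.params[1], abs=1e-10)


class TestWeightedMedian:
    def test_equal_weights_plain_median(self):
        hs = [make_instrument(f"rs{i}", 1.0, 0.1 * r, 0.1)
              for i, r in enumerate([1, 2, 3])]
        est = weighted_median(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_two_point_interpolation(self):
        # s = {0.25, 0.75} -> linear interpolation at 0.5 gives the midpoint
        point = _weighted_median_point(
            np.array([0.1, 0.2]), np.array([1.0, 1.0])
        )
        assert point == pytest.approx(0.15)

    def test_dominant_weight_instrument_wins(self):
        hs = [
            make_instrument("rs1", 1.0, 0.30, 0.001),   # > 50% of the weight
            make_instrument("rs2", 0.1, 0.01, 0.01),
            make_instrument("rs3", 0.1, 0.02, 0.01),
        ]
        est = weighted_median(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.30, abs=1e-3)

    def test_bootstrap_se_reproducible(self, random_instruments):
        a = weighted_median(random_instruments, n_boot=200, seed=7)
        b = weighted_median(random_instruments, n_boot=200, seed=7)
        assert a.se == b.se > 0


class TestWeightedMode:
    def test_majority_cluster_ignores_outlier(self):
        hs = [make_instrument(f"rs{i}", 0.1, 0.1 * r, 0.01)
              for i, r in enumerate([0.2, 0.2, 0.2, 0.9])]
        est = weighted_mode(hs, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.2, abs=0.01)

    def test_constant_ratios_for_any_bandwidth(self):
        hs = [make_instrument(f"rs{i}", 0.1, 0.03, 0.01) for i in range(4)]
        for factor in (0.5, 1.0, 3.0):
            est = weighted_mode(hs, bandwidth_factor=factor, n_boot=50, seed=1)
            assert est.beta == pytest.approx(0.3, abs=1e-6)

    def test_zero_bandwidth_is_config_error(self):
        with pytest.raises(ValueError):
            mode_bandwidth(np.array([0.1, 0.2, 0.3]), bandwidth_factor=0.0)

    def test_argmax_matches_grid_oracle(self, rng):
        ratios = rng.normal(0.2, 0.1, size=7)
        weights = rng.uniform(0.5, 2.0, size=7)
        point = _weighted_mode_point(ratios, weights, 1.0)
        h = mode_bandwidth(ratios, 1.0)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 100_000)
        dens = (weights[None, :] * np.exp(
            -0.5 * ((grid[:, None] - ratios) / h) ** 2)).sum(axis=1)
        oracle = grid[int(np.argmax(dens))]
        assert point == pytest.approx(oracle, abs=grid[1] - grid[0])


@st.composite
def instrument_sets(draw):
    j = draw(st.integers(min_value=3, max_value=8))
    hs = []
    for i in range(j):
        # spread exposure effects apart so the Egger design stays full rank
        bx = draw(st.floats(min_value=0.05, max_value=0.15)) + 0.1 * i
        sign = draw(st.sampled_from([-1.0, 1.0]))
        by = draw(st.floats(min_value=-0.1, max_value=0.1))
        sy = draw(st.floats(min_value=0.005, max_value=0.05))
        hs.append(make_instrument(f"rs{i}", sign * bx, by, sy))
    return hs


class TestEquivariance:
    @given(instrument_sets())
    @settings(max_examples=20, deadline=None)
    def test_negating_outcome_negates_estimates(self, hs):
        neg = [make_instrument(h.variant_id, h.beta_exp, -h.beta_out,
                               h.se_out, h.se_exp, h.eaf_exp) for h in hs]
        assert ivw(neg).beta == pytest.approx(-ivw(hs).beta, rel=1e-9, abs=1e-12)
        assert egger(neg).beta == pytest.approx(-egger(hs).beta, rel=1e-9, abs=1e-12)
        wm_pos = weighted_median(hs, n_boot=10, seed=1).beta
        wm_neg = weighted_median(neg, n_boot=10, seed=1).beta
        assert wm_neg == pytest.approx(-wm_pos, rel=1e-9, abs=1e-12)

    @given(instrument_sets(), st.floats(min_value=0.5, max_value=3.0))
    @settings(max_examples=20, deadline=None)
    def test_scaling_exposure_divides_estimates(self, hs, c):
        scaled = [make_instrument(h.variant_id, c * h.beta_exp, h.beta_out,
                                  h.se_out, h.se_exp, h.eaf_exp) for h in hs]
        assert ivw(scaled).beta == pytest.approx(ivw(hs).beta / c, rel=1e-9,
                                                 abs=1e-12)
        assert egger(scaled).beta == pytest.approx(egger(hs).beta / c,
                                                   rel=1e-9, abs=1e-12)
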