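"""RMA regression, bootstrap percentile CIs, and the two-group D test."""

import numpy as np
import pytest

from stomapattern import (CSR_INTERCEPT, CSR_SLOPE, DEFAULT_WINDOW,
                          bootstrap_rma, compare_groups, rma_fit,
                          simulate_csr, window_stats)


def csr_scaling_data(rng, n_windows=224, count_range=(155, 437),
                     metric="toroidal"):
    """(ln MNND, ln SD) pairs from CSR windows over a density gradient."""
    lams = np.linspace(*count_range, n_windows)
    x = np.empty(n_windows)
    y = np.empty(n_windows)
    for i, lam in enumerate(lams):
        pat = simulate_csr(DEFAULT_WINDOW, lam / DEFAULT_WINDOW.area_um2, rng)
        while pat.n < 2:  # Poisson can realize < 2 only at absurd intensity
            pat = simulate_csr(DEFAULT_WINDOW,
                               lam / DEFAULT_WINDOW.area_um2, rng)
        st = window_stats(pat, metric=metric)
        x[i] = np.log(st.mnnd)
        y[i] = np.log(st.sd)
    return x, y


class TestRMAFit:
    def test_exact_positive_line(self):
        fit = rma_fit([0, 1, 2], [0, 2, 4])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_negative_line(self):
        fit = rma_fit([0, 1, 2], [2, 1, 0])
        assert fit.slope == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_slope_magnitude_is_sd_ratio(self, rng):
        x = rng.normal(0, 2.0, 50)
        y = 3.0 * x + rng.normal(0, 1.0, 50)
        fit = rma_fit(x, y)
        assert abs(fit.slope) == pytest.approx(
            y.std(ddof=1) / x.std(ddof=1), rel=1e-12)
        assert fit.intercept == pytest.approx(
            y.mean() - fit.slope * x.mean(), rel=1e-12)

    def test_swap_symmetry(self, rng):
        x = rng.normal(0, 1, 40)
        y = -2.0 * x + rng.normal(0, 0.5, 40)
        fwd = rma_fit(x, y)
        rev = rma_fit(y, x)
        assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=1e-12)

    def test_shift_equivariance(self, rng):
        x = rng.normal(5, 1, 30)
        y = 1.7 * x + rng.normal(0, 0.3, 30)
        base = rma_fit(x, y)
        shifted = rma_fit(x + 10.0, y)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-12)
        assert shifted.intercept == pytest.approx(
            base.intercept - base.slope * 10.0, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            rma_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="n >= 3"):
            rma_fit([0.0, 1.0], [0.0, 1.0])

    def test_prediction_inverts_log_transform(self):
        fit = rma_fit([0, 1, 2], [12, 10, 8])  # y = 12 - 2x
        assert fit.predict_density(np.e) == pytest.approx(np.exp(10.0))


class TestBootstrap:
    def test_collinear_data_gives_degenerate_ci(self):
        x = np.arange(10.0)
        fit = bootstrap_rma(x, 2.0 * x + 1.0, n_boot=200, seed=0)
        assert fit.ci_slope == pytest.approx((2.0, 2.0))
        assert fit.ci_intercept == pytest.approx((1.0, 1.0))

    def test_fixed_seed_is_bit_reproducible(self, rng):
        x = rng.normal(0, 1, 60)
        y = -2 * x + rng.normal(0, 0.2, 60)
        f1 = bootstrap_rma(x, y, n_boot=500, seed=42)
        f2 = bootstrap_rma(x, y, n_boot=500, seed=42)
        assert f1.ci_slope == f2.ci_slope
        assert f1.ci_intercept == f2.ci_intercept
        np.testing.assert_array_equal(f1.boot_slope, f2.boot_slope)

    def test_ci_bounds_ordered_and_bracket_typical_mass(self, rng):
        x = rng.normal(0, 1, 80)
        y = -2 * x + rng.normal(0, 0.3, 80)
        fit = bootstrap_rma(x, y, n_boot=1000, seed=3)
        assert fit.ci_slope[0] <= fit.ci_slope[1]
        inside = np.mean((fit.boot_slope >= fit.ci_slope[0])
                         & (fit.boot_slope <= fit.ci_slope[1]))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_cluster_bootstrap_respects_leaf_structure(self, rng):
        # variation lives entirely at the leaf level (windows of a leaf are
        # identical): the pair bootstrap overstates the effective sample
        # size 6-fold, so resampling leaves must widen the intercept CI
        leaves = np.repeat(np.arange(12), 6)
        leaf_x = rng.normal(3.5, 0.3, 12)
        leaf_y = 12.4 - 2.0 * leaf_x + rng.normal(0, 0.3, 12)
        x = leaf_x[leaves]
        y = leaf_y[leaves]
        pair = bootstrap_rma(x, y, n_boot=600, seed=21)
        clus = bootstrap_rma(x, y, n_boot=600, seed=21, clusters=leaves)
        assert clus.ci_intercept[0] <= clus.ci_intercept[1]
        width = lambda ci: ci[1] - ci[0]  # noqa: E731
        assert width(clus.ci_intercept) > width(pair.ci_intercept)
        again = bootstrap_rma(x, y, n_boot=600, seed=21, clusters=leaves)
        assert again.ci_intercept == clus.ci_intercept

    def test_sign_flip_maps_percentile_ci(self, rng):
        # percentile CI of a monotone (sign-flip) transform equals the
        # transformed, reordered bounds — same resamples via same seed
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 0.4, 50)
        up = bootstrap_rma(x, y, n_boot=400, seed=7)
        dn = bootstrap_rma(x, -y, n_boot=400, seed=7)
        assert dn.ci_slope[0] == pytest.approx(-up.ci_slope[1], rel=1e-12)
        assert dn.ci_slope[1] == pytest.approx(-up.ci_slope[0], rel=1e-12)

    def test_csr_recovery_of_theoretical_anchors(self, rng):
        # edge-bias-free CSR windows across a wide gradient recover the
        # Clark–Evans log–log line: slope −2, intercept ln(1e6/4)
        lams = np.exp(rng.uniform(np.log(2000), np.log(20000), 150))
        x = np.empty(150)
        y = np.empty(150)
        for i, lam in enumerate(lams):
            pat = simulate_csr(DEFAULT_WINDOW,
                               lam / DEFAULT_WINDOW.area_um2, rng)
            st = window_stats(pat, metric="toroidal")
            x[i], y[i] = np.log(st.mnnd), np.log(st.sd)
        fit = rma_fit(x, y)
        assert fit.slope == pytest.approx(CSR_SLOPE, abs=0.03)
        assert fit.intercept == pytest.approx(CSR_INTERCEPT, abs=0.12)
        assert fit.r_squared > 0.99

    def test_study_scale_attenuation_is_bounded(self, rng):
        # at study-scale per-window counts (155–437) the per-window MNND
        # sampling noise inflates s_x and attenuates the RMA slope a few
        # percent below 2 in magnitude — a documented small-sample effect
        x, y = csr_scaling_data(rng)
        fit = rma_fit(x, y)
        assert -2.05 < fit.slope < -1.88


class TestCompareGroups:
    def test_identical_groups_show_no_difference(self, rng):
        x = rng.normal(3.5, 0.15, 100)
        y = 12.4 - 2.0 * x + rng.normal(0, 0.05, 100)
        cmp = compare_groups(x, y, x, y, n_boot=800, seed=5)
        assert cmp.verdict_intercept == "no significant difference"
        assert cmp.verdict_slope == "no significant difference"
        assert cmp.ci_d_intercept[0] < 0 < cmp.ci_d_intercept[1]

    def test_injected_intercept_offset_is_detected(self, rng):
        # parameter-recovery oracle: group 2 = group 1 with y + 5
        x, y = csr_scaling_data(rng, n_windows=150)
        cmp = compare_groups(x, y, x, y + 5.0, n_boot=800, seed=5)
        assert cmp.verdict_intercept == "group2 larger"
        assert cmp.ci_d_intercept[1] < 0
        assert cmp.verdict_slope == "no significant difference"

    def test_verdict_rule_matches_ci(self, rng):
        x = rng.normal(0, 1, 60)
        y = 2 * x + rng.normal(0, 0.3, 60)
        cmp = compare_groups(x, y, x, y, n_boot=300, seed=9)
        for ci, verdict in ((cmp.ci_d_intercept, cmp.verdict_intercept),
                            (cmp.ci_d_slope, cmp.verdict_slope)):
            if ci[0] > 0:
                assert verdict == "group1 larger"
            elif ci[1] < 0:
                assert verdict == "group2 larger"
            else:
                assert verdict == "no significant difference"

    def test_streams_are_independent_but_seed_derived(self, rng):
        x = rng.normal(0, 1, 50)
        y = 2 * x + rng.normal(0, 0.3, 50)
        c1 = compare_groups(x, y, x, y, n_boot=200, seed=1)
        c2 = compare_groups(x, y, x, y, n_boot=200, seed=1)
        np.testing.assert_array_equal(c1.d_slope, c2.d_slope)
        # identical data, but different streams → replicates differ pairwise
        assert not np.allclose(c1.fit1.boot_slope, c1.fit2.boot_slope)
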