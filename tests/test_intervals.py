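import numpy as np
import pytest

from dgmean import (
    DeltaGammaParams,
    ci_difference,
    ci_single,
    equal_tailed_interval,
    hpd_interval,
    sample_delta_gamma,
)
from dgmean.intervals import _hpd_window


def hpd_oracle(draws, gamma):
    """Exhaustive first-minimum search over all sorted windows of the HPD size."""
    s = sorted(float(v) for v in draws)
    n = len(s)
    g = max(1, min(n - 1, int(np.round(n * (1 - gamma)))))
    best_i, best_w = 0, float("inf")
    for i in range(n - g):
        w = s[i + g] - s[i]
        if w < best_w:
            best_i, best_w = i, w
    return s[best_i], s[best_i + g]


class TestEqualTailed:
    def test_interpolated_quantile_rule(self):
        # h = 1 + 999 * 0.025 = 25.975 on draws 1..1000
        iv = equal_tailed_interval(np.arange(1, 1001, dtype=float), gamma=0.05)
        assert iv.lower == pytest.approx(25.975)
        assert iv.upper == pytest.approx(975.025)

    def test_constant_draws(self):
        iv = equal_tailed_interval(np.full(100, 3.5), gamma=0.05)
        assert (iv.lower, iv.upper) == (3.5, 3.5)

    def test_integer_positions_return_order_statistics(self):
        # gamma = 0.1 on 1..1001: h = 1 + 1000*0.05 = 51 exactly
        iv = equal_tailed_interval(np.arange(1, 1002, dtype=float), gamma=0.1)
        assert iv.lower == 51.0
        assert iv.upper == 951.0

    def test_requires_two_draws(self):
        with pytest.raises(ValueError):
            equal_tailed_interval([1.0], gamma=0.05)


class TestHpd:
    def test_all_windows_tie_first_wins(self):
        # on 1..100 every window of size 95 has width 95; the first is taken
        iv = hpd_interval(np.arange(1, 101, dtype=float), gamma=0.05)
        assert (iv.lower, iv.upper) == (1.0, 96.0)

    def test_constant_draws(self):
        iv = hpd_interval(np.full(50, -2.0), gamma=0.05)
        assert (iv.lower, iv.upper) == (-2.0, -2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_skewed_draws(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 2000))
        draws = rng.gamma(2.0, size=n) ** 2  # right-skewed
        iv = hpd_interval(draws, gamma=0.05)
        assert (iv.lower, iv.upper) == hpd_oracle(draws, 0.05)

    def test_matches_arviz_hdi(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(123)
        for n in (2000, 5000):  # 0.95*n integral: round and floor rules coincide
            draws = rng.gamma(3.0, size=n) ** 1.5
            iv = hpd_interval(draws, gamma=0.05)
            lo, hi = az.hdi(draws, hdi_prob=0.95)
            assert iv.lower == pytest.approx(lo, rel=1e-12)
            assert iv.upper == pytest.approx(hi, rel=1e-12)

    def test_window_size_clamped(self):
        assert _hpd_window(2, 0.05) == 1
        assert _hpd_window(100, 0.05) == 95
        assert _hpd_window(10, 1e-9) == 9

    @pytest.mark.parametrize("seed", range(10))
    def test_hpd_never_wider_than_equal_tailed(self, seed):
        rng = np.random.default_rng(100 + seed)
        draws = rng.lognormal(size=1500)
        hp = hpd_interval(draws, gamma=0.05)
        eq = equal_tailed_interval(draws, gamma=0.05)
        assert hp.width <= eq.width + 1e-12


class TestCiSingle:
    @pytest.mark.parametrize("method", ["jeffreys_credible", "jeffreys_hpd",
                                        "uniform_credible", "uniform_hpd", "fq"])
    def test_structural(self, method, rng):
        obs = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 60, rng)
        iv = ci_single(obs, method, ndraws=2000, rng=5)
        assert np.isfinite(iv.lower) and np.isfinite(iv.upper)
        assert iv.lower <= iv.upper
        assert iv.method == method
        assert iv.ndraws == 2000

    def test_uniform_needs_four_positives(self):
        obs = [0.0, 0.0, 1.0, 2.0, 3.0]  # n_pos = 3
        with pytest.raises(ValueError):
            ci_single(obs, "uniform_credible", rng=0)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            ci_single([1.0, 2.0, 3.0], "bootstrap", rng=0)

    def test_hpd_no_wider_than_credible_same_draws(self, rng):
        obs = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 60, rng)
        hp = ci_single(obs, "jeffreys_hpd", ndraws=4000, rng=9)
        eq = ci_single(obs, "jeffreys_credible", ndraws=4000, rng=9)
        assert hp.width <= eq.width + 1e-12

    def test_fq_scale_equivariance(self, rng):
        # scaling the data by c^3 scales cube-root statistics by c and the
        # fiducial gamma-mean draws by c^3, so bounds scale exactly by c^3
        obs = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 60, rng)
        c3 = 2.7**3
        base = ci_single(obs, "fq", ndraws=2000, rng=17)
        scaled = ci_single(obs * c3, "fq", ndraws=2000, rng=17)
        assert scaled.lower == pytest.approx(base.lower * c3, rel=1e-10)
        assert scaled.upper == pytest.approx(base.upper * c3, rel=1e-10)


class TestCiDifference:
    def test_swap_gives_sign_flipped_interval(self, rng):
        a = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 40, rng)
        b = sample_delta_gamma(DeltaGammaParams(2.0, 1.0, 0.5), 60, rng)
        fwd = ci_difference(a, b, "fq", ndraws=2000, seed=7)
        rev = ci_difference(b, a, "fq", ndraws=2000, seed=7)
        assert rev.lower == pytest.approx(-fwd.upper, rel=1e-12)
        assert rev.upper == pytest.approx(-fwd.lower, rel=1e-12)

    def test_identical_inputs_degenerate_at_zero(self, rng):
        a = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 40, rng)
        iv = ci_difference(a, a.copy(), "jeffreys_credible", ndraws=1000, seed=3)
        assert iv.lower == iv.upper == 0.0

    def test_unequal_sizes_accepted(self, rng):
        a = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 30, rng)
        b = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 50, rng)
        iv = ci_difference(a, b, "uniform_hpd", ndraws=1000, seed=4)
        assert iv.lower <= iv.upper

    def test_error_names_offending_sample(self, rng):
        good = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 40, rng)
        with pytest.raises(ValueError, match="sample B"):
            ci_difference(good, np.zeros(20), "fq", seed=0)

    def test_zero_difference_coverage(self):
        # independent pairs from one population: the 95% interval for the
        # difference should contain 0 in about 95% of replicates
        p = DeltaGammaParams(4.0, 1.5, 0.3)
        hits = 0
        reps = 200
        rng = np.random.default_rng(2024)
        for i in range(reps):
            a = sample_delta_gamma(p, 40, rng)
            b = sample_delta_gamma(p, 40, rng)
            iv = ci_difference(a, b, "fq", ndraws=1000, seed=int(i))
            hits += iv.lower <= 0 <= iv.upper
        # 3 binomial SEs below 0.95 at 200 replicates
        assert hits / reps >= 0.95 - 3 * np.sqrt(0.95 * 0.05 / reps)

    def test_generator_seed_also_accepted(self, rng):
        a = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 40, rng)
        b = sample_delta_gamma(DeltaGammaParams(4.0, 1.5, 0.3), 40, rng)
        iv = ci_difference(a, b, "fq", ndraws=500, seed=np.random.default_rng(0))
        assert np.isfinite(iv.width)
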