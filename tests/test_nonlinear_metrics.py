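import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import swaylab as sl

from conftest import logistic_map


def sampen_oracle(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Independent O(n^2) template-count oracle: full Chebyshev distance
    matrices between embedded windows, self-matches removed."""
    x = np.asarray(x, float)
    r = r_frac * np.std(x)
    nt = len(x) - m
    em = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    e1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    b = (np.sum(cdist(em, em, "chebyshev") <= r) - nt) / 2
    a = (np.sum(cdist(e1, e1, "chebyshev") <= r) - nt) / 2
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


class TestSampleEntropy:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 300))
            x = rng.standard_normal(n)
            assert sl.sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-12)

    def test_alternating_sequence_is_perfectly_regular(self):
        x = np.array([1.0, -1.0] * 50)
        assert sl.sample_entropy(x) == 0.0

    def test_linear_ramp_is_perfectly_regular(self):
        assert sl.sample_entropy(np.arange(1.0, 101.0)) == 0.0

    def test_gaussian_noise_level(self):
        """White Gaussian noise at m=2, r=0.2*SD sits near 2.2."""
        vals = [sl.sample_entropy(np.random.default_rng(s).standard_normal(3000))
                for s in range(20)]
        assert np.mean(vals) == pytest.approx(2.2, abs=0.15)

    def test_affine_invariance_is_exact(self, rng):
        x = rng.standard_normal(400)
        assert sl.sample_entropy(3.7 * x + 11.0) == pytest.approx(
            sl.sample_entropy(x), abs=1e-12
        )

    def test_constant_series_rejected(self):
        with pytest.raises(sl.DegenerateInputError):
            sl.sample_entropy(np.ones(100))

    def test_bad_params_rejected(self):
        with pytest.raises(sl.ParameterError):
            sl.SampEnParams(m=0)
        with pytest.raises(sl.ParameterError):
            sl.SampEnParams(r_frac=0.0)


class TestHiguchi:
    def test_k1_is_total_variation(self):
        assert sl.higuchi_curve_length([0, 3, 3, 7], 1) == pytest.approx(7.0)

    def test_constant_series_has_zero_length(self):
        assert sl.higuchi_curve_length(np.full(100, 4.2), 5) == 0.0

    def test_line_curve_length_scales_inverse_k(self):
        """For a straight line L(k) = a (N-1) / k exactly: log-log slope -1."""
        x = 0.7 * np.arange(1000.0)
        ks = np.arange(1, 21)
        lk = [sl.higuchi_curve_length(x, int(k)) for k in ks]
        slope, _ = np.polyfit(np.log(ks), np.log(lk), 1)
        assert slope == pytest.approx(-1.0, abs=1e-3)

    def test_line_has_dimension_one(self):
        assert sl.higuchi_fd(np.arange(3000.0) * 0.5) == pytest.approx(1.0, abs=0.01)

    def test_white_noise_has_dimension_two(self):
        fds = [sl.higuchi_fd(np.random.default_rng(s).standard_normal(3000))
               for s in range(5)]
        assert np.mean(fds) == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("hurst", [0.3, 0.5, 0.7])
    def test_fbm_dimension_is_two_minus_h(self, hurst):
        fds = [sl.higuchi_fd(sl.gen_fbm(3000, hurst, seed=s)) for s in range(5)]
        assert np.mean(fds) == pytest.approx(2.0 - hurst, abs=0.1)

    def test_noise_raises_dimension_of_a_line(self):
        """FD(line) < FD(line + noise) for any nonzero noise amplitude."""
        line = np.arange(2000.0)
        fd_line = sl.higuchi_fd(line)
        for s in range(20):
            noisy = line + 0.5 * np.random.default_rng(s).standard_normal(2000)
            assert sl.higuchi_fd(noisy) > fd_line

    def test_kmax_and_degenerate_validation(self):
        with pytest.raises(sl.ParameterError):
            sl.higuchi_fd(np.arange(100.0), sl.HiguchiParams(k_max=60))
        with pytest.raises(sl.DegenerateInputError):
            sl.higuchi_fd(np.zeros(3000))
        with pytest.raises(sl.ParameterError):
            sl.higuchi_curve_length(np.arange(10.0), 0)


class TestWolf:
    def test_logistic_map_exponent_is_ln2(self):
        x = logistic_map(3000)
        lam = sl.wolf_lyapunov(x, sl.WolfParams(embed_dim=2, delay=1, evolve_steps=1))
        assert lam == pytest.approx(math.log(2), abs=0.07)

    def test_sine_wave_is_not_chaotic(self):
        t = np.arange(3000) / 100.0
        lam = sl.wolf_lyapunov(np.sin(2 * np.pi * t))
        assert lam <= 0.05

    def test_deterministic_given_inputs(self, small_sway_params):
        x = sl.gen_cop_trial("addicted", "2ec", small_sway_params, seed=1).ap
        assert sl.wolf_lyapunov(x) == sl.wolf_lyapunov(x)

    def test_short_and_constant_series_rejected(self):
        with pytest.raises(sl.ValidationError):
            sl.wolf_lyapunov(np.arange(30.0))
        with pytest.raises(sl.DegenerateInputError):
            sl.wolf_lyapunov(np.zeros(3000))


class TestTrialDriver:
    def test_identical_axes_give_identical_metrics(self, small_sway_params):
        base = sl.gen_cop_trial("addicted", "2eo", small_sway_params, seed=2)
        trial = sl.CoPTrial("s", "addicted", "2eo", base.ml, base.ml.copy())
        out = sl.sway_nonlinear_metrics(trial)
        for name in ("sampen", "fd", "lye"):
            assert out[f"{name}_ml"] == out[f"{name}_ap"]

    def test_matches_direct_per_axis_calls(self, small_sway_params):
        trial = sl.gen_cop_trial("non_addicted", "ecR", small_sway_params, seed=4)
        out = sl.sway_nonlinear_metrics(trial)
        assert out["sampen_ap"] == sl.sample_entropy(trial.ap)
        assert out["fd_ml"] == sl.higuchi_fd(trial.ml)
        assert out["lye_ap"] == sl.wolf_lyapunov(trial.ap)

    def test_errors_are_tagged_with_axis(self, small_sway_params):
        good = sl.gen_cop_trial("addicted", "2eo", small_sway_params, seed=2)
        trial = sl.CoPTrial("s", "addicted", "2eo", good.ml, np.zeros(len(good.ml)))
        with pytest.raises(sl.DegenerateInputError, match="axis=ap"):
            sl.sway_nonlinear_metrics(trial)
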