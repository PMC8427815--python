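import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfdeeg import (
    HfdConfig,
    SynthConfig,
    curve_length,
    extract_features,
    extract_windows,
    generate_dataset,
    generate_fbm_signal,
    higuchi_fd,
    higuchi_fd_batch,
    read_features,
    write_features,
)
from hfdeeg.higuchi import DegenerateSignalError, WindowError


def naive_curve_length(signal, k):
    """Direct double-loop transcription of the curve-length definition:
    independent oracle for the vectorised implementation."""
    s = list(signal)
    n = len(s)
    total = 0.0
    for m in range(k):
        n_m = (n - 1 - m) // k
        acc = 0.0
        for i in range(1, n_m + 1):
            acc += abs(s[m + i * k] - s[m + (i - 1) * k])
        total += acc * (n - 1) / (n_m * k) / k
    return total / k


class TestCurveLength:
    def test_ramp_hand_values(self):
        # for a linear ramp L(k) = (N-1)/k exactly; N=10: L(2)=4.5, L(3)=3.0
        ramp = np.arange(10.0)
        assert curve_length(ramp, 2) == pytest.approx(4.5, abs=1e-9)
        assert curve_length(ramp, 3) == pytest.approx(3.0, abs=1e-9)

    def test_constant_signal_has_zero_length(self):
        for k in (2, 3, 5):
            assert curve_length(np.full(30, 2.5), k) == 0.0

    def test_window_too_short_rejected(self):
        with pytest.raises(WindowError):
            curve_length(np.arange(9.0), 5)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(20, 200))
            sig = rng.standard_normal(n)
            for k in range(2, 8):
                fast = curve_length(sig, k)
                slow = naive_curve_length(sig, k)
                assert fast == pytest.approx(slow, rel=1e-12)


class TestHiguchiFd:
    @pytest.mark.parametrize("n", [20, 100, 500])
    def test_ramp_attains_lower_bound(self, n):
        assert higuchi_fd(np.arange(float(n))) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_near_upper_bound(self):
        rng = np.random.default_rng(0)
        batch = rng.standard_normal((100, 500))
        mean_d = float(np.mean(higuchi_fd_batch(batch)))
        assert 1.90 <= mean_d <= 2.00

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.standard_normal(300)
        assert higuchi_fd(3.0 * s + 7.0) == pytest.approx(higuchi_fd(s),
                                                          abs=1e-10)
        assert higuchi_fd(-2.0 * s) == pytest.approx(higuchi_fd(s), abs=1e-10)

    def test_constant_signal_raises(self):
        with pytest.raises(DegenerateSignalError):
            higuchi_fd(np.ones(100))

    def test_estimates_decrease_with_hurst(self):
        # fractal dimension of fBm is 2 - H: estimates must order accordingly
        means = []
        for h in (0.2, 0.4, 0.6, 0.8):
            paths = np.stack(
                [generate_fbm_signal(500, h, seed=s) for s in range(100)]
            )
            means.append(float(np.mean(higuchi_fd_batch(paths))))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_battery_estimates_within_admissible_range(self):
        rng = np.random.default_rng(2)
        battery = [np.arange(500.0), rng.standard_normal(500)]
        battery += [generate_fbm_signal(500, h, seed=9) for h in (0.2, 0.5, 0.8)]
        for sig in battery:
            assert 0.95 <= higuchi_fd(sig) <= 2.05

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(30, 300),
        k=st.integers(2, 7),
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_curve_length_scaling_property(self, seed, n, k, scale, shift):
        # L(a*S + b) = |a| * L(S): curve length is homogeneous in amplitude
        sig = np.random.default_rng(seed).standard_normal(n)
        base = curve_length(sig, k)
        assert curve_length(scale * sig + shift, k) == pytest.approx(
            scale * base, rel=1e-9)
        assert curve_length(-sig, k) == pytest.approx(base, rel=1e-12)

    def test_k_grid_validation(self):
        with pytest.raises(ValueError):
            HfdConfig(k_grid=(1, 2, 3))
        with pytest.raises(ValueError):
            HfdConfig(k_max=7, k_grid=(2, 9))
        assert HfdConfig(k_max=7).k_grid == (2, 3, 4, 5, 6, 7)


class TestWindows:
    def test_canonical_250hz_windows(self):
        # 5-s trial at 250 Hz: four 2-s windows at samples 0, 250, 500, 750
        trial = np.arange(1250.0)
        wins = extract_windows(trial, 250.0, HfdConfig())
        assert [w.shape[-1] for w in wins] == [500] * 4
        assert [w[0] for w in wins] == [0.0, 250.0, 500.0, 750.0]

    def test_canonical_256hz_windows(self):
        wins = extract_windows(np.arange(1280.0), 256.0, HfdConfig())
        assert [w.shape[-1] for w in wins] == [512] * 4

    def test_half_overlap_of_consecutive_windows(self):
        trial = np.arange(1250.0)
        wins = extract_windows(trial, 250.0, HfdConfig())
        assert np.array_equal(wins[0][250:], wins[1][:250])

    def test_offset_beyond_trial_named_in_error(self):
        with pytest.raises(WindowError, match="3"):
            extract_windows(np.arange(750.0), 250.0,
                            HfdConfig(window_offsets=(0.0, 3.0)))


class TestExtractFeatures:
    def test_row_count_and_order(self, effect_dataset, effect_features):
        p, t, k, c, _ = effect_dataset.data.shape
        w = 4
        assert len(effect_features) == p * t * k * c * w
        assert list(effect_features.columns) == [
            "group", "participant", "trial", "task", "channel",
            "window_offset", "hfd",
        ]
        assert effect_features["hfd"].notna().all()
        assert effect_features["hfd"].between(0.95, 2.05).all()

    def test_toy_counting(self, small_montage):
        cfg = SynthConfig(montage=small_montage.subset(["FCz", "Oz"]),
                          n_groups=1, participants_per_group=1,
                          trials_per_task=1, tasks=("LH",), seed=0)
        feat = extract_features(generate_dataset(cfg), HfdConfig())
        assert len(feat) == 1 * 1 * 1 * 2 * 4

    def test_determinism_across_regeneration(self, small_montage):
        cfg = SynthConfig(montage=small_montage.subset(["FCz"]), n_groups=1,
                          participants_per_group=1, trials_per_task=2,
                          tasks=("LH",), seed=21)
        a = extract_features(generate_dataset(cfg), HfdConfig())
        b = extract_features(generate_dataset(cfg), HfdConfig())
        assert a.equals(b)

    def test_batch_matches_scalar_estimator(self, effect_dataset):
        win = effect_dataset.data[0, 0, 0, :, :500]
        batch = higuchi_fd_batch(win)
        scalar = [higuchi_fd(row) for row in win]
        assert np.allclose(batch, scalar, rtol=1e-12)

    def test_csv_round_trip(self, effect_features, tmp_path):
        path = tmp_path / "f.csv"
        write_features(effect_features, path)
        back = read_features(path)
        assert len(back) == len(effect_features)
        assert np.allclose(back["hfd"], effect_features["hfd"])
        with pytest.raises(ValueError, match="missing columns"):
            (tmp_path / "bad.csv").write_text("a,b\n1,2\n")
            read_features(tmp_path / "bad.csv")
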