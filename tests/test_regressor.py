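"""CNN classifier, threshold detection, and the V-slope baseline."""

import numpy as np
import pandas as pd
import pytest

from cpetml import _nn
from cpetml.cpetio import (REGRESSOR_CHANNELS, derive_ratios,
                           interpolate_to_seconds, normalize_minmax)
from cpetml.errors import CPETError, InsufficientDataError
from cpetml.regressor import (CNNDomainClassifier, DomainProbabilities,
                              RegressorConfig, ThresholdEstimate,
                              bisegmental_fit, build_regressor,
                              detect_thresholds, infer_probabilities,
                              label_windows, train_regressor, vslope_baseline)
from cpetml.simulate import SimConfig, noise_free_second_table, simulate_cpet

from conftest import constant_second_table


def preprocessed(cfg):
    bt, gt = simulate_cpet(cfg)
    st = derive_ratios(interpolate_to_seconds(bt))
    return st, normalize_minmax(st, REGRESSOR_CHANNELS), gt


class TestModelShape:
    def test_maps_40x6_to_3_probabilities(self, rng):
        model = build_regressor(seed=0)
        p = model.predict_proba(rng.random((7, 40, 6)))
        assert p.shape == (7, 3)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_layer_sequence_matches_contract(self):
        model = build_regressor(seed=0)
        kinds = [type(l).__name__ for l in model.net.layers
                 if type(l).__name__ != "Relu"]
        assert kinds == ["Conv1D", "AvgPool1D", "BatchNorm", "Flatten",
                         "Dropout", "Dense", "Dropout", "BatchNorm", "Dense"]
        dense_hidden = [l for l in model.net.layers
                        if isinstance(l, _nn.Dense)][0]
        assert dense_hidden.params[0].shape[1] == 16

    def test_wrong_window_shape_rejected(self, rng):
        model = build_regressor(seed=0)
        with pytest.raises(Exception):
            model.predict_proba(rng.random((1, 30, 6)))

    def test_save_load_round_trip(self, rng, tmp_path):
        model = build_regressor(seed=3)
        x = rng.random((4, 40, 6))
        p = tmp_path / "m.npz"
        model.save(p)
        clone = CNNDomainClassifier.load(p)
        np.testing.assert_array_equal(model.predict_proba(x),
                                      clone.predict_proba(x))


class TestLabeling:
    def test_center_rule(self):
        cfg = SimConfig(VT1_s=330.0, noise_level=0.0)
        _, nt, gt = preprocessed(cfg)
        tensor, onehot, starts = label_windows(nt, gt)
        centers = starts + 19.5
        # a window fully inside moderate
        k = np.argmin(np.abs(starts - 100))
        assert onehot[k].tolist() == [1, 0, 0]
        # the first window whose center passed VT1 is heavy
        k = np.nonzero(centers > 330.0)[0][0]
        assert onehot[k].tolist() == [0, 1, 0]

    def test_counts_match_per_window_oracle(self):
        _, nt, gt = preprocessed(SimConfig(noise_level=0.2, seed=4))
        tensor, onehot, starts = label_windows(nt, gt)
        expect = np.zeros(3)
        for s in starts:  # brute-force relabeling
            expect[gt.domain_at(s + 19.5)] += 1
        np.testing.assert_array_equal(onehot.sum(axis=0), expect)


class TestTraining:
    def _toy_windows(self, rng, n=120):
        """Channel 0 alone separates the three classes."""
        y = rng.integers(0, 3, n)
        x = rng.random((n, 40, 6)) * 0.1
        x[:, :, 0] = y[:, None] * 0.45 + 0.05
        return x, np.eye(3)[y]

    def test_separable_toy_set_reaches_full_accuracy(self, rng):
        x, y = self._toy_windows(rng)
        cfg = RegressorConfig(epochs=30, batch_size=32, dropout=0.0)
        model, history = train_regressor(x, y, cfg, seed=0)
        assert history["accuracy"][-1] == 1.0
        pred = model.predict_proba(x).argmax(1)
        assert (pred == y.argmax(1)).mean() == 1.0

    def test_same_seed_identical_history(self, rng):
        x, y = self._toy_windows(rng)
        cfg = RegressorConfig(epochs=3)
        _, h1 = train_regressor(x, y, cfg, seed=5)
        _, h2 = train_regressor(x, y, cfg, seed=5)
        assert h1 == h2

    def test_absent_class_is_named(self, rng):
        x = rng.random((10, 40, 6))
        y = np.eye(3)[np.zeros(10, int)]
        with pytest.raises(CPETError, match="heavy"):
            train_regressor(x, y, RegressorConfig(epochs=1), seed=0)


class TestInference:
    def test_row_count_and_normalization(self):
        _, nt, _ = preprocessed(SimConfig(seed=1))
        nt.data = nt.data.iloc[:100]
        model = build_regressor(seed=0)
        dp = infer_probabilities(model, nt)
        assert len(dp) == 61
        np.testing.assert_allclose(dp.probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_equals_per_window_calls(self):
        _, nt, _ = preprocessed(SimConfig(seed=2))
        nt.data = nt.data.iloc[:80]
        model = build_regressor(seed=1)
        dp = infer_probabilities(model, nt)
        from cpetml.cpetio import window_tensor
        tensor, _ = window_tensor(nt)
        singles = np.vstack([model.predict_proba(tensor[k])
                             for k in range(tensor.shape[0])])
        np.testing.assert_allclose(dp.probs, singles, atol=1e-9)


def dp_from_segments(n_mod, n_heavy, n_severe, t0=0.0, scale=1.0):
    labels = [0] * n_mod + [1] * n_heavy + [2] * n_severe
    p = (np.eye(3)[labels] * 0.8 + 0.1) * scale
    t = t0 + np.arange(len(labels), dtype=float)
    return DomainProbabilities(pd.DataFrame(
        {"t": t, "p_moderate": p[:, 0], "p_heavy": p[:, 1],
         "p_severe": p[:, 2]}))


class TestDetection:
    def test_exact_crossings_by_construction(self):
        dp = dp_from_segments(300, 300, 200)
        st = constant_second_table(n=800, VO2=np.linspace(500, 3000, 800))
        est = detect_thresholds(dp, st)
        assert est.VT1_s == 300.0 and est.VT2_s == 600.0

    def test_all_moderate_reports_absent(self):
        dp = dp_from_segments(400, 0, 0)
        st = constant_second_table(n=400)
        est = detect_thresholds(dp, st)
        assert est.VT1_s is None and est.VT2_s is None

    def test_vo2_is_windowed_mean_around_change(self):
        dp = dp_from_segments(300, 300, 200)
        vo2 = np.linspace(500, 3000, 800)
        st = constant_second_table(n=800, VO2=vo2)
        est = detect_thresholds(dp, st)
        t = st.t
        mask = (t >= est.VT1_s - 5) & (t <= est.VT1_s + 5)
        assert est.VT1_VO2 == pytest.approx(vo2[mask].mean())

    def test_invariant_to_uniform_probability_rescaling(self):
        st = constant_second_table(n=800, VO2=np.linspace(500, 3000, 800))
        a = detect_thresholds(dp_from_segments(250, 350, 200), st)
        b = detect_thresholds(dp_from_segments(250, 350, 200, scale=0.37), st)
        assert a.VT1_s == b.VT1_s and a.VT2_s == b.VT2_s

    def test_time_offset_shifts_estimates(self):
        dp = dp_from_segments(300, 300, 200)
        st = constant_second_table(n=900, VO2=np.linspace(500, 3000, 900))
        est = detect_thresholds(dp, st, time_offset_s=19.5)
        assert est.VT1_s == pytest.approx(319.5)

    def test_chattering_argmax_is_projected_monotone(self, rng):
        # noisy probabilities around clean segment boundaries
        labels = np.array([0] * 200 + [1] * 200 + [2] * 200)
        p = np.eye(3)[labels] + rng.random((600, 3)) * 0.9
        p /= p.sum(1, keepdims=True)
        dp = DomainProbabilities(pd.DataFrame(
            {"t": np.arange(600.0), "p_moderate": p[:, 0],
             "p_heavy": p[:, 1], "p_severe": p[:, 2]}))
        st = constant_second_table(n=600, VO2=np.linspace(500, 3000, 600))
        est = detect_thresholds(dp, st)
        assert est.VT1_s is not None and est.VT2_s is not None
        assert est.VT1_s < est.VT2_s
        assert abs(est.VT1_s - 200) < 30 and abs(est.VT2_s - 400) < 30


class TestVSlope:
    def test_noiseless_two_segment_geometry_recovered(self):
        x = np.linspace(500, 3000, 200)
        y = np.where(x < 1500, 0.9 * x, 0.9 * 1500 + 1.2 * (x - 1500))
        fit = bisegmental_fit(x, y)
        assert fit["x_break"] == pytest.approx(1500, abs=np.diff(x)[0])
        assert fit["p_value"] < 0.05

    def test_pure_line_gives_no_threshold(self):
        st, _ = noise_free_second_table(SimConfig(noise_level=0.0))
        df = st.data.copy()
        df["VCO2"] = 0.95 * df["VO2"] + 10.0  # exactly one line
        est = vslope_baseline(type(st)(df), ramp_start_s=60.0)
        assert est.VT1_VO2 is None

    def test_matches_exhaustive_polyfit_oracle(self):
        cfg = SimConfig(noise_level=0.5, seed=8)
        bt, _ = simulate_cpet(cfg)
        st = interpolate_to_seconds(bt)
        df = st.data[st.data["t"] >= cfg.ramp_start_s]
        x = df["VO2"].to_numpy()
        y = df["VCO2"].to_numpy()
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], y[order]
        best, bk = np.inf, None
        for k in range(5, len(xs) - 4):  # naive oracle over all splits
            r1 = np.polyfit(xs[:k], ys[:k], 1, full=True)[1]
            r2 = np.polyfit(xs[k:], ys[k:], 1, full=True)[1]
            rss = float(r1[0]) + float(r2[0])
            if rss < best - 1e-12:
                best, bk = rss, k
        fit = bisegmental_fit(x, y)
        assert fit["split_index"] == bk
        assert fit["rss_two"] == pytest.approx(best)

    def test_recovers_simulated_thresholds_noise_free(self):
        cfg = SimConfig(noise_level=0.0)
        st, gt = noise_free_second_table(cfg)
        est = vslope_baseline(st, ramp_start_s=cfg.ramp_start_s)
        assert est.method == "vslope"
        assert est.VT1_VO2 == pytest.approx(gt.VT1_VO2, abs=30)
        assert est.VT2_VO2 == pytest.approx(gt.VT2_VO2, abs=30)

    def test_too_few_points_rejected(self):
        st = constant_second_table(n=8)
        with pytest.raises(InsufficientDataError):
            vslope_baseline(st)
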