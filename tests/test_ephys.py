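"""Spike-train analysis: QC, rates, clustering, latency, waveforms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from acx import ephys as ep
from acx import synthetic as syn


def unit_from_trains(trains, waveform=None, fs=30000.0, **kw):
    if waveform is None:
        waveform = syn.make_waveform_template(0.4, fs)
    return {
        "unit_id": kw.get("unit_id", "u0"),
        "spikes": [np.asarray(t, float) for t in trains],
        "waveform": np.asarray(waveform, float),
        "waveform_fs_hz": fs,
        "depth_mm": kw.get("depth_mm", 0.5),
        "isolation": kw.get("isolation", "single"),
    }


def trial_frame(n_off, n_on, duration_ms=250.0, level_db=60.0):
    rows = []
    for i in range(n_off + n_on):
        laser = i >= n_off
        rows.append(
            {
                "trial_index": i,
                "level_db": level_db,
                "duration_ms": duration_ms,
                "laser": laser,
                "laser_onset_ms": -100.0 if laser else np.nan,
                "laser_offset_ms": duration_ms + 100.0 if laser else np.nan,
            }
        )
    return pd.DataFrame(rows)


class TestQC:
    def test_regular_train_passes_single_unit(self):
        unit = unit_from_trains([np.arange(0, 200, 10.0)])
        qc = ep.qc_units([unit])
        assert qc.iloc[0]["isi_violation_fraction"] == 0.0
        assert qc.iloc[0]["passes_single_unit"]

    def test_three_percent_violations_fail(self):
        # 100 ISIs, exactly 3 shorter than 2 ms
        times = np.cumsum(np.r_[np.full(4, 1.0), np.full(97, 10.0)])
        unit = unit_from_trains([times])
        qc = ep.qc_units([unit])
        assert qc.iloc[0]["isi_violation_fraction"] == pytest.approx(0.03)
        assert not qc.iloc[0]["passes_single_unit"]

    def test_biphasic_waveform_not_artifact(self):
        assert not ep.is_artifact_waveform(syn.make_waveform_template(0.4))

    def test_monophasic_positive_flagged(self):
        t = np.linspace(-1, 1, 60)
        assert ep.is_artifact_waveform(np.exp(-0.5 * (t / 0.1) ** 2))

    def test_empty_unit_unanalyzable(self):
        unit = unit_from_trains([np.empty(0), np.empty(0)])
        qc = ep.qc_units([unit])
        assert not qc.iloc[0]["analyzable"]


class TestFiringRates:
    def test_arithmetic(self):
        # 5 spikes in every 250 ms evoked window -> 20 spikes/s
        trials = trial_frame(4, 4)
        trains = [np.linspace(10, 240, 5) for _ in range(8)]
        prof = ep.firing_rates(unit_from_trains(trains), trials)
        assert prof["evoked_off_hz"] == pytest.approx(20.0)
        assert prof["evoked_on_hz"] == pytest.approx(20.0)

    def test_spontaneous_window_is_pre_sound(self):
        trials = trial_frame(2, 2)
        trains = [np.array([-50.0, -10.0, 30.0]) for _ in range(4)]
        prof = ep.firing_rates(unit_from_trains(trains), trials)
        assert prof["spont_off_hz"] == pytest.approx(20.0)  # 2 in 100 ms

    def test_suppressed_unit_has_positive_change(self, small_ephys):
        units, trials, truth, _ = small_ephys
        prof = ep.modulation_profiles(units, trials)
        merged = prof.merge(truth.unit_class, on="unit_id")
        sup = merged[merged.true_class == "suppressed"]
        assert (sup["evoked_change_hz"] > 0).mean() > 0.9


class TestDetectEvoked:
    def test_strong_step_flagged(self, rng):
        trials = trial_frame(20, 0)
        trains = [
            np.sort(rng.uniform(0, 250, rng.poisson(8))) for _ in range(20)
        ]
        assert ep.detect_evoked(unit_from_trains(trains), trials)

    def test_identical_rates_not_flagged(self, rng):
        trials = trial_frame(20, 0)
        trains = [
            np.sort(rng.uniform(-250, 250, 10)) for _ in range(20)
        ]
        assert not ep.detect_evoked(unit_from_trains(trains), trials)


class TestKneePoint:
    def test_worked_curve(self):
        curve = [100, 20, 15, 12, 10, 9, 8.5, 8, 7.8, 7.6]
        assert ep.knee_point(np.array(curve)) == 2

    @given(
        hst.lists(
            hst.floats(min_value=0.1, max_value=1000.0),
            min_size=3,
            max_size=10,
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, values):
        curve = np.sort(np.asarray(values))[::-1]
        # oracle: exhaustive point-to-chord perpendicular distance
        x = np.arange(1, len(curve) + 1, dtype=float)
        x0, y0, x1, y1 = x[0], curve[0], x[-1], curve[-1]
        denom = np.hypot(x1 - x0, y1 - y0)
        best, best_d = 1, -1.0
        for i in range(len(curve)):
            d = abs((y1 - y0) * x[i] - (x1 - x0) * curve[i] + x1 * y0 - y1 * x0)
            d = d / denom if denom else 0.0
            if d > best_d:
                best, best_d = i + 1, d
        assert ep.knee_point(curve) == best


class TestClusterModulation:
    @staticmethod
    def _profiles(feats):
        return pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(len(feats))],
                "evoked_off_hz": [f[0] for f in feats],
                "evoked_on_hz": [f[1] for f in feats],
            }
        )

    def test_cosine_invariance_to_scaling(self, rng):
        base = [(10.0, 2.0)] * 12 + [(2.0, 10.0)] * 12
        profiles = self._profiles(base)
        a = ep.cluster_modulation(profiles, k_range=range(1, 4), seed=0)
        scaled = [(x * c, y * c) for (x, y), c in zip(base, rng.uniform(0.1, 40, 24))]
        b = ep.cluster_modulation(self._profiles(scaled), k_range=range(1, 4), seed=0)
        assert np.array_equal(a.labels, b.labels)

    def test_two_rays_split_perfectly(self):
        feats = [(1.0, 0.2), (5.0, 1.0), (50.0, 10.0)] * 4
        feats += [(0.2, 1.0), (1.0, 5.0), (10.0, 50.0)] * 4
        assignment = ep.cluster_modulation(
            self._profiles(feats), k_range=range(1, 5), seed=0
        )
        assert assignment.knee_k == 2
        labels = assignment.labels
        assert len(set(labels[:12])) == 1
        assert len(set(labels[12:])) == 1
        assert labels[0] == 1  # suppressed group is cluster 1

    def test_zero_feature_rows_excluded(self):
        feats = [(10.0, 2.0)] * 6 + [(2.0, 10.0)] * 6 + [(0.0, 0.0)]
        assignment = ep.cluster_modulation(
            self._profiles(feats), k_range=range(1, 4), seed=0
        )
        assert assignment.excluded == ["u12"]

    def test_recovers_generated_classes(self, small_ephys):
        units, trials, truth, _ = small_ephys
        prof = ep.modulation_profiles(units, trials)
        assignment = ep.cluster_modulation(prof, seed=0)
        assert assignment.knee_k == 2
        pred = assignment.label_series().reindex(prof.unit_id)
        klass = truth.unit_class.set_index("unit_id").true_class.reindex(prof.unit_id)
        acc = ((pred == 1) == (klass == "suppressed")).mean()
        assert acc >= 0.9


class TestPerUnitLaserTest:
    def test_suppressed_unit_detected(self, rng):
        trials = trial_frame(40, 40)
        trains = []
        for i in range(80):
            rate = 60.0 if i < 40 else 10.0  # off trials first
            n = rng.poisson(rate * 0.25)
            trains.append(np.sort(rng.uniform(-100, 150, n)))
        p, direction = ep.per_unit_laser_test(unit_from_trains(trains), trials)
        assert p < 0.01
        assert direction == "suppressed"

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = 0
        n_rep = 100
        for _ in range(n_rep):
            trials = trial_frame(15, 15)
            trains = [
                np.sort(rng.uniform(-100, 150, rng.poisson(6))) for _ in range(30)
            ]
            p, _ = ep.per_unit_laser_test(unit_from_trains(trains), trials)
            if p < 0.05:
                rejections += 1
        assert rejections <= 11  # ~5% nominal, binomial slack

    def test_degenerate_equal_counts(self):
        trials = trial_frame(6, 6)
        trains = [np.array([10.0]) for _ in range(12)]
        p, direction = ep.per_unit_laser_test(unit_from_trains(trains), trials)
        assert p == 1.0
        assert direction == "none"


class TestDepthProfile:
    def test_uniform_depth_percentile(self):
        n = 400
        rng = np.random.default_rng(1)
        prof = pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(n)],
                "depth_mm": rng.uniform(0, 1, n),
            }
        )
        flags = pd.Series(True, index=prof.unit_id)
        out = ep.depth_profile(prof, flags, flags)
        assert abs(out["evoked_depth_p95_mm"] - 0.95) < 0.03

    def test_inactivated_shallower_than_evoked(self, small_ephys):
        units, trials, truth, _ = small_ephys
        prof = ep.modulation_profiles(units, trials)
        klass = truth.unit_class.set_index("unit_id").true_class
        evoked = pd.Series(True, index=prof.unit_id)
        suppressed = klass.reindex(prof.unit_id) == "suppressed"
        out = ep.depth_profile(prof, evoked, suppressed)
        assert out["inactivated_depth_p90_mm"] <= out["evoked_depth_p95_mm"] + 0.2

    def test_small_groups_omitted(self):
        prof = pd.DataFrame({"unit_id": ["a", "b"], "depth_mm": [0.1, 0.2]})
        out = ep.depth_profile(
            prof,
            pd.Series([True, False], index=["a", "b"]),
            pd.Series([False, False], index=["a", "b"]),
        )
        assert out == {}


class TestPSTH:
    def test_one_spike_per_bin_rate(self):
        trials = trial_frame(1, 0)
        # one spike in each 1 ms bin of the first 100 ms after "laser onset"
        # (laser-off trials share the laser-aligned time base)
        spikes = np.arange(-99.5, 0.0, 1.0)
        unit = unit_from_trains([spikes])
        mat, edges = ep.psth(unit, trials, bin_ms=1.0)
        assert mat.shape == (1, 100)
        assert np.all(mat == 1000.0)

    def test_count_conserved_across_binnings(self, rng):
        trials = trial_frame(5, 0)
        trains = [np.sort(rng.uniform(-100, 0, 30)) for _ in range(5)]
        unit = unit_from_trains(trains)
        for bin_ms in (0.5, 1.0, 2.0, 5.0):
            mat, _ = ep.psth(unit, trials, bin_ms=bin_ms)
            total = mat.sum() * bin_ms / 1000.0
            assert total == pytest.approx(150.0)

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            ep.psth(unit_from_trains([np.empty(0)]), trial_frame(1, 0), bin_ms=0.0)


class TestClusterPermutationLatency:
    def _make_psth(self, rng, n_trials, rate_profile_hz, bin_ms=0.5):
        n_bins = len(rate_profile_hz)
        lam = np.asarray(rate_profile_hz) * bin_ms / 1000.0
        return rng.poisson(lam, (n_trials, n_bins)) / (bin_ms / 1000.0)

    def test_step_suppression_latency_recovered(self, rng):
        edges = np.arange(0, 100, 0.5)
        profile_off = np.full(len(edges), 150.0)
        profile_on = profile_off.copy()
        profile_on[10:] = 2.0  # near-complete silencing from 5 ms
        hits = []
        for _ in range(10):
            on = self._make_psth(rng, 150, profile_on)
            off = self._make_psth(rng, 150, profile_off)
            res = ep.cluster_permutation_latency(on, off, edges, n_perm=300, seed=1)
            if np.isfinite(res["latency_ms"]):
                hits.append(res["latency_ms"])
        assert len(hits) >= 9
        assert abs(np.median(hits) - 5.0) <= 0.5

    def test_null_rarely_significant(self, rng):
        edges = np.arange(0, 100, 0.5)
        profile = np.full(len(edges), 30.0)
        n_sig = 0
        for i in range(40):
            on = self._make_psth(rng, 20, profile)
            off = self._make_psth(rng, 20, profile)
            res = ep.cluster_permutation_latency(on, off, edges, n_perm=200, seed=i)
            if any(c["p"] < 0.05 for c in res["clusters"]):
                n_sig += 1
        assert n_sig <= 5  # nominal 5% family-wise rate

    def test_no_effect_no_latency(self):
        edges = np.arange(0, 100, 0.5)
        zeros = np.zeros((10, len(edges)))
        res = ep.cluster_permutation_latency(zeros, zeros, edges, n_perm=50, seed=0)
        assert np.isnan(res["latency_ms"])
        assert res["clusters"] == []


class TestWaveformStats:
    def test_trough_to_peak_arithmetic(self):
        w = np.zeros(100)
        w[30] = -1.0
        w[42] = 0.6
        assert ep.trough_to_peak(w, 30000.0) == pytest.approx(0.4, abs=1e-9)

    @pytest.mark.parametrize("target", [0.402, 0.338])
    def test_template_measured_within_one_sample(self, target):
        fs = 30000.0
        w = syn.make_waveform_template(target, fs)
        assert abs(ep.trough_to_peak(w, fs) - target) < 1000.0 / fs

    def test_inverted_waveform_rejected(self):
        w = -syn.make_waveform_template(0.4)
        with pytest.raises(ValueError):
            ep.trough_to_peak(w, 30000.0)

    def test_permutation_detects_shift(self, rng):
        lat1 = rng.normal(0.402, 0.05, 80)
        lat2 = rng.normal(0.338, 0.05, 20)
        lat = np.r_[lat1, lat2]
        labels = np.r_[np.ones(80), np.full(20, 2)]
        res = ep.waveform_permutation_test(lat, labels, n_iter=1000, seed=0)
        assert res["observed_diff_ms"] == pytest.approx(
            lat1.mean() - lat2.mean()
        )
        assert res["p"] < 0.05

    def test_null_p_not_extreme(self, rng):
        pvals = []
        for i in range(30):
            lat = rng.normal(0.4, 0.05, 60)
            labels = np.r_[np.ones(40), np.full(20, 2)]
            res = ep.waveform_permutation_test(lat, labels, n_iter=300, seed=i)
            pvals.append(res["p"])
        assert (np.array(pvals) < 0.05).mean() <= 0.2

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            ep.waveform_permutation_test(np.ones(10), np.ones(10))


class TestModulationTable:
    def test_counts_and_percentages(self):
        qc = pd.DataFrame(
            {
                "unit_id": [f"u{i}" for i in range(10)],
                "isolation": ["single"] * 4 + ["multi"] * 6,
            }
        )
        labels = pd.Series(
            [1, 1, 2, 2, 1, 1, 1, 2, 2, 2], index=qc.unit_id
        )
        sig = pd.Series(
            [True, False, True, False, True, True, False, False, True, False],
            index=qc.unit_id,
        )
        table = ep.modulation_table(qc, labels, sig)
        assert table.loc[1, "total_total"] == 5
        assert table.loc[1, "total_significant"] == 3
        pct = ep.significant_percentages(table)
        assert pct.loc[1, "total"] == pytest.approx(60.0)
        assert pct.loc["total", "total"] == pytest.approx(50.0)
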