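"""Feature families, bilateral aggregation and feature-matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import rigipose as rp
from rigipose.errors import SchemaError
from rigipose.features import (
    FeatureDescriptor,
    FeatureExtractionConfig,
    extract_recording_features,
)
from rigipose.recording import preprocess_recording
from rigipose.signals import detect_peaks_valleys, smooth_signal


class TestKinematicFeatures:
    def test_pure_sine(self, sine_channel):
        """Sine of amplitude A: cycle amplitude 2A, frequency f, no decrement."""
        A, f = 0.7, 2.0
        sig = sine_channel(freq=f, amplitude=A, duration=10.0)
        pv = detect_peaks_valleys(sig)
        k = rp.kinematic_features(sig, pv)
        assert k["kin_amp_mean"] == pytest.approx(2 * A, rel=0.02)
        assert k["kin_freq_mean"] == pytest.approx(f, abs=0.1)
        assert abs(k["kin_decrement"]) < 1e-3
        assert k["kin_hesitations"] == 0
        assert k["kin_degenerate"] == 0.0

    def test_geometric_decay_negative_decrement(self):
        t = np.arange(240) / 20.0
        env = 0.8 ** np.floor(1.0 * t)  # amplitudes 1.0, 0.8, 0.64, ...
        x = env * 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))
        sig = rp.SignalChannel(name="d", values=x, frame_rate=20.0)
        pv = detect_peaks_valleys(sig)
        k = rp.kinematic_features(sig, pv)
        assert k["kin_decrement"] < 0

    def test_stretched_cycle_counts_as_hesitation(self):
        fs = 20.0
        # 6 cycles of 1 s, a 1 s pause (one cycle stretched to twice the
        # median peak-to-peak duration), then 3 more 1 s cycles
        cycle = 0.5 * (1 - np.cos(2 * np.pi * np.arange(int(fs)) / fs))
        x = np.concatenate([np.tile(cycle, 6), np.zeros(int(fs)),
                            np.tile(cycle, 3)])
        sig = rp.SignalChannel(name="h", values=x, frame_rate=fs)
        pv = detect_peaks_valleys(sig)
        k = rp.kinematic_features(sig, pv)
        assert k["kin_hesitations"] == 1

    def test_degenerate_when_too_few_cycles(self, sine_channel):
        sig = sine_channel(amplitude=0.0, offset=1.0)
        pv = detect_peaks_valleys(sig)
        k = rp.kinematic_features(sig, pv)
        assert k["kin_degenerate"] == 1.0
        assert k["kin_amp_mean"] == 0.0


class TestTimeDomainFeatures:
    def test_constant_flagged(self):
        sig = rp.SignalChannel(name="c", values=np.full(50, -2.0), frame_rate=20.0)
        td = rp.time_domain_features(sig)
        assert td["td_std"] == 0.0
        assert td["td_rms"] == pytest.approx(2.0)
        assert td["td_absmean"] == pytest.approx(2.0)
        assert td["td_skewness"] == 0.0 and td["td_kurtosis"] == 0.0
        assert td["td_zerovar"] == 1.0

    def test_ramp_median(self):
        x = np.linspace(0.0, 1.0, 101)
        td = rp.time_domain_features(rp.SignalChannel(name="r", values=x, frame_rate=20.0))
        assert td["td_q50"] == pytest.approx(0.5, abs=0.01)
        assert td["td_range"] == pytest.approx(1.0)

    def test_standard_normal_moments(self):
        x = np.random.default_rng(123).standard_normal(100_000)
        td = rp.time_domain_features(rp.SignalChannel(name="n", values=x, frame_rate=20.0))
        assert abs(td["td_skewness"]) < 0.05
        assert abs(td["td_kurtosis"]) < 0.1
        assert td["td_std"] == pytest.approx(1.0, abs=0.02)


class TestFrequencyDomainFeatures:
    def test_sine_dominant_frequency(self, sine_channel):
        sig = sine_channel(freq=2.0, duration=10.0)
        fd = rp.frequency_domain_features(sig)
        bin_width = sig.frame_rate / sig.values.size
        assert fd["fd_domfreq"] == pytest.approx(2.0, abs=bin_width)
        assert fd["fd_frac_voluntary"] > 0.9
        assert fd["fd_flat"] == 0.0

    def test_white_noise_high_entropy(self):
        x = np.random.default_rng(7).standard_normal(512)
        fd = rp.frequency_domain_features(
            rp.SignalChannel(name="w", values=x, frame_rate=20.0)
        )
        assert fd["fd_entropy"] > 0.9

    def test_constant_flagged_zero_power(self):
        fd = rp.frequency_domain_features(
            rp.SignalChannel(name="c", values=np.ones(64), frame_rate=20.0)
        )
        assert fd["fd_flat"] == 1.0
        assert fd["fd_totalpower"] == 0.0
        assert fd["fd_frac_voluntary"] == 0.0 and fd["fd_frac_tremor"] == 0.0


class TestBilateralAggregate:
    def test_hand_example(self):
        agg = rp.bilateral_aggregate({"s": 1.0}, {"s": 3.0})
        assert agg[("s", "mean")] == 2.0
        assert agg[("s", "max")] == 3.0
        assert agg[("s", "min")] == 1.0
        assert agg[("s", "absdiff")] == 2.0

    def test_identical_sides_zero_absdiff(self):
        stats = {"a": 0.4, "b": -1.2}
        agg = rp.bilateral_aggregate(stats, dict(stats))
        assert agg[("a", "absdiff")] == 0.0
        assert agg[("b", "absdiff")] == 0.0

    @given(
        st.dictionaries(
            st.sampled_from(["s1", "s2", "s3"]),
            st.floats(-10, 10, allow_nan=False),
            min_size=1,
        ),
        st.dictionaries(
            st.sampled_from(["s1", "s2", "s3"]),
            st.floats(-10, 10, allow_nan=False),
            min_size=1,
        ),
    )
    @settings(max_examples=50, derandomize=True)
    def test_swapping_sides_invariant(self, left, right):
        keys = set(left) & set(right)
        left = {k: left[k] for k in keys} or {"s1": 1.0}
        right = {k: right[k] for k in keys} or {"s1": 2.0}
        assert rp.bilateral_aggregate(left, right) == rp.bilateral_aggregate(
            right, left
        )

    def test_mismatched_stats_error(self):
        with pytest.raises(SchemaError, match="mismatched"):
            rp.bilateral_aggregate({"a": 1.0}, {"b": 1.0})


class TestFeatureDescriptor:
    def test_roundtrip_through_full_name(self, small_cohort_features):
        descs = list(next(iter(small_cohort_features.values())))
        assert len(descs) > 100
        for d in descs:
            assert FeatureDescriptor.parse(d.full_name) == d


class TestBuildFeatureMatrix:
    def test_rig_le_uses_lower_limb_motions(self, small_cohort,
                                            small_cohort_features):
        X = rp.build_feature_matrix(
            small_cohort_features, small_cohort.labels["Rig-LE"], "Rig-LE"
        )
        assert len(X.X) == 16
        assert X.motions == ("AFC", "GAIT", "LA", "TT")

    def test_deterministic_assembly(self, small_cohort, small_cohort_features):
        a = rp.build_feature_matrix(
            small_cohort_features, small_cohort.labels["PS"], "PS"
        )
        b = rp.build_feature_matrix(
            small_cohort_features, small_cohort.labels["PS"], "PS"
        )
        assert list(a.X.columns) == list(b.X.columns)
        assert a.X.equals(b.X)

    def test_empty_cohort_errors(self, small_cohort):
        with pytest.raises(SchemaError, match="empty"):
            rp.build_feature_matrix({}, small_cohort.labels["PS"], "PS")

    def test_unknown_motion_errors(self, small_cohort, small_cohort_features):
        with pytest.raises(SchemaError, match="unknown"):
            rp.build_feature_matrix(
                small_cohort_features, small_cohort.labels["PS"], "PS",
                motion_set=("WALTZ",),
            )

    def test_csv_roundtrip(self, small_cohort, small_cohort_features, tmp_path):
        X = rp.build_feature_matrix(
            small_cohort_features, small_cohort.labels["Rig-LE"], "Rig-LE"
        )
        X.to_csv(tmp_path / "m.csv")
        back = rp.FeatureMatrix.read_csv(tmp_path / "m.csv")
        assert back.target == "Rig-LE"
        assert list(back.X.columns) == list(X.X.columns)
        np.testing.assert_allclose(back.X.to_numpy(), X.X.to_numpy(), rtol=1e-9)


def test_scale_invariance_of_features():
    """Doubling raw pixel coordinates leaves extracted features unchanged."""
    cfg = rp.SyntheticCohortConfig(n_subjects=1, seed=3)
    rec = rp.simulate_recording(1, "LA", cfg, np.random.default_rng(5))
    rec2 = rp.MotionRecording(
        subject_id=rec.subject_id, motion=rec.motion, frame_rate=rec.frame_rate,
        skeleton=rec.skeleton,
        body=np.concatenate(
            [rec.body[:, :, :2] * 2.0, rec.body[:, :, 2:]], axis=2
        ),
    )
    f1 = extract_recording_features(preprocess_recording(rec))
    f2 = extract_recording_features(preprocess_recording(rec2))
    assert set(f1) == set(f2)
    for d in f1:
        assert f1[d] == pytest.approx(f2[d], rel=1e-6, abs=1e-9), d.full_name


def test_amplitude_decreases_with_severity():
    """Mean cycle amplitude falls with latent severity (rank corr < 0)."""
    cfg = rp.SyntheticCohortConfig(n_subjects=1, seed=0)
    rng_master = np.random.default_rng(2024)
    sev = rng_master.integers(0, 4, size=200)
    amps = []
    fc = FeatureExtractionConfig()
    for i, s in enumerate(sev):
        rec = rp.simulate_recording(
            int(s), "LA", cfg, np.random.default_rng(10_000 + i)
        )
        feats = extract_recording_features(preprocess_recording(rec), fc)
        d = {k.full_name: v for k, v in feats.items()}
        amps.append(d["LA__toe_height__kin_amp_mean__mean"])
    rho, p = sps.spearmanr(sev, amps)
    assert rho < 0
    assert p < 0.01
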