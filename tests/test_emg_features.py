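import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from eeslab.emg_features import (
    EnvelopeParams,
    compare_groups,
    compute_rauc,
    epoch,
    normalize_rauc,
    preprocess_emg,
    recruitment_curve,
    selectivity_index,
    threshold_amplitude,
)


class TestPreprocess:
    def test_mains_tone_attenuated_at_least_20db(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        tone = np.sin(2 * np.pi * 60.0 * t)
        env, _ = preprocess_emg(tone, fs)
        raw_rms = np.sqrt(np.mean(tone**2))
        assert 20 * np.log10(raw_rms / max(env.mean(), 1e-12)) >= 20

    def test_zero_signal_gives_zero_envelope(self):
        env, _ = preprocess_emg(np.zeros(4000), 2000.0)
        assert np.allclose(env, 0.0)

    def test_dc_offset_rejected_by_highpass(self):
        env, _ = preprocess_emg(np.full(8000, 3.0), 2000.0)
        assert env.mean() < 0.05  # steady-state DC suppressed

    def test_envelope_grid_is_one_value_per_hop(self):
        fs = 1000.0
        env, env_fs = preprocess_emg(np.random.default_rng(0).normal(size=3000), fs)
        hop = int(300 * (1 - 0.5))  # samples
        assert env.size == 1 + (3000 - 1) // hop
        assert env_fs == pytest.approx(fs / hop)

    def test_too_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess_emg(np.zeros(100), 100.0)

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            EnvelopeParams(rms_overlap_fraction=1.0)


class TestEpoch:
    def test_700ms_epoch_at_1khz(self):
        sig = np.zeros(5000)
        out = epoch(sig, 1000.0, [1000], pre_ms=100, post_ms=600)
        assert out.shape == (1, 700)

    def test_500ms_stimulation_triggered_epoch(self):
        sig = np.zeros(5000)
        out = epoch(sig, 1000.0, [1000, 2000], pre_ms=0, post_ms=500)
        assert out.shape == (2, 500)

    def test_event_too_early_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            epoch(np.zeros(1000), 1000.0, [0], pre_ms=100, post_ms=100)

    def test_alignment_half_open(self):
        sig = np.arange(100.0)
        out = epoch(sig, 1000.0, [10], pre_ms=2, post_ms=3)
        assert np.array_equal(out[0], [8, 9, 10, 11, 12])


class TestRauc:
    def test_hand_sum(self):
        assert compute_rauc(np.array([1.0, -2.0, 3.0])) == 6.0

    def test_zero_epoch(self):
        assert compute_rauc(np.zeros(10)) == 0.0

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError):
            compute_rauc(np.array([]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_rectification_symmetry(self, values):
        x = np.asarray(values)
        assert compute_rauc(x) == compute_rauc(-x)


def _table(values_by_muscle):
    rows = []
    for muscle, vals in values_by_muscle.items():
        for i, v in enumerate(vals):
            rows.append({"muscle": muscle, "rauc_raw": v, "electrode": "E00",
                         "amplitude_ua": 100.0 * (i + 1), "frequency_hz": 50.0, "repeat": 0})
    return pd.DataFrame(rows)


class TestNormalizeRauc:
    def test_min_maps_to_zero_max_to_one(self):
        out = normalize_rauc(_table({"m": [2.0, 4.0, 6.0]}))
        assert np.allclose(sorted(out["rauc_norm"]), [0.0, 0.5, 1.0])

    def test_constant_muscle_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_rauc(_table({"m": [3.0, 3.0]}))

    def test_joint_normalization_pools_ranges(self):
        mono = _table({"m": [0.0, 10.0]})
        bipolar = _table({"m": [1.0, 5.0]})
        out = normalize_rauc(bipolar, extra_tables=[mono])
        assert out["rauc_norm"].max() < 1.0  # bipolar max below pooled max
        assert np.allclose(out["rauc_norm"], [0.1, 0.5])


class TestRecruitmentCurve:
    def test_mean_and_population_sd(self):
        rows = pd.DataFrame(
            {
                "electrode": ["E00"] * 4,
                "frequency_hz": [50.0] * 4,
                "amplitude_ua": [100.0] * 4,
                "muscle": ["m"] * 4,
                "rauc_norm": [0.2, 0.2, 0.2, 0.2],
            }
        )
        curve = recruitment_curve(rows, "E00", 50.0)
        assert curve["mean"].iloc[0] == pytest.approx(0.2)
        assert curve["sd"].iloc[0] == 0.0

    def test_single_repeat_sd_zero(self):
        rows = pd.DataFrame(
            {"electrode": ["E00"], "frequency_hz": [50.0], "amplitude_ua": [100.0],
             "muscle": ["m"], "rauc_norm": [0.7]}
        )
        assert recruitment_curve(rows, "E00", 50.0)["sd"].iloc[0] == 0.0

    def test_missing_condition_rejected(self):
        rows = _table({"m": [1.0]})
        with pytest.raises(KeyError):
            recruitment_curve(rows, "E99", 50.0, value_col="rauc_raw")

    def test_monotone_ground_truth_yields_monotone_curve(self, ground_truth, hd64_layout):
        from eeslab.synthetic_data import simulate_activation

        amps = [100.0, 450.0, 800.0, 1150.0, 1500.0]
        rows = []
        for a in amps:
            act = simulate_activation(ground_truth, hd64_layout.coords_mm[3], a, 50)
            for m, name in enumerate(ground_truth.muscle_names):
                rows.append({"electrode": "E03", "frequency_hz": 50.0, "amplitude_ua": a,
                             "muscle": name, "rauc_norm": act[m]})
        curve = recruitment_curve(pd.DataFrame(rows), "E03", 50.0)
        for name in ground_truth.muscle_names:
            means = curve[curve["muscle"] == name].sort_values("amplitude_ua")["mean"]
            assert np.all(np.diff(means) >= -1e-12)


class TestThreshold:
    def _curve(self, means, amps):
        return pd.DataFrame({"muscle": "m", "amplitude_ua": amps, "mean": means})

    def test_hand_example(self):
        curve = self._curve([0.1, 0.5, 0.9], [200.0, 400.0, 600.0])
        assert threshold_amplitude(curve, "m") == 400.0

    def test_max_attained_in_curve_always_reached(self):
        curve = self._curve([0.0, 0.0, 0.8], [200.0, 400.0, 600.0])
        assert threshold_amplitude(curve, "m") == 600.0

    def test_global_max_mode_yields_not_reached(self):
        curve = self._curve([0.01, 0.02, 0.05], [200.0, 400.0, 600.0])
        assert np.isnan(threshold_amplitude(curve, "m", max_activation=1.0))


class TestSelectivity:
    def test_perfectly_selective(self):
        si = selectivity_index([1, 0, 0, 0, 0, 0])
        assert np.allclose(si, [1, 0, 0, 0, 0, 0])

    def test_uniform_activation(self):
        assert np.allclose(selectivity_index(np.ones(6)), 1 / 6)

    def test_ratio_arithmetic(self):
        assert np.allclose(selectivity_index([3, 1, 0, 0, 0, 0]), [0.75, 0.25, 0, 0, 0, 0])

    def test_all_zero_gives_all_zero(self):
        si = selectivity_index(np.zeros(6))
        assert np.allclose(si, 0.0) and si.sum() == 0.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            selectivity_index([-1, 2])

    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_zero_or_one(self, vals):
        s = selectivity_index(np.asarray(vals)).sum()
        assert s == pytest.approx(0.0) or s == pytest.approx(1.0)


def brute_force_u(a, b):
    """Pairwise-comparison count oracle for the Mann–Whitney U statistic."""
    u = 0.0
    for x in a:
        for y in b:
            u += 1.0 if x > y else (0.5 if x == y else 0.0)
    return u


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        _, p = compare_groups([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert p > 0.9

    def test_disjoint_groups_u_is_zero_for_low_group(self):
        u, _ = compare_groups([1, 2, 3], [10, 11, 12])
        assert u == 0.0

    def test_u_matches_pairwise_count_oracle(self, rng):
        for _ in range(10):
            a = rng.integers(0, 20, size=8).astype(float)
            b = rng.integers(0, 20, size=8).astype(float)
            u, _ = compare_groups(a, b)
            assert u == pytest.approx(brute_force_u(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])


class TestBipoleSelectivityContrast:
    def test_narrow_bipoles_more_selective_than_wide(self, ground_truth):
        """Tight cathode-anode spacing concentrates the field near one pool;
        wide spacing recruits across pools, which shifts the selectivity
        distribution detectably at the highest amplitude."""
        from eeslab.synthetic_data import simulate_activation

        rng = np.random.default_rng(42)
        amp = 1500.0

        def si_samples(spread_mm):
            # bipolar field approximated by its midpoint, with dispersion
            # growing with contact separation: wide bipoles blur toward the
            # contralateral pools
            out = []
            for _ in range(40):
                centre = np.array([rng.uniform(1, 5), rng.uniform(4, 19)])
                jitter = rng.normal(0, spread_mm / 2, size=2)
                act = simulate_activation(ground_truth, centre + jitter, amp, 50)
                out.append(selectivity_index(act).max())
            return np.asarray(out)

        narrow = si_samples(0.7)
        wide = si_samples(6.0)
        _, p = compare_groups(narrow, wide)
        assert p < 0.05
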