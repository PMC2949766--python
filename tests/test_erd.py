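"""Laplacian re-referencing, time-frequency maps, and ERD/ERS statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mibci as m
from mibci.erd import TFMap

RATE = 256.0


def tone_recording(labels, freq=10.0, seconds=13.0, amps=None):
    t = np.arange(int(seconds * RATE)) / RATE
    base = np.sin(2 * np.pi * freq * t)
    amps = amps or [1.0] * len(labels)
    return m.EEGRecording(RATE, labels, np.vstack([a * base for a in amps]))


class TestLaplacian:
    def test_constant_field_annihilated(self, montage):
        labels = tuple(l for l in montage.labels if not l.endswith("'"))
        rec = m.EEGRecording(RATE, labels, np.full((27, 64), 42.0))
        out = m.laplacian(rec, montage)
        assert np.allclose(out.data, 0)
        assert out.reference == "laplacian"

    def test_focal_signal_passes_unchanged(self, montage):
        labels = tuple(l for l in montage.labels if not l.endswith("'"))
        data = np.zeros((27, 256))
        s = np.sin(2 * np.pi * 10 * np.arange(256) / RATE)
        data[labels.index("Cz")] = s
        rec = m.EEGRecording(RATE, labels, data)
        out = m.laplacian(rec, montage, channels=["Cz"])
        np.testing.assert_allclose(out.channel("Cz"), s)

    def test_cz_uses_its_four_grid_neighbors(self, montage):
        labels = ("Cz", "FCz", "C1", "C2", "CPz")
        data = np.vstack([np.full(8, 10.0), np.full(8, 2.0), np.full(8, 4.0),
                          np.full(8, 6.0), np.full(8, 8.0)])
        rec = m.EEGRecording(RATE, labels, data)
        out = m.laplacian(rec, m.montage_subset(montage, labels), channels=["Cz"])
        np.testing.assert_allclose(out.channel("Cz"), 10.0 - 5.0)

    def test_edge_channels_flagged_as_partial(self, montage):
        labels = tuple(l for l in montage.labels if not l.endswith("'"))
        rec = m.EEGRecording(RATE, labels,
                             np.random.default_rng(0).normal(size=(27, 64)))
        out = m.laplacian(rec, montage)
        assert "FT7" in out.partial_channels  # grid corner: 2 neighbours
        assert "Cz" not in out.partial_channels

    @given(st.floats(-5, 5), st.floats(-5, 5))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, a, b):
        labels = ("Cz", "FCz", "C1", "C2", "CPz")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, 32))
        Y = rng.normal(size=(5, 32))
        sub = m.montage_subset(m.default_montage(), labels)
        lap = lambda d: m.laplacian(m.EEGRecording(RATE, labels, d), sub,
                                    channels=["Cz"]).data
        np.testing.assert_allclose(lap(a * X + b * Y), a * lap(X) + b * lap(Y),
                                   atol=1e-9)

    def test_bipolar_input_rejected(self, montage):
        rec = m.EEGRecording(RATE, ("Cz",), np.zeros((1, 8)), reference="bipolar")
        with pytest.raises(m.ValidationError, match="monopolar"):
            m.laplacian(rec, montage)


class TestTimeFreq:
    def test_pure_tone_peaks_at_its_bin(self):
        rec = tone_recording(("Cz",), freq=10.0)
        trials = m.TrialSet([0.0], ("feet",))
        tf = m.time_freq(rec, trials, "feet", "Cz")
        assert np.all(tf.freqs[np.argmax(tf.power, axis=0)] == 10.0)
        # rectangular-window scaling: an in-bin tone of amplitude A reads A^2/2
        assert tf.power.max() == pytest.approx(0.5, rel=1e-6)

    def test_frequency_grid_is_1hz_4_to_45(self):
        rec = tone_recording(("Cz",))
        tf = m.time_freq(rec, m.TrialSet([0.0], ("feet",)), "feet", "Cz")
        np.testing.assert_allclose(np.diff(tf.freqs), 1.0)
        assert tf.freqs[0] == 4.0 and tf.freqs[-1] == 45.0

    def test_segments_advance_by_rate_over_16(self):
        rec = tone_recording(("Cz",))
        tf = m.time_freq(rec, m.TrialSet([0.0], ("feet",)), "feet", "Cz")
        # 13-s trial, 1-s segments, step 1/16 s -> 193 segments
        assert len(tf.times) == 193
        np.testing.assert_allclose(np.diff(tf.times), 1 / 16)

    def test_identical_trials_average_to_single_trial(self):
        t = np.arange(int(26 * RATE)) / RATE
        one = np.sin(2 * np.pi * 10 * (t[:int(13 * RATE)]))
        rec = m.EEGRecording(RATE, ("Cz",), np.tile(one, 2)[None, :])
        single = m.time_freq(rec, m.TrialSet([0.0], ("feet",)), "feet", "Cz")
        double = m.time_freq(rec, m.TrialSet([0.0, 13.0], ("feet", "feet")),
                             "feet", "Cz")
        np.testing.assert_allclose(double.power, single.power, rtol=1e-10)

    def test_trial_past_end_rejected(self):
        rec = tone_recording(("Cz",), seconds=10.0)
        with pytest.raises(m.ValidationError, match="past the recording end"):
            m.time_freq(rec, m.TrialSet([0.0], ("feet",)), "feet", "Cz")


def flat_map(power_profile, freqs=None):
    """TFMap with a given power-versus-time profile, equal across frequencies."""
    freqs = freqs if freqs is not None else np.arange(4.0, 46.0)
    times = np.arange(0.5, 12.51, 1 / 16)
    power = np.tile(np.asarray(power_profile, float), (len(freqs), 1))
    return TFMap("Cz", freqs, times, power)


class TestErdErs:
    def test_power_equal_to_baseline_is_zero_percent(self):
        times = np.arange(0.5, 12.51, 1 / 16)
        emap = m.erd_ers(flat_map(np.full(len(times), 3.7)))
        assert np.allclose(emap.values, 0.0)

    def test_task_power_045_of_rest_is_minus_55(self):
        times = np.arange(0.5, 12.51, 1 / 16)
        profile = np.where((times >= 5) & (times < 10), 0.45, 1.0)
        emap = m.erd_ers(flat_map(profile))
        mi = (emap.times >= 5) & (emap.times < 10)
        assert np.allclose(emap.values[:, mi], -55.0)

    def test_task_power_131_of_rest_is_plus_31(self):
        times = np.arange(0.5, 12.51, 1 / 16)
        profile = np.where((times >= 5) & (times < 10), 1.31, 1.0)
        emap = m.erd_ers(flat_map(profile))
        mi = (emap.times >= 5) & (emap.times < 10)
        assert np.allclose(emap.values[:, mi], 31.0)

    def test_zero_baseline_power_names_frequency(self):
        times = np.arange(0.5, 12.51, 1 / 16)
        tf = flat_map(np.ones(len(times)))
        tf.power[3, :] = 0.0  # 7 Hz row
        with pytest.raises(m.ValidationError, match="7"):
            m.erd_ers(tf)

    def test_invariant_under_global_amplitude_scaling(self):
        rng = np.random.default_rng(4)
        times = np.arange(0.5, 12.51, 1 / 16)
        profile = 1.0 + 0.5 * rng.random(len(times))
        tf = flat_map(profile)
        scaled = TFMap("Cz", tf.freqs, tf.times, 9.0 * tf.power)
        np.testing.assert_allclose(m.erd_ers(tf).values,
                                   m.erd_ers(scaled).values, atol=1e-9)


class TestBandCurve:
    def test_constant_band_passes_through(self):
        emap = m.erd_ers(flat_map(np.full(193, 2.0)))
        emap.values[:, :] = -50.0
        curve = m.band_curve(emap, (8, 13))
        assert np.allclose(curve.erd_percent, -50.0)

    def test_mean_of_split_band(self):
        emap = m.erd_ers(flat_map(np.full(193, 2.0)))
        rows = (emap.freqs >= 8) & (emap.freqs <= 13)
        vals = np.where(emap.freqs[rows] < 11, -40.0, -60.0)  # 8,9,10 / 11,12,13
        emap.values[rows, :] = vals[:, None]
        curve = m.band_curve(emap, (8, 13))
        assert np.allclose(curve.erd_percent, -50.0)

    def test_empty_band_rejected(self):
        emap = m.erd_ers(flat_map(np.ones(193)))
        with pytest.raises(m.ValidationError, match="band"):
            m.band_curve(emap, (46.5, 47.5))

    def test_recovers_injected_mu_erd(self, c4_montage):
        # Monte-Carlo oracle: amplitude factor sqrt(0.5) -> band-curve ERD -50%
        subject = m.SubjectModel(modulation={("left_hand", "C4", "mu"): np.sqrt(0.5)})
        vals = []
        for seed in range(5):
            rec, trials = m.generate_session(m.SessionProtocol(n_trials=100),
                                             subject, c4_montage, seed=seed)
            lap = m.laplacian(rec, c4_montage, channels=["C4"])
            emap = m.erd_ers(m.time_freq(lap, trials, "left_hand", "C4"))
            curve = m.band_curve(emap, (8, 13))
            plateau = (curve.times >= 5.5) & (curve.times < 10)
            vals.append(curve.erd_percent[plateau].mean())
        assert np.mean(vals) == pytest.approx(-50.0, abs=6.0)


class TestCompareDays:
    def _curves(self, rng, n, level, jitter=1.0):
        times = np.arange(0.5, 12.51, 1 / 16)
        out = []
        for _ in range(n):
            vals = level(times) + jitter * rng.normal(size=len(times))
            out.append(m.BandCurve("Cz", (8.0, 13.0), times, vals))
        return out

    def test_identical_inputs_have_no_marks(self):
        rng = np.random.default_rng(5)
        pre = self._curves(rng, 10, lambda t: np.zeros(len(t)))
        table = m.compare_days(pre, pre)
        assert not table["significant"].any()

    def test_constant_shift_marks_all_window_points(self):
        rng = np.random.default_rng(6)
        pre = self._curves(rng, 50, lambda t: np.full(len(t), -20.0))
        post = self._curves(rng, 50, lambda t: np.full(len(t), -50.0))
        table = m.compare_days(pre, post)
        assert table["significant"].all()
        assert table["time_s"].min() >= 5.0 and table["time_s"].max() < 10.0

    def test_alpha_zero_marks_nothing(self):
        rng = np.random.default_rng(7)
        pre = self._curves(rng, 20, lambda t: np.zeros(len(t)))
        post = self._curves(rng, 20, lambda t: np.full(len(t), -50.0))
        table = m.compare_days(pre, post, alpha=0.0)
        assert not table["significant"].any()

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(8)
        pre = self._curves(rng, 5, lambda t: np.zeros(len(t)))
        with pytest.raises(m.ValidationError, match="6"):
            m.compare_days(pre, pre)


class TestTopography:
    def _zero_curves(self, montage):
        times = np.arange(0.5, 12.51, 1 / 16)
        labels = [l for l in montage.labels if not l.endswith("'")]
        return {ch: m.BandCurve(ch, (8.0, 13.0), times, np.zeros(len(times)))
                for ch in labels}

    def test_all_zero_gives_27_zero_rows(self, montage):
        table = m.topography_export(self._zero_curves(montage), montage)
        assert len(table) == 27
        assert np.allclose(table["value"], 0.0)

    def test_modulated_channel_is_the_extremum(self, montage):
        curves = self._zero_curves(montage)
        times = curves["C4"].times
        vals = np.where((times >= 5) & (times < 10), -50.0, 0.0)
        curves["C4"] = m.BandCurve("C4", (8.0, 13.0), times, vals)
        table = m.topography_export(curves, montage)
        assert table.loc[table["value"].idxmin(), "channel"] == "C4"

    def test_missing_channels_listed(self, montage):
        curves = self._zero_curves(montage)
        del curves["CP3"]
        with pytest.raises(m.ValidationError, match="CP3"):
            m.topography_export(curves, montage)
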