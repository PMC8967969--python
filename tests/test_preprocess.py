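import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from emgsi.errors import DataError, ExclusionError, ParameterError
from emgsi.io import ArtifactTable, EventTable
from emgsi.montage import CANONICAL_CHANNELS, ChannelLabel, TaskId
from emgsi.preprocess import (
    BaselineProfile,
    FilterSpec,
    cut_artifacts,
    estimate_baseline,
    highpass,
    notch,
    window_rms,
)
from emgsi.similarity import response_vector

from conftest import full_event_table, make_events, make_recording

FS = 500.0


def central(x, frac=0.25):
    n = len(x)
    return x[int(n * frac) : int(n * (1 - frac))]


def sine(freq, duration_s, fs=FS):
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestHighpass:
    def test_dc_offset_removed(self):
        rec = make_recording(np.full(4000, 100.0), fs=FS)
        out = highpass(rec)
        assert np.abs(central(out.samples[:, 0])).max() < 1.0
        assert out.n_samples == rec.n_samples

    def test_passband_sinusoid_preserved(self):
        rec = make_recording(sine(100.0, 8.0), fs=FS)
        out = highpass(rec)
        amp = np.sqrt(2) * np.std(central(out.samples[:, 0]))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation_matches_design(self):
        spec = FilterSpec()
        rec = make_recording(sine(5.0, 8.0), fs=FS)
        out = highpass(rec, spec)
        measured = np.sqrt(2) * np.std(central(out.samples[:, 0]))
        w, h = sps.freqz(spec.highpass_taps(FS), worN=[5.0], fs=FS)
        designed = float(np.abs(h[0]))
        assert measured == pytest.approx(designed, abs=5e-3)

    def test_zero_phase(self):
        # a symmetric FIR applied with delay compensation must not shift a burst
        x = np.zeros(4000)
        x[2000] = 1.0
        rec = make_recording(x, fs=FS)
        out = highpass(rec)
        assert np.argmax(np.abs(out.samples[:, 0])) == 2000

    def test_linearity(self, rng):
        x = rng.normal(size=(3000, 10))
        y = rng.normal(size=(3000, 10))
        a, b = 2.5, -0.7
        lhs = highpass(make_recording(a * x + b * y, fs=FS)).samples
        rhs = a * highpass(make_recording(x, fs=FS)).samples + b * highpass(
            make_recording(y, fs=FS)
        ).samples
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(np.zeros(2000), fs=FS)
        with pytest.raises(ParameterError):
            highpass(rec, FilterSpec(highpass_cutoff_hz=300.0))

    def test_auto_order_even_and_scaled(self):
        assert FilterSpec().resolved_order(1500.0) == 300
        assert FilterSpec().resolved_order(FS) % 2 == 0


class TestNotch:
    def _flags(self, *on):
        flags = np.zeros(10, bool)
        flags[list(on)] = True
        return flags

    def test_flagged_channel_mains_suppressed(self):
        rec = make_recording(sine(50.0, 8.0), fs=FS, notch_flags=self._flags(0))
        out = notch(rec)
        residual = np.sqrt(2) * np.std(central(out.samples[:, 0]))
        assert residual < 0.05

    def test_unflagged_channel_bit_identical(self):
        rec = make_recording(sine(50.0, 8.0), fs=FS, notch_flags=self._flags(0))
        out = notch(rec)
        assert (out.samples[:, 1] == rec.samples[:, 1]).all()

    def test_flagged_channel_passband_preserved(self):
        rec = make_recording(sine(100.0, 8.0), fs=FS, notch_flags=self._flags(0))
        out = notch(rec)
        amp = np.sqrt(2) * np.std(central(out.samples[:, 0]))
        assert amp == pytest.approx(1.0, rel=0.05)


class TestCutArtifacts:
    def _artifacts(self, rows):
        return ArtifactTable(pd.DataFrame(rows, columns=list(ArtifactTable.COLUMNS)))

    def test_global_cut_shifts_events(self, rng):
        rec = make_recording(rng.normal(size=(9000, 10)), fs=1500.0)
        events = make_events([(1.0, 2.0), (2.5, 3.5), (4.0, 5.0)])
        art = self._artifacts([[0.2, 0.7, "all", "cable"]])
        rec2, ev2, excl = cut_artifacts(rec, art, events)
        assert rec2.n_samples == 9000 - 750
        assert ev2.window(TaskId("ankle", "less"), 1) == pytest.approx((0.5, 1.5))
        assert excl == frozenset()

    def test_no_artifacts_identity(self, rng, empty_artifacts):
        rec = make_recording(rng.normal(size=(9000, 10)), fs=1500.0)
        events = make_events([(1.0, 2.0), (2.5, 3.5), (4.0, 5.0)])
        rec2, ev2, excl = cut_artifacts(rec, empty_artifacts, events)
        assert rec2 is rec
        assert ev2 is events

    def test_samples_outside_cuts_preserved_in_order(self, rng):
        rec = make_recording(rng.normal(size=(9000, 10)), fs=1500.0)
        events = make_events([(4.0, 4.5), (4.6, 5.0), (5.1, 5.5)])
        art = self._artifacts([[1.0, 1.5, "all", "a"], [2.0, 2.2, "all", "b"]])
        rec2, _, _ = cut_artifacts(rec, art, events)
        keep = np.ones(9000, bool)
        keep[1500:2250] = False
        keep[3000:3300] = False
        np.testing.assert_array_equal(rec2.samples, rec.samples[keep])

    def test_channel_scoped_artifact_excludes_repetition(self, rng):
        fs = 100.0
        samples = rng.normal(size=(1200, 10)) * 0.001
        # channel TA_r: constant amplitude 4, 6, 8 in the three repetitions
        samples[100:200, 0] = 4.0
        samples[300:400, 0] = 6.0
        samples[500:600, 0] = 8.0
        rec = make_recording(samples, fs=fs)
        events = make_events([(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)])
        art = self._artifacts([[3.2, 3.4, "TA_r", "touched"]])
        rec2, ev2, excl = cut_artifacts(rec, art, events)
        task = TaskId("ankle", "less")
        assert excl == frozenset({(task, 2, ChannelLabel("TA", "r"))})
        rv = response_vector(rec2, ev2, task, exclusions=excl)
        # mean over remaining reps {1, 3}: (4 + 8) / 2
        assert rv.values[0] == pytest.approx(6.0, rel=1e-3)
        assert rv.n_reps_used[0] == 2
        assert rv.n_reps_used[1] == 3

    def test_artifact_covering_full_repetition_raises(self, rng):
        rec = make_recording(rng.normal(size=(9000, 10)), fs=1500.0)
        events = make_events([(1.0, 2.0), (2.5, 3.5), (4.0, 5.0)])
        art = self._artifacts([[2.4, 3.6, "all", "swallows rep 2"]])
        with pytest.raises(ExclusionError, match="repetition 2"):
            cut_artifacts(rec, art, events)


class TestBaseline:
    def test_all_zero_channel(self):
        rec = make_recording(np.zeros((1000, 10)), fs=100.0)
        profile = estimate_baseline(rec)
        assert (profile.baseline_rms == 0).all()

    def test_silent_gap_located(self, rng):
        fs = 100.0
        x = 10.0 * rng.choice([-1.0, 1.0], size=3000)  # constant-amplitude noise
        x[1200:1500] = 0.0  # 3-s silent gap at 12 s
        rec = make_recording(x, fs=fs)
        profile = estimate_baseline(rec, step_s=0.1)
        assert profile.baseline_rms[0] == pytest.approx(0.0, abs=1e-12)
        assert profile.window_start_s[0] == pytest.approx(12.0, abs=0.1)

    def test_stride_vs_exhaustive_oracle(self, rng):
        fs = 100.0
        t = np.arange(3000) / fs
        envelope = 5.0 + 4.0 * np.sin(2 * np.pi * t / 30.0)  # smooth, >= 1
        x = envelope * rng.normal(size=3000)
        rec = make_recording(x, fs=fs)
        fast = estimate_baseline(rec, step_s=0.1)
        exact = estimate_baseline(rec, step_s=1.0 / fs)  # stride-1 oracle
        assert fast.baseline_rms[0] >= exact.baseline_rms[0] - 1e-12
        assert fast.baseline_rms[0] == pytest.approx(exact.baseline_rms[0], rel=0.02)

    def test_minimality_against_every_window(self, rng):
        fs = 50.0
        rec = make_recording(rng.normal(size=(400, 10)), fs=fs)
        profile = estimate_baseline(rec, step_s=1.0 / fs)
        w = int(3.0 * fs)
        x = rec.samples[:, 0]
        all_rms = [
            np.sqrt(np.mean(x[s : s + w] ** 2)) for s in range(len(x) - w + 1)
        ]
        assert profile.baseline_rms[0] == pytest.approx(min(all_rms), abs=1e-12)

    def test_too_short_recording(self):
        rec = make_recording(np.zeros((300, 10)), fs=100.0)
        with pytest.raises(DataError):
            estimate_baseline(rec, window_s=4.0)


class TestWindowRms:
    def test_constant(self):
        rec = make_recording(np.full(1000, 5.0), fs=100.0)
        assert window_rms(rec, 1.0, 3.0, 0) == pytest.approx(5.0)

    def test_unit_sinusoid_integer_periods(self):
        fs = 100.0
        t = np.arange(1000) / fs
        rec = make_recording(np.sin(2 * np.pi * 5.0 * t), fs=fs)
        assert window_rms(rec, 0.0, 2.0, 0) == pytest.approx(1 / np.sqrt(2), rel=1e-9)

    def test_brute_force_eight_samples(self):
        x = np.array([1.0, -2.0, 3.0, 0.5, -0.5, 2.0, -1.0, 4.0])
        rec = make_recording(np.tile(np.r_[x, np.zeros(292)][:, None], (1, 10)), fs=1.0)
        expected = np.sqrt(np.sum(x**2) / 8)
        assert window_rms(rec, 0.0, 8.0, 3) == pytest.approx(expected, rel=1e-12)

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=400)
        rec_pos = make_recording(x, fs=100.0)
        rec_neg = make_recording(-x, fs=100.0)
        assert window_rms(rec_pos, 0.5, 3.5, 0) == window_rms(rec_neg, 0.5, 3.5, 0)

    def test_empty_window(self):
        rec = make_recording(np.zeros(400), fs=100.0)
        with pytest.raises(DataError):
            window_rms(rec, 1.0, 1.0, 0)

    def test_half_open_convention(self):
        fs = 10.0
        x = np.zeros(40)
        x[10:20] = 3.0  # exactly [1.0 s, 2.0 s)
        rec = make_recording(x, fs=fs)
        assert window_rms(rec, 1.0, 2.0, 0) == pytest.approx(3.0)
        assert window_rms(rec, 2.0, 3.0, 0) == pytest.approx(0.0)
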