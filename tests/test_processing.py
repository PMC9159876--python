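import numpy as np
import pytest
from hypothesis import given, strategies as st

from painmap.geometry import ElectrodeGrid, EMGRecording, PhaseWindow
from painmap.processing import (
    RMSMap,
    bandpass_filter,
    compute_rms,
    exclude_noisy,
    extension_activity,
    normalize_rms,
    rms_map,
    segment_phases,
)

FS = 1000.0


def sine(freq, seconds=2.0, fs=FS):
    t = np.arange(int(seconds * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def tiny_grids():
    left = ElectrodeGrid(side="left", n_electrodes=2)
    right = ElectrodeGrid(side="right", n_electrodes=2)
    return (left, right)


def toy_map(values, normalized=False, excluded=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[1]
    return RMSMap(
        values=values,
        channel_y_cm=1.25 + 2.5 * np.arange(n),
        channel_sides=tuple(["left"] * (n // 2) + ["right"] * (n - n // 2)),
        normalized=normalized,
        excluded=excluded,
    )


class TestBandpass:
    def test_dc_removed(self):
        out = bandpass_filter(np.full(2000, 5.0), FS)
        assert np.max(np.abs(out[200:-200])) < 0.05

    def test_passband_gain_near_unity(self):
        out = bandpass_filter(sine(100.0), FS)
        # amplitude via RMS: sample peaks of a 100 Hz tone at 1 kHz miss the crest
        amp = np.sqrt(2) * compute_rms(out[200:-200])
        assert amp == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuates_movement_artefact(self):
        out = bandpass_filter(sine(2.0), FS)
        assert np.max(np.abs(out[400:-400])) < 0.05

    def test_idempotent_on_in_band_content(self):
        once = bandpass_filter(sine(100.0, seconds=4.0), FS)
        twice = bandpass_filter(once, FS)
        mid = slice(500, -500)
        ratio = np.max(np.abs(twice[mid])) / np.max(np.abs(once[mid]))
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_short_signal_error_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            bandpass_filter(np.ones(10), FS)


class TestSegmentation:
    def make_recording(self, n_samples):
        return EMGRecording(samples=np.zeros((n_samples, 8)))

    def test_windows_partition_recording(self):
        windows = segment_phases(self.make_recording(12_000))
        assert [w.name for w in windows] == [
            "standing", "flexion", "full_flexion", "extension",
        ]
        assert windows[-1].start_sample == 9000
        assert windows[-1].end_sample == 12_000
        spans = [(w.start_sample, w.end_sample) for w in windows]
        assert spans == [(0, 3000), (3000, 6000), (6000, 9000), (9000, 12_000)]

    def test_duration_mismatch_reports_counts(self):
        with pytest.raises(ValueError, match="11999"):
            segment_phases(self.make_recording(11_999))


class TestRMS:
    @pytest.mark.parametrize(
        "samples,expected",
        [
            (np.full(100, 3.0), 3.0),
            (np.full(100, -3.0), 3.0),
            (np.array([3.0, 4.0]), np.sqrt(12.5)),
        ],
    )
    def test_closed_forms(self, samples, expected):
        assert compute_rms(samples) == pytest.approx(expected, rel=1e-12)

    def test_unit_sine_over_whole_periods(self):
        assert compute_rms(sine(50.0, seconds=1.0)) == pytest.approx(
            1 / np.sqrt(2), abs=1e-3
        )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_rms(np.array([]))

    @given(
        st.floats(min_value=-100, max_value=100),
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3), min_size=2, max_size=50
        ),
    )
    def test_homogeneity(self, a, samples):
        x = np.asarray(samples)
        assert compute_rms(a * x) == pytest.approx(
            abs(a) * compute_rms(x), rel=1e-9, abs=1e-9
        )


class TestRMSMapOracle:
    def test_hand_computed_toy_recording(self):
        # 8 samples, 2 channels, fictitious 2-sample phases, filter bypassed
        samples = np.array(
            [
                [1.0, 2.0], [-1.0, 2.0],       # standing
                [3.0, 0.0], [4.0, 0.0],        # flexion
                [0.0, 1.0], [0.0, -1.0],       # full flexion
                [2.0, 6.0], [2.0, 8.0],        # extension
            ]
        )
        windows = [
            PhaseWindow(name, 2 * i, 2 * i + 2)
            for i, name in enumerate(("standing", "flexion", "full_flexion", "extension"))
        ]
        rec = EMGRecording(
            samples=samples, grids=tiny_grids(), phase_boundaries=windows
        )
        m = rms_map(rec, bandpass=False)
        expected = np.array(
            [
                [1.0, 2.0],
                [np.sqrt(12.5), 0.0],
                [0.0, 1.0],
                [2.0, np.sqrt(50.0)],
            ]
        )
        np.testing.assert_allclose(m.values, expected, rtol=1e-12)
        assert not m.normalized

    def test_all_zero_recording_gives_zero_map(self):
        rec = EMGRecording(samples=np.zeros((12_000, 8)))
        assert not rms_map(rec).values.any()

    def test_channel_order_matches_grids(self, small_cohort):
        pid = small_cohort.patients[0].patient_id
        rec = small_cohort.recordings[(pid, 0)]
        m = rms_map(rec)
        assert list(m.channel_sides) == rec.channel_sides
        np.testing.assert_allclose(m.channel_y_cm, rec.channel_y_cm)

    def test_phase_amplitude_ratio_round_trip(self):
        from painmap.cohort import CohortConfig, synthesize_trial
        from painmap.geometry import default_grid_pair

        cfg = CohortConfig(
            phase_amplitude_factors=(1.0, 2.0, 0.5, 1.0), noise_floor=0.0
        )
        rec = synthesize_trial(
            np.ones(8), cfg, default_grid_pair(), np.random.default_rng(3)
        )
        m = rms_map(rec)
        ratio = m.values[1] / m.values[0]
        assert np.all(np.abs(ratio - 2.0) < 0.2)


class TestNormalization:
    def test_self_normalization_extension_row_is_one(self):
        m = toy_map(np.random.default_rng(0).uniform(0.5, 2.0, (4, 4)))
        norm = normalize_rms([m], m)
        np.testing.assert_allclose(norm.values[-1], 1.0, rtol=1e-12)
        assert norm.normalized

    def test_scale_matches_cohort_descriptive(self):
        ref = toy_map(np.full((4, 4), 2.0))
        exp = toy_map(np.full((4, 4), 2.02))
        norm = normalize_rms([exp], ref)
        np.testing.assert_allclose(norm.values[-1], 1.01, rtol=1e-12)

    def test_homogeneity_in_experimental_signal(self):
        rng = np.random.default_rng(1)
        ref = toy_map(rng.uniform(0.5, 2.0, (4, 4)))
        exp = toy_map(rng.uniform(0.5, 2.0, (4, 4)))
        doubled = toy_map(2.0 * exp.values)
        np.testing.assert_allclose(
            normalize_rms([doubled], ref).values,
            2.0 * normalize_rms([exp], ref).values,
            rtol=1e-12,
        )

    def test_zero_reference_channel_rejected(self):
        ref_values = np.full((4, 4), 2.0)
        ref_values[-1, 1] = 0.0
        with pytest.raises(ValueError, match="zero"):
            normalize_rms([toy_map(np.ones((4, 4)))], toy_map(ref_values))

    def test_mean_over_trials(self):
        ref = toy_map(np.full((4, 4), 1.0))
        a = toy_map(np.full((4, 4), 1.0))
        b = toy_map(np.full((4, 4), 3.0))
        np.testing.assert_allclose(normalize_rms([a, b], ref).values, 2.0)


class TestExtensionActivity:
    def test_uniform_map(self):
        m = toy_map(np.ones((4, 4)), normalized=True)
        assert extension_activity(m) == 1.0

    def test_masked_side_ignored(self):
        values = np.ones((4, 4))
        values[-1] = [0.8, 1.0, 1.2, 99.0]
        excluded = np.zeros((4, 4), dtype=bool)
        excluded[-1, 3] = True
        m = toy_map(values, normalized=True, excluded=excluded)
        assert extension_activity(m) == pytest.approx(1.0)

    def test_requires_normalized_map(self):
        with pytest.raises(ValueError, match="normalized"):
            extension_activity(toy_map(np.ones((4, 4))))

    def test_all_excluded_rejected(self):
        m = toy_map(np.ones((4, 4)), normalized=True,
                    excluded=np.ones((4, 4), dtype=bool))
        with pytest.raises(ValueError, match="excluded"):
            extension_activity(m)


class TestNoiseExclusion:
    def test_homogeneous_map_untouched(self):
        m = exclude_noisy(toy_map(np.ones((4, 4))))
        assert not m.excluded.any()

    def test_gross_outlier_excluded(self):
        values = np.ones((4, 4))
        values[2, 1] = 100.0
        m = exclude_noisy(toy_map(values))
        assert m.excluded[2, 1]
        assert m.excluded.sum() == 1
        # values retained, only masked
        assert m.values[2, 1] == 100.0

    def test_infinite_threshold_excludes_nothing(self):
        values = np.ones((4, 4))
        values[2, 1] = 100.0
        assert not exclude_noisy(toy_map(values), threshold_mad=np.inf).excluded.any()
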