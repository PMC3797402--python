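import numpy as np
import pytest

from nirsfuse.io import EventTable, FNIRSRecording, paradigm_to_events
from nirsfuse.preprocess import (
    MBLLConfig,
    average_channels,
    average_epoch_groups,
    bandpass_filter,
    default_mbll_config,
    forward_beer_lambert,
    mbll_convert,
    parse_channel_set,
    round_half_up,
    segment_epochs,
    select_sections,
    standardize_maps,
)

import pandas as pd


def _od_recording(data, fs=9.75):
    n_pairs = data.shape[0] // 2
    labels = []
    for k in range(n_pairs):
        labels += [f"ch{k + 1}@781", f"ch{k + 1}@856"]
    return FNIRSRecording(data, fs, "OD", tuple(labels), (781.0, 856.0))


def _session_recording(paradigm, fs=9.75, n_channels=24, rng=None):
    rng = rng or np.random.default_rng(0)
    n = round_half_up(paradigm.total_duration * fs)
    data = rng.standard_normal((n_channels, n))
    return FNIRSRecording(
        data, fs, "HbO2", tuple(str(i) for i in range(1, n_channels + 1))
    )


class TestMBLL:
    identity_cfg = MBLLConfig(extinction_matrix=np.eye(2), dpf=(1.0, 1.0),
                              source_detector_distance=1.0)

    def test_zero_in_zero_out(self):
        od = _od_recording(np.zeros((4, 10)))
        hbo, hbr = mbll_convert(od, default_mbll_config())
        assert np.all(hbo.data == 0) and np.all(hbr.data == 0)
        assert hbo.chromophore == "HbO2" and hbr.chromophore == "HbR"

    def test_linearity(self, rng):
        od = _od_recording(rng.standard_normal((4, 50)))
        od2 = od.with_data(2.0 * od.data)
        cfg = default_mbll_config()
        hbo1, hbr1 = mbll_convert(od, cfg)
        hbo2, hbr2 = mbll_convert(od2, cfg)
        np.testing.assert_allclose(hbo2.data, 2.0 * hbo1.data, rtol=1e-12)
        np.testing.assert_allclose(hbr2.data, 2.0 * hbr1.data, rtol=1e-12)

    def test_identity_system_passes_through(self, rng):
        # extinction = I, dpf = 1, d = 1: the 2x2 solve is the identity,
        # so HbO2 gets the first wavelength row, HbR the second
        data = rng.standard_normal((2, 20))
        od = _od_recording(data)
        hbo, hbr = mbll_convert(od, self.identity_cfg)
        np.testing.assert_allclose(hbo.data[0], data[0], rtol=1e-12)
        np.testing.assert_allclose(hbr.data[0], data[1], rtol=1e-12)

    def test_forward_then_invert_is_identity(self, rng):
        # property: mbll_convert o forward Beer-Lambert = identity to 1e-10
        cfg = default_mbll_config()
        conc = rng.standard_normal((2, 3, 100))  # chromophore x channel x sample
        hbo = FNIRSRecording(conc[0], 9.75, "HbO2", ("a", "b", "c"), (781.0, 856.0))
        hbr = FNIRSRecording(conc[1], 9.75, "HbR", ("a", "b", "c"), (781.0, 856.0))
        od = forward_beer_lambert(hbo, hbr, cfg)
        hbo2, hbr2 = mbll_convert(od, cfg)
        np.testing.assert_allclose(hbo2.data, conc[0], atol=1e-10)
        np.testing.assert_allclose(hbr2.data, conc[1], atol=1e-10)

    def test_singular_extinction_rejected(self):
        cfg = MBLLConfig(extinction_matrix=np.ones((2, 2)))
        od = _od_recording(np.ones((2, 5)))
        with pytest.raises(ValueError, match="singular"):
            mbll_convert(od, cfg)

    def test_unpaired_rows_rejected(self):
        data = np.ones((3, 5))
        rec = FNIRSRecording(data, 9.75, "OD", ("a@781", "a@856", "b@781"), (781.0, 856.0))
        with pytest.raises(ValueError, match="paired"):
            mbll_convert(rec, default_mbll_config())


class TestBandpass:
    def test_out_of_band_sinusoid_attenuated(self):
        fs = 9.75
        t = np.arange(int(100 * fs)) / fs
        sig = np.sin(2 * np.pi * 2.0 * t)[None, :]
        rec = FNIRSRecording(sig, fs, "HbO2", ("1",))
        out = bandpass_filter(rec, 0.01, 0.5)
        assert np.mean(out.data**2) < 0.01 * np.mean(sig**2)

    def test_constant_removed_by_highpass(self):
        rec = FNIRSRecording(np.full((1, 2000), 7.0), 9.75, "HbO2", ("1",))
        out = bandpass_filter(rec, 0.05, 0.5)
        assert np.abs(out.data).max() < 1e-3

    def test_in_band_signal_preserved(self):
        fs = 9.75
        t = np.arange(int(400 * fs)) / fs
        sig = np.sin(2 * np.pi * 0.1 * t)[None, :]
        rec = FNIRSRecording(sig, fs, "HbO2", ("1",))
        out = bandpass_filter(rec, 0.01, 0.5)
        # interior (away from filter edge effects)
        sl = slice(500, -500)
        assert np.mean(out.data[0, sl] ** 2) > 0.9 * np.mean(sig[0, sl] ** 2)

    @pytest.mark.parametrize("band", [(0.5, 0.1), (0.1, 0.1), (-0.1, 0.5), (0.1, 5.0)])
    def test_invalid_band_rejected(self, band):
        rec = FNIRSRecording(np.zeros((1, 100)), 9.75, "HbO2", ("1",))
        with pytest.raises(ValueError):
            bandpass_filter(rec, *band)


class TestEpoching:
    def test_full_paradigm_yields_ten_epochs(self, paradigm):
        rec = _session_recording(paradigm)
        ep = segment_epochs(rec, paradigm_to_events(paradigm), 35.0, 35.0)
        assert ep.n_epochs == 10
        assert ep.n_samples == 684  # round(70 * 9.75) + 1
        assert ep.onsets_used == tuple(paradigm.onsets())

    def test_epoch_content_matches_recording_slice(self, paradigm):
        rec = _session_recording(paradigm)
        ep = segment_epochs(rec, paradigm_to_events(paradigm), 35.0, 35.0)
        start = round_half_up((42.0 - 35.0) * 9.75)
        np.testing.assert_array_equal(ep.data[0], rec.data[:, start : start + 684])

    def test_boundary_epoch_dropped_with_warning(self, paradigm):
        rec = _session_recording(paradigm)
        events = EventTable(pd.DataFrame(
            {"onset": [10.0, 100.0], "duration": [21.0, 21.0], "label": ["t", "t"]}))
        with pytest.warns(UserWarning, match="dropped 1"):
            ep = segment_epochs(rec, events, 35.0, 35.0)
        assert ep.n_epochs == 1
        assert ep.onsets_used == (100.0,)

    def test_no_surviving_epochs_is_error(self, paradigm):
        rec = _session_recording(paradigm)
        events = EventTable(pd.DataFrame(
            {"onset": [10.0], "duration": [21.0], "label": ["t"]}))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no event window"):
                segment_epochs(rec, events, 35.0, 35.0)

    def test_translation_consistency(self, paradigm, rng):
        # shifting events and recording by the same whole-sample offset
        # leaves epoch data unchanged
        fs = 9.75
        rec = _session_recording(paradigm, rng=rng)
        events = paradigm_to_events(paradigm)
        shift = 13  # samples
        shifted_rec = rec.with_data(
            np.concatenate([rng.standard_normal((24, shift)), rec.data], axis=1)
        )
        shifted_events = EventTable(
            events.frame.assign(onset=events.onsets + shift / fs)
        )
        ep0 = segment_epochs(rec, events, 35.0, 35.0)
        ep1 = segment_epochs(shifted_rec, shifted_events, 35.0, 35.0)
        np.testing.assert_array_equal(ep0.data, ep1.data)


class TestChannelAveraging:
    def test_mean_identity(self, paradigm, rng):
        rec = _session_recording(paradigm, rng=rng)
        x = rng.standard_normal(rec.n_samples)
        data = np.zeros_like(rec.data)
        data[9] = 5.0 * x  # channel label "10"
        rec = rec.with_data(data)
        ep = segment_epochs(rec, paradigm_to_events(paradigm), 35.0, 35.0)
        avg = average_channels(ep, ["8", "9", "10", "11", "12"])
        start = round_half_up(7.0 * 9.75)
        np.testing.assert_allclose(avg.data[0, 0], x[start : start + 684], rtol=1e-12)

    def test_motor_channel_set_resolves_to_five(self):
        labels = tuple(str(i) for i in range(1, 25))
        assert parse_channel_set("8-12", labels) == ["8", "9", "10", "11", "12"]

    def test_identical_channels_average_to_themselves(self, paradigm, rng):
        rec = _session_recording(paradigm, n_channels=1, rng=rng)
        data = np.repeat(rec.data, 3, axis=0)
        rec3 = FNIRSRecording(data, 9.75, "HbO2", ("a", "b", "c"))
        ep = segment_epochs(rec3, paradigm_to_events(paradigm), 35.0, 35.0)
        avg = average_channels(ep, ["a", "b", "c"])
        np.testing.assert_allclose(avg.data[:, 0], ep.data[:, 0], rtol=1e-12)

    def test_unknown_label_rejected(self, paradigm):
        rec = _session_recording(paradigm)
        ep = segment_epochs(rec, paradigm_to_events(paradigm), 35.0, 35.0)
        with pytest.raises(ValueError, match="unknown channel"):
            average_channels(ep, ["99"])

    def test_average_commutes_with_epoching(self, paradigm, rng):
        # average-then-epoch == epoch-then-average
        rec = _session_recording(paradigm, rng=rng)
        events = paradigm_to_events(paradigm)
        chan = ["8", "9", "10", "11", "12"]
        a = average_channels(segment_epochs(rec, events, 35, 35), chan)
        idx = [int(c) - 1 for c in chan]
        pre_avg = rec.with_data(
            rec.data[idx].mean(axis=0, keepdims=True), channel_labels=("m",)
        )
        b = segment_epochs(pre_avg, events, 35, 35)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12, atol=1e-14)


class TestSections:
    def _averaged(self, paradigm, rng):
        rec = _session_recording(paradigm, rng=rng)
        ep = segment_epochs(rec, paradigm_to_events(paradigm), 35.0, 35.0)
        return average_channels(ep, ["8", "9", "10", "11", "12"])

    def test_canonical_five_section_selection(self, paradigm, rng):
        traces = select_sections(self._averaged(paradigm, rng), [2, 4, 6, 8, 10])
        assert len(traces) == 5
        assert [t.section_id for t in traces] == [2, 4, 6, 8, 10]
        t = traces[0].time_axis
        assert t[0] == -35.0 and t[-1] >= 35.0
        assert np.all(np.diff(t) > 0)

    def test_single_section_equals_epoch(self, paradigm, rng):
        avg = self._averaged(paradigm, rng)
        traces = select_sections(avg, [1])
        np.testing.assert_array_equal(traces[0].trace, avg.data[0, 0])

    def test_out_of_range_id_rejected(self, paradigm, rng):
        with pytest.raises(IndexError):
            select_sections(self._averaged(paradigm, rng), [11])

    def test_group_averaging_mode(self, paradigm, rng):
        avg = self._averaged(paradigm, rng)
        traces = average_epoch_groups(avg, [[1, 2], [3, 4]])
        np.testing.assert_allclose(
            traces[0].trace, avg.data[[0, 1], 0].mean(axis=0), rtol=1e-12
        )


class TestStandardizeMaps:
    def test_zscore_definition(self, rng, small_grid):
        raw = rng.standard_normal((3, small_grid.n_voxels)) * 5 + 2
        ms = standardize_maps(raw, small_grid)
        np.testing.assert_allclose(ms.maps.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(ms.maps.std(axis=1), 1, atol=1e-9)

    def test_affine_invariance(self, rng, small_grid):
        raw = rng.standard_normal((2, small_grid.n_voxels))
        a, b = 3.7, -12.0
        z1 = standardize_maps(raw, small_grid).maps
        z2 = standardize_maps(a * raw + b, small_grid).maps
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_constant_map_rejected(self, small_grid):
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_maps(np.full((1, small_grid.n_voxels), 3.0), small_grid)
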