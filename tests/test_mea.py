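"""MEA filtering, spike detection, activity summaries, drug response."""

import numpy as np
import pytest

from neurophenotyper.mea import (
    bandpass,
    detect_spikes,
    drug_response,
    robust_noise_sd,
    spike_trains_from_times,
    summarize_activity,
)
from neurophenotyper.synth import MEARecording, generate_mea_recording

FS = 12_500.0


def sine_recording(freq_hz, duration_s=2.0, amplitude=10.0):
    t = np.arange(int(duration_s * FS)) / FS
    return MEARecording(voltage=amplitude * np.sin(2 * np.pi * freq_hz * t))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = sine_recording(1000.0)
        out = bandpass(rec)
        mid = out.voltage[0, 5000:-5000]
        assert mid.max() == pytest.approx(10.0, rel=0.05)

    def test_mains_tone_attenuated(self):
        rec = sine_recording(50.0)
        out = bandpass(rec)
        atten_db = 20 * np.log10(np.abs(out.voltage[0, 5000:-5000]).max() / 10.0)
        assert atten_db < -20

    def test_dc_rejected(self):
        rec = MEARecording(voltage=np.full((1, 25000), 42.0))
        out = bandpass(rec)
        assert np.abs(out.voltage).max() < 1e-6

    def test_idempotent_on_in_band_signal(self):
        rec = sine_recording(1000.0, duration_s=4.0)
        once = bandpass(rec)
        twice = bandpass(once)
        mid = slice(10000, -10000)
        assert np.allclose(once.voltage[0, mid], twice.voltage[0, mid], atol=0.05)

    def test_band_outside_nyquist_rejected(self):
        rec = sine_recording(1000.0)
        with pytest.raises(ValueError):
            bandpass(rec, low_hz=200, high_hz=7000)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        rec = MEARecording(voltage=np.zeros((1, 25000)))
        with pytest.warns(UserWarning):
            spikes = detect_spikes(rec)
        assert spikes.trains[0].count == 0

    def test_pure_noise_negligible_detections(self):
        rec, _ = generate_mea_recording(np.zeros(4), duration_s=120.0, seed=5)
        spikes = detect_spikes(bandpass(rec))
        assert sum(t.count for t in spikes.trains) == 0

    def test_inserted_spikes_recovered_with_timing(self):
        rec, gt = generate_mea_recording(
            np.full(4, 6.0), amplitude_sd_multiple=10.0, duration_s=120.0, seed=6
        )
        spikes = detect_spikes(bandpass(rec))
        for det, truth in zip(spikes.trains, gt.spike_times):
            assert abs(det.count - len(truth)) <= 1
            if len(truth) and det.count:
                d = np.abs(det.times_s[:, None] - truth[None, :]).min(axis=1)
                assert np.median(d) < 0.001

    def test_threshold_monotonicity(self):
        rec, _ = generate_mea_recording([20.0], amplitude_sd_multiple=8.0,
                                        duration_s=60.0, seed=7)
        filt = bandpass(rec)
        counts = [detect_spikes(filt, threshold_sd=s).trains[0].count
                  for s in (4.0, 6.0, 8.0, 12.0)]
        assert counts == sorted(counts, reverse=True)

    def test_robust_sd_ignores_spikes(self, rng):
        x = rng.normal(0, 2.0, 50000)
        x[::1000] += 100.0                # sparse large events
        assert robust_noise_sd(x) == pytest.approx(2.0, rel=0.05)


class TestSummaries:
    def _trains(self, counts, duration_s=300.0, well_map=None):
        times = {f"E{i}": np.linspace(1, duration_s - 1, c) for i, c in enumerate(counts)}
        return spike_trains_from_times(times, duration_s, well_map or {})

    def test_exactly_five_per_min_is_inactive(self):
        trains = self._trains([25])       # 25 spikes / 300 s = 5.0 per min
        assert not trains.trains[0].active

    def test_just_above_five_per_min_is_active(self):
        trains = self._trains([26])
        t = trains.trains[0]
        assert t.active
        assert t.rate_per_min == pytest.approx(5.2)

    def test_well_mean_over_active_only(self):
        # 4 active electrodes at 0.2/0.2/0.4/0.2 spikes/s, 12 silent
        counts = [60, 60, 120, 60] + [0] * 12
        trains = self._trains(counts)
        summary = summarize_activity(trains)
        row = summary.iloc[0]
        assert row["n_active"] == 4
        assert row["mean_rate_active_per_s"] == pytest.approx(0.25)

    def test_silent_well_flagged(self):
        summary = summarize_activity(self._trains([0, 0]))
        assert not summary.iloc[0]["has_activity"]
        assert np.isnan(summary.iloc[0]["mean_rate_active_per_s"])


class TestDrugResponse:
    def _set(self, counts, wells):
        times = {f"E{i}": np.linspace(1, 299, c) for i, c in enumerate(counts)}
        well_map = {f"E{i}": w for i, w in enumerate(wells)}
        return spike_trains_from_times(times, 300.0, well_map)

    def test_identical_ratio_one(self):
        pre = self._set([50, 30], ["W0", "W0"])
        post = self._set([50, 30], ["W0", "W0"])
        assert drug_response(pre, post)["ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_post_ratio_zero(self):
        pre = self._set([40], ["W0"])
        post = self._set([0], ["W0"])
        assert drug_response(pre, post)["ratio"].iloc[0] == 0.0

    def test_zero_pre_excluded_with_warning(self):
        pre = self._set([0, 40], ["W0", "W1"])
        post = self._set([10, 20], ["W0", "W1"])
        with pytest.warns(UserWarning):
            out = drug_response(pre, post)
        assert list(out["well"]) == ["W1"]

    def test_mismatched_wells_error(self):
        pre = self._set([10], ["W0"])
        post = self._set([10], ["W1"])
        with pytest.raises(ValueError):
            drug_response(pre, post)

    def test_simulated_rate_halving(self):
        pre_rec, _ = generate_mea_recording(np.full(8, 60.0), duration_s=60.0, seed=8)
        post_rec, _ = generate_mea_recording(np.full(8, 30.0), duration_s=60.0, seed=9)
        pre = detect_spikes(bandpass(pre_rec))
        post = detect_spikes(bandpass(post_rec))
        ratios = drug_response(pre, post)["ratio"]
        # Poisson error on ~60 spikes/electrode x 8: sd of ratio ~ 0.5*sqrt(2/480)
        assert ratios.mean() == pytest.approx(0.5, abs=0.1)
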