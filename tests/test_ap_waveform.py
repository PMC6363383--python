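"""AP extraction, rise-speed measurement, frequency binning, aggregation."""

import numpy as np
import pytest

from dendrogain import ap_waveform as ap
from dendrogain import synthetic as sy
from dendrogain.biophysics import VoltageTrace


def sweep_with_spikes(times_s, fs=25_000.0, duration=0.3, rise_speed=300.0):
    """Sweep built from the synthetic AP shape at prescribed spike times."""
    v = np.full(int(duration * fs), -70.0)
    for t in times_s:
        sy._insert_ap(v, int(round(t * fs)), fs, base=-70.0, peak=30.0,
                      target_dvdt=rise_speed)
    return VoltageTrace(dt=1.0 / fs, voltage=v)


def make_event(speed, f_inst=None, first=False):
    return ap.APEvent(
        time=0.1, sweep=0, waveform=np.zeros(10), dt=4e-5, max_rise_speed=speed,
        instantaneous_frequency=f_inst, is_first_in_train=first,
    )


class TestExtract:
    def test_three_spikes_and_instantaneous_frequencies(self):
        sweep = sweep_with_spikes([0.100, 0.150, 0.175])
        events = ap.extract_aps([sweep])
        assert len(events) == 3
        assert events[0].is_first_in_train
        assert events[0].instantaneous_frequency is None
        assert events[1].instantaneous_frequency == pytest.approx(20.0, rel=0.02)
        assert events[2].instantaneous_frequency == pytest.approx(40.0, rel=0.02)

    def test_subthreshold_sweep_yields_no_events(self):
        sweep = VoltageTrace(dt=4e-5, voltage=np.full(5000, -65.0))
        assert ap.extract_aps([sweep]) == []

    def test_low_sampling_rejected(self):
        sweep = VoltageTrace(dt=1e-3, voltage=np.full(500, -65.0))
        with pytest.raises(ap.SamplingRateError):
            ap.extract_aps([sweep])

    def test_include_mask_skips_sweeps(self):
        sweep = sweep_with_spikes([0.1])
        assert ap.extract_aps([sweep, sweep], include_mask=[True, False])
        assert len(ap.extract_aps([sweep, sweep], include_mask=[False, False])) == 0

    def test_detection_count_matches_planted_over_100_sweeps(self):
        """Generator-bookkeeping oracle on the synthetic sweep source."""
        fat = sy.FatigueModel(first_ap_rise_speed=300.0, slowing_coefficient=0.005)
        sweeps, truth = sy.generate_recording_sweeps(
            fat, n_sweeps=100, seed=11, return_truth=True
        )
        planted = sum(len(t) for t in truth)
        detected = len(ap.extract_aps(sweeps))
        assert detected == planted


class TestMaxRiseSpeed:
    def test_sine_oracle_two_pi_f_a(self):
        """50 mV, 1 kHz sine: max dV/dt = 2π·1·50 ≈ 314.16 mV/ms."""
        dt = 2e-6  # dense sampling so the discrete derivative is unbiased
        t = np.arange(0, 2e-3, dt)
        w = 50.0 * np.sin(2 * np.pi * 1000.0 * t)
        got = ap.max_rise_speed(w, dt=dt)
        assert got == pytest.approx(2 * np.pi * 1000.0 * 50.0 * 1e-3, rel=1e-3)

    def test_linear_ramp_slope(self):
        dt = 4e-5
        m = 150.0  # mV/ms
        w = np.arange(200) * (m * dt * 1e3)
        assert ap.max_rise_speed(w, dt=dt) == pytest.approx(m, rel=1e-9)

    def test_planted_speed_recovered_from_waveform(self):
        sweep = sweep_with_spikes([0.1], rise_speed=340.0)
        ev = ap.extract_aps([sweep])[0]
        assert ev.max_rise_speed == pytest.approx(340.0, rel=0.01)

    def test_clipped_waveform_flagged(self):
        sweep = sweep_with_spikes([0.1], rise_speed=300.0)
        v = sweep.voltage.copy()
        v[v > 10.0] = 10.0  # saturate the amplifier
        ev = ap.extract_aps([VoltageTrace(dt=sweep.dt, voltage=v)])[0]
        assert not ev.quality_ok


class TestBinning:
    def test_exactly_20_hz_lands_in_11_to_20_bin(self):
        events = [make_event(300.0, first=True), make_event(250.0, f_inst=20.0)]
        b = ap.bin_by_frequency(events)
        assert b.bin_counts[1] == 1  # (10, 20]
        assert b.bin_counts[2] == 0

    def test_uniform_speeds_give_unit_relative_values(self):
        events = [make_event(280.0, first=True)] + [
            make_event(280.0, f_inst=f) for f in (5.0, 15.0, 25.0, 35.0)
        ]
        b = ap.bin_by_frequency(events)
        np.testing.assert_allclose(b.relative[:4], 1.0)
        assert b.relative_20_40 == pytest.approx(1.0)

    def test_ratio_arithmetic_for_20_40_band(self):
        events = [make_event(300.0, first=True),
                  make_event(246.0, f_inst=25.0), make_event(246.0, f_inst=35.0)]
        b = ap.bin_by_frequency(events)
        assert b.relative_20_40 == pytest.approx(0.82)

    def test_no_first_ap_is_normalization_error(self):
        with pytest.raises(ap.NormalizationError):
            ap.bin_by_frequency([make_event(300.0, f_inst=12.0)])

    def test_first_ap_relative_reference_is_identity(self):
        events = [make_event(310.0, first=True), make_event(310.0, first=True)]
        b = ap.bin_by_frequency(events)
        assert b.first_ap_mean / b.first_ap_mean == 1.0


class TestAggregation:
    def _neuron(self, first, bin3_speed):
        events = [make_event(first, first=True),
                  make_event(bin3_speed, f_inst=25.0),
                  make_event(bin3_speed, f_inst=35.0)]
        return ap.bin_by_frequency(events)

    def test_single_neuron_equals_subject(self):
        n = self._neuron(300.0, 240.0)
        row = ap.aggregate_subject([n], "s1")
        assert row["first_ap_rise_speed"] == pytest.approx(300.0)
        assert row["rise_speed_20_40"] == pytest.approx(240.0)
        assert row["relative_rise_speed_20_40"] == pytest.approx(0.8)

    def test_two_neurons_unweighted_mean(self):
        row = ap.aggregate_subject([self._neuron(300.0, 200.0),
                                    self._neuron(300.0, 300.0)], "s")
        assert row["rise_speed_20_40"] == pytest.approx(250.0)

    def test_hand_audit_fixture(self):
        # neuron A: first 200, band 150 (rel 0.75); neuron B: first 400, band 380
        # (rel 0.95): subject = mean of neuron values, not AP-count weighted
        row = ap.aggregate_subject([self._neuron(200.0, 150.0),
                                    self._neuron(400.0, 380.0)], "s")
        assert row["first_ap_rise_speed"] == pytest.approx(300.0)
        assert row["rise_speed_20_40"] == pytest.approx((150 + 380) / 2)
        assert row["relative_rise_speed_20_40"] == pytest.approx((0.75 + 0.95) / 2)

    def test_empty_neuron_list_rejected(self):
        with pytest.raises(ValueError):
            ap.aggregate_subject([], "s")


class TestGeneratorRecovery:
    def test_planted_first_ap_speed_recovered(self):
        fat = sy.FatigueModel(first_ap_rise_speed=300.0, slowing_coefficient=0.0)
        sweeps = sy.generate_recording_sweeps(fat, n_sweeps=50, seed=21)
        b = ap.bin_by_frequency(ap.extract_aps(sweeps))
        assert b.first_ap_mean == pytest.approx(300.0, abs=5.0)

    def test_planted_relative_rise_speed_recovered(self):
        fat = sy.FatigueModel(first_ap_rise_speed=300.0,
                              slowing_coefficient=(1 - 0.74) / 30.0)
        sweeps = sy.generate_recording_sweeps(fat, n_sweeps=50, seed=22)
        b = ap.bin_by_frequency(ap.extract_aps(sweeps))
        assert b.relative_20_40 == pytest.approx(0.74, abs=0.03)

    def test_zero_slowing_keeps_speed_flat(self):
        fat = sy.FatigueModel(first_ap_rise_speed=300.0, slowing_coefficient=0.0,
                              within_noise_sd=4.0)
        sweeps = sy.generate_recording_sweeps(fat, n_sweeps=30, seed=23)
        events = [e for e in ap.extract_aps(sweeps) if e.quality_ok]
        speeds = np.array([e.max_rise_speed for e in events])
        assert np.all(np.abs(speeds - 300.0) < 5 * 4.0)

    def test_rise_speed_tracks_onset_rapidity_across_neurons(self):
        """Per-neuron mean max rise speed and mean phase-plane onset
        rapidity are strongly positively correlated across 60 synthetic
        neurons of varying AP speed (both metrics track the upstroke time
        constant; tested as r > 0.5)."""
        from dendrogain.transfer_gain import onset_rapidity

        rng = np.random.default_rng(5)
        mean_speed, mean_rapidity = [], []
        for i in range(60):
            fat = sy.FatigueModel(
                first_ap_rise_speed=float(rng.uniform(200, 420)),
                slowing_coefficient=(1 - float(rng.uniform(0.6, 0.95))) / 30.0,
                within_noise_sd=8.0,
            )
            sweeps = sy.generate_recording_sweeps(fat, n_sweeps=3, seed=100 + i)
            speeds, raps = [], []
            for sw in sweeps:
                speeds += [e.max_rise_speed for e in ap.extract_aps([sw])]
                raps += list(onset_rapidity(sw).per_ap)
            mean_speed.append(np.mean(speeds))
            mean_rapidity.append(np.mean(raps))
        r = np.corrcoef(mean_speed, mean_rapidity)[0, 1]
        assert r > 0.5

    def test_relative_band_decreases_with_fatigue_strength(self):
        vals = []
        for c in (0.0, 0.004, 0.0087):
            fat = sy.FatigueModel(first_ap_rise_speed=300.0, slowing_coefficient=c)
            sweeps = sy.generate_recording_sweeps(fat, n_sweeps=40, seed=24)
            vals.append(ap.bin_by_frequency(ap.extract_aps(sweeps)).relative_20_40)
        assert vals[0] > vals[1] > vals[2]
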