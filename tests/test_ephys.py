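"""Evoked/spontaneous current measurements on synthetic ground-truth sweeps."""

from dataclasses import replace

import numpy as np
import pytest

from sipstruct.errors import ValidationError
from sipstruct.ephys import (
    MeasurementWindows,
    QCRecord,
    SweepTrace,
    Undefined,
    ampa_nmda_ratio,
    average_traces,
    detect_sepscs,
    input_output_curve,
    oepsc_amplitude,
    paired_pulse_ratio,
    population_spike_amplitude,
    qc_filter,
    read_trace_csv,
    write_trace_csv,
)
from sipstruct.synth import SweepParams, double_exp, generate_sweeps

NOISELESS = replace(SweepParams(), noise_sigma_pA=0.0)


def flat_trace(value=0.0, duration=0.6, stim=0.2):
    n = int(duration * 10_000)
    return SweepTrace(np.full(n, value), 10_000.0, -60.0, (stim,), 0.5)


class TestEvokedAmplitude:
    def test_flat_trace_zero_amplitude(self):
        assert oepsc_amplitude(flat_trace()) == 0.0

    def test_noiseless_configured_peak_recovered_exactly(self):
        p = replace(NOISELESS, max_amplitude_pA=600.0, half_power_mW=0.0001)
        traces, truth = generate_sweeps("oepsc", p, seed=0)
        # near-saturating powers: configured amplitudes essentially 300+ pA
        for tr, amp in zip(traces[1:], truth["amplitudes_pA"][1:]):
            assert oepsc_amplitude(tr) == pytest.approx(amp, abs=1e-9)

    def test_input_output_recovery_under_noise(self):
        traces, truth = generate_sweeps("oepsc", SweepParams(), seed=8)
        curve = input_output_curve(traces)
        # noise-predicted uncertainty of a max over the search window
        n_win = int(0.048 * 10_000)
        bias_bound = 2.0 * np.sqrt(2 * np.log(n_win)) + 3 * 2.0
        for amp, want in zip(curve["amplitude"], sorted(truth["amplitudes_pA"])):
            assert abs(amp - want) <= bias_bound

    def test_amplitude_is_linear_in_trace_scale(self):
        traces, _ = generate_sweeps("oepsc", NOISELESS, seed=0)
        tr = traces[3]
        scaled = SweepTrace(tr.samples * 2.5, tr.fs_hz, tr.holding_potential_mV,
                            tr.stimulus_onsets_s, tr.light_power_mW)
        assert oepsc_amplitude(scaled) == pytest.approx(2.5 * oepsc_amplitude(tr))

    def test_windows_outside_trace_rejected(self):
        with pytest.raises(ValidationError):
            oepsc_amplitude(flat_trace(duration=0.21), MeasurementWindows(search_stop_s=0.5))


class TestAmpaNmda:
    @staticmethod
    def measure(params, seed=0):
        traces, truth = generate_sweeps("ampa_nmda", params, seed=seed)
        m80 = average_traces([t for t in traces if t.holding_potential_mV < 0])
        p40 = average_traces([t for t in traces if t.holding_potential_mV > 0])
        return ampa_nmda_ratio(m80, p40), truth

    def test_configured_ratio_recovered(self):
        ratio, truth = self.measure(NOISELESS)
        assert ratio == pytest.approx(truth["ratio"], rel=0.005)

    def test_recovery_within_two_percent_under_noise(self):
        ratio, truth = self.measure(SweepParams(), seed=5)
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_pure_fast_cell_flags_undefined(self):
        p = replace(NOISELESS, nmda_window_mean_pA=0.0)
        ratio, _ = self.measure(p)
        assert isinstance(ratio, Undefined)

    def test_scale_invariance(self):
        traces, _ = generate_sweeps("ampa_nmda", NOISELESS, seed=0)
        m80 = average_traces([t for t in traces if t.holding_potential_mV < 0])
        p40 = average_traces([t for t in traces if t.holding_potential_mV > 0])
        r1 = ampa_nmda_ratio(m80, p40)
        scale = lambda tr, c: SweepTrace(tr.samples * c, tr.fs_hz,
                                         tr.holding_potential_mV,
                                         tr.stimulus_onsets_s, tr.light_power_mW)
        r2 = ampa_nmda_ratio(scale(m80, 3.0), scale(p40, 3.0))
        assert r2 == pytest.approx(r1)

    def test_window_discipline(self):
        # content outside the defined windows must not move the result
        traces, _ = generate_sweeps("ampa_nmda", NOISELESS, seed=0)
        m80 = average_traces([t for t in traces if t.holding_potential_mV < 0])
        p40 = average_traces([t for t in traces if t.holding_potential_mV > 0])
        r1 = ampa_nmda_ratio(m80, p40)
        tampered = p40.samples.copy()
        tampered[-500:] += 500.0  # way past the 125 ms window
        r2 = ampa_nmda_ratio(m80, SweepTrace(tampered, p40.fs_hz, 40.0,
                                             p40.stimulus_onsets_s, 0.5))
        assert r2 == pytest.approx(r1)


class TestPairedPulse:
    def test_identical_pulses_give_unity(self):
        p = replace(NOISELESS, ppr=1.0, isi_s=0.2)
        traces, _ = generate_sweeps("ppr", p, seed=0)
        assert paired_pulse_ratio(traces) == pytest.approx(1.0, abs=0.005)

    def test_configured_ratio_recovered_noiseless(self):
        traces, truth = generate_sweeps("ppr", NOISELESS, seed=0)
        assert paired_pulse_ratio(traces) == pytest.approx(0.75, abs=0.005)

    def test_recovery_within_two_percent_under_noise(self):
        traces, _ = generate_sweeps("ppr", SweepParams(), seed=9)
        assert paired_pulse_ratio(traces) == pytest.approx(0.75, rel=0.02)

    def test_tail_baseline_handles_overlapping_decay(self):
        # 50 ms ISI with 12 ms decay: P1 is still relaxing under P2, so the
        # pre-stimulus baseline would overestimate P2; the tail baseline and
        # the superposition oracle (subtract a P1-only trace) must agree
        fs = 10_000.0
        t = np.arange(int(0.8 * fs)) / fs
        stims = (0.2, 0.25)
        p1 = -double_exp(t - stims[0], 200.0, 0.0015, 0.012)
        p2 = -double_exp(t - stims[1], 150.0, 0.0015, 0.012)
        both = SweepTrace(p1 + p2, fs, -60.0, stims, 0.5)
        assert abs(p1[int(stims[1] * fs)]) > 2.0  # decays genuinely overlap
        ratio = paired_pulse_ratio([both])
        assert ratio == pytest.approx(150.0 / 200.0, rel=0.02)
        oracle_p2 = np.abs(p2).max()  # superposition: (p1+p2) - p1
        assert ratio * 200.0 == pytest.approx(oracle_p2, rel=0.02)

    def test_wrong_stimulus_count_rejected(self):
        with pytest.raises(ValidationError):
            paired_pulse_ratio([flat_trace()])


class TestPopulationSpike:
    def test_flat_and_noiseless_and_recovery(self):
        tr = flat_trace()
        assert population_spike_amplitude(tr) == 0.0
        traces, truth = generate_sweeps("ops", NOISELESS, seed=0)
        for trace, amp in zip(traces, truth["amplitudes"]):
            assert population_spike_amplitude(trace) == pytest.approx(amp, abs=1e-9)
        noisy, truth = generate_sweeps("ops", SweepParams(), seed=6)
        for trace, amp in zip(noisy[1:], truth["amplitudes"][1:]):
            assert population_spike_amplitude(trace) == pytest.approx(amp, abs=12.0)

    def test_peak_to_peak_convention_at_least_as_large(self):
        traces, _ = generate_sweeps("ops", SweepParams(), seed=6)
        for tr in traces:
            assert population_spike_amplitude(tr, convention="peak_to_peak") >= \
                population_spike_amplitude(tr)


class TestSepscDetection:
    def test_planted_events_recovered_exactly_noiseless(self):
        fs = 10_000.0
        t = np.arange(int(10.0 * fs)) / fs
        y = np.zeros_like(t)
        onsets = 0.5 + np.arange(10) * 0.9
        for o in onsets:
            seg = slice(int(o * fs), int(o * fs) + int(0.08 * fs))
            w = -double_exp(t[seg] - o, 30.0, 0.0015, 0.005)
            y[seg] += w * (30.0 / np.abs(w).max())
        events, freq = detect_sepscs(SweepTrace(y, fs, -60.0, (), 0.0), 10.0)
        assert len(events) == 10
        assert freq == pytest.approx(1.0)
        for e in events:
            assert e.amplitude_pA == pytest.approx(30.0, abs=1e-6)

    def test_decay_tau_recovered(self):
        traces, truth = generate_sweeps("sepsc", NOISELESS, seed=2)
        events, _ = detect_sepscs(traces[0], 10.0)
        taus = np.array([e.decay_tau_ms for e in events])
        assert np.nanmean(taus) == pytest.approx(5.0, abs=0.5)

    def test_frequency_within_poisson_band_under_noise(self):
        p = SweepParams()
        traces, truth = generate_sweeps("sepsc", p, seed=2)
        events, freq = detect_sepscs(traces[0], 10.0)
        lam = p.sepsc_rate_hz * p.sepsc_duration_s
        assert abs(len(events) - lam) <= 1.96 * np.sqrt(lam) + 3

    def test_empty_trace_and_bad_threshold(self):
        tr = SweepTrace(np.zeros(1000), 10_000.0, -60.0, (), 0.0)
        events, freq = detect_sepscs(tr, 10.0)
        assert events == [] and freq == 0.0
        with pytest.raises(ValidationError):
            detect_sepscs(tr, -1.0)


class TestQC:
    @pytest.mark.parametrize(
        "start,end,keep",
        [
            (10.0, 10.0, True),
            (26.0, 26.0, False),   # above the 25 MOhm cap
            (20.0, 23.5, False),   # 17.5% drift
            (20.0, 22.9, True),    # 14.5% drift
            (25.0, 25.0, True),    # boundary: rule is strictly greater-than
        ],
    )
    def test_series_resistance_rule(self, start, end, keep):
        assert qc_filter(QCRecord(start, end)) is keep

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValidationError):
            QCRecord(0.0, 10.0)


class TestTraceIO:
    def test_csv_round_trip(self, tmp_path):
        traces, _ = generate_sweeps("ppr", SweepParams(), seed=1)
        path = tmp_path / "sweep.csv"
        write_trace_csv(traces[0], path)
        back = read_trace_csv(path)
        assert np.allclose(back.samples, traces[0].samples)
        assert back.stimulus_onsets_s == traces[0].stimulus_onsets_s
        assert back.fs_hz == traces[0].fs_hz
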