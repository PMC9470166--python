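"""Slice-electrophysiology measurements on voltage-clamp / field traces.

Conventions: currents are in pA with inward currents negative; all reported
amplitudes are positive magnitudes.  Default sampling rate is 10 kHz.
Baselines are the mean of a 50 ms window immediately preceding the stimulus
and evoked peaks are searched 2–50 ms post-stimulus unless configured
otherwise (both windows are free parameters — the measurement geometry, not
the biology).

Measurements implemented:

* ``oepsc_amplitude`` — baseline-to-extremum amplitude of an optically
  evoked EPSC; applied across light powers it yields the input-output curve.
* ``ampa_nmda_ratio`` — AMPA-receptor peak at −80 mV over the
  NMDA-receptor current estimated as the baseline-subtracted mean
  100–125 ms post-stimulus at +40 mV (by then the fast component has fully
  decayed, so the window isolates the slow current).
* ``paired_pulse_ratio`` — mean second-pulse amplitude (tail current just
  before the second stimulus as baseline) over mean first-pulse amplitude
  (pre-stimulus baseline), averaged over technical replicates.
* ``population_spike_amplitude`` — baseline-to-negative-peak of a field
  response (peak-to-peak available as an option).
* ``detect_sepscs`` — threshold detector for spontaneous events on gap-free
  recordings with per-event amplitude, 10–90% rise time and
  single-exponential decay tau; a transparent reference detector, not a
  clone of any commercial tool.
* ``qc_filter`` — series-resistance quality control: exclude cells above
  25 MΩ or drifting more than 15% during the recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError

__all__ = [
    "SweepTrace",
    "QCRecord",
    "MeasurementWindows",
    "Undefined",
    "oepsc_amplitude",
    "input_output_curve",
    "ampa_nmda_ratio",
    "paired_pulse_ratio",
    "population_spike_amplitude",
    "detect_sepscs",
    "SepscEvent",
    "qc_filter",
    "read_trace_csv",
    "write_trace_csv",
    "average_traces",
]

DEFAULT_FS_HZ = 10_000.0


@dataclass(frozen=True)
class SweepTrace:
    """A sampled current trace with stimulus metadata."""

    samples: np.ndarray  # pA (or a.u. for field traces)
    fs_hz: float = DEFAULT_FS_HZ
    holding_potential_mV: float = -60.0
    stimulus_onsets_s: tuple[float, ...] = ()
    light_power_mW: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("trace contains non-finite samples")
        dur = len(self.samples) / self.fs_hz
        for s in self.stimulus_onsets_s:
            if not 0 <= s < dur:
                raise ValidationError(f"stimulus onset {s} s outside trace of {dur:.3f} s")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz

    def window(self, start_s: float, stop_s: float) -> np.ndarray:
        if start_s < 0 or stop_s > self.duration_s + 1e-9 or stop_s <= start_s:
            raise ValidationError(
                f"window [{start_s}, {stop_s}) s outside trace of {self.duration_s:.3f} s"
            )
        lo = int(round(start_s * self.fs_hz))
        hi = int(round(stop_s * self.fs_hz))
        return self.samples[lo:hi]


@dataclass(frozen=True)
class MeasurementWindows:
    """Measurement geometry relative to the stimulus (seconds)."""

    baseline_s: float = 0.050       # mean of this much pre-stimulus signal
    search_start_s: float = 0.002   # peak search opens this long post-stimulus
    search_stop_s: float = 0.050    # ... and closes here
    nmda_start_s: float = 0.100     # slow-current estimation window
    nmda_stop_s: float = 0.125


class Undefined:
    """Sentinel for measurements whose denominator is at/below the noise floor."""

    def __init__(self, reason: str):
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"Undefined({self.reason!r})"


def _baseline(trace: SweepTrace, stim: float, win: MeasurementWindows) -> float:
    start = max(0.0, stim - win.baseline_s)
    if stim <= 0:
        raise ValidationError("no pre-stimulus signal available for baseline")
    return float(trace.window(start, stim).mean())


def oepsc_amplitude(
    trace: SweepTrace, windows: MeasurementWindows = MeasurementWindows()
) -> float:
    """|extremum − baseline| of the evoked current after the first stimulus."""
    if not trace.stimulus_onsets_s:
        raise ValidationError("trace has no stimulus onset")
    stim = trace.stimulus_onsets_s[0]
    base = _baseline(trace, stim, windows)
    seg = trace.window(stim + windows.search_start_s, stim + windows.search_stop_s)
    dev = seg - base
    return float(np.abs(dev).max())


def input_output_curve(
    traces: list[SweepTrace], windows: MeasurementWindows = MeasurementWindows()
) -> pd.DataFrame:
    """Amplitude vs light power across an input-output sweep set."""
    rows = [
        {"light_power_mW": tr.light_power_mW, "amplitude": oepsc_amplitude(tr, windows)}
        for tr in traces
    ]
    return pd.DataFrame(rows).sort_values("light_power_mW").reset_index(drop=True)


def average_traces(traces: list[SweepTrace]) -> SweepTrace:
    """Point-wise mean of replicate sweeps (metadata from the first)."""
    if not traces:
        raise ValidationError("no traces to average")
    first = traces[0]
    if any(len(t.samples) != len(first.samples) or t.fs_hz != first.fs_hz for t in traces):
        raise ValidationError("replicates must share length and sampling rate")
    mean = np.mean([t.samples for t in traces], axis=0)
    return SweepTrace(mean, first.fs_hz, first.holding_potential_mV,
                      first.stimulus_onsets_s, first.light_power_mW)


def ampa_nmda_ratio(
    trace_minus80: SweepTrace,
    trace_plus40: SweepTrace,
    windows: MeasurementWindows = MeasurementWindows(),
    noise_floor_pA: float = 5.0,
) -> float | Undefined:
    """AMPA peak at −80 mV over the 100–125 ms window mean at +40 mV.

    Returns :class:`Undefined` instead of a number when the slow-current
    window mean does not exceed ``noise_floor_pA``.
    """
    if not (trace_minus80.stimulus_onsets_s and trace_plus40.stimulus_onsets_s):
        raise ValidationError("both traces need a stimulus onset")
    ampa = oepsc_amplitude(trace_minus80, windows)
    stim = trace_plus40.stimulus_onsets_s[0]
    base = _baseline(trace_plus40, stim, windows)
    seg = trace_plus40.window(stim + windows.nmda_start_s, stim + windows.nmda_stop_s)
    nmda = abs(float(seg.mean()) - base)
    if nmda <= noise_floor_pA:
        return Undefined(
            f"slow-current window mean {nmda:.3g} pA at/below noise floor {noise_floor_pA} pA"
        )
    return ampa / nmda


def paired_pulse_ratio(
    replicates: list[SweepTrace],
    windows: MeasurementWindows = MeasurementWindows(),
    tail_window_s: float = 0.005,
) -> float | Undefined:
    """mean(P2)/mean(P1) over replicate two-pulse sweeps.

    P1 is measured against the pre-stimulus baseline; P2 against the tail
    current in the ``tail_window_s`` immediately preceding the second
    stimulus, which absorbs whatever of P1's decay is still present.
    """
    if not replicates:
        raise ValidationError("need at least one replicate")
    p1s, p2s = [], []
    for tr in replicates:
        if len(tr.stimulus_onsets_s) != 2:
            raise ValidationError("paired-pulse traces need exactly two stimulus onsets")
        s1, s2 = tr.stimulus_onsets_s
        base1 = _baseline(tr, s1, windows)
        seg1 = tr.window(s1 + windows.search_start_s, min(s1 + windows.search_stop_s, s2))
        p1s.append(float(np.abs(seg1 - base1).max()))
        tail = float(tr.window(s2 - tail_window_s, s2).mean())
        seg2 = tr.window(s2 + windows.search_start_s, s2 + windows.search_stop_s)
        p2s.append(float(np.abs(seg2 - tail).max()))
    mean_p1 = float(np.mean(p1s))
    if mean_p1 == 0.0:
        return Undefined("mean first-pulse amplitude is zero")
    return float(np.mean(p2s)) / mean_p1


def population_spike_amplitude(
    trace: SweepTrace,
    windows: MeasurementWindows = MeasurementWindows(),
    convention: str = "baseline_to_negative_peak",
) -> float:
    """Field population-spike amplitude from the pre-stimulus baseline.

    Default convention is baseline-to-negative-peak; ``peak_to_peak`` is
    available as an alternative measurement geometry.
    """
    if not trace.stimulus_onsets_s:
        raise ValidationError("trace has no stimulus onset")
    stim = trace.stimulus_onsets_s[0]
    base = _baseline(trace, stim, windows)
    seg = trace.window(stim + windows.search_start_s, stim + windows.search_stop_s)
    if convention == "baseline_to_negative_peak":
        return float(base - seg.min())
    if convention == "peak_to_peak":
        return float(seg.max() - seg.min())
    raise ValidationError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class SepscEvent:
    onset_s: float
    peak_s: float
    amplitude_pA: float
    rise_10_90_ms: float
    decay_tau_ms: float


def detect_sepscs(
    trace: SweepTrace,
    threshold_pA: float,
    refractory_s: float = 0.002,
    fit_window_s: float = 0.030,
    fit_start_s: float = 0.004,
) -> tuple[list[SepscEvent], float]:
    """Detect spontaneous inward events on a gap-free recording.

    Events are contiguous runs where the signal is more negative than
    ``-threshold_pA`` relative to the trace median, merged when separated by
    less than ``refractory_s``.  For each event: peak amplitude, 10–90% rise
    time (linear interpolation), and a single-exponential decay tau fitted
    from the peak over ``fit_window_s``.  Returns ``(events, frequency_hz)``.
    """
    if threshold_pA <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold_pA}")
    y = trace.samples - np.median(trace.samples)
    noise_sigma = 1.4826 * float(np.median(np.abs(y)))  # MAD noise estimate
    below = y < -threshold_pA
    if not below.any():
        return [], 0.0
    fs = trace.fs_hz
    # run starts/stops
    edges = np.diff(below.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    stops = list(np.nonzero(edges == -1)[0] + 1)
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        stops.append(len(y))
    merged: list[list[int]] = []
    gap = int(refractory_s * fs)
    for a, b in zip(starts, stops):
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events: list[SepscEvent] = []
    for a, b in merged:
        seg = y[a:b]
        peak_rel = int(np.argmin(seg))
        peak_idx = a + peak_rel
        amp = float(-y[peak_idx])
        events.append(
            SepscEvent(
                onset_s=a / fs,
                peak_s=peak_idx / fs,
                amplitude_pA=amp,
                rise_10_90_ms=_rise_time_ms(y, a, peak_idx, amp, fs),
                decay_tau_ms=_decay_tau_ms(
                    y, peak_idx, amp, fs, fit_window_s, fit_start_s, noise_sigma
                ),
            )
        )
    freq = len(events) / trace.duration_s
    return events, freq


def _rise_time_ms(y: np.ndarray, onset: int, peak: int, amp: float, fs: float) -> float:
    seg = -y[max(onset - int(0.002 * fs), 0) : peak + 1]
    t10, t90 = 0.1 * amp, 0.9 * amp
    idx90 = np.argmax(seg >= t90)
    idx10 = np.argmax(seg >= t10)
    # linear interpolation between samples bracketing each threshold
    def interp(i: int, level: float) -> float:
        if i == 0 or seg[i - 1] >= level:
            return float(i)
        return i - 1 + (level - seg[i - 1]) / (seg[i] - seg[i - 1])
    return (interp(idx90, t90) - interp(idx10, t10)) / fs * 1000.0


def _decay_tau_ms(
    y: np.ndarray,
    peak: int,
    amp: float,
    fs: float,
    fit_window_s: float,
    fit_start_s: float,
    noise_sigma: float,
) -> float:
    # start the fit a few ms past the peak: the residual rise component
    # decays fast but biases tau upward if the fit starts at the peak
    skip = max(1, int(fit_start_s * fs))
    hi = min(len(y), peak + int(fit_window_s * fs))
    seg = -y[peak + skip : hi]
    t = np.arange(len(seg)) / fs
    # fit only the contiguous decay above the noise floor, so a following
    # event inside the window cannot contaminate the fit
    floor = max(0.05 * amp, 3.0 * noise_sigma)
    below = np.nonzero(seg <= floor)[0]
    stop = below[0] if below.size else len(seg)
    if stop < 4:
        return float("nan")
    t, seg = t[:stop], seg[:stop]
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau: a * np.exp(-tt / tau),
            t, seg, p0=(min(amp, seg[0]), 0.005),
            bounds=([0.0, 1e-4], [np.inf, 0.2]), maxfev=2000,
        )
        return float(popt[1] * 1000.0)
    except RuntimeError:  # pragma: no cover - pathological fits
        return float("nan")


@dataclass(frozen=True)
class QCRecord:
    series_resistance_start_MOhm: float
    series_resistance_end_MOhm: float

    def __post_init__(self) -> None:
        if min(self.series_resistance_start_MOhm, self.series_resistance_end_MOhm) <= 0:
            raise ValidationError("series resistances must be positive")


def qc_filter(record: QCRecord, limit_MOhm: float = 25.0, drift: float = 0.15) -> bool:
    """True iff the recording passes series-resistance QC.

    Excluded when either resistance exceeds ``limit_MOhm`` or the relative
    change from start to end exceeds ``drift``.
    """
    rs0 = record.series_resistance_start_MOhm
    rs1 = record.series_resistance_end_MOhm
    if rs0 > limit_MOhm or rs1 > limit_MOhm:
        return False
    return abs(rs1 - rs0) / rs0 <= drift


# ---------------------------------------------------------------------------
# Trace IO: CSV (time_s, current_pA) and NPZ containers
# ---------------------------------------------------------------------------


def write_trace_csv(trace: SweepTrace, path: str | Path) -> None:
    t = np.arange(len(trace.samples)) / trace.fs_hz
    df = pd.DataFrame({"time_s": t, "current_pA": trace.samples})
    with open(path, "w") as fh:
        fh.write(
            f"# fs_hz={trace.fs_hz} holding_mV={trace.holding_potential_mV} "
            f"stims={','.join(str(s) for s in trace.stimulus_onsets_s)} "
            f"power_mW={trace.light_power_mW}\n"
        )
        df.to_csv(fh, index=False)


def read_trace_csv(path: str | Path) -> SweepTrace:
    meta: dict[str, str] = {}
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                meta[k] = v
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    fs = float(meta.get("fs_hz", 0)) or None
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        fs = 1.0 / float(np.median(dt))
    stims = tuple(float(s) for s in meta.get("stims", "").split(",") if s)
    return SweepTrace(
        df["current_pA"].to_numpy(dtype=float),
        fs,
        float(meta.get("holding_mV", "nan")),
        stims,
        float(meta.get("power_mW", 0.0)),
    )
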