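"""Seeded generative models of limited-access drinking and synaptic sweeps.

The behavioral generator emulates a six-week limited-access schedule (five
sessions per week: four 2 h weekday sessions and one 4 h session) for a
cohort split into four fluid × virus classes.  Each session is a latent
renewal process of drinking bouts:

* latency to the first bout is log-normal;
* inter-bout intervals are gamma-renewal, with the interval scale divided
  by a front-loading boost during the first 30 min of access;
* each bout is a train of licks at a fixed within-bout rate (default 7 Hz,
  a typical mouse lick rate) whose individual beam-break lengths vary, and
  bout durations are log-normal;
* bottle-weight loss is a noisy monotone function of total licks, so
  intake correlates tightly with microstructure;
* rare leak/chew artifacts are planted as device-level bouts with the
  characteristic long-duration/few-licks and many-licks/short-duration
  signatures, flagged in the ground truth.

Class structure: alcohol sessions differ from water at baseline (longer
latency, sparser but longer bouts, stronger front-loading), and the
ChR2 × alcohol class additionally loses bouts/licks (−30%) and
front-loading (−40%) during weeks 5–6, emulating the effect of driving
cortical input to the striatum during established binge drinking.  All
class-dependent deviations are free parameters; a single
``class_separation`` dial raises every class multiplier to the power ``d``
so that ``d = 0`` makes the four classes statistically identical (chance
classification) and larger ``d`` increases separability monotonically.

Randomness derives from one cohort seed via per-animal
``SeedSequence([seed, class_index, animal_index, ...])`` substreams, so
adding an animal never perturbs existing animals' data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
import numpy as np

from .errors import ValidationError
from .lickometer import (
    CLASS_ORDER,
    DEVICE_WRITE_GAP_S,
    BoutRecord,
    LickEvent,
    SessionRecord,
    device_emulate,
)

__all__ = [
    "CohortConfig",
    "BehaviorParams",
    "GroundTruth",
    "generate_cohort",
    "SweepParams",
    "generate_sweeps",
    "double_exp",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and schedule."""

    n_per_class: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("water", "ChR2"): 8,
            ("water", "eGFP"): 11,
            ("alcohol", "ChR2"): 8,
            ("alcohol", "eGFP"): 8,
        }
    )
    weeks: int = 6
    sessions_per_week: int = 5  # four 2 h sessions + one 4 h session
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_class.values()):
            raise ValidationError("animal counts must be positive")
        if self.weeks < 1 or self.sessions_per_week < 1:
            raise ValidationError("schedule must have >= 1 week and session")

    @property
    def n_sessions(self) -> int:
        return self.weeks * self.sessions_per_week

    def session_length_h(self, session_index: int) -> float:
        # last session of each week is the long (4 h) one
        return 4.0 if session_index % self.sessions_per_week == 0 else 2.0


@dataclass(frozen=True)
class BehaviorParams:
    """Generative parameters; baseline values describe a water control."""

    # latency to first bout: log-normal
    latency_median_s: float = 240.0
    latency_sigma: float = 0.7
    # inter-bout intervals: gamma renewal (mean = shape * scale)
    ibi_shape: float = 2.0
    ibi_scale_s: float = 150.0
    # bout durations: log-normal
    bout_duration_median_s: float = 4.0
    bout_duration_sigma: float = 0.5
    # within-bout licking
    lick_rate_hz: float = 7.0
    lick_len_mean_s: float = 0.08
    # within-bout beam-break lengths are stereotyped; a tight CV keeps
    # genuine bouts' lick/duration residuals well inside the cleaning
    # threshold, as in real recordings where >99.9% of bouts survive
    lick_len_cv: float = 0.08
    # front-loading: interval scale divided by this boost during first 30 min
    front_loading_boost: float = 2.0
    # intake coupling
    grams_per_lick: float = 2.0e-3
    intake_noise_cv: float = 0.05
    body_weight_mean_g: float = 26.0
    body_weight_sd_g: float = 1.5
    # contamination (expected planted artifacts per session)
    leak_rate_per_session: float = 0.002
    chew_rate_per_session: float = 0.002
    # class structure ------------------------------------------------------
    # alcohol baseline deviations (multipliers relative to water)
    alcohol_latency_mult: float = 1.5
    alcohol_ibi_scale_mult: float = 1.25
    alcohol_duration_mult: float = 1.2
    alcohol_front_excess_mult: float = 1.3
    # ChR2 x alcohol deficit applied in weeks 5-6 only
    chr2_effect_weeks: tuple[int, ...] = (5, 6)
    chr2_bout_rate_mult: float = 0.7   # -30% bouts
    chr2_duration_mult: float = 0.7    # -30% licks (licks scale with duration)
    chr2_front_excess_mult: float = 0.6  # -40% front-loading
    # separability dial: every class multiplier m becomes m ** class_separation
    class_separation: float = 1.0

    def __post_init__(self) -> None:
        positives = (
            self.latency_median_s, self.latency_sigma, self.ibi_shape,
            self.ibi_scale_s, self.bout_duration_median_s, self.bout_duration_sigma,
            self.lick_rate_hz, self.lick_len_mean_s, self.grams_per_lick,
        )
        if any(p <= 0 for p in positives):
            raise ValidationError("distribution parameters must be positive")
        if self.front_loading_boost < 1.0:
            raise ValidationError("front_loading_boost must be >= 1")
        if min(self.leak_rate_per_session, self.chew_rate_per_session) < 0:
            raise ValidationError("contamination rates must be >= 0")

    # -- effective per-session parameters ---------------------------------

    def _pw(self, m: float) -> float:
        return m ** self.class_separation

    def effective(self, fluid: str, virus: str, week: int) -> dict[str, float]:
        """Resolved (latency median, ibi scale, duration median, boost) for a class-week."""
        lat = self.latency_median_s
        scale = self.ibi_scale_s
        dur = self.bout_duration_median_s
        excess = self.front_loading_boost - 1.0
        if fluid == "alcohol":
            lat *= self._pw(self.alcohol_latency_mult)
            scale *= self._pw(self.alcohol_ibi_scale_mult)
            dur *= self._pw(self.alcohol_duration_mult)
            excess *= self._pw(self.alcohol_front_excess_mult)
            if virus == "ChR2" and week in self.chr2_effect_weeks:
                scale /= self._pw(self.chr2_bout_rate_mult)
                dur *= self._pw(self.chr2_duration_mult)
                excess *= self._pw(self.chr2_front_excess_mult)
        return {
            "latency_median_s": lat,
            "ibi_scale_s": scale,
            "bout_duration_median_s": dur,
            "front_loading_boost": 1.0 + excess,
        }

    def neutral(self) -> "BehaviorParams":
        """Copy with all class structure and front-loading switched off."""
        return replace(self, class_separation=0.0, front_loading_boost=1.0,
                       leak_rate_per_session=0.0, chew_rate_per_session=0.0)


@dataclass
class GroundTruth:
    """Latent truth saved alongside a generated cohort, keyed by (animal, session)."""

    events: dict[tuple[str, int], list[LickEvent]] = field(default_factory=dict)
    contamination: dict[tuple[str, int], list[str]] = field(default_factory=dict)
    latency_s: dict[tuple[str, int], float] = field(default_factory=dict)
    ibis_s: dict[tuple[str, int], list[float]] = field(default_factory=dict)
    true_class: dict[str, tuple[str, str]] = field(default_factory=dict)
    params: BehaviorParams | None = None


def _session_events(
    rng: np.random.Generator, p: BehaviorParams, eff: dict[str, float], T: float
) -> tuple[list[LickEvent], float, list[float]]:
    """Draw the latent lick stream for one session."""
    max_len = 0.9 / p.lick_rate_hz
    latency = float(rng.lognormal(math.log(eff["latency_median_s"]), p.latency_sigma))
    events: list[LickEvent] = []
    ibis: list[float] = []
    t = latency
    prev_end = -math.inf
    while t < T:
        # keep successive device bouts separated by more than the write gap
        start = max(t, prev_end + DEVICE_WRITE_GAP_S + 0.05)
        duration = float(
            rng.lognormal(math.log(eff["bout_duration_median_s"]), p.bout_duration_sigma)
        )
        n_licks = max(1, int(round(duration * p.lick_rate_hz)))
        if start + duration < T:
            onsets = start + np.arange(n_licks) / p.lick_rate_hz
            lens = rng.normal(p.lick_len_mean_s, p.lick_len_cv * p.lick_len_mean_s, n_licks)
            lens = np.clip(lens, 0.01, max_len)
            events.extend(LickEvent(float(o), float(o + l)) for o, l in zip(onsets, lens))
            prev_end = float(onsets[-1] + lens[-1])
        boost = eff["front_loading_boost"] if t < 1800.0 else 1.0
        ibi = float(rng.gamma(p.ibi_shape, eff["ibi_scale_s"] / boost))
        ibis.append(ibi)
        t = start + ibi
    return events, latency, ibis


def _planted_artifacts(
    rng: np.random.Generator, p: BehaviorParams, T: float
) -> list[tuple[BoutRecord, str]]:
    out: list[tuple[BoutRecord, str]] = []
    for kind, rate in (("leak", p.leak_rate_per_session), ("chew", p.chew_rate_per_session)):
        for _ in range(rng.poisson(rate)):
            start = float(rng.uniform(0, T - 70))
            if kind == "leak":
                # a dribbling valve holds the beam broken for seconds with
                # almost no licks; kept shorter than the longest genuine
                # bouts so a rare leak cannot lever the pooled OLS line at
                # desk-scale bout counts (its residual is still ~20x the
                # cleaning threshold)
                dur = float(rng.uniform(5.0, 12.0))
                bout = BoutRecord(start, start + dur, int(rng.integers(1, 4)), dur)
            else:
                dur = float(rng.uniform(0.5, 1.5))
                bout = BoutRecord(
                    start, start + max(dur, DEVICE_WRITE_GAP_S),
                    int(rng.integers(60, 140)), dur,
                )
            out.append((bout, kind))
    return out


def generate_cohort(
    config: CohortConfig = CohortConfig(), params: BehaviorParams = BehaviorParams()
) -> tuple[list[SessionRecord], GroundTruth]:
    """Generate a full cohort of session records plus latent ground truth.

    Deterministic given ``config.seed``; the returned sessions hold the
    device-level bout records (true lick streams passed through the 2 s
    write rule, plus any planted artifacts), while the ground truth keeps
    the raw event streams, per-bout contamination flags, drawn latencies
    and inter-bout intervals, and the resolved parameters.
    """
    truth = GroundTruth(params=params)
    sessions: list[SessionRecord] = []
    for ci, (fluid, virus) in enumerate(CLASS_ORDER):
        n_animals = config.n_per_class.get((fluid, virus), 0)
        for ai in range(n_animals):
            animal_id = f"{fluid}-{virus}-{ai:02d}"
            truth.true_class[animal_id] = (fluid, virus)
            body_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, ci, ai, 10**6])
            )
            body_weight = float(
                np.clip(
                    body_rng.normal(params.body_weight_mean_g, params.body_weight_sd_g),
                    18.0, 38.0,
                )
            )
            for si in range(1, config.n_sessions + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, ci, ai, si])
                )
                week = math.ceil(si / config.sessions_per_week)
                T = config.session_length_h(si) * 3600.0
                eff = params.effective(fluid, virus, week)
                events, latency, ibis = _session_events(rng, params, eff, T)
                bouts = device_emulate(events)
                flags = ["clean"] * len(bouts)
                for bout, kind in _planted_artifacts(rng, params, T):
                    bouts.append(bout)
                    flags.append(kind)
                order = np.argsort([b.start for b in bouts], kind="stable")
                bouts = [bouts[i] for i in order]
                flags = [flags[i] for i in order]
                total_licks = sum(b.n_licks for b in bouts)
                grams = total_licks * params.grams_per_lick * float(
                    rng.lognormal(0.0, params.intake_noise_cv)
                )
                pre = float(rng.uniform(42.0, 48.0))
                key = (animal_id, si)
                truth.events[key] = events
                truth.contamination[key] = flags
                truth.latency_s[key] = latency
                truth.ibis_s[key] = ibis
                sessions.append(
                    SessionRecord(
                        animal_id=animal_id,
                        session_index=si,
                        session_length_h=config.session_length_h(si),
                        fluid=fluid,
                        virus=virus,
                        stim_mode="closed_loop" if week >= 4 else "none",
                        bottle_weight_pre_g=pre,
                        bottle_weight_post_g=pre - grams,
                        body_weight_g=body_weight,
                        bouts=bouts,
                    )
                )
    sessions.sort(key=lambda s: (s.animal_id, s.session_index))
    return sessions, truth


# ---------------------------------------------------------------------------
# Synthetic synaptic sweeps
# ---------------------------------------------------------------------------


def double_exp(
    t: np.ndarray, amplitude: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Difference-of-exponentials synaptic waveform with peak = ``amplitude``.

    ``t`` is time from stimulus onset (s); negative times give 0.
    """
    if not 0 < tau_rise < tau_decay:
        raise ValidationError(
            f"need 0 < tau_rise < tau_decay, got ({tau_rise}, {tau_decay})"
        )
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    t_peak = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    peak = math.exp(-t_peak / tau_decay) - math.exp(-t_peak / tau_rise)
    return amplitude * raw / peak


@dataclass(frozen=True)
class SweepParams:
    """Waveform and noise settings for :func:`generate_sweeps`."""

    fs_hz: float = 10_000.0
    noise_sigma_pA: float = 2.0
    # fast (AMPA-receptor-like) kinetics
    tau_rise_s: float = 0.0015
    tau_decay_s: float = 0.012
    # slow (NMDA-receptor-like) kinetics
    nmda_tau_rise_s: float = 0.006
    nmda_tau_decay_s: float = 0.060
    stim_onset_s: float = 0.2
    # oEPSC input-output: saturating amplitude vs light power
    light_powers_mW: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)
    max_amplitude_pA: float = 400.0
    half_power_mW: float = 0.3
    # paired pulses
    p1_amplitude_pA: float = 200.0
    ppr: float = 0.75
    isi_s: float = 0.100
    n_replicates: int = 3
    # AMPA/NMDA
    ampa_amplitude_pA: float = 300.0
    nmda_window_mean_pA: float = 150.0
    # spontaneous events
    sepsc_rate_hz: float = 2.0
    sepsc_amplitude_pA: float = 30.0
    sepsc_duration_s: float = 120.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        for r, d in ((self.tau_rise_s, self.tau_decay_s),
                     (self.nmda_tau_rise_s, self.nmda_tau_decay_s)):
            if not 0 < r < d:
                raise ValidationError(f"need 0 < rise < decay, got ({r}, {d})")


def _trace_times(duration: float, fs: float) -> np.ndarray:
    return np.arange(int(round(duration * fs))) / fs


def _sampled_wave(
    t_rel: np.ndarray, amplitude: float, tau_rise: float, tau_decay: float
) -> np.ndarray:
    """Double-exponential sampled so its extremum equals ``amplitude`` exactly."""
    y = double_exp(t_rel, amplitude, tau_rise, tau_decay)
    m = float(np.abs(y).max())
    if m > 0:
        y *= amplitude / m
    return y


def generate_sweeps(
    kind: str, params: SweepParams = SweepParams(), seed: int = 0
) -> tuple[list, dict]:
    """Synthesize sweeps of the given kind with known ground truth.

    ``kind`` is one of ``oepsc``, ``ppr``, ``ampa_nmda``, ``ops``,
    ``sepsc``.  Returns ``(traces, truth)`` where traces are
    :class:`~sipstruct.ephys.SweepTrace` objects and ``truth`` records the
    configured amplitudes/kinetics being recovered.  Evoked sweeps follow
    the 30 s inter-sweep protocol implicitly (each trace is one sweep).
    """
    from .ephys import SweepTrace  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    fs = params.fs_hz
    p = params

    def noise(n: int) -> np.ndarray:
        return rng.normal(0.0, p.noise_sigma_pA, n) if p.noise_sigma_pA > 0 else np.zeros(n)

    traces: list[SweepTrace] = []
    if kind == "oepsc":
        t = _trace_times(0.6, fs)
        amps = []
        for power in p.light_powers_mW:
            amp = p.max_amplitude_pA * power / (power + p.half_power_mW) if power > 0 else 0.0
            amps.append(amp)
            y = -_sampled_wave(t - p.stim_onset_s, amp, p.tau_rise_s, p.tau_decay_s)
            traces.append(SweepTrace(y + noise(len(t)), fs, -60.0, (p.stim_onset_s,), power))
        truth = {"amplitudes_pA": amps, "light_powers_mW": list(p.light_powers_mW)}
    elif kind == "ppr":
        t = _trace_times(p.stim_onset_s + p.isi_s + 0.3, fs)
        p2 = p.p1_amplitude_pA * p.ppr
        stims = (p.stim_onset_s, p.stim_onset_s + p.isi_s)
        for _ in range(p.n_replicates):
            y = -_sampled_wave(t - stims[0], p.p1_amplitude_pA, p.tau_rise_s, p.tau_decay_s)
            y -= _sampled_wave(t - stims[1], p2, p.tau_rise_s, p.tau_decay_s)
            traces.append(SweepTrace(y + noise(len(t)), fs, -60.0, stims, 0.5))
        truth = {"p1_pA": p.p1_amplitude_pA, "p2_pA": p2, "ppr": p.ppr, "isi_s": p.isi_s}
    elif kind == "ampa_nmda":
        t = _trace_times(0.6, fs)
        rel = t - p.stim_onset_s
        ampa = -_sampled_wave(rel, p.ampa_amplitude_pA, p.tau_rise_s, p.tau_decay_s)
        nmda_shape = double_exp(rel, 1.0, p.nmda_tau_rise_s, p.nmda_tau_decay_s)
        win = (rel >= 0.100) & (rel < 0.125)
        scale = p.nmda_window_mean_pA / float(nmda_shape[win].mean())
        # at +40 mV both components are outward; the fast one is gone by 100 ms
        plus40 = scale * nmda_shape + _sampled_wave(
            rel, 0.5 * p.ampa_amplitude_pA, p.tau_rise_s, p.tau_decay_s
        )
        for _ in range(p.n_replicates):
            traces.append(SweepTrace(ampa + noise(len(t)), fs, -80.0, (p.stim_onset_s,), 0.5))
        for _ in range(p.n_replicates):
            traces.append(SweepTrace(plus40 + noise(len(t)), fs, 40.0, (p.stim_onset_s,), 0.5))
        truth = {
            "ampa_pA": p.ampa_amplitude_pA,
            "nmda_window_mean_pA": p.nmda_window_mean_pA,
            "ratio": (
                p.ampa_amplitude_pA / p.nmda_window_mean_pA
                if p.nmda_window_mean_pA > 0
                else float("inf")
            ),
        }
    elif kind == "ops":
        t = _trace_times(0.4, fs)
        powers = tuple(pw * 1.15 for pw in p.light_powers_mW)
        amps = []
        for power in powers:
            amp = p.max_amplitude_pA * power / (power + p.half_power_mW) if power > 0 else 0.0
            amps.append(amp)
            y = -_sampled_wave(t - p.stim_onset_s, amp, 0.002, 0.008)
            traces.append(SweepTrace(y + noise(len(t)), fs, float("nan"), (p.stim_onset_s,), power))
        truth = {"amplitudes": amps, "light_powers_mW": list(powers)}
    elif kind == "sepsc":
        t = _trace_times(p.sepsc_duration_s, fs)
        n_events = rng.poisson(p.sepsc_rate_hz * p.sepsc_duration_s)
        onsets = np.sort(rng.uniform(0.05, p.sepsc_duration_s - 0.1, n_events))
        # enforce separation by forward-shifting so events stay resolvable
        # without thinning the Poisson count
        min_gap = 0.020
        for i in range(1, len(onsets)):
            onsets[i] = max(onsets[i], onsets[i - 1] + min_gap)
        onsets = onsets[onsets < p.sepsc_duration_s - 0.1]
        amps = rng.lognormal(math.log(p.sepsc_amplitude_pA), 0.2, len(onsets))
        y = np.zeros_like(t)
        for o, a in zip(onsets, amps):
            lo = int(o * fs)
            hi = min(len(t), lo + int(0.08 * fs))
            y[lo:hi] -= _sampled_wave(t[lo:hi] - o, a, p.tau_rise_s, 0.005)
        traces.append(SweepTrace(y + noise(len(t)), fs, -60.0, (), 0.0))
        truth = {
            "onsets_s": onsets.tolist(),
            "amplitudes_pA": amps.tolist(),
            "rate_hz": p.sepsc_rate_hz,
            "tau_decay_s": 0.005,
        }
    else:
        raise ValidationError(f"unknown sweep kind {kind!r}")
    return traces, truth
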