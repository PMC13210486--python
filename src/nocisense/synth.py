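"""Synthetic cohort generator emulating the two-modality pain protocol.

Each simulated subject completes a pre-test rest followed by two blocks of
trials: three thermal-grill (TGI) trials at levels 0, 2, 1 in that order,
then five electrical-stimulation (TENS) trials at levels 2, 0, 1, 3, 4.
Every trial is a 10 s anticipation countdown, 10 s of stimulation, 10 s of
ramp-down and a 30 s recovery, recorded continuously.

The physiological model is deliberately simple and fully controllable:

* a latent per-trial arousal value, monotone in stimulation level with
  multiplicative subject heterogeneity;
* EDA (4 Hz) = tonic drift (slow random walk + arousal-scaled ramp)
  + Poisson sweat-burst events (rate linear in arousal, log-normal
  amplitudes) convolved with the Bateman kernel
  + a band-limited 0.08-0.24 Hz oscillation whose amplitude tracks arousal
  + white sensor noise;
* PPG (50 Hz) = beats from an inhomogeneous interval process whose rate
  follows base HR plus a first-order-lagged arousal elevation and
  respiratory sinus modulation, rendered as a systolic lobe plus dicrotic
  notch per beat;
* VAS self-reports = clipped, rounded linear responses — pain to the
  trial's own arousal, anxiety to the *previous* trial's arousal, which
  builds in the positive anxiety/previous-pain association the proxy
  labels rely on.

Anticipation arousal is a fraction of the upcoming stimulus blended with
the previous trial's realized arousal, so anticipation windows carry
learnable previous-trial signal. Every draw flows from one seed, making
whole cohorts bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from nocisense.eda import bateman_kernel
from nocisense.signal_io import EventMarker, Session, SignalChannel, VASResponse

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "TrialPlan",
    "generate_cohort",
    "generate_eda",
    "generate_ppg",
    "generate_vas",
    "protocol_trials",
]

EDA_FS = 4.0
PPG_FS = 50.0
TGI_ORDER = (0, 2, 1)
TENS_ORDER = (2, 0, 1, 3, 4)

#: per-level latent arousal (strong-effect defaults, monotone in level)
TGI_GAINS = {0: 0.0, 1: 1.0, 2: 1.6}
TENS_GAINS = {0: 0.0, 1: 0.8, 2: 1.6, 3: 2.4, 4: 3.2}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults define the simulated study."""

    n_subjects: int = 20
    seed: int = 0
    # protocol timing (seconds)
    rest_duration: float = 30.0
    anticipation_s: float = 10.0
    stimulation_s: float = 10.0
    rampdown_s: float = 10.0
    recovery_s: float = 30.0
    # arousal model
    tgi_gains: dict = field(default_factory=lambda: dict(TGI_GAINS))
    tens_gains: dict = field(default_factory=lambda: dict(TENS_GAINS))
    anticipation_fraction: float = 0.6
    prev_blend: float = 0.5
    subject_gain_sd: float = 0.15  # log-scale heterogeneity
    # EDA model
    scr_base_rate: float = 0.05  # events/s at zero arousal
    scr_rate_gain: float = 0.25  # events/s per arousal unit
    scr_amp_mean: float = 0.3  # µS, log-normal location
    scr_amp_sd: float = 0.4  # log-scale
    osc_gain: float = 0.12  # µS oscillation amplitude per arousal unit
    osc_freq_range: tuple = (0.08, 0.24)  # Hz, per-subject draw
    tonic_level: float = 2.0  # µS
    tonic_walk_sd: float = 0.002  # µS per step random walk
    tonic_ramp_gain: float = 0.01  # µS/s per arousal unit during stimulation
    eda_noise_sd: float = 0.01  # µS white noise
    # PPG model
    base_hr: float = 70.0  # bpm
    hr_subject_sd: float = 6.0  # bpm between subjects
    hr_gain: float = 4.0  # bpm per arousal unit
    hr_lag_s: float = 3.0  # first-order lag of HR to arousal
    rsa_amp: float = 2.0  # bpm respiratory sinus modulation
    rsa_freq: float = 0.25  # Hz
    beat_jitter_sd: float = 0.01  # fractional interval jitter
    dicrotic_amp: float = 0.4  # relative to systole
    ppg_noise_sd: float = 0.005
    # VAS response model
    pain_slope: float = 2.2
    anxiety_slope: float = 2.0
    vas_noise_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for gains in (self.tgi_gains, self.tens_gains):
            levels = sorted(gains)
            vals = [gains[L] for L in levels]
            if any(b < a for a, b in zip(vals, vals[1:])):
                raise ValueError("level gains must be monotone non-decreasing")

    def null_effect(self) -> "CohortConfig":
        """All stimulation levels share one arousal: no class signal."""
        mid_tgi = float(np.mean(list(self.tgi_gains.values())))
        mid_tens = float(np.mean(list(self.tens_gains.values())))
        return replace(
            self,
            tgi_gains={k: mid_tgi for k in self.tgi_gains},
            tens_gains={k: mid_tens for k in self.tens_gains},
        )


@dataclass(frozen=True)
class TrialPlan:
    trial_index: int
    modality: str
    level: int
    t_anticipation: float
    t_stimulation: float
    t_rampdown: float
    t_recovery_end: float
    stim_arousal: float = 0.0
    antic_arousal: float = 0.0


@dataclass
class GroundTruth:
    """Per-subject generating truths for oracle-style tests."""

    trials: dict[str, list[TrialPlan]] = field(default_factory=dict)
    scr_onsets: dict[str, np.ndarray] = field(default_factory=dict)
    scr_amplitudes: dict[str, np.ndarray] = field(default_factory=dict)
    beat_times: dict[str, np.ndarray] = field(default_factory=dict)
    subject_params: dict[str, dict] = field(default_factory=dict)


def protocol_trials(config: CohortConfig) -> list[tuple[str, int]]:
    """(modality, level) sequence of the full protocol."""
    return [("TGI", L) for L in TGI_ORDER] + [("TENS", L) for L in TENS_ORDER]


def _plan_trials(config: CohortConfig, subject_gain: float) -> list[TrialPlan]:
    t = config.rest_duration
    plans: list[TrialPlan] = []
    prev_arousal = {"TGI": 0.0, "TENS": 0.0}
    for idx, (modality, level) in enumerate(protocol_trials(config)):
        gains = config.tgi_gains if modality == "TGI" else config.tens_gains
        stim = gains[level] * subject_gain
        antic = config.anticipation_fraction * (
            (1 - config.prev_blend) * stim
            + config.prev_blend * prev_arousal[modality])
        plans.append(TrialPlan(
            trial_index=idx, modality=modality, level=level,
            t_anticipation=t,
            t_stimulation=t + config.anticipation_s,
            t_rampdown=t + config.anticipation_s + config.stimulation_s,
            t_recovery_end=t + config.anticipation_s + config.stimulation_s
                           + config.rampdown_s + config.recovery_s,
            stim_arousal=stim, antic_arousal=antic))
        prev_arousal[modality] = stim
        t = plans[-1].t_recovery_end
    return plans


def _arousal_schedule(plans: list[TrialPlan], duration: float, fs: float,
                      config: CohortConfig) -> np.ndarray:
    """Piecewise arousal over the session; ramp-down decays exponentially."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    a = np.zeros(n)
    for p in plans:
        a[(t >= p.t_anticipation) & (t < p.t_stimulation)] = p.antic_arousal
        a[(t >= p.t_stimulation) & (t < p.t_rampdown)] = p.stim_arousal
        ramp = (t >= p.t_rampdown) & (t < p.t_rampdown + config.rampdown_s)
        a[ramp] = p.stim_arousal * np.exp(-(t[ramp] - p.t_rampdown) / 3.0)
    return a


def generate_eda(arousal: np.ndarray, config: CohortConfig,
                 rng: np.random.Generator, stim_mask: np.ndarray | None = None
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EDA samples plus the injected SCR onset times and amplitudes.

    Components: tonic drift (random walk + arousal-scaled ramp during
    stimulation), Poisson sweat bursts convolved with the Bateman kernel,
    an arousal-amplitude-modulated oscillation at a random in-band
    frequency, and white noise. Output is clipped to stay positive.
    """
    if np.any(np.asarray(arousal) < 0):
        raise ValueError("arousal schedule must be >= 0")
    fs = EDA_FS
    n = len(arousal)
    dt = 1.0 / fs
    t = np.arange(n) * dt

    walk = np.cumsum(rng.normal(0.0, config.tonic_walk_sd, size=n))
    ramp_rate = config.tonic_ramp_gain * arousal * (
        stim_mask if stim_mask is not None else 1.0)
    tonic = config.tonic_level + walk + np.cumsum(ramp_rate) * dt

    rate = config.scr_base_rate + config.scr_rate_gain * arousal
    events = rng.random(n) < rate * dt
    onsets_idx = np.flatnonzero(events)
    amps = np.exp(rng.normal(np.log(config.scr_amp_mean), config.scr_amp_sd,
                             size=len(onsets_idx)))
    driver = np.zeros(n)
    driver[onsets_idx] = amps
    kernel = bateman_kernel(fs=fs)
    phasic = np.convolve(driver, kernel)[:n]

    lo, hi = config.osc_freq_range
    freq = rng.uniform(lo, hi) if hi > lo else lo
    # smooth the amplitude envelope so the oscillation stays band-limited
    env = config.osc_gain * _smooth(arousal, int(2 * fs))
    oscillation = env * np.sin(2 * np.pi * freq * t)

    noise = rng.normal(0.0, config.eda_noise_sd, size=n)
    samples = np.maximum(tonic + phasic + oscillation + noise, 0.01)
    return samples, onsets_idx * dt, amps


def _smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def generate_ppg(arousal: np.ndarray, config: CohortConfig,
                 rng: np.random.Generator, base_hr: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """PPG samples and the true systolic peak times.

    Heart rate follows arousal through a first-order lag (time constant
    ``hr_lag_s``) plus respiratory sinus modulation; beats arrive from the
    integrated instantaneous rate with fractional interval jitter; each
    beat renders a Gaussian systolic lobe centered on the beat time and a
    dicrotic notch 0.3 s later.
    """
    if np.any(np.asarray(arousal) < 0):
        raise ValueError("arousal schedule must be >= 0")
    fs = PPG_FS
    base = config.base_hr if base_hr is None else base_hr
    n4 = len(arousal)
    duration = n4 / EDA_FS
    # first-order lag of the arousal drive
    alpha = (1.0 / EDA_FS) / max(config.hr_lag_s, 1.0 / EDA_FS)
    lagged = np.empty(n4)
    acc = 0.0
    for i, a in enumerate(arousal):
        acc += alpha * (a - acc)
        lagged[i] = acc
    t4 = np.arange(n4) / EDA_FS
    hr_t = base + config.hr_gain * lagged + config.rsa_amp * np.sin(
        2 * np.pi * config.rsa_freq * t4)

    beats = []
    t_beat = 0.3  # first beat shortly after start
    while t_beat < duration:
        beats.append(t_beat)
        hr_now = float(np.interp(t_beat, t4, hr_t))
        interval = 60.0 / max(hr_now, 20.0)
        if config.beat_jitter_sd > 0:
            interval *= 1.0 + rng.normal(0.0, config.beat_jitter_sd)
        t_beat += max(interval, 0.25)
    beat_times = np.asarray(beats)

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    ppg = np.zeros(n)
    sys_w, dic_w, dic_delay = 0.06, 0.09, 0.30
    for tb in beat_times:
        lo = max(int((tb - 0.3) * fs), 0)
        hi = min(int((tb + 0.7) * fs), n)
        tt = t[lo:hi]
        ppg[lo:hi] += np.exp(-0.5 * ((tt - tb) / sys_w) ** 2)
        ppg[lo:hi] += config.dicrotic_amp * np.exp(
            -0.5 * ((tt - tb - dic_delay) / dic_w) ** 2)
    if config.ppg_noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.ppg_noise_sd, size=n)
    return ppg, beat_times


def generate_vas(plans: list[TrialPlan], config: CohortConfig,
                 rng: np.random.Generator) -> list[VASResponse]:
    """Clipped, rounded linear VAS responses.

    Pain tracks the trial's own arousal; anxiety tracks the previous
    trial's arousal within the same block, which is what makes previous
    pain an informative anxiety proxy downstream.
    """
    responses = []
    prev_arousal = {"TGI": 0.0, "TENS": 0.0}
    for p in plans:
        pain = config.pain_slope * p.stim_arousal + rng.normal(0, config.vas_noise_sd)
        anx = (config.anxiety_slope * prev_arousal[p.modality]
               + rng.normal(0, config.vas_noise_sd))
        prev_arousal[p.modality] = p.stim_arousal
        responses.append(VASResponse(
            trial_index=p.trial_index,
            anxiety_score=int(np.clip(round(anx), 0, 10)),
            pain_score=int(np.clip(round(pain), 0, 10))))
    return responses


def generate_cohort(config: CohortConfig) -> tuple[list[Session], GroundTruth]:
    """Simulate a full cohort; bitwise-deterministic given ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    sessions: list[Session] = []
    truth = GroundTruth()

    for i, seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seq)
        subject_id = f"S{i:03d}"
        subject_gain = float(np.exp(rng.normal(0.0, config.subject_gain_sd)))
        base_hr = float(config.base_hr + rng.normal(0.0, config.hr_subject_sd))

        plans = _plan_trials(config, subject_gain)
        duration = plans[-1].t_recovery_end
        arousal = _arousal_schedule(plans, duration, EDA_FS, config)
        t4 = np.arange(int(round(duration * EDA_FS))) / EDA_FS
        stim_mask = np.zeros(len(t4))
        for p in plans:
            stim_mask[(t4 >= p.t_stimulation) & (t4 < p.t_rampdown)] = 1.0

        eda, onsets, amps = generate_eda(arousal, config, rng, stim_mask)
        ppg, beats = generate_ppg(arousal, config, rng, base_hr=base_hr)
        vas = generate_vas(plans, config, rng)

        markers = []
        for p in plans:
            for phase, (s, e) in (
                ("anticipation", (p.t_anticipation, p.t_stimulation)),
                ("stimulation", (p.t_stimulation, p.t_rampdown)),
                ("rampdown", (p.t_rampdown, p.t_rampdown + config.rampdown_s)),
            ):
                markers.append(EventMarker(
                    trial_index=p.trial_index, modality=p.modality,
                    level=p.level, phase=phase, t_start=s, t_end=e))

        b0 = config.rest_duration / 3.0
        session = Session(
            subject_id=subject_id,
            eda=SignalChannel("eda", EDA_FS, 0.0, eda),
            ppg=SignalChannel("ppg", PPG_FS, 0.0, ppg),
            markers=tuple(markers), vas=tuple(vas),
            baseline_window=(b0, b0 + 10.0))
        sessions.append(session)
        truth.trials[subject_id] = plans
        truth.scr_onsets[subject_id] = onsets
        truth.scr_amplitudes[subject_id] = amps
        truth.beat_times[subject_id] = beats
        truth.subject_params[subject_id] = {
            "subject_gain": subject_gain, "base_hr": base_hr}
    return sessions, truth
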