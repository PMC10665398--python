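"""Synthetic waveforms, stimulation sessions and cohorts with known truth.

Every downstream stage (beat fitting, MEC_K detection, ROC_BP, cohort
statistics) is testable against generator ground truth:

* ``gen_beat_waveform`` — within-beat PPG/arterial-pressure samples that
  obey the spring-damper impedance model exactly (plus optional Gaussian
  pressure noise).  The PPG pulse is a raised-cosine single hump per beat;
  the pressure trace is built from the same central-difference PPG
  derivative the estimator uses, so with zero noise the per-beat fit
  recovers (K, B) to machine precision.
* ``gen_session`` — a per-beat K series spanning a 10-to-80 mA tetanic
  ladder in which stimuli at/above a subject threshold evoke a transient
  multiplicative K rise (linear rise to peak, exponential decay, contained
  in the 20-s post window), baseline K fluctuates with a small CV, and an
  optional isolated artifact spike exercises noise rejection.
* ``gen_cohort`` — subjects obeying a linear MEC_K -> ROC_BP law with
  Gaussian residuals, a histogram-shaped MEC_K distribution with an
  out-of-range tail, and optional two-group slope/intercept overrides.
* ``gen_incision_series`` — a per-beat sBP trace with a controlled
  post-incision rise for exercising ROC_BP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .beat_mechanics import KSeries, WaveformRecord, differentiate_ppg
from .cohort_stats import SubjectRecord
from .mec_detection import OUT_OF_RANGE, StimulusEvent

#: MEC_K histogram used for cohort sampling: mode at 30 mA, more than half
#: the mass between 20 and 40 mA, and a small out-of-range tail (one
#: expected OOR subject in a cohort of ~30).
DEFAULT_MECK_DISTRIBUTION: dict[int | str, float] = {
    10: 0.07, 20: 0.17, 30: 0.27, 40: 0.17,
    50: 0.12, 60: 0.08, 70: 0.05, 80: 0.04,
    OUT_OF_RANGE: 0.03,
}


@dataclass
class WaveformConfig:
    """Parameters of the within-beat waveform generator."""

    n_beats: int
    k_true: float = 2.0            # mmHg per % PPG
    b_true: float = 0.5            # mmHg*s per % PPG
    sample_rate_hz: float = 100.0
    heart_rate_bpm: float = 60.0
    ppg_pulse_amplitude_pct: float = 10.0
    baseline_pressure_mmhg: float = 80.0
    noise_sd_mmhg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be positive")
        if self.k_true <= 0 or self.b_true <= 0:
            raise ValueError("k_true and b_true must be positive")
        if self.noise_sd_mmhg < 0:
            raise ValueError("noise_sd_mmhg must be non-negative")
        if self.samples_per_beat < 8:
            raise ValueError(
                "fewer than 8 samples per beat: raise sample_rate_hz or "
                "lower heart_rate_bpm")

    @property
    def samples_per_beat(self) -> int:
        return int(round(self.sample_rate_hz * 60.0 / self.heart_rate_bpm))


def gen_beat_waveform(config: WaveformConfig) -> WaveformRecord:
    """Generate an arterial-pressure/PPG record obeying the impedance model.

    The PPG is a raised-cosine hump per beat (zero amplitude and zero
    slope at beat onsets).  Within each beat, starting from its onset t0,

        Pb(t) = Pb(t0) + K*dPl(t) + B*dPl_dot(t) + eps,

    with dPl_dot built from the central-difference PPG derivative (the
    discrete model the estimator fits) and eps i.i.d. Normal(0, noise_sd).
    Emits ``n_beats`` onsets; samples extend one period past the last
    onset so that every beat is complete.
    """
    rng = np.random.default_rng(config.seed)
    period = config.samples_per_beat
    n_samples = config.n_beats * period + 1
    t = np.arange(n_samples) / config.sample_rate_hz
    phase = (np.arange(n_samples) % period) / period
    ppg = 0.5 * config.ppg_pulse_amplitude_pct * (1.0 - np.cos(2.0 * np.pi * phase))
    ppg_dot = differentiate_ppg(ppg, config.sample_rate_hz)

    onsets = np.arange(config.n_beats) * period
    abp = np.full(n_samples, config.baseline_pressure_mmhg)
    bounds = np.append(onsets, n_samples - 1)
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        sl = slice(i0, i1 if i1 < n_samples - 1 else n_samples)
        abp[sl] += (config.k_true * (ppg[sl] - ppg[i0])
                    + config.b_true * (ppg_dot[sl] - ppg_dot[i0]))
    if config.noise_sd_mmhg > 0:
        abp = abp + rng.normal(0.0, config.noise_sd_mmhg, n_samples)
    return WaveformRecord(
        time_s=t, abp_mmhg=abp, ppg_pct=ppg,
        sample_rate_hz=config.sample_rate_hz, beat_onsets=onsets,
        k_true=config.k_true, b_true=config.b_true,
    )


def _default_evoked_gain(intensity_ma: float, threshold_ma: float) -> float:
    """Fractional K rise evoked by one stimulus: 0 below the subject
    threshold, 0.10 at/above it (twice the 5% detection criterion, so the
    1% baseline CV cannot mask a genuine response)."""
    return 0.10 if intensity_ma >= threshold_ma else 0.0


@dataclass
class SessionConfig:
    """Parameters of the tetanic-stimulation session generator."""

    threshold_ma: float            # 10..80, or math.inf for never-responds
    intensities_ma: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80)
    stim_duration_s: float = 5.0
    inter_stimulus_gap_s: float = 45.0
    evoked_gain: Callable[[float], float] | Mapping[int, float] | None = None
    baseline_k: float = 10.0       # mmHg/%
    baseline_cv: float = 0.01
    spike_at_ma: int | None = None
    spike_gain: float = 0.10
    beat_interval_s: float = 1.0
    rise_time_s: float = 8.0       # linear rise to transient peak
    decay_tau_s: float = 2.5       # exponential decay after the peak
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.threshold_ma in set(self.intensities_ma)
                or math.isinf(self.threshold_ma)):
            raise ValueError("threshold_ma must be a tested intensity or inf")
        if list(self.intensities_ma) != sorted(set(self.intensities_ma)):
            raise ValueError("intensities must be strictly increasing")
        if self.baseline_k <= 0:
            raise ValueError("baseline_k must be positive")
        if self.baseline_cv < 0 or self.baseline_cv > 0.02:
            raise ValueError(
                "baseline_cv must be in [0, 0.02] so baseline fluctuation "
                "cannot alone satisfy the 5% criterion")
        # transient must be over, and a clean pre-window available, before
        # the next stimulus
        needed = self.rise_time_s + 5.0 * self.decay_tau_s + 10.0
        if self.inter_stimulus_gap_s < needed:
            raise ValueError(
                f"inter_stimulus_gap_s must be >= {needed:.0f} s for K to "
                "return to baseline before the next pre-stimulus window")
        for i in self.intensities_ma:
            if i >= self.threshold_ma and self.gain(i) < 0.05:
                raise ValueError(
                    "evoked_gain must be >= 0.05 at/above the threshold")

    def gain(self, intensity_ma: float) -> float:
        if self.evoked_gain is None:
            return _default_evoked_gain(intensity_ma, self.threshold_ma)
        if callable(self.evoked_gain):
            return float(self.evoked_gain(intensity_ma))
        return float(self.evoked_gain.get(int(intensity_ma), 0.0))


def _transient_shape(dt: float, rise_s: float, tau_s: float) -> float:
    """Unit-peak transient: linear rise over ``rise_s``, then exponential
    decay; zero before the stimulus offset."""
    if dt <= 0:
        return 0.0
    if dt <= rise_s:
        return dt / rise_s
    return math.exp(-(dt - rise_s) / tau_s)


def gen_session(
    config: SessionConfig,
) -> tuple[KSeries, list[StimulusEvent], float]:
    """Generate a per-beat K series spanning a full stimulation ladder.

    Returns (kseries, events, true threshold).  Stimuli at/above the
    threshold evoke a multiplicative transient whose peak exceeds 5% of
    baseline within 20 s of stimulus offset; between stimuli K returns to
    within the baseline CV of baseline_k.  ``spike_at_ma`` injects a
    single-beat artifact rise after that (sub-threshold) stimulus.
    """
    rng = np.random.default_rng(config.seed)
    pre_roll = 15.0
    step = config.stim_duration_s + config.inter_stimulus_gap_s
    events = [
        StimulusEvent(onset_s=pre_roll + j * step, intensity_ma=int(i),
                      duration_s=config.stim_duration_s)
        for j, i in enumerate(config.intensities_ma)
    ]
    t_end = events[-1].offset_s + 30.0
    times = np.arange(0.0, t_end, config.beat_interval_s)
    k = config.baseline_k * (1.0 + config.baseline_cv * rng.standard_normal(times.size))
    for ev in events:
        g = config.gain(ev.intensity_ma)
        if g > 0:
            for i, tb in enumerate(times):
                s = _transient_shape(tb - ev.offset_s, config.rise_time_s,
                                     config.decay_tau_s)
                if s > 0:
                    k[i] *= 1.0 + g * s
        if config.spike_at_ma is not None and ev.intensity_ma == config.spike_at_ma:
            spike_t = ev.offset_s + config.rise_time_s
            i = int(np.argmin(np.abs(times - spike_t)))
            k[i] *= 1.0 + config.spike_gain
    return KSeries(times, k), events, config.threshold_ma


@dataclass
class GroupSpec:
    """Optional per-group overrides for two-group cohorts."""

    label: str
    weight: float
    slope: float | None = None
    intercept: float | None = None


@dataclass
class CohortConfig:
    """Parameters of the cohort generator: a linear MEC_K -> ROC_BP law
    with Gaussian residuals, defaults matching the fitted regression of
    the sevoflurane study (slope -0.27 %/mA, intercept 28.81%)."""

    n_subjects: int
    slope: float = -0.27           # % per mA
    intercept: float = 28.81       # %
    residual_sd: float = 5.0       # %
    meck_distribution: Mapping[int | str, float] = field(
        default_factory=lambda: dict(DEFAULT_MECK_DISTRIBUTION))
    groups: tuple[GroupSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("n_subjects must be >= 3")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        total = sum(self.meck_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("meck_distribution must sum to 1")
        if self.groups is not None:
            if len(self.groups) != 2:
                raise ValueError("groups must contain exactly two entries")
            if abs(sum(g.weight for g in self.groups) - 1.0) > 1e-9:
                raise ValueError("group weights must sum to 1")


def gen_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Sample a cohort of (MEC_K, ROC_BP, group) subject records.

    ROC_BP_i = slope*MEC_K_i + intercept + Normal(0, residual_sd^2);
    out-of-range subjects carry no ROC_BP value (None).
    """
    rng = np.random.default_rng(config.seed)
    levels = list(config.meck_distribution.keys())
    probs = np.array([config.meck_distribution[l] for l in levels], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=config.n_subjects, p=probs)
    subjects: list[SubjectRecord] = []
    for i, li in enumerate(idx):
        meck = levels[li]
        group = None
        slope, intercept = config.slope, config.intercept
        if config.groups is not None:
            gsel = config.groups[int(rng.random() >= config.groups[0].weight)]
            group = gsel.label
            slope = gsel.slope if gsel.slope is not None else slope
            intercept = gsel.intercept if gsel.intercept is not None else intercept
        if meck == OUT_OF_RANGE:
            rocbp = None
        else:
            rocbp = slope * float(meck) + intercept \
                + rng.normal(0.0, config.residual_sd)
        subjects.append(SubjectRecord(
            subject_id=f"S{i + 1:03d}", meck_ma=meck,
            rocbp_pct=rocbp, group=group))
    return subjects


def gen_incision_series(
    pre_level: float,
    rise_fraction: float,
    n_pre_beats: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    post_duration_s: float = 60.0,
    beat_interval_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-beat sBP series around a skin incision.

    Pre-incision beats fluctuate about ``pre_level``; post-incision beats
    follow a smooth hump whose noise-free maximum is exactly
    pre_level*(1 + rise_fraction).  Returns (beat_time_s, sbp_mmhg,
    incision_time_s).
    """
    if pre_level <= 0:
        raise ValueError("pre_level must be positive")
    if n_pre_beats < 10:
        raise ValueError("need at least 10 pre-incision beats")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_post = int(round(post_duration_s / beat_interval_s))
    t = np.arange(n_pre_beats + n_post) * beat_interval_s
    incision_time = (n_pre_beats - 0.5) * beat_interval_s
    sbp = np.full(t.size, float(pre_level))
    post_t = t[n_pre_beats:] - incision_time
    # triangular hump whose apex falls exactly on the middle post beat, so
    # the noise-free maximum equals pre_level*(1 + rise_fraction)
    peak_t = post_t[post_t.size // 2]
    shape = np.clip(1.0 - np.abs(post_t - peak_t) / peak_t, 0.0, None)
    sbp[n_pre_beats:] = pre_level * (1.0 + rise_fraction * shape)
    if noise_sd > 0:
        sbp = sbp + rng.normal(0.0, noise_sd, t.size)
    return t, sbp, float(incision_time)
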