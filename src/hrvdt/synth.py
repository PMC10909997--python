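"""Synthetic dual-task study data: n-back trials, RR series, ECG, behavior, TLX.

Everything the downstream pipeline consumes can be generated here under a
configurable condition-effect map, so the full analysis chain is testable
without any recorded subject data.  The RR generator is an integral pulse
frequency modulation (IPFM) model: a heart-rate modulating function with one
low-frequency (~0.1 Hz, sympathetic + baroreflex) and one high-frequency
(~0.25 Hz, respiratory/vagal) sinusoid is integrated, and a beat is emitted
each time the integral crosses an integer.  This is the standard test bench
for HRV spectral estimators because the injected band powers are known.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import logging

import numpy as np

from .ecg import ECGRecord, RRSeries

logger = logging.getLogger(__name__)

PL_LEVELS = ("none", "medium", "high")
CL_LEVELS = (1, 2, 3)

TLX_DIMENSIONS = ("mental", "physical", "temporal", "performance", "effort", "frustration")

#: counterbalancing rotations of the three n-back runs (subgroup -> CL order)
TASK_ORDERS = ((1, 2, 3), (2, 3, 1), (3, 1, 2))

DEFAULT_ALPHABET = tuple("BCDFGHKL")  # 8 consonants: avoids vowel chunking


# --------------------------------------------------------------------------
# condition / effect types
# --------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Condition:
    """One cell of the 3x3 within-subject design."""

    cl_level: int        # n of n-back: 1, 2 or 3
    pl_level: str        # physical load: none / medium / high

    def __post_init__(self):
        if self.cl_level not in CL_LEVELS:
            raise ValueError(f"cl_level must be one of {CL_LEVELS}")
        if self.pl_level not in PL_LEVELS:
            raise ValueError(f"pl_level must be one of {PL_LEVELS}")

    @property
    def label(self) -> str:
        return f"{self.cl_level}back_{self.pl_level}"


ALL_CONDITIONS = tuple(Condition(c, p) for c in CL_LEVELS for p in PL_LEVELS)


@dataclass(frozen=True)
class ConditionEffect:
    """Multipliers/shifts applied on top of baseline generator parameters."""

    mean_rr_mult: float = 1.0
    a_lf_mult: float = 1.0
    a_hf_mult: float = 1.0
    rt_shift_ms: float = 0.0
    rt_sigma_shift: float = 0.0
    miss_shift: float = 0.0
    false_alarm_shift: float = 0.0
    tlx_shift: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for name in ("mean_rr_mult", "a_lf_mult", "a_hf_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for d in self.tlx_shift:
            if d not in TLX_DIMENSIONS:
                raise ValueError(f"unknown TLX dimension {d!r}")


def _combine(cl: ConditionEffect, pl: ConditionEffect) -> ConditionEffect:
    tlx = dict(cl.tlx_shift)
    for d, v in pl.tlx_shift.items():
        tlx[d] = tlx.get(d, 0.0) + v
    return ConditionEffect(
        mean_rr_mult=cl.mean_rr_mult * pl.mean_rr_mult,
        a_lf_mult=cl.a_lf_mult * pl.a_lf_mult,
        a_hf_mult=cl.a_hf_mult * pl.a_hf_mult,
        rt_shift_ms=cl.rt_shift_ms + pl.rt_shift_ms,
        rt_sigma_shift=cl.rt_sigma_shift + pl.rt_sigma_shift,
        miss_shift=cl.miss_shift + pl.miss_shift,
        false_alarm_shift=cl.false_alarm_shift + pl.false_alarm_shift,
        tlx_shift=tlx,
    )


@dataclass(frozen=True)
class EffectMap:
    """Per-condition generator effects for the 9-cell design.

    The default map encodes the directions the dual-task literature reports:
    rising physical load lowers mean RR (raises heart rate) and suppresses
    vagally-mediated HF modulation, shifting the LF/HF balance upward; rising
    cognitive load lengthens reaction times, lowers the correct-response
    rate and raises subjective workload ratings.
    """

    effects: dict[Condition, ConditionEffect]

    def __getitem__(self, condition: Condition) -> ConditionEffect:
        return self.effects[condition]

    @classmethod
    def identity(cls) -> "EffectMap":
        return cls({c: ConditionEffect() for c in ALL_CONDITIONS})

    @classmethod
    def default(cls) -> "EffectMap":
        cl_fx = {
            1: ConditionEffect(),
            2: ConditionEffect(rt_shift_ms=80, miss_shift=0.07, false_alarm_shift=0.02,
                               tlx_shift={"mental": 3.0, "effort": 2.5, "frustration": 2.0}),
            3: ConditionEffect(rt_shift_ms=160, miss_shift=0.17, false_alarm_shift=0.03,
                               tlx_shift={"mental": 6.0, "effort": 5.0, "frustration": 4.0}),
        }
        pl_fx = {
            "none": ConditionEffect(),
            "medium": ConditionEffect(mean_rr_mult=0.92, a_hf_mult=0.70,
                                      rt_shift_ms=20, miss_shift=0.02,
                                      tlx_shift={"physical": 3.0, "temporal": 1.5, "effort": 1.5}),
            "high": ConditionEffect(mean_rr_mult=0.85, a_hf_mult=0.55, a_lf_mult=0.95,
                                    rt_shift_ms=40, miss_shift=0.04,
                                    tlx_shift={"physical": 6.0, "temporal": 3.0, "effort": 3.0}),
        }
        return cls({c: _combine(cl_fx[c.cl_level], pl_fx[c.pl_level]) for c in ALL_CONDITIONS})


# --------------------------------------------------------------------------
# n-back trials and run schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialSpec:
    """One n-back trial: the letter sequence with its target structure and timing."""

    n_back: int
    letters: tuple[str, ...]
    target_flags: tuple[bool, ...]
    stimulus_onsets: tuple[float, ...]      # s from trial start
    stimulus_duration: float = 0.5          # s each letter is on screen
    inter_stimulus_interval: float = 1.5    # s blank between letters

    def __post_init__(self):
        n = len(self.letters)
        if len(self.target_flags) != n or len(self.stimulus_onsets) != n:
            raise ValueError("letters, flags and onsets must align")
        for i, flag in enumerate(self.target_flags):
            is_match = i >= self.n_back and self.letters[i] == self.letters[i - self.n_back]
            if flag != is_match:
                raise ValueError(f"target flag at position {i} inconsistent with sequence")

    @property
    def n_targets(self) -> int:
        return sum(self.target_flags)

    @property
    def stimulus_period(self) -> float:
        return self.stimulus_duration + self.inter_stimulus_interval

    @property
    def active_span(self) -> float:
        """Time from trial start to the end of the last response window."""
        return self.stimulus_onsets[-1] + self.stimulus_period


@dataclass(frozen=True)
class RunSchedule:
    """A run of consecutive identical-difficulty trials."""

    trials: tuple[TrialSpec, ...]
    instruction_duration: float
    inter_trial_break: float
    per_trial_duration: float
    total_duration: float

    @property
    def trial_starts(self) -> tuple[float, ...]:
        return tuple(i * self.per_trial_duration for i in range(len(self.trials)))


def gen_nback_sequence(n_back: int, n_letters: int = 20, n_targets: int = 5,
                       alphabet: tuple[str, ...] = DEFAULT_ALPHABET,
                       seed: int = 0,
                       stimulus_duration: float = 0.5,
                       inter_stimulus_interval: float = 1.5) -> TrialSpec:
    """Generate a letter sequence with exactly ``n_targets`` lag-``n_back`` matches.

    Target positions are sampled uniformly among the eligible positions
    (index >= n_back); every non-target position at lag range is filled with
    a letter different from the one ``n_back`` positions earlier, so the
    emitted sequence has no accidental matches.
    """
    if n_back < 1:
        raise ValueError("n_back must be >= 1")
    if len(set(alphabet)) < 2:
        raise ValueError("alphabet must contain at least 2 distinct symbols")
    eligible = n_letters - n_back
    if n_targets > eligible or n_targets < 0:
        raise ValueError(
            f"cannot place {n_targets} targets in {n_letters} letters at lag {n_back} "
            f"(only {max(eligible, 0)} eligible positions)")
    rng = np.random.default_rng(seed)
    alphabet = tuple(alphabet)
    target_pos = set(rng.choice(np.arange(n_back, n_letters), size=n_targets,
                                replace=False).tolist()) if n_targets else set()
    letters: list[str] = []
    for i in range(n_letters):
        if i in target_pos:
            letters.append(letters[i - n_back])
        elif i >= n_back:
            choices = [a for a in alphabet if a != letters[i - n_back]]
            letters.append(choices[rng.integers(len(choices))])
        else:
            letters.append(alphabet[rng.integers(len(alphabet))])
    flags = tuple(i in target_pos for i in range(n_letters))
    period = stimulus_duration + inter_stimulus_interval
    onsets = tuple(i * period for i in range(n_letters))
    return TrialSpec(n_back=n_back, letters=tuple(letters), target_flags=flags,
                     stimulus_onsets=onsets, stimulus_duration=stimulus_duration,
                     inter_stimulus_interval=inter_stimulus_interval)


def build_run_schedule(trial: TrialSpec | list[TrialSpec] | tuple[TrialSpec, ...],
                       n_trials: int = 6, per_trial_duration: float = 50.0,
                       instruction_duration: float = 2.0) -> RunSchedule:
    """Schedule ``n_trials`` consecutive trials of one n-back difficulty.

    With the defaults (6 trials of 50 s) a run lasts 300 s = 5 min.  The
    inter-trial break absorbs whatever time the instruction and the letter
    sequence do not use.
    """
    trials = tuple(trial) if isinstance(trial, (list, tuple)) else (trial,) * n_trials
    if len(trials) != n_trials:
        raise ValueError("number of trials must equal n_trials")
    if n_trials < 1:
        raise ValueError("need at least one trial")
    span = instruction_duration + trials[0].active_span
    if per_trial_duration < span:
        raise ValueError(
            f"per_trial_duration {per_trial_duration} s shorter than the "
            f"instruction + stimulus span ({span} s)")
    return RunSchedule(
        trials=trials,
        instruction_duration=instruction_duration,
        inter_trial_break=per_trial_duration - span,
        per_trial_duration=per_trial_duration,
        total_duration=n_trials * per_trial_duration,
    )


# --------------------------------------------------------------------------
# IPFM RR-series generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AutonomicParams:
    """IPFM generator parameters.

    ``a_lf``/``a_hf`` are modulation amplitudes as dimensionless fractions of
    the mean rate; ``jitter_sd`` adds white beat-to-beat noise in ms on top of
    the oscillatory structure.
    """

    mean_rr: float = 800.0     # ms
    a_lf: float = 0.04
    a_hf: float = 0.04
    f_lf: float = 0.10         # Hz, inside the 0.040-0.150 LF band
    f_hf: float = 0.25         # Hz, inside the 0.150-0.400 HF band
    jitter_sd: float = 10.0    # ms
    seed: int = 0

    def __post_init__(self):
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if not (0 <= self.a_lf + self.a_hf < 1):
            raise ValueError("need 0 <= a_lf + a_hf < 1")
        if not (0.040 <= self.f_lf < 0.150):
            raise ValueError("f_lf must lie in the LF band [0.040, 0.150)")
        if not (0.150 <= self.f_hf < 0.400):
            raise ValueError("f_hf must lie in the HF band [0.150, 0.400)")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def gen_rr_series(params: AutonomicParams, duration: float = 300.0) -> RRSeries:
    """Generate an RR series from the IPFM model.

    The modulating rate is ``m(t) = (1/T0)(1 + a_lf sin(2 pi f_lf t + p1)
    + a_hf sin(2 pi f_hf t + p2))`` with T0 the mean RR in seconds; a beat is
    emitted at each integer crossing of its integral (computed analytically
    and inverted on a dense grid).  Phases are drawn from the seeded stream,
    then white jitter is added per interval.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if duration < 60:
        logger.warning("RR series of %.0f s is too short for spectral analysis", duration)
    rng = np.random.default_rng(params.seed)
    phi1, phi2 = rng.uniform(0, 2 * math.pi, size=2)
    t0 = params.mean_rr / 1000.0

    def integral(t: np.ndarray) -> np.ndarray:
        out = t / t0
        if params.a_lf:
            w = 2 * math.pi * params.f_lf
            out = out + params.a_lf / (w * t0) * (np.cos(phi1) - np.cos(w * t + phi1))
        if params.a_hf:
            w = 2 * math.pi * params.f_hf
            out = out + params.a_hf / (w * t0) * (np.cos(phi2) - np.cos(w * t + phi2))
        return out

    grid = np.arange(0.0, duration + 1e-9, 1.0 / 64)
    m_grid = integral(grid)
    n_beats = int(np.floor(m_grid[-1]))
    if n_beats < 2:
        raise ValueError("duration too short to emit two beats")
    # invert M(t) at integer crossings; M is strictly increasing (a_lf+a_hf<1)
    beat_times = np.interp(np.arange(1, n_beats + 1), m_grid, grid)
    intervals = np.diff(beat_times) * 1000.0
    if params.jitter_sd > 0:
        intervals = intervals + rng.normal(0.0, params.jitter_sd, size=len(intervals))
        intervals = np.maximum(intervals, 250.0)  # keep physiological
        beat_times = np.concatenate(([beat_times[0]],
                                     beat_times[0] + np.cumsum(intervals) / 1000.0))
    return RRSeries(beat_times=beat_times, intervals=intervals)


# --------------------------------------------------------------------------
# synthetic ECG
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Additive ECG noise components; an amplitude of 0 disables a component."""

    powerline_hz: float = 50.0
    powerline_amp: float = 0.0        # uV
    emg_bandwidth: tuple[float, float] = (20.0, 100.0)   # Hz
    emg_amp: float = 0.0              # uV RMS
    baseline_wander_hz: float = 0.2   # Hz, slow drift
    baseline_amp: float = 0.0         # uV
    seed: int = 0

    def __post_init__(self):
        for name in ("powerline_amp", "emg_amp", "baseline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_wander_hz >= 0.5:
            raise ValueError("baseline wander must be slower than 0.5 Hz")


def _pqrst_template(t: np.ndarray) -> np.ndarray:
    """Gaussian-lobe PQRST template centered on the R peak, in uV."""
    def lobe(amp, mu, sigma):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    return (lobe(80.0, -0.20, 0.025)     # P
            + lobe(-120.0, -0.035, 0.012)  # Q
            + lobe(1000.0, 0.0, 0.012)     # R
            + lobe(-150.0, 0.035, 0.012)   # S
            + lobe(200.0, 0.25, 0.070))    # T

QRS_WIDTH_S = 0.10  # nominal QRS width used for the impossible-input check


def gen_ecg(rr: RRSeries, fs: float = 256.0, noise: NoiseSpec = NoiseSpec(),
            duration: float | None = None) -> ECGRecord:
    """Render an RR series as a sampled single-lead ECG with additive noise.

    A PQRST-like template (dominant R deflection ~90 ms wide) is centered at
    each beat time; powerline, band-limited EMG and slow baseline-wander
    components are added per the noise spec.  Ground-truth beat times are
    stored as annotations.
    """
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    beats = rr.beat_times if rr is not None else np.array([])
    if len(beats) >= 2 and np.min(np.diff(beats)) < QRS_WIDTH_S:
        raise ValueError("beat interval shorter than the QRS template width")
    if duration is None:
        duration = float(beats[-1] + 0.5) if len(beats) else 1.0
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for b in beats:
        lo = max(0, int((b - 0.35) * fs))
        hi = min(n, int((b + 0.45) * fs) + 1)
        x[lo:hi] += _pqrst_template(t[lo:hi] - b)

    rng = np.random.default_rng(noise.seed)
    if noise.powerline_amp > 0:
        x = x + noise.powerline_amp * np.sin(2 * math.pi * noise.powerline_hz * t)
    if noise.baseline_amp > 0:
        x = x + noise.baseline_amp * np.sin(2 * math.pi * noise.baseline_wander_hz * t
                                            + rng.uniform(0, 2 * math.pi))
    if noise.emg_amp > 0:
        from scipy.signal import butter, sosfiltfilt
        white = rng.standard_normal(n)
        lo_hz, hi_hz = noise.emg_bandwidth
        hi_hz = min(hi_hz, 0.45 * fs)
        sos = butter(4, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
        emg = sosfiltfilt(sos, white)
        emg *= noise.emg_amp / np.std(emg)
        x = x + emg

    ann = beats[(beats >= 0) & (beats <= duration)] if len(beats) else None
    return ECGRecord(samples=x, fs=fs, annotations=ann)


# --------------------------------------------------------------------------
# behavioral responses and TLX
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseEvent:
    onset: float          # stimulus onset, s from trial start
    is_target: bool
    responded: bool
    rt_ms: float | None = None

    def __post_init__(self):
        if self.rt_ms is not None and not self.responded:
            raise ValueError("rt present implies responded")
        if self.rt_ms is not None and self.rt_ms <= 0:
            raise ValueError("rt must be positive")


@dataclass(frozen=True)
class ResponseLog:
    """Per-stimulus behavioral events for one trial."""

    events: tuple[ResponseEvent, ...]
    response_window_s: float = 2.0


@dataclass(frozen=True)
class BehaviorParams:
    """Baseline response model: lognormal RTs, miss and false-alarm rates."""

    rt_median_ms: float = 500.0
    rt_sigma: float = 0.25         # lognormal shape
    miss_prob: float = 0.05
    false_alarm_prob: float = 0.02
    response_window_s: float = 2.0


def gen_response_log(trial: TrialSpec, condition: Condition,
                     effects: EffectMap, seed: int = 0,
                     base: BehaviorParams = BehaviorParams()) -> ResponseLog:
    """Simulate key presses for one trial under a load condition.

    Each target is hit with probability ``1 - miss_prob`` with a lognormal
    RT whose location shifts with load; responses landing beyond the
    response window count as misses.  Non-targets draw false alarms with a
    small condition-dependent probability.
    """
    fx = effects[condition]
    rng = np.random.default_rng(seed)
    median = base.rt_median_ms + fx.rt_shift_ms
    sigma = max(base.rt_sigma + fx.rt_sigma_shift, 0.0)
    p_miss = float(np.clip(base.miss_prob + fx.miss_shift, 0.0, 1.0))
    p_fa = float(np.clip(base.false_alarm_prob + fx.false_alarm_shift, 0.0, 1.0))
    window_ms = base.response_window_s * 1000.0

    events = []
    for onset, is_target in zip(trial.stimulus_onsets, trial.target_flags):
        responded, rt = False, None
        if is_target:
            if rng.random() >= p_miss:
                rt_draw = median * math.exp(sigma * rng.standard_normal())
                if rt_draw <= window_ms:
                    responded, rt = True, rt_draw
        else:
            if rng.random() < p_fa:
                rt_draw = median * math.exp(sigma * rng.standard_normal())
                if rt_draw <= window_ms:
                    responded, rt = True, rt_draw
        events.append(ResponseEvent(onset=onset, is_target=is_target,
                                    responded=responded, rt_ms=rt))
    return ResponseLog(events=tuple(events), response_window_s=base.response_window_s)


@dataclass(frozen=True)
class TLXBase:
    """Baseline NASA-TLX rating means on the 0-20 scale, and rating noise."""

    means: dict[str, float] = field(default_factory=lambda: {
        "mental": 8.0, "physical": 4.0, "temporal": 8.0,
        "performance": 8.0, "effort": 8.0, "frustration": 6.0})
    rating_sd: float = 2.0


def gen_tlx_response(condition: Condition, effects: EffectMap, seed: int = 0,
                     base: TLXBase = TLXBase()):
    """Draw a six-dimension TLX rating sheet plus the 15 pairwise choices.

    Ratings are normal draws around condition-shifted dimension means,
    rounded and clipped to the 21-point (0-20) scale.  Each pairwise choice
    picks the dimension with the larger latent importance (its shifted mean
    plus noise), so choices are consistent with rating magnitudes.
    """
    from .taskload import TLXResponse  # avoid import cycle at module load

    fx = effects[condition]
    rng = np.random.default_rng(seed)
    means = {d: base.means[d] + fx.tlx_shift.get(d, 0.0) for d in TLX_DIMENSIONS}
    ratings = {}
    for d in TLX_DIMENSIONS:
        r = means[d] + (base.rating_sd * rng.standard_normal() if base.rating_sd else 0.0)
        ratings[d] = int(np.clip(round(r), 0, 20))
    latent = {d: means[d] + (base.rating_sd * rng.standard_normal()
                             if base.rating_sd else 0.0) for d in TLX_DIMENSIONS}
    choices = []
    for a, b in itertools.combinations(TLX_DIMENSIONS, 2):
        if latent[a] == latent[b]:
            chosen = a if rng.random() < 0.5 else b
        else:
            chosen = a if latent[a] > latent[b] else b
        choices.append(((a, b), chosen))
    return TLXResponse(ratings=ratings, pair_choices=tuple(choices))


# --------------------------------------------------------------------------
# full study dataset
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionData:
    """Everything recorded for one subject in one design cell."""

    condition: Condition
    rr: RRSeries
    response_logs: tuple[ResponseLog, ...]
    tlx: "object"  # TLXResponse
    ecg: ECGRecord | None = None


@dataclass(frozen=True)
class SubjectData:
    subject_id: int
    subgroup: int                    # 0, 1, 2 -> rotation of run order
    task_order: tuple[int, int, int]
    conditions: dict[Condition, ConditionData]


@dataclass(frozen=True)
class StudyDataset:
    subjects: tuple[SubjectData, ...]
    effects: EffectMap
    seed: int


@dataclass(frozen=True)
class StudyDesign:
    """Study-level generator settings (the paper's protocol by default)."""

    n_letters: int = 20
    n_targets: int = 5
    n_trials: int = 6
    per_trial_duration: float = 50.0
    rr_duration: float = 300.0
    base_autonomic: AutonomicParams = AutonomicParams()
    base_behavior: BehaviorParams = BehaviorParams()
    base_tlx: TLXBase = TLXBase()
    subject_rr_sd: float = 50.0      # ms, between-subject mean RR spread
    subject_rt_sd: float = 50.0      # ms, between-subject RT-location spread
    include_ecg: bool = False
    ecg_fs: float = 256.0
    ecg_noise: NoiseSpec = NoiseSpec()


def gen_study_dataset(n_subjects: int = 35, effects: EffectMap | None = None,
                      seed: int = 0, design: StudyDesign = StudyDesign()) -> StudyDataset:
    """Generate the full within-subject study: n subjects x 9 conditions.

    Each subject carries random effects (baseline mean RR and RT offset)
    shared across all of their conditions, and is assigned to one of the
    three counterbalanced run-order subgroups (sizes differ by at most one).
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effects = effects if effects is not None else EffectMap.default()
    root = np.random.SeedSequence(seed)
    subgroup_of = np.random.default_rng(root.spawn(1)[0]).permutation(
        np.arange(n_subjects) % 3)

    subjects = []
    subject_seeds = root.spawn(n_subjects)
    for sid in range(n_subjects):
        sub_root = subject_seeds[sid]
        rng = np.random.default_rng(sub_root)
        rr_offset = rng.normal(0.0, design.subject_rr_sd)
        rt_offset = rng.normal(0.0, design.subject_rt_sd)
        cond_seeds = sub_root.spawn(len(ALL_CONDITIONS))
        conditions = {}
        for cond, cseed in zip(ALL_CONDITIONS, cond_seeds):
            fx = effects[cond]
            streams = cseed.generate_state(3 + 2 * design.n_trials) % (2 ** 31)
            base = design.base_autonomic
            params = replace(
                base,
                mean_rr=(base.mean_rr + rr_offset) * fx.mean_rr_mult,
                a_lf=base.a_lf * fx.a_lf_mult,
                a_hf=base.a_hf * fx.a_hf_mult,
                seed=int(streams[0]),
            )
            rr = gen_rr_series(params, duration=design.rr_duration)
            behavior = replace(design.base_behavior,
                               rt_median_ms=design.base_behavior.rt_median_ms + rt_offset)
            logs = []
            for k in range(design.n_trials):
                trial = gen_nback_sequence(cond.cl_level, design.n_letters,
                                           design.n_targets, seed=int(streams[3 + k]))
                logs.append(gen_response_log(
                    trial, cond, effects,
                    seed=int(streams[3 + design.n_trials + k]), base=behavior))
            tlx = gen_tlx_response(cond, effects, seed=int(streams[1]),
                                   base=design.base_tlx)
            ecg = None
            if design.include_ecg:
                ecg = gen_ecg(rr, fs=design.ecg_fs,
                              noise=replace(design.ecg_noise, seed=int(streams[2])))
            conditions[cond] = ConditionData(condition=cond, rr=rr,
                                             response_logs=tuple(logs), tlx=tlx, ecg=ecg)
        subjects.append(SubjectData(
            subject_id=sid, subgroup=int(subgroup_of[sid]),
            task_order=TASK_ORDERS[int(subgroup_of[sid])], conditions=conditions))
    return StudyDataset(subjects=tuple(subjects), effects=effects, seed=seed)
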