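"""Synthetic StartReact sessions: trial designs, EMG signals and ground truth.

Emulates a simple wrist-extension reaction-time task in which an irrelevant
auditory prepulse (80-120 dB) is presented before a visual go-signal.  Loud
prepulses probabilistically elicit a short-latency startle burst in the
sternocleidomastoid (SCM) and may involuntarily trigger the prepared
response in the agonist (ECR) at short latency.  The generator draws all
trial-level events (startle, triggering, reaction times, error trials)
first and only then renders the four-channel signal set, so event-level
ground truth is reproducible with or without waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

CHANNELS = ("ecr", "fcr", "scm")

LOUD_INTENSITIES = (110, 120)  # dB levels subject to placement constraints


class DesignError(RuntimeError):
    """Raised when a pseudorandom trial order cannot satisfy its constraints."""


@dataclass(frozen=True)
class ConditionSpec:
    """Stimulus condition of a single trial.

    Auditory trials carry an intensity (dB) and a presentation offset in ms
    relative to the visual go-signal (negative = before); visual-only trials
    carry neither.
    """

    stimulus_kind: str
    intensity_db: int | None = None
    presentation_offset_ms: int | None = None

    def __post_init__(self) -> None:
        if self.stimulus_kind == "auditory":
            if self.intensity_db is None or self.presentation_offset_ms is None:
                raise ValueError("auditory condition requires intensity and offset")
        elif self.stimulus_kind == "visual_only":
            if self.intensity_db is not None or self.presentation_offset_ms is not None:
                raise ValueError("visual_only condition carries no auditory fields")
        else:
            raise ValueError(f"unknown stimulus_kind {self.stimulus_kind!r}")

    @property
    def is_auditory(self) -> bool:
        return self.stimulus_kind == "auditory"


@dataclass(frozen=True)
class RTDist:
    """Shifted-lognormal reaction-time distribution (all values in ms)."""

    shift_ms: float
    log_mean: float
    log_sd: float

    def sample(self, rng: np.random.Generator) -> float:
        return self.shift_ms + float(rng.lognormal(self.log_mean, self.log_sd))

    @property
    def mean_ms(self) -> float:
        return self.shift_ms + math.exp(self.log_mean + 0.5 * self.log_sd**2)


def _as_lookup(value, key):
    """Probability parameters may be scalars or mappings keyed by
    (intensity, offset) or by intensity alone."""
    if isinstance(value, Mapping):
        if key in value:
            return value[key]
        if key[0] in value:
            return value[key[0]]
        raise KeyError(f"no probability configured for condition {key}")
    return value


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic session generator.

    Defaults describe the acquisition used throughout: 4000 Hz sampling on a
    [-2000, +2000] ms window around the go-signal, a 2500-3000 ms variable
    foreperiod, SCM startle latencies in the 20-120 ms window and
    reaction-time distributions centred near 103 ms (triggered, SCM+),
    143 ms (triggered, SCM-) and 200 ms (visual).
    """

    sample_rate: float = 4000.0
    record_window_ms: tuple[float, float] = (-2000.0, 2000.0)
    foreperiod_range_ms: tuple[float, float] = (2500.0, 3000.0)
    # probability of an SCM startle burst, per (intensity_db, offset_ms)
    p_scm: Mapping | float = field(default_factory=dict)
    p_trigger_given_scm_plus: Mapping | float = 0.8
    p_trigger_given_scm_minus: Mapping | float = 0.18
    scm_latency_mean_ms: float = 75.0
    scm_latency_sd_ms: float = 15.0
    scm_latency_window_ms: tuple[float, float] = (20.0, 120.0)
    rt_dist_triggered_scm_plus: RTDist = field(
        default_factory=lambda: RTDist(70.0, math.log(30.0), 0.35)
    )
    rt_dist_triggered_scm_minus: RTDist = field(
        default_factory=lambda: RTDist(90.0, math.log(48.0), 0.40)
    )
    rt_dist_visual: RTDist = field(
        default_factory=lambda: RTDist(140.0, math.log(55.0), 0.30)
    )
    baseline_rms: Mapping[str, float] = field(
        default_factory=lambda: {"ecr": 1.0, "fcr": 1.0, "scm": 1.0}
    )
    burst_gain: Mapping[str, float] = field(
        default_factory=lambda: {"ecr": 10.0, "fcr": 6.0, "scm": 10.0}
    )
    burst_duration_ms: Mapping[str, float] = field(
        default_factory=lambda: {"ecr": 150.0, "fcr": 100.0, "scm": 75.0}
    )
    emg_band_hz: tuple[float, float] = (20.0, 450.0)
    # burst amplitude-envelope ramps; surface-EMG bursts rise over ~10-30 ms
    burst_rise_ms: float = 20.0
    burst_fall_ms: float = 20.0
    error_rates: Mapping[str, float] = field(
        default_factory=lambda: {"anticipation": 0.009, "slow": 0.010, "movement": 0.004}
    )
    electromechanical_delay_ms: float = 40.0
    movement_amplitude_deg: float = 20.0
    movement_duration_ms: float = 150.0
    fcr_lag_ms: float = 60.0
    # between-subject heterogeneity: SD of a logit-normal jitter on p_scm
    heterogeneity_logit_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.record_window_ms
        if hi <= lo:
            raise ValueError("record window must be non-empty")
        for dist in (
            self.rt_dist_triggered_scm_plus,
            self.rt_dist_triggered_scm_minus,
            self.rt_dist_visual,
        ):
            if dist.log_sd <= 0:
                raise ValueError("RT distributions must have positive scale")
        probs = list(self.error_rates.values())
        for name in ("p_trigger_given_scm_plus", "p_trigger_given_scm_minus"):
            v = getattr(self, name)
            probs.extend(v.values() if isinstance(v, Mapping) else [v])
        if isinstance(self.p_scm, Mapping):
            probs.extend(self.p_scm.values())
        else:
            probs.append(self.p_scm)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        # baseline window for detection is [-1500, -1000); the record must
        # cover it together with the earliest auditory stimulus
        if lo > -1500.0:
            raise ValueError("record window must cover the 500 ms baseline window")

    @property
    def n_samples(self) -> int:
        lo, hi = self.record_window_ms
        return int(round((hi - lo) * self.sample_rate / 1000.0))

    def time_axis_ms(self) -> np.ndarray:
        lo, _ = self.record_window_ms
        return lo + np.arange(self.n_samples) * (1000.0 / self.sample_rate)


@dataclass
class TrialRecord:
    """One trial: identity, event times and (optionally) sampled signals.

    Trial-local time puts the visual go-signal at 0 ms; the auditory
    stimulus, when present, occurs at -1000 or -300 ms.  ``signals`` maps
    channel name (ecr, fcr, scm, position) to a float array on the record
    window, or is None for event-only cohorts.
    """

    participant_id: str
    block_index: int
    trial_index: int
    condition: ConditionSpec
    go_time_ms: float = 0.0
    auditory_time_ms: float | None = None
    foreperiod_ms: float = 2750.0
    movement_error: bool = False
    sample_rate: float = 4000.0
    record_window_ms: tuple[float, float] = (-2000.0, 2000.0)
    signals: dict[str, np.ndarray] | None = None


@dataclass
class GroundTruth:
    """Generator-side labels used only as a test oracle."""

    scm_burst_injected: bool
    scm_true_onset_ms: float | None
    response_triggered: bool
    ecr_true_onset_ms: float | None
    error_injected: str = "none"  # none | anticipation | slow | movement

    def __post_init__(self) -> None:
        if self.scm_burst_injected != (self.scm_true_onset_ms is not None):
            raise ValueError("scm_true_onset_ms present iff scm_burst_injected")


@dataclass
class Session:
    """All trials of one synthetic participant, in presentation order."""

    participant_id: str
    preset: str
    trials: list[TrialRecord]
    truths: list[GroundTruth]
    master_seed: int

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# preset configurations


def exp1_config(**overrides) -> GeneratorConfig:
    """Defaults for the 50%-auditory design: four intensities at two offsets.

    Startle and triggering probabilities rise with intensity and with later
    (closer-to-go) presentation.
    """
    p_scm = {
        (80, -1000): 0.08, (100, -1000): 0.35, (110, -1000): 0.55, (120, -1000): 0.70,
        (80, -300): 0.15, (100, -300): 0.50, (110, -300): 0.70, (120, -300): 0.85,
    }
    p_plus = {80: 0.55, 100: 0.75, 110: 0.80, 120: 0.85}
    p_minus = {80: 0.05, 100: 0.15, 110: 0.20, 120: 0.30}
    cfg = GeneratorConfig(
        p_scm=p_scm,
        p_trigger_given_scm_plus=p_plus,
        p_trigger_given_scm_minus=p_minus,
    )
    return replace(cfg, **overrides) if overrides else cfg


def exp2_config(**overrides) -> GeneratorConfig:
    """Defaults for the 20%-auditory design: 114/120 dB at -300 ms only."""
    p_scm = {(114, -300): 0.71, (120, -300): 0.83}
    cfg = GeneratorConfig(
        p_scm=p_scm,
        p_trigger_given_scm_plus=0.92,
        p_trigger_given_scm_minus=0.55,
        error_rates={"anticipation": 0.020, "slow": 0.025, "movement": 0.005},
    )
    return replace(cfg, **overrides) if overrides else cfg


def preset_config(preset: str, **overrides) -> GeneratorConfig:
    if preset == "exp1":
        return exp1_config(**overrides)
    if preset == "exp2":
        return exp2_config(**overrides)
    raise ValueError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# trial design


def _exp1_block() -> list[ConditionSpec]:
    trials = [ConditionSpec("visual_only")] * 16
    for intensity in (80, 100, 110, 120):
        for offset in (-1000, -300):
            trials += [ConditionSpec("auditory", intensity, offset)] * 2
    return trials


def _exp2_block() -> list[ConditionSpec]:
    trials = [ConditionSpec("visual_only")] * 24
    for intensity in (114, 120):
        trials += [ConditionSpec("auditory", intensity, -300)] * 3
    return trials


def _exp1_ok(order: Sequence[ConditionSpec]) -> bool:
    loud = [c.is_auditory and c.intensity_db in LOUD_INTENSITIES for c in order]
    if loud[0] or loud[1]:
        return False
    return not any(a and b for a, b in zip(loud, loud[1:]))


def _exp2_ok(order: Sequence[ConditionSpec]) -> bool:
    aud = [c.is_auditory for c in order]
    if aud[0] or aud[1]:
        return False
    return not any(a and b for a, b in zip(aud, aud[1:]))


_BLOCKS = {"exp1": (_exp1_block, _exp1_ok), "exp2": (_exp2_block, _exp2_ok)}


def build_design(
    preset: str,
    n_blocks: int,
    rng_seed: int | np.random.Generator = 0,
    max_retries: int = 10_000,
) -> list[ConditionSpec]:
    """Pseudorandom trial order for ``n_blocks`` testing blocks.

    exp1 blocks hold 16 visual-only trials plus 2 trials per
    intensity-by-offset cell (32 total); exp2 blocks hold 24 visual-only
    plus 3 per intensity (30 total).  Orders are re-drawn (bounded retries)
    until placement constraints hold: the loudest stimuli (exp1: 110/120 dB;
    exp2: any auditory trial) never occupy the first two positions of a
    block nor two consecutive positions.
    """
    if preset not in _BLOCKS:
        raise ValueError(f"unknown preset {preset!r}")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    block_fn, ok_fn = _BLOCKS[preset]
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    design: list[ConditionSpec] = []
    for _ in range(n_blocks):
        block = block_fn()
        for attempt in range(max_retries):
            order = list(rng.permutation(len(block)))
            candidate = [block[i] for i in order]
            if ok_fn(candidate):
                design.extend(candidate)
                break
        else:
            raise DesignError(
                f"could not satisfy placement constraints in {max_retries} shuffles"
            )
    return design


# ---------------------------------------------------------------------------
# single-trial synthesis


def _truncnorm_ms(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(spstats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_events(
    condition: ConditionSpec,
    config: GeneratorConfig,
    rng: np.random.Generator,
    p_scm_override: Mapping | None = None,
) -> tuple[GroundTruth, bool]:
    """Draw startle/trigger/RT/error outcomes for one trial.

    Returns the ground truth plus a movement-error flag (the latter is
    carried on the TrialRecord so classification can see it without
    consulting the ground truth).
    """
    aud = condition.presentation_offset_ms
    err = "none"
    u = rng.random()
    rates = config.error_rates
    if u < rates.get("anticipation", 0.0):
        err = "anticipation"
    elif u < rates.get("anticipation", 0.0) + rates.get("slow", 0.0):
        err = "slow"
    elif u < sum(rates.get(k, 0.0) for k in ("anticipation", "slow", "movement")):
        err = "movement"

    scm = False
    scm_onset = None
    if condition.is_auditory:
        key = (condition.intensity_db, condition.presentation_offset_ms)
        table = p_scm_override if p_scm_override is not None else config.p_scm
        p = _as_lookup(table, key)
        scm = rng.random() < p
        if scm:
            lo, hi = config.scm_latency_window_ms
            lat = _truncnorm_ms(
                rng, config.scm_latency_mean_ms, config.scm_latency_sd_ms, lo, hi
            )
            scm_onset = aud + lat

    triggered = False
    if condition.is_auditory:
        key = (condition.intensity_db, condition.presentation_offset_ms)
        p_trig = _as_lookup(
            config.p_trigger_given_scm_plus if scm else config.p_trigger_given_scm_minus,
            key,
        )
        triggered = rng.random() < p_trig

    # response onset (the participant always responds in this simple-RT task)
    if err == "anticipation":
        rt = rng.uniform(5.0, 45.0)
        ecr_onset = (aud + rt) if condition.is_auditory else rt
        triggered = bool(condition.is_auditory)
    elif err == "slow":
        if condition.is_auditory and triggered and aud == -1000:
            # a sluggish triggered response: lands after the 300 ms bound
            # but still before the go-signal (the dead zone)
            ecr_onset = aud + rng.uniform(310.0, 600.0)
        else:
            triggered = False
            ecr_onset = rng.uniform(410.0, 560.0)
    elif triggered:
        dist = (
            config.rt_dist_triggered_scm_plus
            if scm
            else config.rt_dist_triggered_scm_minus
        )
        ecr_onset = aud + dist.sample(rng)
    else:
        ecr_onset = config.rt_dist_visual.sample(rng)

    gt = GroundTruth(
        scm_burst_injected=scm,
        scm_true_onset_ms=scm_onset,
        response_triggered=triggered,
        ecr_true_onset_ms=float(ecr_onset),
        error_injected=err,
    )
    return gt, err == "movement"


def _bandpassed_noise(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float], rms: float
) -> np.ndarray:
    sos = sps.butter(4, band, btype="band", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x * (rms / np.std(x))


def _burst_profile(n: int, fs: float, rise_ms: float = 20.0, fall_ms: float = 20.0):
    """Trapezoid amplitude profile: fast linear rise, plateau, linear fall."""
    rise = max(1, int(round(rise_ms * fs / 1000.0)))
    fall = max(1, int(round(fall_ms * fs / 1000.0)))
    rise = min(rise, n)
    fall = min(fall, max(0, n - rise))
    prof = np.ones(n)
    prof[:rise] = np.linspace(0.0, 1.0, rise, endpoint=False)
    if fall:
        prof[n - fall:] = np.linspace(1.0, 0.0, fall)
    return prof


def _add_burst(
    sig: np.ndarray,
    rng: np.random.Generator,
    onset_ms: float,
    duration_ms: float,
    amplitude: float,
    t0_ms: float,
    fs: float,
    band: tuple[float, float],
    rise_ms: float = 20.0,
    fall_ms: float = 20.0,
) -> None:
    i0 = int(round((onset_ms - t0_ms) * fs / 1000.0))
    n = int(round(duration_ms * fs / 1000.0))
    i0, i1 = max(i0, 0), min(i0 + n, sig.size)
    if i1 <= i0:
        return
    seg = _bandpassed_noise(rng, i1 - i0, fs, band, amplitude)
    sig[i0:i1] += seg * _burst_profile(i1 - i0, fs, rise_ms, fall_ms)


def _render_signals(
    condition: ConditionSpec,
    gt: GroundTruth,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    fs = config.sample_rate
    n = config.n_samples
    t0 = config.record_window_ms[0]
    band = config.emg_band_hz
    sigs: dict[str, np.ndarray] = {}
    for ch in CHANNELS:
        sigs[ch] = _bandpassed_noise(rng, n, fs, band, config.baseline_rms[ch])

    def gain(ch: str) -> float:
        return config.burst_gain[ch] * config.baseline_rms[ch]

    ramps = (config.burst_rise_ms, config.burst_fall_ms)
    if gt.scm_burst_injected:
        _add_burst(
            sigs["scm"], rng, gt.scm_true_onset_ms,
            config.burst_duration_ms["scm"], gain("scm"), t0, fs, band, *ramps,
        )
    if gt.ecr_true_onset_ms is not None:
        _add_burst(
            sigs["ecr"], rng, gt.ecr_true_onset_ms,
            config.burst_duration_ms["ecr"], gain("ecr"), t0, fs, band, *ramps,
        )
        _add_burst(
            sigs["fcr"], rng, gt.ecr_true_onset_ms + config.fcr_lag_ms,
            config.burst_duration_ms["fcr"], gain("fcr"), t0, fs, band, *ramps,
        )

    # wrist position: quiet, then a smooth (cosine-ramp) 20 degree extension
    # beginning one electromechanical delay after agonist EMG onset
    pos = np.zeros(n)
    if gt.ecr_true_onset_ms is not None:
        move_on = gt.ecr_true_onset_ms + config.electromechanical_delay_ms
        i0 = int(round((move_on - t0) * fs / 1000.0))
        m = int(round(config.movement_duration_ms * fs / 1000.0))
        if i0 < n:
            ramp = 0.5 * (1 - np.cos(np.pi * np.linspace(0, 1, m)))
            i1 = min(i0 + m, n)
            pos[i0:i1] = config.movement_amplitude_deg * ramp[: i1 - i0]
            pos[i1:] = config.movement_amplitude_deg
        pos = np.clip(pos, 0, None)
    pos += 0.02 * rng.standard_normal(n)
    sigs["position"] = pos
    return sigs


def synthesize_trial(
    condition: ConditionSpec,
    config: GeneratorConfig,
    rng: np.random.Generator | int = 0,
    *,
    participant_id: str = "P00",
    block_index: int = 0,
    trial_index: int = 0,
    p_scm_override: Mapping | None = None,
    signals: bool = True,
) -> tuple[TrialRecord, GroundTruth]:
    """Synthesize one trial: draw events, then optionally render signals.

    Two independent RNG streams (spawned from ``rng``) serve event draws and
    waveform noise, so event-level ground truth does not depend on whether
    waveforms are rendered.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ev_ss, noise_ss = rng.bit_generator.seed_seq.spawn(2)
    rng_events = np.random.default_rng(ev_ss)
    rng_noise = np.random.default_rng(noise_ss)

    if condition.is_auditory:
        key = (condition.intensity_db, condition.presentation_offset_ms)
        _as_lookup(config.p_scm, key)  # raises if unsupported condition

    gt, movement = _draw_events(condition, config, rng_events, p_scm_override)
    foreperiod = float(rng_events.uniform(*config.foreperiod_range_ms))
    record = TrialRecord(
        participant_id=participant_id,
        block_index=block_index,
        trial_index=trial_index,
        condition=condition,
        auditory_time_ms=(
            float(condition.presentation_offset_ms) if condition.is_auditory else None
        ),
        foreperiod_ms=foreperiod,
        movement_error=movement,
        sample_rate=config.sample_rate,
        record_window_ms=config.record_window_ms,
        signals=_render_signals(condition, gt, config, rng_noise) if signals else None,
    )
    if movement:
        gt.error_injected = "movement"
    return record, gt


def _jittered_p_scm(
    config: GeneratorConfig, rng: np.random.Generator
) -> Mapping | float:
    """Participant-level startle susceptibility: one shared logit-normal
    deviate shifts every condition's p_scm."""
    sd = config.heterogeneity_logit_sd
    if sd <= 0:
        return config.p_scm
    shift = rng.normal(0.0, sd)

    def jitter(p: float) -> float:
        p = min(max(p, 1e-6), 1 - 1e-6)
        return float(1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + shift))))

    if isinstance(config.p_scm, Mapping):
        return {k: jitter(v) for k, v in config.p_scm.items()}
    return jitter(config.p_scm)


def generate_cohort(
    config: GeneratorConfig,
    preset: str,
    n_participants: int,
    seed: int | None = None,
    *,
    n_blocks: int = 4,
    signals: bool = True,
) -> list[Session]:
    """Generate a cohort of synthetic sessions, one per participant.

    Per-participant seeds derive deterministically from the master seed, and
    each participant receives a logit-normal startle-susceptibility jitter so
    the >50% SCM+ participant screen has something to screen.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    master = config.seed if seed is None else seed
    root = np.random.SeedSequence(master)
    sessions: list[Session] = []
    block_len = len(_BLOCKS[preset][0]())
    for p_idx, part_ss in enumerate(root.spawn(n_participants)):
        pid = f"P{p_idx:02d}"
        design_ss, hetero_ss, trials_ss = part_ss.spawn(3)
        design = build_design(preset, n_blocks, np.random.default_rng(design_ss))
        p_scm_i = _jittered_p_scm(config, np.random.default_rng(hetero_ss))
        records, truths = [], []
        for t_idx, (cond, t_ss) in enumerate(zip(design, trials_ss.spawn(len(design)))):
            rec, gt = synthesize_trial(
                cond,
                config,
                np.random.default_rng(t_ss),
                participant_id=pid,
                block_index=t_idx // block_len,
                trial_index=t_idx,
                p_scm_override=p_scm_i,
                signals=signals,
            )
            records.append(rec)
            truths.append(gt)
        sessions.append(Session(pid, preset, records, truths, master))
    return sessions
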