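"""EMG envelope computation and sustained-threshold burst-onset detection.

The onset rule: on the DC-corrected, rectified, 25 Hz low-pass (elliptic)
filtered EMG, a burst begins at the first sample that rises more than
``threshold_sd_multiplier`` baseline standard deviations above the baseline
mean and stays above that threshold for at least ``sustain_ms``.  Baseline
statistics come from the 500 ms immediately before the earliest possible
auditory stimulus.

Conventions: times are in ms relative to the visual go-signal; windows are
half-open [start, end) except the upper SCM bound, which is inclusive at
the onset sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synth import TrialRecord


@dataclass
class DetectorConfig:
    """Envelope filter and sustained-threshold parameters.

    The filter realization is a zero-phase order-2 elliptic low-pass
    (0.5 dB ripple, 40 dB stopband); zero-phase keeps onset latency
    unbiased.  A single-pass causal mode is available via ``zero_phase``.
    ``sustain_fraction`` relaxes the strict every-sample sustain rule when
    set below 1 (the first sample must always exceed threshold).
    """

    lowpass_cutoff_hz: float = 25.0
    filter_order: int = 2
    passband_ripple_db: float = 0.5
    stopband_atten_db: float = 40.0
    zero_phase: bool = True
    threshold_sd_multiplier: float = 2.0
    sustain_ms: float = 25.0
    sustain_fraction: float = 1.0
    baseline_window_ms: tuple[float, float] = (-1500.0, -1000.0)
    scm_window_ms: tuple[float, float] = (20.0, 120.0)  # relative to stimulus
    # generous search ceiling past the go-signal: the RT error filters (not
    # the search window) enforce the 300/400 ms slow-response rules, so
    # slow responses must remain detectable to be filtered with the right
    # reason rather than vanishing
    rt_upper_bound_ms: float = 600.0
    baseline_sd_ddof: int = 0  # population SD


@dataclass
class EnvelopeSignal:
    """Nonnegative EMG amplitude series on the trial's record window."""

    samples: np.ndarray
    sample_rate: float
    t0_ms: float  # time of sample 0, relative to the go-signal

    def index(self, time_ms: float) -> int:
        return int(round((time_ms - self.t0_ms) * self.sample_rate / 1000.0))

    def time_ms(self, i: int) -> float:
        return self.t0_ms + i * 1000.0 / self.sample_rate


@dataclass
class BaselineStats:
    mean: float
    sd: float
    window_ms: tuple[float, float]


@dataclass
class BurstOnset:
    channel: str
    onset_ms: float  # nan when not found
    threshold: float
    found: bool
    baseline_mean: float = np.nan
    baseline_sd: float = np.nan


def compute_envelope(
    raw: np.ndarray, sample_rate: float, cfg: DetectorConfig | None = None
) -> EnvelopeSignal:
    """clip0(lowpass(|x - mean(x)|)): DC-correct, rectify, filter, clip.

    Small negative filter ringing is clipped to zero so the envelope is a
    valid amplitude.  Length is preserved.
    """
    cfg = cfg or DetectorConfig()
    x = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("raw signal contains non-finite samples")
    if sample_rate <= 2 * cfg.lowpass_cutoff_hz:
        raise ValueError("sample rate must exceed twice the low-pass cutoff")
    b, a = sps.ellip(
        cfg.filter_order,
        cfg.passband_ripple_db,
        cfg.stopband_atten_db,
        cfg.lowpass_cutoff_hz,
        btype="low",
        fs=sample_rate,
    )
    # even-order elliptic filters sit at -ripple dB at DC; normalise to unit
    # DC gain so envelope amplitudes are calibrated (detection itself is
    # scale-invariant, baseline stats and threshold scale together)
    b = b / (np.sum(b) / np.sum(a))
    minlen = 3 * (max(len(a), len(b)) - 1) + 1
    if x.size < minlen:
        raise ValueError(f"signal too short for filtering (need >= {minlen} samples)")
    rect = np.abs(x - x.mean())
    filt = sps.filtfilt(b, a, rect) if cfg.zero_phase else sps.lfilter(b, a, rect)
    return EnvelopeSignal(np.clip(filt, 0.0, None), sample_rate, 0.0)


def baseline_stats(
    env: EnvelopeSignal, window_ms: tuple[float, float] | None = None, ddof: int = 0
) -> BaselineStats:
    """Mean and SD of the envelope on the half-open window [start, end)."""
    window_ms = window_ms or (-1500.0, -1000.0)
    i0, i1 = env.index(window_ms[0]), env.index(window_ms[1])
    if i0 < 0 or i1 > env.samples.size or i1 <= i0:
        raise ValueError(f"baseline window {window_ms} outside recording")
    seg = env.samples[i0:i1]
    return BaselineStats(float(seg.mean()), float(seg.std(ddof=ddof)), window_ms)


def _sustain_samples(cfg: DetectorConfig, sample_rate: float) -> int:
    # the sustain interval [t, t + sustain_ms] is inclusive at both ends
    return int(round(cfg.sustain_ms * sample_rate / 1000.0)) + 1


def detect_onset(
    env: EnvelopeSignal,
    base: BaselineStats,
    search_ms: tuple[float, float],
    cfg: DetectorConfig | None = None,
    *,
    channel: str = "",
    end_inclusive: bool = False,
) -> BurstOnset:
    """Earliest sample in the search window whose envelope exceeds
    baseline mean + k*SD and remains above it for the sustain interval.

    Candidates come from the search window; the sustain interval may extend
    past its end (but not past the recording).  ``found`` is False when no
    sample qualifies.
    """
    cfg = cfg or DetectorConfig()
    thr = base.mean + cfg.threshold_sd_multiplier * base.sd
    k = _sustain_samples(cfg, env.sample_rate)
    i0 = max(env.index(search_ms[0]), 0)
    i1 = env.index(search_ms[1]) + (1 if end_inclusive else 0)
    i1 = min(i1, env.samples.size)
    if i1 - i0 < k - 1:
        raise ValueError("search window shorter than the sustain interval")
    above = env.samples > thr
    # candidates whose full sustain interval fits in the recording
    last = min(i1, above.size - k + 1)
    if last <= i0:
        return BurstOnset(channel, np.nan, thr, False, base.mean, base.sd)
    counts = np.convolve(above.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
    window = counts[i0:last]
    need = int(np.ceil(cfg.sustain_fraction * k))
    hits = np.nonzero((window >= need) & above[i0:last])[0]
    if hits.size == 0:
        return BurstOnset(channel, np.nan, thr, False, base.mean, base.sd)
    onset = env.time_ms(i0 + int(hits[0]))
    return BurstOnset(channel, onset, thr, True, base.mean, base.sd)


def detect_trial_bursts(
    trial: TrialRecord, cfg: DetectorConfig | None = None
) -> dict[str, BurstOnset]:
    """SCM and ECR burst onsets for one trial.

    SCM is searched only on auditory trials, in [stimulus+20, stimulus+120]
    (upper bound inclusive).  ECR is searched from the initiating stimulus
    (auditory stimulus if present, otherwise the go-signal) to
    go + ``rt_upper_bound_ms``, so anticipations and slow responses remain
    visible to the error filters downstream.
    """
    cfg = cfg or DetectorConfig()
    if trial.signals is None:
        raise ValueError("trial carries no signals")
    for ch in ("scm", "ecr"):
        if ch not in trial.signals:
            raise ValueError(f"missing channel {ch!r}")
    out: dict[str, BurstOnset] = {}
    t0 = trial.record_window_ms[0]
    for ch in ("scm", "ecr"):
        env = compute_envelope(trial.signals[ch], trial.sample_rate, cfg)
        env.t0_ms = t0
        base = baseline_stats(env, cfg.baseline_window_ms, cfg.baseline_sd_ddof)
        if ch == "scm":
            if trial.auditory_time_ms is None:
                out["SCM"] = BurstOnset("SCM", np.nan, np.nan, False)
                continue
            lo, hi = cfg.scm_window_ms
            search = (trial.auditory_time_ms + lo, trial.auditory_time_ms + hi)
            out["SCM"] = detect_onset(
                env, base, search, cfg, channel="SCM", end_inclusive=True
            )
        else:
            start = (
                trial.auditory_time_ms
                if trial.auditory_time_ms is not None
                else trial.go_time_ms
            )
            search = (start, trial.go_time_ms + cfg.rt_upper_bound_ms)
            out["ECR"] = detect_onset(env, base, search, cfg, channel="ECR")
    return out


def brute_force_onset(
    env: np.ndarray,
    threshold: float,
    i0: int,
    i1: int,
    sustain_samples: int,
    sustain_fraction: float = 1.0,
) -> int | None:
    """Exhaustive reference scan for the sustain rule (test oracle).

    Checks every candidate index t in [i0, i1) whose sustain interval fits
    in the array; returns the first t with env[t] above threshold and at
    least ``ceil(fraction * k)`` of env[t:t+k] above threshold.
    """
    k = sustain_samples
    need = int(np.ceil(sustain_fraction * k))
    for t in range(i0, min(i1, env.size - k + 1)):
        if env[t] <= threshold:
            continue
        n_above = 0
        for v in env[t : t + k]:
            if v > threshold:
                n_above += 1
        if n_above >= need:
            return t
    return None
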