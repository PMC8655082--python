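"""Trial categorization: SCM+/-, triggered vs visual, error filters,
participant screening, confusion categories and summary tables.

Rules, all in trial-local time (go-signal at 0 ms):

* SCM+ iff a detected SCM burst onset lies within [stimulus+20,
  stimulus+120] ms of the auditory stimulus (upper bound inclusive).
* A response with ECR onset before the go-signal on an auditory trial is a
  candidate *triggered* response (RT measured from the auditory stimulus);
  onsets at or after the go-signal are *visual* responses (RT from the
  go-signal).
* Error filters (strict inequalities, boundary values kept): anticipation
  RT < 50 ms; slow auditory RT > 300 ms; slow visual RT > 400 ms; plus a
  pass-through movement-error flag.  On early (-1000 ms) trials, responses
  landing between stimulus+300 and the go-signal are slow-auditory errors.
* Confusion categories treat SCM presence as a predictor of triggering:
  TP = SCM+ triggered, FP = SCM+ not triggered, TN = SCM- not triggered,
  FN = SCM- triggered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal import BurstOnset
from .synth import Session, TrialRecord

ANTICIPATION_MS = 50.0
SLOW_AUDITORY_MS = 300.0
SLOW_VISUAL_MS = 400.0


@dataclass
class ClassifiedTrial:
    participant_id: str
    block_index: int
    trial_index: int
    stimulus_kind: str
    intensity_db: int | None
    offset_ms: int | None
    scm_status: str  # SCM+ | SCM- | not_applicable
    response_class: str  # triggered | visual | none
    premotor_rt_ms: float | None
    adjusted_rt_ms: float | None
    keep: bool
    error_reason: str  # none | anticipation | slow_auditory | slow_visual | movement_error
    confusion: str | None  # true_/false_ positive/negative, kept auditory only


@dataclass
class ProportionTable:
    """Per-subject cell proportions plus trial-pooled composites.

    ``per_subject`` has one row per participant x cell with numerator,
    denominator and proportion (cells with no trials are absent, never 0).
    ``pooled`` sums numerators and denominators across participants — the
    grand-mean composite used for descriptive figures.
    """

    outcome: str
    per_subject: pd.DataFrame
    pooled: pd.DataFrame


def label_scm(trial: TrialRecord, scm_onset: BurstOnset) -> str:
    """SCM+ iff a found onset lies in [stimulus+20, stimulus+120] ms."""
    if trial.auditory_time_ms is None:
        return "not_applicable"
    if not scm_onset.found or not math.isfinite(scm_onset.onset_ms):
        return "SCM-"
    lat = scm_onset.onset_ms - trial.auditory_time_ms
    return "SCM+" if 20.0 <= lat <= 120.0 else "SCM-"


def label_response(
    trial: TrialRecord, ecr_onset: BurstOnset
) -> tuple[str, float | None, float | None]:
    """(response_class, premotor_rt_ms, adjusted_rt_ms).

    The premotor and adjusted RT coincide under this scheme: both are
    measured from the initiating stimulus (auditory when the response
    precedes the go-signal, the go-signal otherwise).
    """
    if not ecr_onset.found or not math.isfinite(ecr_onset.onset_ms):
        return "none", None, None
    onset = ecr_onset.onset_ms
    go = trial.go_time_ms
    if trial.auditory_time_ms is not None and onset < go:
        rt = onset - trial.auditory_time_ms
        return "triggered", rt, rt
    rt = onset - go
    return "visual", rt, rt


def apply_filters(ct: ClassifiedTrial) -> ClassifiedTrial:
    """Set keep/error_reason.  Boundary RTs of exactly 50/300/400 ms are
    kept: the filters use strict inequalities."""
    reason = "none"
    if ct.error_reason == "movement_error" or ct.response_class == "none":
        reason = "movement_error"
    elif ct.adjusted_rt_ms is not None:
        rt = ct.adjusted_rt_ms
        if rt < ANTICIPATION_MS:
            reason = "anticipation"
        elif ct.response_class == "triggered" and rt > SLOW_AUDITORY_MS:
            reason = "slow_auditory"
        elif ct.response_class == "visual" and rt > SLOW_VISUAL_MS:
            reason = "slow_visual"
    ct.error_reason = reason
    ct.keep = reason == "none"
    ct.confusion = confusion(ct) if (ct.keep and ct.scm_status in ("SCM+", "SCM-")) else None
    return ct


def confusion(ct: ClassifiedTrial) -> str:
    """Confusion category of a kept auditory trial."""
    scm = ct.scm_status == "SCM+"
    trig = ct.response_class == "triggered"
    if scm and trig:
        return "true_positive"
    if scm and not trig:
        return "false_positive"
    if not scm and not trig:
        return "true_negative"
    return "false_negative"


def classify_trial(
    trial: TrialRecord, onsets: dict[str, BurstOnset]
) -> ClassifiedTrial:
    """Full per-trial categorization from detected burst onsets."""
    scm_status = label_scm(trial, onsets["SCM"])
    response_class, premotor, adjusted = label_response(trial, onsets["ECR"])
    ct = ClassifiedTrial(
        participant_id=trial.participant_id,
        block_index=trial.block_index,
        trial_index=trial.trial_index,
        stimulus_kind=trial.condition.stimulus_kind,
        intensity_db=trial.condition.intensity_db,
        offset_ms=trial.condition.presentation_offset_ms,
        scm_status=scm_status,
        response_class=response_class,
        premotor_rt_ms=premotor,
        adjusted_rt_ms=adjusted,
        keep=True,
        error_reason="movement_error" if trial.movement_error else "none",
        confusion=None,
    )
    return apply_filters(ct)


def classify_table(manifest: pd.DataFrame, onsets: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification from saved manifest + onsets tables.

    Recomputing from CSV artifacts reproduces exactly the labels produced
    trial-by-trial (pipeline idempotence).  Expected manifest columns:
    participant, block, trial, stimulus_kind, intensity_db, offset_ms,
    auditory_time_ms, movement_error.  Onsets columns: participant, trial,
    channel, onset_ms, found.
    """
    wide = onsets.pivot_table(
        index=["participant", "trial"],
        columns="channel",
        values=["onset_ms", "found"],
        aggfunc="first",
    )
    rows = []
    for _, m in manifest.iterrows():
        key = (m["participant"], m["trial"])
        cond_kind = m["stimulus_kind"]
        aud = m.get("auditory_time_ms")
        aud = None if pd.isna(aud) else float(aud)
        intensity = None if pd.isna(m.get("intensity_db")) else int(m["intensity_db"])
        offset = None if pd.isna(m.get("offset_ms")) else int(m["offset_ms"])
        trial = TrialRecord(
            participant_id=m["participant"],
            block_index=int(m["block"]),
            trial_index=int(m["trial"]),
            condition=_condition_from_fields(cond_kind, intensity, offset),
            auditory_time_ms=aud,
            movement_error=bool(m.get("movement_error", False)),
        )
        ons = {}
        for ch in ("SCM", "ECR"):
            try:
                found = bool(wide.loc[key, ("found", ch)])
                onset = float(wide.loc[key, ("onset_ms", ch)])
            except KeyError:
                found, onset = False, np.nan
            ons[ch] = BurstOnset(ch, onset, np.nan, found)
        rows.append(classify_trial(trial, ons))
    return pd.DataFrame([vars(ct) for ct in rows])


def _condition_from_fields(kind, intensity, offset):
    from .synth import ConditionSpec

    if kind == "auditory":
        return ConditionSpec("auditory", intensity, offset)
    return ConditionSpec("visual_only")


def classify_session(session: Session, detector_cfg=None) -> pd.DataFrame:
    """Detect bursts and classify every trial of a session."""
    from .signal import detect_trial_bursts

    rows = [
        vars(classify_trial(t, detect_trial_bursts(t, detector_cfg)))
        for t in session.trials
    ]
    return pd.DataFrame(rows)


def classify_cohort(sessions: list[Session], detector_cfg=None) -> pd.DataFrame:
    return pd.concat(
        [classify_session(s, detector_cfg) for s in sessions], ignore_index=True
    )


# ---------------------------------------------------------------------------
# cohort-level summaries


def screen_participants(
    classified: pd.DataFrame,
    threshold: float = 0.5,
    strict: bool = False,
    criterion_intensity: int | None = None,
    criterion_offset: int | None = None,
) -> pd.DataFrame:
    """Participant screen on the loudest, latest stimulus condition.

    A participant is included iff their SCM+ proportion on the criterion
    condition (default: maximum intensity at the offset closest to the
    go-signal) reaches ``threshold`` (>= by default; > when ``strict``).
    """
    aud = classified[classified["stimulus_kind"] == "auditory"]
    if aud.empty:
        raise ValueError("no auditory trials to screen on")
    intensity = criterion_intensity or int(aud["intensity_db"].max())
    sub = aud[aud["intensity_db"] == intensity]
    offset = criterion_offset if criterion_offset is not None else int(sub["offset_ms"].max())
    sub = sub[sub["offset_ms"] == offset]
    out = []
    for pid in classified["participant_id"].unique():
        cell = sub[sub["participant_id"] == pid]
        if cell.empty:
            raise ValueError(f"participant {pid} has no trials in the screen condition")
        n = len(cell)
        n_plus = int((cell["scm_status"] == "SCM+").sum())
        prop = n_plus / n
        included = prop > threshold if strict else prop >= threshold
        out.append(
            dict(
                participant_id=pid,
                criterion_intensity_db=intensity,
                criterion_offset_ms=offset,
                n_trials=n,
                n_scm_plus=n_plus,
                proportion=prop,
                included=included,
            )
        )
    return pd.DataFrame(out)


def confusion_summary(classified: pd.DataFrame) -> pd.DataFrame:
    """Percentage of kept auditory trials in each confusion category, per
    condition cell and overall; accuracy = (TP + TN) / kept."""
    kept = classified[classified["keep"] & classified["confusion"].notna()]
    cats = ["true_positive", "false_positive", "true_negative", "false_negative"]
    rows = []
    groups = [("all", kept)] + [
        (f"{int(i)}dB@{int(o)}ms", g)
        for (i, o), g in kept.groupby(["intensity_db", "offset_ms"], dropna=False)
    ]
    for key, g in groups:
        n = len(g)
        counts = g["confusion"].value_counts()
        row = {"cell": key, "n": n}
        for c in cats:
            row[c + "_pct"] = 100.0 * counts.get(c, 0) / n if n else np.nan
        row["accuracy_pct"] = (
            100.0 * (counts.get("true_positive", 0) + counts.get("true_negative", 0)) / n
            if n
            else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


_OUTCOMES = {
    "scm_plus": ("scm_status", "SCM+"),
    "triggered": ("response_class", "triggered"),
}


def summarize_proportions(
    classified: pd.DataFrame,
    outcome: str = "scm_plus",
    grouping: tuple[str, ...] = ("intensity_db", "offset_ms"),
) -> ProportionTable:
    """Per-subject condition-cell proportions plus trial-pooled composites.

    ``triggered_given_scm_status`` additionally conditions the denominator
    on SCM status (the composite conditional-proportion figures).  Empty
    cells are absent from the tables rather than reported as 0.
    """
    grouping = list(grouping)
    if outcome == "triggered_given_scm_status":
        col, val = _OUTCOMES["triggered"]
        grouping = grouping + ["scm_status"]
    elif outcome in _OUTCOMES:
        col, val = _OUTCOMES[outcome]
    else:
        raise ValueError(f"unknown outcome {outcome!r}")
    kept = classified[
        classified["keep"] & (classified["stimulus_kind"] == "auditory")
    ].copy()
    kept["_hit"] = (kept[col] == val).astype(int)
    per = (
        kept.groupby(["participant_id"] + grouping, dropna=False)["_hit"]
        .agg(numerator="sum", denominator="count")
        .reset_index()
    )
    per["proportion"] = per["numerator"] / per["denominator"]
    pooled = (
        per.groupby(grouping, dropna=False)[["numerator", "denominator"]]
        .sum()
        .reset_index()
    )
    pooled["proportion"] = pooled["numerator"] / pooled["denominator"]
    return ProportionTable(outcome, per, pooled)


def rt_histogram(
    classified: pd.DataFrame, bin_width_ms: float = 10.0, split_by: str | None = None
) -> pd.DataFrame:
    """RT counts in half-open [k*w, (k+1)*w) bins for kept trials.

    ``split_by`` may be 'triggered' (response class), 'scm' (SCM status) or
    'confusion'.
    """
    kept = classified[classified["keep"] & classified["adjusted_rt_ms"].notna()].copy()
    col = {
        None: None,
        "triggered": "response_class",
        "scm": "scm_status",
        "confusion": "confusion",
    }[split_by]
    kept["bin_left_ms"] = (
        np.floor(kept["adjusted_rt_ms"] / bin_width_ms) * bin_width_ms
    )
    keys = ["bin_left_ms"] if col is None else [col, "bin_left_ms"]
    out = kept.groupby(keys, dropna=False).size().reset_index(name="count")
    return out
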