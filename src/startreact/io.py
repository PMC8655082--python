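"""Session file formats: cohort manifest, per-trial long-format signal
tables, ground-truth table and a plain-text generator config.

A cohort directory holds::

    manifest.csv        one row per trial (identity, condition, event times)
    ground_truth.csv    generator labels, for scoring only
    config.yaml         generator configuration + master seed
    signals/P00_t000.csv ...   time_ms, ecr, fcr, scm, position

All numeric round-trips are at full precision (shortest-repr floats).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import (
    ConditionSpec,
    GeneratorConfig,
    GroundTruth,
    RTDist,
    Session,
    TrialRecord,
)

MANIFEST_COLUMNS = [
    "participant",
    "block",
    "trial",
    "stimulus_kind",
    "intensity_db",
    "offset_ms",
    "go_time_ms",
    "auditory_time_ms",
    "foreperiod_ms",
    "movement_error",
    "sample_rate",
    "record_start_ms",
    "record_end_ms",
    "preset",
    "master_seed",
]

SIGNAL_COLUMNS = ["time_ms", "ecr", "fcr", "scm", "position"]


class SchemaError(ValueError):
    pass


def _signal_name(pid: str, trial: int) -> str:
    return f"{pid}_t{trial:03d}.csv"


def manifest_frame(sessions: list[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t in s.trials:
            rows.append(
                dict(
                    participant=t.participant_id,
                    block=t.block_index,
                    trial=t.trial_index,
                    stimulus_kind=t.condition.stimulus_kind,
                    intensity_db=t.condition.intensity_db,
                    offset_ms=t.condition.presentation_offset_ms,
                    go_time_ms=t.go_time_ms,
                    auditory_time_ms=t.auditory_time_ms,
                    foreperiod_ms=t.foreperiod_ms,
                    movement_error=t.movement_error,
                    sample_rate=t.sample_rate,
                    record_start_ms=t.record_window_ms[0],
                    record_end_ms=t.record_window_ms[1],
                    preset=s.preset,
                    master_seed=s.master_seed,
                )
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def ground_truth_frame(sessions: list[Session]) -> pd.DataFrame:
    rows = []
    for s in sessions:
        for t, gt in zip(s.trials, s.truths):
            rows.append(
                dict(
                    participant=t.participant_id,
                    trial=t.trial_index,
                    scm_burst_injected=gt.scm_burst_injected,
                    scm_true_onset_ms=gt.scm_true_onset_ms,
                    response_triggered=gt.response_triggered,
                    ecr_true_onset_ms=gt.ecr_true_onset_ms,
                    error_injected=gt.error_injected,
                )
            )
    return pd.DataFrame(rows)


def config_to_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    for key in ("p_scm", "p_trigger_given_scm_plus", "p_trigger_given_scm_minus"):
        v = d[key]
        if isinstance(v, dict):
            d[key] = {
                ",".join(str(x) for x in k) if isinstance(k, tuple) else str(k): float(p)
                for k, p in v.items()
            }
    for key in (
        "rt_dist_triggered_scm_plus",
        "rt_dist_triggered_scm_minus",
        "rt_dist_visual",
    ):
        d[key] = dict(d[key])
    for key in ("record_window_ms", "foreperiod_range_ms", "scm_latency_window_ms",
                "emg_band_hz"):
        d[key] = list(d[key])
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)

    def parse_key(k: str):
        parts = str(k).split(",")
        return tuple(int(p) for p in parts) if len(parts) > 1 else int(parts[0])

    for key in ("p_scm", "p_trigger_given_scm_plus", "p_trigger_given_scm_minus"):
        if isinstance(d.get(key), dict):
            d[key] = {parse_key(k): float(v) for k, v in d[key].items()}
    for key in (
        "rt_dist_triggered_scm_plus",
        "rt_dist_triggered_scm_minus",
        "rt_dist_visual",
    ):
        if isinstance(d.get(key), dict):
            d[key] = RTDist(**d[key])
    for key in ("record_window_ms", "foreperiod_range_ms", "scm_latency_window_ms",
                "emg_band_hz"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def write_cohort(
    sessions: list[Session],
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    write_signals: bool = True,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_frame(sessions).to_csv(out / "manifest.csv", index=False)
    ground_truth_frame(sessions).to_csv(out / "ground_truth.csv", index=False)
    if config is not None:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    if write_signals:
        sig_dir = out / "signals"
        sig_dir.mkdir(exist_ok=True)
        for s in sessions:
            for t in s.trials:
                if t.signals is None:
                    continue
                n = next(iter(t.signals.values())).size
                time_ms = t.record_window_ms[0] + np.arange(n) * 1000.0 / t.sample_rate
                df = pd.DataFrame({"time_ms": time_ms, **{c: t.signals[c]
                                   for c in ("ecr", "fcr", "scm", "position")}})
                df.to_csv(sig_dir / _signal_name(t.participant_id, t.trial_index),
                          index=False)
    return out


def _validate_manifest(manifest: pd.DataFrame) -> None:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise SchemaError(f"manifest missing columns: {missing}")
    aud = manifest[manifest["stimulus_kind"] == "auditory"]
    bad = aud[aud["auditory_time_ms"].isna() | aud["intensity_db"].isna()]
    if not bad.empty:
        row = bad.iloc[0]
        raise SchemaError(
            "auditory trial missing auditory_time_ms/intensity_db: "
            f"participant {row['participant']} trial {int(row['trial'])}"
        )


def read_cohort(in_dir: str | Path, load_signals: bool = True) -> list[Session]:
    """Read a cohort directory back into Session objects.

    Validates the manifest schema and, when loading signals, checks each
    trial's sample count against the record window in the manifest.
    """
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv", float_precision="round_trip")
    _validate_manifest(manifest)
    gt_path = src / "ground_truth.csv"
    gts = (
        pd.read_csv(gt_path, float_precision="round_trip")
        if gt_path.exists()
        else None
    )
    sessions = []
    for pid, grp in manifest.groupby("participant", sort=True):
        trials, truths = [], []
        grp = grp.sort_values("trial")
        for _, m in grp.iterrows():
            aud = None if pd.isna(m["auditory_time_ms"]) else float(m["auditory_time_ms"])
            cond = (
                ConditionSpec(
                    "auditory", int(m["intensity_db"]), int(m["offset_ms"])
                )
                if m["stimulus_kind"] == "auditory"
                else ConditionSpec("visual_only")
            )
            window = (float(m["record_start_ms"]), float(m["record_end_ms"]))
            signals = None
            if load_signals:
                path = src / "signals" / _signal_name(str(pid), int(m["trial"]))
                if path.exists():
                    sig = pd.read_csv(path, float_precision="round_trip")
                    missing = [c for c in SIGNAL_COLUMNS if c not in sig.columns]
                    if missing:
                        raise SchemaError(f"{path.name}: missing columns {missing}")
                    expected = int(
                        round((window[1] - window[0]) * m["sample_rate"] / 1000.0)
                    )
                    if len(sig) != expected:
                        raise SchemaError(
                            f"{path.name}: {len(sig)} samples, expected {expected}"
                        )
                    signals = {c: sig[c].to_numpy() for c in SIGNAL_COLUMNS[1:]}
            trials.append(
                TrialRecord(
                    participant_id=str(pid),
                    block_index=int(m["block"]),
                    trial_index=int(m["trial"]),
                    condition=cond,
                    go_time_ms=float(m["go_time_ms"]),
                    auditory_time_ms=aud,
                    foreperiod_ms=float(m["foreperiod_ms"]),
                    movement_error=bool(m["movement_error"]),
                    sample_rate=float(m["sample_rate"]),
                    record_window_ms=window,
                    signals=signals,
                )
            )
            if gts is not None:
                g = gts[(gts["participant"] == pid) & (gts["trial"] == m["trial"])]
                if len(g) == 1:
                    g = g.iloc[0]
                    truths.append(
                        GroundTruth(
                            scm_burst_injected=bool(g["scm_burst_injected"]),
                            scm_true_onset_ms=(
                                None if pd.isna(g["scm_true_onset_ms"])
                                else float(g["scm_true_onset_ms"])
                            ),
                            response_triggered=bool(g["response_triggered"]),
                            ecr_true_onset_ms=(
                                None if pd.isna(g["ecr_true_onset_ms"])
                                else float(g["ecr_true_onset_ms"])
                            ),
                            error_injected=str(g["error_injected"]),
                        )
                    )
        preset = str(grp["preset"].iloc[0])
        seed = int(grp["master_seed"].iloc[0])
        sessions.append(Session(str(pid), preset, trials, truths, seed))
    return sessions
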