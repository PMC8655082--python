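"""End-to-end orchestration: simulate -> detect -> classify -> summarize ->
fit -> report, with every stage emitting a CSV artifact and a JSON manifest
recording the seed and per-table content hashes for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import glmm as _glmm
from . import io as _io
from . import stats as _stats
from .signal import DetectorConfig, detect_trial_bursts
from .synth import GeneratorConfig, Session, generate_cohort, preset_config

log = logging.getLogger("startreact")


@dataclass
class PipelineConfig:
    preset: str = "exp1"
    n_participants: int = 11
    n_blocks: int = 4
    seed: int = 0
    out_dir: str | Path | None = None
    write_signals: bool = False
    generator: GeneratorConfig | None = None
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    # models to fit: subset of anova_scm, anova_trigger, ttest_scm,
    # ttest_trigger, lmm, glmm
    models: tuple[str, ...] = ("anova_scm", "anova_trigger", "lmm", "glmm")
    glmm_nodes: int = 10
    screen_threshold: float = 0.5

    def resolved_generator(self) -> GeneratorConfig:
        return self.generator or preset_config(self.preset)


@dataclass
class ReportBundle:
    """Machine-readable stand-ins for the study's figures and tables."""

    tables: dict[str, pd.DataFrame]
    seed: int
    preset: str

    def hashes(self) -> dict[str, str]:
        return {
            name: hashlib.sha256(
                df.to_csv(index=False).encode()
            ).hexdigest()
            for name, df in self.tables.items()
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "seed": self.seed,
            "preset": self.preset,
            "tables": self.hashes(),
        }
        (out / "report_manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def detect_cohort(sessions: list[Session], detector: DetectorConfig) -> pd.DataFrame:
    """Run burst detection on every trial; one row per trial x channel."""
    rows = []
    for s in sessions:
        for t in s.trials:
            for ch, onset in detect_trial_bursts(t, detector).items():
                rows.append(
                    dict(
                        participant=t.participant_id,
                        block=t.block_index,
                        trial=t.trial_index,
                        channel=ch,
                        onset_ms=onset.onset_ms,
                        threshold=onset.threshold,
                        baseline_mean=onset.baseline_mean,
                        baseline_sd=onset.baseline_sd,
                        found=onset.found,
                    )
                )
    return pd.DataFrame(rows)


def _anova_stage(classified: pd.DataFrame, outcome: str) -> dict[str, pd.DataFrame]:
    """Arcsine-root-transformed per-subject proportions into a 2x4
    repeated-measures ANOVA (presentation time x intensity)."""
    table = _classify.summarize_proportions(classified, outcome)
    per = table.per_subject.copy()
    per["transformed"] = _stats.arcsine_sqrt(per["proportion"].to_numpy())
    res = _stats.rm_anova2(
        per,
        dv="transformed",
        within=("offset_ms", "intensity_db"),
        subject="participant_id",
    )
    posthoc = _stats.posthoc_pairwise(
        per,
        "intensity_db",
        dv="transformed",
        within=("offset_ms", "intensity_db"),
        subject="participant_id",
    )
    return {
        f"anova_{outcome}": res.table,
        f"anova_{outcome}_posthoc_intensity": posthoc,
    }


def _ttest_stage(classified: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Paired t (arcsine-transformed proportions) between the two
    intensities of the two-intensity design, with Cohen's d."""
    table = _classify.summarize_proportions(classified, outcome)
    per = table.per_subject
    piv = per.pivot_table(
        index="participant_id", columns="intensity_db", values="proportion"
    ).dropna()
    hi, lo = max(piv.columns), min(piv.columns)
    res = _stats.paired_t(
        _stats.arcsine_sqrt(piv[hi].to_numpy()),
        _stats.arcsine_sqrt(piv[lo].to_numpy()),
    )
    return pd.DataFrame(
        [
            dict(
                outcome=outcome,
                intensity_high=hi,
                intensity_low=lo,
                mean_high=piv[hi].mean(),
                mean_low=piv[lo].mean(),
                t=res.t,
                df=res.df,
                p=res.p,
                cohen_d=res.cohen_d,
            )
        ]
    )


def _lmm_stage(classified: pd.DataFrame, preset: str) -> dict[str, pd.DataFrame]:
    trig = classified[
        classified["keep"] & (classified["response_class"] == "triggered")
    ].copy()
    if preset == "exp1":
        trig["presentation_time"] = np.where(
            trig["offset_ms"] == -1000, "early", "late"
        )
        formula = (
            "adjusted_rt_ms ~ C(scm_status) * C(intensity_db) * C(presentation_time)"
        )
    else:
        formula = "adjusted_rt_ms ~ C(scm_status) * C(intensity_db)"
    fit = _stats.fit_lmm(trig, formula=formula)
    coeffs = pd.DataFrame(
        {"term": fit.params.index, "estimate": fit.params.values, "se": fit.bse.values}
    )
    emm = fit.emmeans("scm_status")
    meta = pd.DataFrame(
        [
            dict(
                formula=fit.formula,
                llf=fit.llf,
                aic=fit.aic,
                converged=fit.converged,
                slope_dropped=fit.slope_dropped,
                **fit.vc,
            )
        ]
    )
    return {
        "lmm_rt_coefficients": coeffs,
        "lmm_rt_wald": fit.wald,
        "lmm_rt_emm_scm": emm,
        "lmm_rt_meta": meta,
    }


def _glmm_stage(
    classified: pd.DataFrame, preset: str, nodes: int
) -> dict[str, pd.DataFrame]:
    data = _glmm.triggering_data(classified)
    ladder = _glmm.candidate_ladder(
        include_time=(preset == "exp1"), include_intensity=True
    )
    fits = []
    for spec in ladder:
        fits.append(_glmm.fit_glmm(data, spec, quadrature_nodes=nodes,
                                   compute_se=(spec.name == "full")))
    ranking = _glmm.rank_models(fits)
    full = next(f for f in fits if f.spec.name == "full")
    coeffs = pd.DataFrame(
        {
            "term": full.params.index,
            "estimate": full.params.values,
            "se": full.se.values,
            "z": full.z.values,
            "p": full.pvalues.values,
            "odds_ratio": _glmm.odds_ratio(full.params.values),
        }
    )
    return {"glmm_model_comparison": ranking, "glmm_full_coefficients": coeffs}


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Full deterministic pipeline run; returns (and optionally writes)
    the report bundle."""
    gen = config.resolved_generator()
    log.info("simulate: preset=%s participants=%d blocks=%d seed=%d",
             config.preset, config.n_participants, config.n_blocks, config.seed)
    sessions = generate_cohort(
        gen, config.preset, config.n_participants, config.seed,
        n_blocks=config.n_blocks,
    )
    tables: dict[str, pd.DataFrame] = {}
    tables["manifest"] = _io.manifest_frame(sessions)
    tables["ground_truth"] = _io.ground_truth_frame(sessions)

    onsets = detect_cohort(sessions, config.detector)
    tables["onsets"] = onsets
    log.info("detect: %d onsets (%d found)", len(onsets), int(onsets["found"].sum()))

    classified = _classify.classify_cohort(sessions, config.detector)
    tables["classified"] = classified
    n_kept = int(classified["keep"].sum())
    log.info("classify: %d trials, %d kept (%.1f%%)",
             len(classified), n_kept, 100.0 * n_kept / len(classified))

    screen = _classify.screen_participants(classified, config.screen_threshold)
    tables["participant_screen"] = screen
    included = set(screen[screen["included"]]["participant_id"])
    log.info("screen: %d/%d participants included", len(included), len(screen))
    kept = classified[classified["participant_id"].isin(included)]

    for outcome in ("scm_plus", "triggered"):
        tab = _classify.summarize_proportions(kept, outcome)
        tables[f"proportions_{outcome}_subject"] = tab.per_subject
        tables[f"proportions_{outcome}_pooled"] = tab.pooled
    cond = _classify.summarize_proportions(kept, "triggered_given_scm_status")
    tables["proportions_conditional_pooled"] = cond.pooled
    tables["confusion"] = _classify.confusion_summary(kept)
    for split in ("triggered", "scm", "confusion"):
        tables[f"rt_histogram_{split}"] = _classify.rt_histogram(kept, split_by=split)

    for model in config.models:
        if model == "anova_scm":
            tables.update(_anova_stage(kept, "scm_plus"))
        elif model == "anova_trigger":
            tables.update(_anova_stage(kept, "triggered"))
        elif model == "ttest_scm":
            tables["ttest_scm"] = _ttest_stage(kept, "scm_plus")
        elif model == "ttest_trigger":
            tables["ttest_trigger"] = _ttest_stage(kept, "triggered")
        elif model == "lmm":
            tables.update(_lmm_stage(kept, config.preset))
        elif model == "glmm":
            tables.update(_glmm_stage(kept, config.preset, config.glmm_nodes))
        else:
            raise ValueError(f"unknown model stage {model!r}")

    bundle = ReportBundle(tables, config.seed, config.preset)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        _io.write_cohort(sessions, out / "cohort", gen, config.write_signals)
        bundle.write(out)
    return bundle
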