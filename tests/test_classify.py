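"""Trial categorization rules, filters, screening and summaries."""

import numpy as np
import pandas as pd
import pytest

import startreact as sr
from startreact.classify import ClassifiedTrial
from startreact.signal import BurstOnset
from startreact.synth import ConditionSpec, TrialRecord


def make_trial(kind="auditory", intensity=120, offset=-300, movement=False):
    cond = (
        ConditionSpec("auditory", intensity, offset)
        if kind == "auditory"
        else ConditionSpec("visual_only")
    )
    return TrialRecord(
        participant_id="P00",
        block_index=0,
        trial_index=0,
        condition=cond,
        auditory_time_ms=float(offset) if kind == "auditory" else None,
        movement_error=movement,
    )


def onset(ms, found=True, channel="SCM"):
    return BurstOnset(channel, ms if found else np.nan, 1.0, found)


class TestLabelScm:
    @pytest.mark.parametrize(
        "latency,expect",
        [(80, "SCM+"), (20, "SCM+"), (120, "SCM+"), (130, "SCM-"), (19, "SCM-")],
    )
    def test_window_rule(self, latency, expect):
        t = make_trial(offset=-300)
        assert sr.label_scm(t, onset(-300 + latency)) == expect

    def test_no_onset_is_scm_minus(self):
        assert sr.label_scm(make_trial(), onset(0, found=False)) == "SCM-"

    def test_visual_trial_not_applicable(self):
        assert sr.label_scm(make_trial("visual_only"), onset(50)) == "not_applicable"


class TestLabelResponse:
    def test_before_go_is_triggered_from_auditory(self):
        cls, rt, adj = sr.label_response(make_trial(offset=-300), onset(-150, channel="ECR"))
        assert cls == "triggered" and rt == 150 and adj == 150

    def test_after_go_is_visual_from_go(self):
        cls, rt, adj = sr.label_response(make_trial(offset=-1000), onset(180, channel="ECR"))
        assert cls == "visual" and rt == 180

    def test_slow_candidate_trigger_kept_for_filtering(self):
        cls, rt, _ = sr.label_response(make_trial(offset=-1000), onset(-500, channel="ECR"))
        assert cls == "triggered" and rt == 500

    def test_no_onset(self):
        cls, rt, adj = sr.label_response(make_trial(), onset(0, found=False))
        assert cls == "none" and rt is None and adj is None


def classified(response_class, rt, scm="SCM+", movement=False):
    ct = ClassifiedTrial(
        participant_id="P00",
        block_index=0,
        trial_index=0,
        stimulus_kind="auditory",
        intensity_db=120,
        offset_ms=-300,
        scm_status=scm,
        response_class=response_class,
        premotor_rt_ms=rt,
        adjusted_rt_ms=rt,
        keep=True,
        error_reason="movement_error" if movement else "none",
        confusion=None,
    )
    return sr.apply_filters(ct)


class TestFilters:
    @pytest.mark.parametrize(
        "cls,rt,keep,reason",
        [
            ("visual", 400.0, True, "none"),  # boundary kept: rule is > 400
            ("visual", 400.25, False, "slow_visual"),
            ("triggered", 300.0, True, "none"),  # boundary kept: rule is > 300
            ("triggered", 300.25, False, "slow_auditory"),
            ("triggered", 49.0, False, "anticipation"),
            ("visual", 49.0, False, "anticipation"),
            ("triggered", 50.0, True, "none"),  # boundary kept: rule is < 50
            ("triggered", 150.0, True, "none"),
        ],
    )
    def test_rt_filters(self, cls, rt, keep, reason):
        ct = classified(cls, rt)
        assert ct.keep is keep and ct.error_reason == reason

    def test_movement_flag_passthrough(self):
        ct = classified("triggered", 150.0, movement=True)
        assert not ct.keep and ct.error_reason == "movement_error"

    def test_dead_zone_early_trial(self):
        """On early trials a response between stimulus+300 and the go-signal
        is a slow-auditory error."""
        t = make_trial(offset=-1000)
        ons = {"SCM": onset(-920), "ECR": onset(-500, channel="ECR")}
        ct = sr.classify_trial(t, ons)
        assert ct.response_class == "triggered"
        assert not ct.keep and ct.error_reason == "slow_auditory"


class TestConfusion:
    @pytest.mark.parametrize(
        "scm,cls,cat",
        [
            ("SCM+", "triggered", "true_positive"),
            ("SCM+", "visual", "false_positive"),
            ("SCM-", "visual", "true_negative"),
            ("SCM-", "triggered", "false_negative"),
        ],
    )
    def test_categories(self, scm, cls, cat):
        assert classified(cls, 150.0, scm=scm).confusion == cat

    def test_all_positive_cohort_perfect_accuracy(self):
        df = pd.DataFrame(
            [vars(classified("triggered", 150.0, scm="SCM+")) for _ in range(10)]
        )
        summary = sr.confusion_summary(df)
        assert summary.iloc[0]["accuracy_pct"] == 100.0


class TestPartition:
    def test_every_auditory_trial_exactly_one_category(self, exp1_classified):
        df, _ = exp1_classified
        aud = df[df["stimulus_kind"] == "auditory"]
        kept = aud[aud["keep"]]
        assert kept["confusion"].notna().all()
        discarded = aud[~aud["keep"]]
        assert (discarded["error_reason"] != "none").all()
        assert len(kept) + len(discarded) == len(aud)


class TestScreening:
    def make_df(self, props):
        rows = []
        for pid, p in props.items():
            n = 8
            for i in range(n):
                rows.append(
                    dict(
                        participant_id=pid,
                        stimulus_kind="auditory",
                        intensity_db=120,
                        offset_ms=-300,
                        scm_status="SCM+" if i < round(p * n) else "SCM-",
                        keep=True,
                    )
                )
        return pd.DataFrame(rows)

    def test_threshold_rule(self):
        df = self.make_df({"A": 5 / 8, "B": 3 / 8, "C": 4 / 8})
        res = sr.screen_participants(df).set_index("participant_id")
        assert res.loc["A", "included"]
        assert not res.loc["B", "included"]
        assert res.loc["C", "included"]  # >= 0.5 by default
        strict = sr.screen_participants(df, strict=True).set_index("participant_id")
        assert not strict.loc["C", "included"]

    def test_missing_criterion_trials_raises(self):
        df = self.make_df({"A": 0.75})
        df2 = pd.concat(
            [df, pd.DataFrame([dict(participant_id="B", stimulus_kind="visual_only",
                                    intensity_db=np.nan, offset_ms=np.nan,
                                    scm_status="not_applicable", keep=True)])],
            ignore_index=True,
        )
        with pytest.raises(ValueError):
            sr.screen_participants(df2)

    def test_planted_low_susceptibility_subjects_excluded(self):
        """Participants generated with near-zero startle probability fail
        the SCM+ screen; high-probability participants pass."""
        rows = []
        cfg = sr.exp1_config(heterogeneity_logit_sd=0.0, error_rates={})
        for pid, p in (("LOW", 0.02), ("HIGH", 0.98)):
            sess = sr.generate_cohort(
                sr.exp1_config(p_scm=p, heterogeneity_logit_sd=0.0, error_rates={}),
                "exp1", 1, seed=17, n_blocks=2, signals=False,
            )[0]
            from startreact import io as srio
            gt = srio.ground_truth_frame([sess])
            man = srio.manifest_frame([sess])
            df = pd.concat([man, gt[["scm_burst_injected"]]], axis=1)
            df = df[df["stimulus_kind"] == "auditory"]
            for _, r in df.iterrows():
                rows.append(
                    dict(
                        participant_id=pid,
                        stimulus_kind="auditory",
                        intensity_db=r["intensity_db"],
                        offset_ms=r["offset_ms"],
                        scm_status="SCM+" if r["scm_burst_injected"] else "SCM-",
                        keep=True,
                    )
                )
        res = sr.screen_participants(pd.DataFrame(rows)).set_index("participant_id")
        assert not res.loc["LOW", "included"]
        assert res.loc["HIGH", "included"]


class TestProportions:
    def test_single_cell_value(self):
        rows = [
            dict(participant_id="A", stimulus_kind="auditory", intensity_db=120,
                 offset_ms=-300, scm_status="SCM+" if i < 6 else "SCM-",
                 response_class="triggered", keep=True)
            for i in range(8)
        ]
        tab = sr.summarize_proportions(pd.DataFrame(rows), "scm_plus")
        assert tab.per_subject["proportion"].iloc[0] == pytest.approx(0.75)

    def test_pooled_is_sum_over_sum_not_mean_of_means(self):
        """Grand-mean composites pool trials: an unbalanced two-subject case
        separates sum/sum from the mean of subject proportions."""
        rows = []
        # subject A: 1/2 triggered; subject B: 9/10 triggered
        for pid, n, k in (("A", 2, 1), ("B", 10, 9)):
            for i in range(n):
                rows.append(
                    dict(participant_id=pid, stimulus_kind="auditory",
                         intensity_db=120, offset_ms=-300, scm_status="SCM+",
                         response_class="triggered" if i < k else "visual",
                         keep=True)
                )
        tab = sr.summarize_proportions(pd.DataFrame(rows), "triggered")
        pooled = tab.pooled["proportion"].iloc[0]
        assert pooled == pytest.approx(10 / 12)  # not (0.5 + 0.9) / 2 = 0.7
        subj_mean = tab.per_subject["proportion"].mean()
        assert subj_mean == pytest.approx(0.7)

    def test_forced_certainty_gives_unit_proportions(self):
        cfg = sr.exp1_config(p_scm=1.0, heterogeneity_logit_sd=0.0, error_rates={})
        sessions = sr.generate_cohort(cfg, "exp1", 2, seed=3, n_blocks=1, signals=False)
        from startreact import io as srio
        gt = srio.ground_truth_frame(sessions)
        man = srio.manifest_frame(sessions)
        df = pd.concat([man, gt[["scm_burst_injected"]]], axis=1)
        df = df[df["stimulus_kind"] == "auditory"].rename(
            columns={"participant": "participant_id"}
        )
        df["scm_status"] = np.where(df["scm_burst_injected"], "SCM+", "SCM-")
        df["keep"] = True
        tab = sr.summarize_proportions(df, "scm_plus")
        assert (tab.per_subject["proportion"] == 1.0).all()

    def test_unknown_outcome_rejected(self, exp1_classified):
        df, _ = exp1_classified
        with pytest.raises(ValueError):
            sr.summarize_proportions(df, "nonexistent")

    def test_conditional_ordering_matches_generator(self, exp1_classified):
        """p(trigger | SCM+) > p(trigger | SCM-) in the generator, and the
        estimated conditional proportions preserve the ordering."""
        df, _ = exp1_classified
        tab = sr.summarize_proportions(df, "triggered_given_scm_status",
                                       grouping=()).pooled
        plus = tab[tab["scm_status"] == "SCM+"]["proportion"].iloc[0]
        minus = tab[tab["scm_status"] == "SCM-"]["proportion"].iloc[0]
        assert plus > minus


class TestRtHistogram:
    def test_half_open_bins(self):
        rows = [
            dict(participant_id="A", stimulus_kind="auditory", intensity_db=120,
                 offset_ms=-300, scm_status="SCM+", response_class="triggered",
                 adjusted_rt_ms=rt, keep=True, confusion="true_positive")
            for rt in (105.0, 110.0)
        ]
        h = sr.rt_histogram(pd.DataFrame(rows)).set_index("bin_left_ms")["count"]
        assert h[100.0] == 1 and h[110.0] == 1

    def test_mass_conserved(self, exp1_classified):
        df, _ = exp1_classified
        kept = df[df["keep"] & df["adjusted_rt_ms"].notna()]
        for split in (None, "triggered", "scm", "confusion"):
            h = sr.rt_histogram(df, split_by=split)
            assert h["count"].sum() == len(kept)


class TestIdempotence:
    def test_recomputing_from_tables_reproduces_labels(self, exp1_cohort):
        """Classifying from saved manifest + onsets CSV round-trip equals
        the in-memory classification."""
        cfg, sessions = exp1_cohort
        from startreact import io as srio
        direct = sr.classify_cohort(sessions)
        manifest = srio.manifest_frame(sessions)
        onsets = sr.detect_cohort(sessions, sr.DetectorConfig())
        redone = sr.classify_table(manifest, onsets)
        cols = ["participant_id", "trial_index", "scm_status", "response_class",
                "keep", "error_reason", "confusion"]
        pd.testing.assert_frame_equal(
            direct[cols].reset_index(drop=True), redone[cols].reset_index(drop=True)
        )


class TestGroundTruthRecovery:
    def test_labels_match_generator_on_kept_trials(self, exp1_classified):
        _, merged = exp1_classified
        kept = merged[merged["keep"] & (merged["stimulus_kind"] == "auditory")]
        scm_acc = (kept["scm_status"].eq("SCM+") == kept["scm_burst_injected"]).mean()
        trig_acc = (
            kept["response_class"].eq("triggered") == kept["response_triggered"]
        ).mean()
        assert scm_acc >= 0.95
        assert trig_acc >= 0.95
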