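"""Synthesize one StartReact trial and detect its EMG burst onsets.

A 120 dB prepulse arrives 300 ms before the visual go-signal; the
generator injects an SCM startle burst and a triggered agonist (ECR)
response, and the sustained-threshold detector recovers both onsets.
"""

import numpy as np

import startreact as sr

cfg = sr.exp1_config(p_scm=1.0, p_trigger_given_scm_plus=1.0)
condition = sr.ConditionSpec("auditory", intensity_db=120, presentation_offset_ms=-300)
trial, truth = sr.synthesize_trial(condition, cfg, np.random.default_rng(1))

onsets = sr.detect_trial_bursts(trial)
print(f"injected SCM onset : {truth.scm_true_onset_ms:8.2f} ms (relative to go)")
print(f"detected SCM onset : {onsets['SCM'].onset_ms:8.2f} ms")
print(f"injected ECR onset : {truth.ecr_true_onset_ms:8.2f} ms")
print(f"detected ECR onset : {onsets['ECR'].onset_ms:8.2f} ms")

ct = sr.classify_trial(trial, onsets)
print(
    f"classification     : {ct.scm_status}, {ct.response_class}, "
    f"premotor RT {ct.adjusted_rt_ms:.2f} ms -> {ct.confusion}"
)
# Detected onsets should sit within a few ms of the injected ones; the trial
# is SCM+ and triggered, so it counts as a true positive for the
# SCM-predicts-triggering rule.
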