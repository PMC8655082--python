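"""Classify a small synthetic cohort and summarise it.

Generates three participants of the 50%-auditory design, runs detection
and classification, and prints condition-wise SCM+ proportions plus the
confusion breakdown of the SCM-predicts-triggering rule.
"""

import startreact as sr

sessions = sr.generate_cohort(sr.exp1_config(), "exp1", 3, seed=11, n_blocks=1)
classified = sr.classify_cohort(sessions)

kept = classified[classified["keep"]]
print(f"{len(classified)} trials, {len(kept)} kept after error filtering\n")

props = sr.summarize_proportions(classified, "scm_plus")
print("pooled SCM+ proportion per condition (intensity dB, offset ms):")
print(props.pooled.to_string(index=False), "\n")

print("confusion breakdown (kept auditory trials):")
print(sr.confusion_summary(classified).to_string(index=False))
# Higher intensities and later (closer to go) prepulses yield more SCM+
# trials; accuracy_pct is the share of trials where SCM presence correctly
# predicts whether the response was triggered.
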