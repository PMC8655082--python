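"""Repeated-measures ANOVA on arcsine-root-transformed SCM+ proportions.

Builds per-participant proportions of startle-positive trials per
(presentation time x intensity) cell from a synthetic cohort, transforms
them, and runs the 2x4 within-subject ANOVA with Tukey post-hocs.
"""

import startreact as sr

sessions = sr.generate_cohort(sr.exp1_config(), "exp1", 8, seed=3, n_blocks=2)
classified = sr.classify_cohort(sessions)

table = sr.summarize_proportions(classified, "scm_plus")
per = table.per_subject.copy()
per["transformed"] = sr.arcsine_sqrt(per["proportion"].to_numpy())

anova = sr.rm_anova2(
    per, dv="transformed", within=("offset_ms", "intensity_db"),
    subject="participant_id",
)
print("2 (time) x 4 (intensity) repeated-measures ANOVA:")
print(anova.table[["effect", "F", "df_effect", "df_error", "p", "partial_eta_sq"]]
      .to_string(index=False), "\n")

posthoc = sr.posthoc_pairwise(
    per, "intensity_db", dv="transformed",
    within=("offset_ms", "intensity_db"), subject="participant_id",
)
print("Tukey pairwise comparisons of intensity levels:")
print(posthoc.to_string(index=False))
# Expect large F for both main effects: the generator's startle probability
# rises with intensity and with later presentation.
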