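"""The study-shaped inferential tables on a synthetic cohort.

Scores a simulated sample, then runs the block-sequential regressions
(main effects of age and the two status dummies, centered two-way
interactions in block 2) for per-role attachment strength and the four
morphology outcomes, plus the demographic crosstab.
"""

from whmt import GeneratorConfig, generate, score_records
from whmt.tables import (
    demographics_table,
    morphology_regressions,
    strength_regressions,
)

scored = score_records(generate(GeneratorConfig(n=930, seed=4)))

demo = demographics_table(scored)
cols = ["age_group", "n", "female_pct", "married_engaged_pct", "child_pct"]
print("demographics:")
print(demo[cols].to_string(index=False, float_format="%.1f"))

print("\nattachment-strength regressions (per role):")
strength = strength_regressions(scored)
cols = ["outcome", "n", "r2_block1", "r2_change_block2", "adj_r2", "F", "df1", "df2", "dropped"]
print(strength[cols].to_string(index=False, float_format="%.3f"))

print("\nmorphology regressions:")
morph = morphology_regressions(scored)
print(morph[cols].to_string(index=False, float_format="%.3f"))

# Per-role models use only participants who placed that role, so n varies
# by row; the romantic-partner model drops the romantic dummy (constant
# among partner-raters) and the child model drops the parental dummy —
# exactly the columns the dropped field records.  R^2 change for block 2
# is the increment from adding the centered interaction products.
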