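"""Reproduce the 14-rule hypoxia classification panel.

Loads the packaged 25-tumor neuroblastoma cohort (8 hypoxic, 17
normoxic), dichotomizes each marker's staining score to high/low, mines
association rules between marker states and the tumors' hypoxia status,
and selects the top-7-by-lift ∪ top-7-by-conviction panel per polarity.
"""

from hyporules import RunConfig, run_pipeline
from hyporules.render import render_text

report = run_pipeline(RunConfig(use_fixture=True, k=7))
print(render_text(report))
print()
print(
    f"{len(report)} rules selected. Each row reads IF the antecedent marker\n"
    "states hold THEN the tumor is in the stated hypoxia cluster; n(A) is\n"
    "how many of the 25 tumors satisfy the antecedent and n(A^B) how many\n"
    "of those are in the predicted cluster. Confidence n(A^B)/n(A) is the\n"
    "rule's precision; coverage n(A^B)/n(B) the fraction of that cluster it\n"
    "captures; lift and conviction exceed 1 when the rule beats chance."
)
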