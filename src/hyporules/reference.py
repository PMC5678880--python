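"""The published 14-rule reference panel for the 25-tumor cohort.

Each entry records a rule's antecedent marker states, its hypoxia-status
consequent, the antecedent/joint occurrence counts, and the five
interestingness metrics as printed (two decimals, trailing zeros
stripped).  The panel serves two roles:

* the consistency target for auditing the fixture's six medium-cell
  resolutions (:func:`hyporules.dichotomize.resolve_by_consistency`
  searches all 64 assignments for the one reproducing every count pair);
* the expected values for end-to-end reproduction checks.

High-hypoxia rules use HIF1A=high / PDK1=high / PHD3=low antecedent
states; low-hypoxia rules the opposite polarities.
"""

from __future__ import annotations

from .dichotomize import HYPOXIA, RulePattern, item

#: (antecedent marker→state, consequent state, nA, nAB,
#:  coverage, confidence, lift, leverage, conviction)
REFERENCE_RULES: tuple[dict, ...] = (
    {"antecedent": {"HIF1A": "high"}, "hypoxia": "high",
     "nA": 11, "nAB": 8, "coverage": 1.00, "confidence": 0.73,
     "lift": 2.27, "leverage": 0.18, "conviction": 1.87},
    {"antecedent": {"PDK1": "high"}, "hypoxia": "high",
     "nA": 9, "nAB": 7, "coverage": 0.88, "confidence": 0.78,
     "lift": 2.43, "leverage": 0.16, "conviction": 2.04},
    {"antecedent": {"PHD3": "low"}, "hypoxia": "high",
     "nA": 10, "nAB": 8, "coverage": 1.00, "confidence": 0.8,
     "lift": 2.5, "leverage": 0.19, "conviction": 2.27},
    {"antecedent": {"HIF1A": "high", "PHD3": "low"}, "hypoxia": "high",
     "nA": 8, "nAB": 8, "coverage": 1.00, "confidence": 1.0,
     "lift": 3.13, "leverage": 0.22, "conviction": 5.44},
    {"antecedent": {"HIF1A": "high", "PDK1": "high"}, "hypoxia": "high",
     "nA": 8, "nAB": 7, "coverage": 0.88, "confidence": 0.88,
     "lift": 2.73, "leverage": 0.18, "conviction": 2.72},
    {"antecedent": {"PDK1": "high", "PHD3": "low"}, "hypoxia": "high",
     "nA": 7, "nAB": 7, "coverage": 0.88, "confidence": 1.0,
     "lift": 3.13, "leverage": 0.19, "conviction": 4.76},
    {"antecedent": {"HIF1A": "high", "PDK1": "high", "PHD3": "low"},
     "hypoxia": "high",
     "nA": 7, "nAB": 7, "coverage": 0.88, "confidence": 1.0,
     "lift": 3.13, "leverage": 0.19, "conviction": 4.76},
    {"antecedent": {"HIF1A": "low"}, "hypoxia": "low",
     "nA": 14, "nAB": 14, "coverage": 0.82, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.18, "conviction": 4.48},
    {"antecedent": {"PDK1": "low"}, "hypoxia": "low",
     "nA": 16, "nAB": 15, "coverage": 0.88, "confidence": 0.94,
     "lift": 1.38, "leverage": 0.16, "conviction": 2.56},
    {"antecedent": {"PHD3": "high"}, "hypoxia": "low",
     "nA": 15, "nAB": 15, "coverage": 0.88, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.19, "conviction": 4.8},
    {"antecedent": {"HIF1A": "low", "PDK1": "low"}, "hypoxia": "low",
     "nA": 13, "nAB": 13, "coverage": 0.76, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.17, "conviction": 4.16},
    {"antecedent": {"HIF1A": "low", "PHD3": "high"}, "hypoxia": "low",
     "nA": 12, "nAB": 12, "coverage": 0.71, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.15, "conviction": 3.84},
    {"antecedent": {"PDK1": "low", "PHD3": "high"}, "hypoxia": "low",
     "nA": 13, "nAB": 13, "coverage": 0.76, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.17, "conviction": 4.16},
    {"antecedent": {"HIF1A": "low", "PDK1": "low", "PHD3": "high"},
     "hypoxia": "low",
     "nA": 11, "nAB": 11, "coverage": 0.65, "confidence": 1.0,
     "lift": 1.47, "leverage": 0.14, "conviction": 3.52},
)


def reference_pattern(entry: dict) -> RulePattern:
    """Convert a panel entry to the (antecedent itemset, consequent) form."""
    antecedent = frozenset(item(m, s) for m, s in entry["antecedent"].items())
    return (antecedent, item(HYPOXIA, entry["hypoxia"]))


def reference_count_pairs() -> dict[RulePattern, tuple[int, int]]:
    """pattern → (nA, nAB) for all 14 reference rules: the consistency
    target of the medium-cell audit."""
    return {reference_pattern(e): (e["nA"], e["nAB"]) for e in REFERENCE_RULES}


def reference_metrics() -> dict[RulePattern, dict[str, float]]:
    """pattern → printed metric values for all 14 reference rules."""
    keys = ("nA", "nAB", "coverage", "confidence", "lift", "leverage", "conviction")
    return {reference_pattern(e): {k: e[k] for k in keys} for e in REFERENCE_RULES}


__all__ = ["REFERENCE_RULES", "reference_pattern", "reference_count_pairs", "reference_metrics"]
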