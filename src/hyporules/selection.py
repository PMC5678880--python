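"""Selection of the reported rule panel: per consequent polarity, the
union of the top-k rules by lift and the top-k by conviction.

On the packaged 25-tumor cohort with k = 7 this yields exactly 14 rules
(7 per hypoxia polarity), because each polarity's rule space over the
three fixed-polarity marker items has exactly 7 non-empty antecedents
and each is admitted by at least one criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .cohort import MARKERS
from .dichotomize import HYPOXIA
from .errors import ParameterError
from .mining import AssociationRule


@dataclass(frozen=True)
class SelectedRule:
    """One selected rule with its label (R1, R2, …) and the criterion
    that admitted it: ``lift``, ``conviction`` or ``both``."""

    label: str
    rule: AssociationRule
    trace: str


@dataclass(frozen=True)
class SelectionReport:
    """Ordered selected rules; the high-hypoxia block precedes low."""

    rules: tuple[SelectedRule, ...]

    def __len__(self) -> int:
        return len(self.rules)

    def by_pattern(self) -> dict:
        return {s.rule.pattern(): s for s in self.rules}


def _item_sort_key(label: str) -> tuple[int, str]:
    name = label.split("=", 1)[0]
    rank = MARKERS.index(name) if name in MARKERS else len(MARKERS)
    return (rank, label)


def _canonical_rule_key(rule: AssociationRule) -> tuple:
    """Deterministic display order: antecedent size, then marker order."""
    return (
        len(rule.antecedent),
        tuple(sorted((_item_sort_key(i) for i in rule.antecedent))),
    )


def _ranking_key(rule: AssociationRule, metric: str) -> tuple:
    value = getattr(rule, metric)
    return (-float(value), len(rule.antecedent), tuple(sorted(rule.antecedent)))


def _consequent_order(consequent: str) -> tuple[int, str]:
    order = {f"{HYPOXIA}=high": 0, f"{HYPOXIA}=low": 1}
    return (order.get(consequent, 2), consequent)


def select_rules(rules: Sequence[AssociationRule], k: int = 7) -> SelectionReport:
    """Union of the top-``k`` rules by lift and by conviction, per
    consequent; ties broken by (metric desc, antecedent size asc,
    lexicographic items).  Idempotent and invariant to input order.
    """
    if k < 1:
        raise ParameterError(f"k must be ≥ 1, got {k}")
    if not rules:
        raise ParameterError("select_rules requires a non-empty rule list")
    groups: dict[str, list[AssociationRule]] = {}
    for rule in rules:
        groups.setdefault(rule.consequent, []).append(rule)
    selected: list[SelectedRule] = []
    for consequent in sorted(groups, key=_consequent_order):
        group = groups[consequent]
        if k > len(group):
            warnings.warn(
                f"k={k} exceeds the {len(group)} distinct rules for "
                f"consequent {consequent}; selecting all",
                stacklevel=2,
            )
        admitted: dict[tuple, set[str]] = {}
        for metric in ("lift", "conviction"):
            top = sorted(group, key=lambda r: _ranking_key(r, metric))[:k]
            for rule in top:
                admitted.setdefault(rule.pattern(), set()).add(metric)
        chosen = {pattern: rule for rule in group if (pattern := rule.pattern()) in admitted}
        for pattern in sorted(chosen, key=lambda p: _canonical_rule_key(chosen[p])):
            criteria = admitted[pattern]
            trace = "both" if len(criteria) == 2 else next(iter(criteria))
            selected.append(SelectedRule(label="", rule=chosen[pattern], trace=trace))
    labelled = tuple(
        SelectedRule(label=f"R{i}", rule=s.rule, trace=s.trace)
        for i, s in enumerate(selected, start=1)
    )
    return SelectionReport(rules=labelled)


__all__ = ["SelectedRule", "SelectionReport", "select_rules"]
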