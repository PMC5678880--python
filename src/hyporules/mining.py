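"""APRIORI frequent-itemset mining and rule interestingness metrics.

The miner is level-wise with candidate pruning by support
anti-monotonicity (every subset of a frequent itemset is frequent);
support counting is vectorized over a boolean one-hot matrix so that
cohorts of tens of thousands of transactions mine in well under a
second.

Metrics are computed in exact rational arithmetic (:class:`fractions.
Fraction`) from the integer contingency counts, so two-decimal rendering
is free of float-rounding artifacts.  Two conventions here differ from
the most common textbook ones and are deliberate:

* **coverage** is consequent recall ``n(A∧B)/n(B)`` — the fraction of,
  say, hypoxic tumors that the rule captures — not antecedent support
  ``n(A)/N``.
* **conviction** uses a +1-smoothed denominator,
  ``n(A)·(N−n(B)) / (N·(n(A)−n(A∧B)+1))``, which keeps confidence-1
  rules finite and comparable.  The classical unsmoothed form (infinite
  at confidence 1) is available via ``variant="classical"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .dichotomize import HYPOXIA, TransactionDB
from .errors import ParameterError


@dataclass(frozen=True)
class Itemset:
    """A set of items with its absolute support count."""

    items: frozenset
    count: int


@dataclass(frozen=True)
class RuleCounts:
    """Contingency counts for one rule A→B.

    ``N`` total transactions, ``nA`` antecedent occurrences, ``nB``
    consequent occurrences, ``nAB`` joint occurrences.
    """

    N: int
    nA: int
    nB: int
    nAB: int

    def __post_init__(self) -> None:
        if not (0 <= self.nAB <= min(self.nA, self.nB) <= max(self.nA, self.nB) <= self.N):
            raise ParameterError(
                f"inconsistent rule counts N={self.N} nA={self.nA} "
                f"nB={self.nB} nAB={self.nAB}"
            )


def confidence(c: RuleCounts) -> Fraction:
    """Rule precision n(A∧B)/n(A)."""
    if c.nA < 1:
        raise ParameterError("confidence undefined for nA = 0")
    return Fraction(c.nAB, c.nA)


def coverage(c: RuleCounts) -> Fraction:
    """Consequent recall n(A∧B)/n(B)."""
    if c.nB < 1:
        raise ParameterError("coverage undefined for nB = 0")
    return Fraction(c.nAB, c.nB)


def lift(c: RuleCounts) -> Fraction:
    """Confidence over consequent prevalence; 1 under independence."""
    if c.nA < 1 or c.nB < 1:
        raise ParameterError("lift undefined for nA = 0 or nB = 0")
    return Fraction(c.nAB * c.N, c.nA * c.nB)


def leverage(c: RuleCounts) -> Fraction:
    """P(A∧B) − P(A)P(B); 0 under independence, bounded by ±0.25."""
    if c.N < 1:
        raise ParameterError("leverage undefined for N = 0")
    return Fraction(c.nAB, c.N) - Fraction(c.nA * c.nB, c.N * c.N)


def conviction(c: RuleCounts, variant: str = "smoothed") -> Fraction | float:
    """P(A)P(¬B)/P(A∧¬B), smoothed by default.

    The smoothed variant adds 1 to the count of counter-examples,
    n(A)·(N−n(B)) / (N·(n(A)−n(A∧B)+1)), making it total and finite.
    ``variant="classical"`` drops the +1 and returns ``math.inf`` for
    confidence-1 rules.
    """
    if c.nA < 1:
        raise ParameterError("conviction undefined for nA = 0")
    if variant == "smoothed":
        return Fraction(c.nA * (c.N - c.nB), c.N * (c.nA - c.nAB + 1))
    if variant == "classical":
        if c.nAB == c.nA:
            return math.inf
        return Fraction(c.nA * (c.N - c.nB), c.N * (c.nA - c.nAB))
    raise ParameterError(f"unknown conviction variant {variant!r}")


@dataclass(frozen=True)
class AssociationRule:
    """A mined rule: antecedent items → single consequent item, with its
    contingency counts and the five interestingness metrics."""

    antecedent: frozenset
    consequent: str
    counts: RuleCounts
    conviction_variant: str = "smoothed"

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ParameterError("rule antecedent must be non-empty")
        if self.consequent in self.antecedent:
            raise ParameterError("antecedent and consequent must be disjoint")

    @property
    def coverage(self) -> Fraction:
        return coverage(self.counts)

    @property
    def confidence(self) -> Fraction:
        return confidence(self.counts)

    @property
    def lift(self) -> Fraction:
        return lift(self.counts)

    @property
    def leverage(self) -> Fraction:
        return leverage(self.counts)

    @property
    def conviction(self) -> Fraction | float:
        return conviction(self.counts, self.conviction_variant)

    def metrics(self) -> dict[str, float]:
        return {
            "coverage": float(self.coverage),
            "confidence": float(self.confidence),
            "lift": float(self.lift),
            "leverage": float(self.leverage),
            "conviction": float(self.conviction),
        }

    def pattern(self) -> tuple[frozenset, str]:
        return (self.antecedent, self.consequent)


def _onehot_matrix(db: TransactionDB) -> tuple[np.ndarray, dict[str, int]]:
    index = {label: i for i, label in enumerate(db.items)}
    matrix = np.zeros((db.n_transactions, len(db.items)), dtype=bool)
    for row, transaction in enumerate(db.transactions):
        for label in transaction:
            matrix[row, index[label]] = True
    return matrix, index


def apriori_frequent_itemsets(db: TransactionDB, min_count: int = 1) -> list[Itemset]:
    """All itemsets with support ≥ ``min_count``, with exact counts.

    Level-wise generation: candidates at level k+1 join frequent
    k-itemsets sharing a (k−1)-prefix and are pruned unless every
    k-subset is frequent.  Returns itemsets sorted by (size, items).
    """
    if min_count < 1:
        raise ParameterError(f"min_count must be ≥ 1, got {min_count}")
    if db.n_transactions == 0:
        return []
    matrix, index = _onehot_matrix(db)

    def count(cols: tuple[int, ...]) -> int:
        return int(matrix[:, cols].all(axis=1).sum())

    results: list[Itemset] = []
    label_of = {i: label for label, i in index.items()}
    current: list[tuple[int, ...]] = []
    for i in sorted(index.values()):
        c = count((i,))
        if c >= min_count:
            current.append((i,))
            results.append(Itemset(frozenset({label_of[i]}), c))
    while current:
        frequent = set(current)
        candidates: list[tuple[int, ...]] = []
        for a, b in itertools.combinations(current, 2):
            if a[:-1] == b[:-1] and a[-1] < b[-1]:
                candidate = a + (b[-1],)
                if all(
                    candidate[:j] + candidate[j + 1 :] in frequent
                    for j in range(len(candidate))
                ):
                    candidates.append(candidate)
        current = []
        for candidate in candidates:
            c = count(candidate)
            if c >= min_count:
                current.append(candidate)
                results.append(
                    Itemset(frozenset(label_of[i] for i in candidate), c)
                )
    results.sort(key=lambda s: (len(s.items), tuple(sorted(s.items))))
    return results


def generate_rules(
    itemsets: Iterable[Itemset],
    db: TransactionDB,
    consequent_domain: Sequence[str] = (f"{HYPOXIA}=high", f"{HYPOXIA}=low"),
    conviction_variant: str = "smoothed",
) -> list[AssociationRule]:
    """One rule per (marker-item antecedent, consequent) pair.

    Antecedents are the mined itemsets free of hypoxia-status items with
    count ≥ 1; joint counts come from the itemset table when present and
    are recounted from the database otherwise (antecedents below the
    mining threshold never reappear as rules, preserving the miner's
    support semantics).
    """
    if not consequent_domain:
        raise ParameterError("consequent_domain must be non-empty")
    for consequent in consequent_domain:
        if consequent not in db.items:
            raise ParameterError(f"consequent {consequent!r} is not an item of the database")
    by_items = {s.items: s.count for s in itemsets}
    n = db.n_transactions
    rules = []
    for items, n_a in by_items.items():
        if n_a < 1 or any(label.startswith(HYPOXIA + "=") for label in items):
            continue
        for consequent in consequent_domain:
            if consequent in items:
                continue
            joint = items | {consequent}
            n_ab = by_items.get(joint)
            if n_ab is None:
                n_ab = db.itemset_count(joint)
            counts = RuleCounts(N=n, nA=n_a, nB=db.item_count(consequent), nAB=n_ab)
            rules.append(
                AssociationRule(
                    antecedent=items,
                    consequent=consequent,
                    counts=counts,
                    conviction_variant=conviction_variant,
                )
            )
    return rules


def mine_rules(
    db: TransactionDB,
    min_count: int = 1,
    conviction_variant: str = "smoothed",
) -> list[AssociationRule]:
    """Convenience: frequent itemsets then rules, with library defaults
    (no support or confidence cut beyond ``min_count``)."""
    itemsets = apriori_frequent_itemsets(db, min_count=min_count)
    return generate_rules(itemsets, db, conviction_variant=conviction_variant)


__all__ = [
    "Itemset",
    "RuleCounts",
    "AssociationRule",
    "confidence",
    "coverage",
    "lift",
    "leverage",
    "conviction",
    "apriori_frequent_itemsets",
    "generate_rules",
    "mine_rules",
]
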