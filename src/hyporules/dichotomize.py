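"""Dichotomization of marker scores and the binary transaction table.

Percentage-positivity bins collapse to three levels (L/M/H); the two
low bins are L, the two high bins are H, and ``21–50%`` is M.  Medium
scores resolve to binary high/low either through an explicit
``medium_resolution`` or, failing that, through the staining-intensity
policy (strong/moderate → high, weak → low — a configurable default,
since only "intensity decides" is established practice, not the cut).

Each tumor then becomes one transaction over both-polarity items
(``HIF1A=high``, ``HIF1A=low``, …, ``HYPOXIA=high``, ``HYPOXIA=low``)
so that rules about low expression are first-class.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import MARKERS, MEDIUM_BIN, MarkerScore, TumorRecord
from .errors import CohortValueError, InconsistencyError, ParameterError, UnresolvedScoreError

HYPOXIA = "HYPOXIA"

#: bin → level; total on the five-bin vocabulary and order-preserving.
BIN_TO_LEVEL: dict[str, str] = {
    "<1%": "L",
    "1–20%": "L",
    "21–50%": "M",
    "51–70%": "H",
    "71–100%": "H",
}

#: default intensity → binary policy for unresolved medium scores
DEFAULT_INTENSITY_POLICY: dict[str, str] = {
    "strong": "high",
    "moderate": "high",
    "weak": "low",
}

#: antecedent pattern of a rule: (frozenset of items, consequent item)
RulePattern = tuple[frozenset, str]


def item(name: str, state: str) -> str:
    """Build an item label such as ``HIF1A=high``."""
    return f"{name}={state}"


def bin_to_level(percent_bin: str) -> str:
    """Map a percentage bin to its L/M/H level."""
    try:
        return BIN_TO_LEVEL[percent_bin]
    except KeyError:
        raise CohortValueError(
            f"unrecognized percentage bin {percent_bin!r}"
        ) from None


def resolve_binary(
    score: MarkerScore,
    intensity_policy: Mapping[str, str] = DEFAULT_INTENSITY_POLICY,
    context: str = "",
) -> str:
    """Resolve a marker score to binary ``high``/``low``.

    L bins force ``low`` and H bins force ``high``.  A medium bin uses
    its explicit ``medium_resolution`` when set, otherwise the intensity
    policy; with neither available an :class:`UnresolvedScoreError` is
    raised (``context`` names the tumor/marker in the message).
    """
    level = bin_to_level(score.percent_bin)
    if level == "L":
        return "low"
    if level == "H":
        return "high"
    if score.medium_resolution != "not_applicable":
        return score.medium_resolution
    if score.intensity in intensity_policy:
        return intensity_policy[score.intensity]
    raise UnresolvedScoreError(
        f"medium score{' for ' + context if context else ''} has neither an "
        "explicit resolution nor a usable staining intensity"
    )


@dataclass(frozen=True)
class TransactionDB:
    """Binary item matrix: one transaction per tumor.

    Every transaction holds exactly one polarity per marker plus one
    hypoxia-status item.
    """

    items: tuple[str, ...]
    transactions: tuple[frozenset, ...]

    @property
    def n_transactions(self) -> int:
        return len(self.transactions)

    def item_count(self, label: str) -> int:
        return self.itemset_count({label})

    def itemset_count(self, items: Iterable[str]) -> int:
        """Absolute support: number of transactions containing all items."""
        items = frozenset(items)
        return sum(1 for t in self.transactions if items <= t)

    def to_onehot(self) -> pd.DataFrame:
        """0/1 matrix, columns = item labels, one row per transaction."""
        data = [[int(label in t) for label in self.items] for t in self.transactions]
        return pd.DataFrame(data, columns=list(self.items))


def cohort_to_transactions(
    cohort: Sequence[TumorRecord],
    intensity_policy: Mapping[str, str] = DEFAULT_INTENSITY_POLICY,
    overrides: Mapping[tuple[int, str], str] | None = None,
) -> TransactionDB:
    """Dichotomize a cohort into its transaction database.

    ``overrides`` maps ``(tumor_id, marker)`` to a binary state and takes
    precedence over the record's own resolution — used by the medium-cell
    consistency audit to try alternative assignments.
    """
    overrides = overrides or {}
    labels = [item(m, s) for m in MARKERS for s in ("high", "low")]
    labels += [item(HYPOXIA, s) for s in ("high", "low")]
    transactions = []
    for record in cohort:
        members = set()
        for marker in MARKERS:
            state = overrides.get((record.tumor_id, marker))
            if state is None:
                state = resolve_binary(
                    record.marker_scores[marker],
                    intensity_policy,
                    context=f"tumor {record.tumor_id} marker {marker}",
                )
            members.add(item(marker, state))
        members.add(item(HYPOXIA, "high" if record.cluster == "hypoxic" else "low"))
        transactions.append(frozenset(members))
    return TransactionDB(items=tuple(labels), transactions=tuple(transactions))


def medium_cells(cohort: Sequence[TumorRecord]) -> list[tuple[int, str]]:
    """(tumor_id, marker) pairs whose percentage bin is the medium bin."""
    return [
        (record.tumor_id, marker)
        for record in cohort
        for marker in MARKERS
        if record.marker_scores[marker].percent_bin == MEDIUM_BIN
    ]


def resolve_by_consistency(
    cohort: Sequence[TumorRecord],
    printed_counts: Mapping[RulePattern, tuple[int, int]],
) -> list[dict[tuple[int, str], str]]:
    """Exhaustively search medium-cell assignments against target counts.

    Enumerates all ``2^k`` high/low assignments of the cohort's medium
    cells and returns every assignment whose induced antecedent and joint
    occurrence counts match ``printed_counts`` exactly — the audit oracle
    that fixes the packaged fixture's resolutions.  Raises
    :class:`InconsistencyError` (listing the nearest misses) when no
    assignment satisfies all count pairs.
    """
    cells = medium_cells(cohort)
    if len(cells) > 20:
        raise ParameterError(
            f"{len(cells)} medium cells exceed the exhaustive-search bound of 20"
        )
    matches: list[dict[tuple[int, str], str]] = []
    best_miss = len(printed_counts) + 1
    near: list[tuple[dict, list[str]]] = []
    for states in itertools.product(("high", "low"), repeat=len(cells)):
        assignment = dict(zip(cells, states))
        db = cohort_to_transactions(cohort, overrides=assignment)
        mismatched = []
        for (antecedent, consequent), (n_a, n_ab) in printed_counts.items():
            got_a = db.itemset_count(antecedent)
            got_ab = db.itemset_count(antecedent | {consequent})
            if (got_a, got_ab) != (n_a, n_ab):
                mismatched.append(
                    f"{sorted(antecedent)}→{consequent}: expected ({n_a},{n_ab}), "
                    f"got ({got_a},{got_ab})"
                )
        if not mismatched:
            matches.append(assignment)
        elif len(mismatched) < best_miss:
            best_miss = len(mismatched)
            near = [(assignment, mismatched)]
        elif len(mismatched) == best_miss and len(near) < 3:
            near.append((assignment, mismatched))
    if not matches:
        details = "; ".join(
            f"assignment {a} misses [{', '.join(m)}]" for a, m in near
        )
        raise InconsistencyError(
            f"no assignment of {len(cells)} medium cells reproduces the target "
            f"counts; nearest misses ({best_miss} mismatched patterns): {details}"
        )
    return matches


def write_onehot(db: TransactionDB, path: str | Path) -> Path:
    path = Path(path)
    db.to_onehot().to_csv(path, index=False)
    return path


def write_baskets(db: TransactionDB, path: str | Path) -> Path:
    """Basket format for cross-checking with external miners: one
    transaction per line, items space-separated in item order."""
    path = Path(path)
    order = {label: i for i, label in enumerate(db.items)}
    with path.open("w", encoding="utf-8") as handle:
        for t in db.transactions:
            handle.write(" ".join(sorted(t, key=order.__getitem__)) + "\n")
    return path


__all__ = [
    "HYPOXIA",
    "BIN_TO_LEVEL",
    "DEFAULT_INTENSITY_POLICY",
    "RulePattern",
    "TransactionDB",
    "item",
    "bin_to_level",
    "resolve_binary",
    "cohort_to_transactions",
    "medium_cells",
    "resolve_by_consistency",
    "write_onehot",
    "write_baskets",
]
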