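import itertools
import random

import pytest

from hyporules import (
    cohort_to_transactions,
    load_fixture,
    mine_rules,
    select_rules,
)
from hyporules.cohort import MarkerScore, TumorRecord
from hyporules.dichotomize import TransactionDB
from hyporules.mining import Itemset


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_db(fixture_cohort):
    return cohort_to_transactions(fixture_cohort)


@pytest.fixture(scope="session")
def fixture_rules(fixture_db):
    return mine_rules(fixture_db, min_count=4)


@pytest.fixture(scope="session")
def fixture_report(fixture_rules):
    return select_rules(fixture_rules, k=7)


def brute_force_itemsets(db: TransactionDB, min_count: int) -> set[tuple[frozenset, int]]:
    """Independent oracle: enumerate every non-empty subset of the item
    vocabulary and count it by scanning all transactions."""
    out = set()
    for size in range(1, len(db.items) + 1):
        for combo in itertools.combinations(db.items, size):
            items = frozenset(combo)
            count = sum(1 for t in db.transactions if items <= t)
            if count >= min_count:
                out.add((items, count))
    return out


def random_db(rng: random.Random, max_transactions: int = 12, max_items: int = 8) -> TransactionDB:
    """A random transaction database over abstract item labels."""
    n_items = rng.randint(1, max_items)
    items = tuple(f"i{j}" for j in range(n_items))
    n = rng.randint(0, max_transactions)
    transactions = tuple(
        frozenset(label for label in items if rng.random() < 0.5) for _ in range(n)
    )
    return TransactionDB(items=items, transactions=transactions)


def make_record(tumor_id: int, cluster: str, bins: dict[str, str], **kwargs) -> TumorRecord:
    scores = {m: MarkerScore(b) if isinstance(b, str) else b for m, b in bins.items()}
    return TumorRecord(tumor_id=tumor_id, cluster=cluster, marker_scores=scores, **kwargs)


def as_itemsets(pairs) -> list[Itemset]:
    return [Itemset(items, count) for items, count in pairs]
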