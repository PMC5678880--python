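"""End-to-end orchestration: read/simulate → dichotomize → mine →
score → select → render, with stage-count logging."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from . import cohort as cohort_io
from .dichotomize import cohort_to_transactions, medium_cells
from .errors import IntegrityError
from .mining import apriori_frequent_itemsets, generate_rules
from .selection import SelectionReport, select_rules

logger = logging.getLogger("hyporules")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration: exactly one input source (a cohort CSV
    path or the packaged fixture), selection depth ``k``, mining
    ``min_count`` and the conviction variant.

    ``min_count`` defaults to 4 (16% relative support on the 25-tumor
    cohort).  A minimum support is intrinsic to APRIORI mining; without
    one, near-singleton antecedents reach confidence 1 by chance and tie
    genuinely predictive rules on lift, polluting the top-k selection.
    The threshold sits far below the smallest antecedent occurrence (7)
    of any rule in the published panel.
    """

    input_path: str | Path | None = None
    use_fixture: bool = False
    k: int = 7
    min_count: int = 4
    conviction_variant: str = "smoothed"

    def __post_init__(self) -> None:
        if bool(self.input_path) == self.use_fixture:
            raise IntegrityError(
                "exactly one input source required: an input path or the fixture flag"
            )


def run_pipeline(config: RunConfig) -> SelectionReport:
    """Run the full analysis and return the selection report.

    Logs tumor, medium-cell, itemset and rule counts at each stage.
    """
    if config.use_fixture:
        records = cohort_io.load_fixture()
    else:
        records = cohort_io.read_cohort(config.input_path)
    logger.info("read %d tumors", len(records))
    if not records:
        raise IntegrityError("empty cohort")
    n_medium = len(medium_cells(records))
    db = cohort_to_transactions(records)
    logger.info("dichotomized %d tumors (%d medium cells resolved)", len(records), n_medium)
    itemsets = apriori_frequent_itemsets(db, min_count=config.min_count)
    logger.info("mined %d frequent itemsets (min_count=%d)", len(itemsets), config.min_count)
    rules = generate_rules(itemsets, db, conviction_variant=config.conviction_variant)
    logger.info("generated %d rules", len(rules))
    report = select_rules(rules, k=config.k)
    logger.info("selected %d rules (k=%d)", len(report), config.k)
    return report


__all__ = ["RunConfig", "run_pipeline"]
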