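"""Synthetic cohort generator mirroring the assumed data structure.

Each tumor draws a latent binary hypoxia status with prevalence ``π``;
each marker then takes its hypoxia-concordant binary state (HIF1A and
PDK1 high, PHD3 low under hypoxia; the opposite states under normoxia)
with probability ``sensitivity`` in hypoxic tumors and ``specificity``
in normoxic ones, independently across markers given the status.
Binary states are re-encoded as percentage-positivity bins: high states
draw uniformly from {51–70%, 71–100%} and low states from {<1%, 1–20%},
except that with probability ``medium_fraction`` the score is emitted
as the ambiguous 21–50% bin carrying only an intensity grade
(strong/moderate for high, weak for low), exercising the
intensity-based resolution path.

Closed forms for single-marker rule quality under this model:

* confidence of {marker concordant-state} → hypoxia=high is the
  positive predictive value  PPV = π·se / (π·se + (1−π)(1−sp));
* lift of the same rule is PPV/π.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import MarkerScore, TumorRecord, MARKERS
from .dichotomize import HYPOXIA, cohort_to_transactions, item
from .errors import ParameterError
from .mining import mine_rules

#: marker state concordant with hypoxia
CONCORDANT_STATE: dict[str, str] = {"HIF1A": "high", "PDK1": "high", "PHD3": "low"}

_HIGH_BINS = ("51–70%", "71–100%")
_LOW_BINS = ("<1%", "1–20%")


def _as_marker_map(value: float | Mapping[str, float], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        mapping = {m: float(value[m]) for m in MARKERS}
    else:
        mapping = {m: float(value) for m in MARKERS}
    for m, p in mapping.items():
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"{name}[{m}] = {p} is not a probability")
    return mapping


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the generative model.

    ``sensitivity``/``specificity`` accept a single float applied to all
    three markers or a per-marker mapping.
    """

    n_tumors: int
    hypoxia_prevalence: float
    sensitivity: float | Mapping[str, float] = 1.0
    specificity: float | Mapping[str, float] = 1.0
    medium_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ParameterError(f"n_tumors must be ≥ 1, got {self.n_tumors}")
        if not 0.0 <= self.hypoxia_prevalence <= 1.0:
            raise ParameterError(
                f"hypoxia_prevalence {self.hypoxia_prevalence} is not a probability"
            )
        if not 0.0 <= self.medium_fraction <= 1.0:
            raise ParameterError(
                f"medium_fraction {self.medium_fraction} is not a probability"
            )
        _as_marker_map(self.sensitivity, "sensitivity")
        _as_marker_map(self.specificity, "specificity")

    @property
    def se(self) -> dict[str, float]:
        return _as_marker_map(self.sensitivity, "sensitivity")

    @property
    def sp(self) -> dict[str, float]:
        return _as_marker_map(self.specificity, "specificity")


def analytic_confidence(spec: SimSpec, marker: str = "HIF1A") -> float:
    """Closed-form PPV of {marker concordant} → hypoxia=high."""
    pi = spec.hypoxia_prevalence
    se, sp = spec.se[marker], spec.sp[marker]
    denominator = pi * se + (1.0 - pi) * (1.0 - sp)
    if denominator == 0.0:
        raise ParameterError("antecedent has probability zero under this spec")
    return pi * se / denominator


def analytic_lift(spec: SimSpec, marker: str = "HIF1A") -> float:
    """Closed-form lift of {marker concordant} → hypoxia=high: PPV/π."""
    if spec.hypoxia_prevalence == 0.0:
        raise ParameterError("lift undefined at zero prevalence")
    return analytic_confidence(spec, marker) / spec.hypoxia_prevalence


def simulate_cohort(spec: SimSpec) -> list[TumorRecord]:
    """Draw one cohort; deterministic given the spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    se, sp = spec.se, spec.sp
    records: list[TumorRecord] = []
    for tumor_id in range(1, spec.n_tumors + 1):
        hypoxic = rng.random() < spec.hypoxia_prevalence
        scores: dict[str, MarkerScore] = {}
        for marker in MARKERS:
            concordant = rng.random() < (se[marker] if hypoxic else sp[marker])
            typical = CONCORDANT_STATE[marker]
            atypical = "low" if typical == "high" else "high"
            if hypoxic:
                state = typical if concordant else atypical
            else:
                state = atypical if concordant else typical
            if rng.random() < spec.medium_fraction:
                if state == "high":
                    intensity = "strong" if rng.random() < 0.5 else "moderate"
                else:
                    intensity = "weak"
                scores[marker] = MarkerScore("21–50%", intensity=intensity)
            else:
                bins = _HIGH_BINS if state == "high" else _LOW_BINS
                scores[marker] = MarkerScore(bins[rng.integers(2)])
        records.append(
            TumorRecord(
                tumor_id=tumor_id,
                cluster="hypoxic" if hypoxic else "normoxic",
                marker_scores=scores,
            )
        )
    return records


def single_marker_rule_metrics(cohort: list[TumorRecord]) -> pd.DataFrame:
    """Mine the cohort and extract confidence/lift of the three
    single-marker concordant-state → hypoxia=high rules."""
    db = cohort_to_transactions(cohort)
    rules = {r.pattern(): r for r in mine_rules(db)}
    rows = []
    for marker in MARKERS:
        pattern = (frozenset({item(marker, CONCORDANT_STATE[marker])}), item(HYPOXIA, "high"))
        rule = rules.get(pattern)
        rows.append(
            {
                "marker": marker,
                "confidence": float(rule.confidence) if rule else np.nan,
                "lift": float(rule.lift) if rule else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("marker")


def recovery_experiment(spec: SimSpec, n_replicates: int) -> pd.DataFrame:
    """Full-pipeline parameter recovery across replicates.

    Replicate r reruns simulate → dichotomize → mine → metrics with seed
    ``spec.seed + r`` and the summary reports the mean and standard
    deviation of each single-marker rule metric, alongside the analytic
    values implied by the spec.
    """
    if n_replicates < 1:
        raise ParameterError(f"n_replicates must be ≥ 1, got {n_replicates}")
    frames = []
    for r in range(n_replicates):
        cohort = simulate_cohort(replace(spec, seed=spec.seed + r))
        frames.append(single_marker_rule_metrics(cohort))
    stacked = pd.concat(frames, keys=range(n_replicates), names=["replicate"])
    summary = stacked.groupby(level="marker").agg(["mean", "std"])
    summary.columns = ["_".join(c) for c in summary.columns]
    summary["analytic_confidence"] = [
        analytic_confidence(spec, m) for m in summary.index
    ]
    summary["analytic_lift"] = [analytic_lift(spec, m) for m in summary.index]
    return summary.loc[list(MARKERS)]


__all__ = [
    "CONCORDANT_STATE",
    "SimSpec",
    "simulate_cohort",
    "analytic_confidence",
    "analytic_lift",
    "single_marker_rule_metrics",
    "recovery_experiment",
]
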