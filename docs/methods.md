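# Methods

## Overview

`hyporules` classifies neuroblastoma tumors as hypoxic or normoxic from
a three-marker immunohistochemistry panel (HIF-1α, PDK1, PHD3) by
association-rule mining. The pipeline has four stages: score
dichotomization, transaction encoding, APRIORI mining with five
interestingness metrics, and top-k rule selection. A synthetic-cohort
generator with known ground truth closes the loop for testing and
parameter-recovery studies.

## Dichotomization

IHC percentage-positivity bins collapse to three levels: <1% and 1–20%
are low (L), 21–50% is medium (M), 51–70% and 71–100% are high (H).
L and H force the binary state; M is genuinely ambiguous and resolves
through staining intensity. The intensity cut is a package policy —
strong/moderate → high, weak → low — chosen as the deterministic
default consistent with the qualitative convention that intensity
decides; it is configurable (`intensity_policy` of
`cohort_to_transactions` / `resolve_binary`), and any score may instead
carry an explicit `medium_resolution` that takes precedence.

The packaged 25-tumor cohort has six medium cells whose individual
intensities were never recorded. Their resolutions are therefore fixed
by an exhaustive consistency audit (`resolve_by_consistency`): all
2^6 = 64 high/low assignments are enumerated and checked against the 14
published (n(A), n(A∧B)) occurrence pairs; exactly one assignment
reproduces all of them, and that assignment is hard-coded in the
fixture. Uniqueness means the resolutions are forced by the published
counts, not guessed; the audit is re-run by the test suite and exposed
as `hyporules resolve-audit`.

Hypoxia status itself comes from the cohort's cluster column (an
expression-signature classification performed upstream); the package
never recomputes it.

## Transaction encoding

Each tumor becomes one transaction over both-polarity items
(`HIF1A=high` and `HIF1A=low` are distinct items, likewise PDK1, PHD3
and `HYPOXIA`). Both polarities are materialized so that rules about
*low* expression are first-class antecedents rather than negations.
Every transaction contains exactly one polarity per marker plus one
hypoxia item. Exports exist as one-hot CSV and whitespace-delimited
basket text for cross-checking against external miners.

## Mining and metrics

`apriori_frequent_itemsets` is a from-scratch level-wise APRIORI:
level-(k+1) candidates join frequent k-itemsets sharing a (k−1)-prefix
and are pruned unless every k-subset is frequent; support counting is
vectorized over a boolean matrix. Correctness is established against an
independent oracle — exhaustive enumeration of every subset of the item
vocabulary — on hundreds of random databases, and anti-monotonicity is
asserted on mined output. No hash-tree or bitmap machinery: the target
data are tiny and clarity wins.

`generate_rules` pairs each hypoxia-free frequent antecedent with each
hypoxia consequent. Metrics are evaluated in exact rational arithmetic
(`fractions.Fraction`) from the integer counts N, n(A), n(B), n(A∧B),
and rendered at two decimals (half-up) with trailing zeros stripped.
Two definitions deviate from common textbook usage and are load-bearing:

* **Coverage is consequent recall** n(A∧B)/n(B) — the fraction of
  hypoxic (or normoxic) tumors the rule captures. The word frequently
  means antecedent support n(A)/N elsewhere; recall is the only reading
  consistent with the reference panel this package reproduces
  (e.g. 14/17 = 0.82 and 11/17 = 0.65 for the low-hypoxia rules).
* **Conviction is +1-smoothed**: n(A)·(N−n(B)) / (N·(n(A)−n(A∧B)+1)).
  The classical formula divides by the count of counter-examples and is
  infinite for every confidence-1 rule; the Laplace-style +1 keeps such
  rules finite and rankable, again matching the reference panel (5.44,
  4.76, 4.8, 4.48 … for confidence-1 rules). The classical variant
  remains available (`conviction(c, "classical")`, CLI
  `--conviction classical`) and the contrast is asserted in the tests.

## Rule selection and the support floor

Selection takes, per consequent polarity, the union of the top-k rules
by lift and the top-k by conviction (k = 7 default), deduplicated, each
rule annotated with the criterion that admitted it; ties break by
(metric desc, antecedent size asc, lexicographic items). Rules are
displayed high-hypoxia block first, each block ordered by antecedent
size then marker order (HIF1A, PDK1, PHD3), labelled R1….

The end-to-end pipeline applies a minimum absolute support of 4
(`RunConfig.min_count`, 16% of the 25-tumor cohort). This floor is not
cosmetic: without one, antecedents occurring once or twice reach
confidence 1 vacuously, tie the genuinely predictive rules on lift
(which depends only on confidence at fixed consequent), and enter every
top-k-by-lift list. Any floor between 4 and 7 yields the same panel on
the packaged cohort, whose smallest genuine antecedent occurrence is 7;
4 was fixed as a conventional ~15% relative support. The mining
operation itself accepts any `min_count ≥ 1` for general use.

## Synthetic cohorts

`simulate_cohort` draws, per tumor, a latent hypoxia status
Bernoulli(π), then each marker's state conditionally independently
given status: the hypoxia-concordant state (HIF1A high, PDK1 high, PHD3
low) with probability `sensitivity` in hypoxic tumors, and the
normoxia-concordant state with probability `specificity` in normoxic
ones. States re-encode as bins — high uniformly from {51–70%, 71–100%},
low uniformly from {<1%, 1–20%} — except that with probability
`medium_fraction` the score is emitted as the ambiguous 21–50% bin with
an intensity grade (strong or moderate, equiprobable, for high; weak
for low), exercising the intensity-resolution path. Defaults: perfect
markers (se = sp = 1), `medium_fraction` 0; the worked configurations
use π = 0.32 (the 8/25 prevalence of the packaged cohort) with se, sp
around 0.82–0.9, the operating range the cohort's own 2×2 marker tables
imply. Replicate r of `recovery_experiment` derives its seed as
`base_seed + r`.

Closed forms under this model anchor the recovery tests: the
single-marker rule {marker concordant} → {hypoxia high} has confidence
converging to PPV = π·se / (π·se + (1−π)(1−sp)) and lift to PPV/π.
What the generator does *not* emulate: inter-marker correlation beyond
the shared latent status, scorer variability in bin boundaries, missing
scores, and any clinical covariate structure — so passing recovery
tests demonstrate pipeline correctness under conditional independence,
not robustness to correlated staining artifacts in real sections.

## Numerical and degenerate-input choices

* Metrics are exact rationals; only rendering rounds (half-up, two
  decimals). Undefined metrics (n(A) = 0 for confidence/lift/conviction,
  n(B) = 0 for coverage/lift) raise a parameter error rather than
  returning sentinels.
* An empty database mines to an empty itemset list, not an error; an
  empty cohort aborts the pipeline with an "empty cohort" diagnostic.
* A medium score with neither resolution nor usable intensity raises an
  unresolved-score error naming the tumor and marker (CLI exit 3).
* Bin strings accept ASCII-hyphen spellings on input ("21-50%") and
  normalize to the canonical en-dash form on output.
* The consistency audit is bounded at 20 medium cells (2^20
  assignments); beyond that it refuses rather than stalls.
* `k` larger than the available rule pool selects everything with a
  warning rather than failing.

## Problem sizes

The packaged analysis is a 25-transaction, 8-item database and runs in
milliseconds; the audit enumerates 64 assignments in well under a
second. Property tests use 200 random databases of ≤ 12 transactions ×
≤ 8 items against the exhaustive oracle and 1000 random contingency
configurations for the metrics; recovery tests use 10 000-tumor
cohorts with 5 replicates per seed — sizes at which Monte-Carlo
standard errors are a few parts per thousand, chosen so the 3-standard-
error recovery bands are meaningfully tight.

## Known limitations

* The pipeline treats the upstream hypoxia cluster label as ground
  truth; label noise propagates directly into every rule metric.
* With 25 tumors the metrics carry no uncertainty quantification — no
  confidence intervals or significance tests are attached to rules, by
  design.
* The intensity→binary default (moderate → high) is a convention; where
  per-sample intensities are available the explicit
  `medium_resolution` column should be preferred.
* Selection can return more than 2k rules per polarity only through
  ties at the k-th rank boundary (ties are truncated deterministically,
  not expanded), and fewer when the rule pool is small.
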