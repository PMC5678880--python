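"""Parameter recovery on synthetic cohorts.

Generates cohorts from the assumed data-generating model — latent
hypoxia status with prevalence π, markers taking their
hypoxia-concordant state with per-status probabilities se/sp — runs the
full dichotomize → mine → score pipeline per replicate, and compares
the recovered single-marker rule metrics with the model's closed forms:
confidence → PPV = π·se / (π·se + (1−π)(1−sp)) and lift → PPV/π.
"""

from hyporules import SimSpec, analytic_confidence, analytic_lift, recovery_experiment

spec = SimSpec(
    n_tumors=5000,
    hypoxia_prevalence=0.32,
    sensitivity=0.875,
    specificity=0.824,
    medium_fraction=0.1,
    seed=42,
)
summary = recovery_experiment(spec, n_replicates=10)

print(summary.round(4).to_string())
print()
print(
    f"analytic PPV = {analytic_confidence(spec):.4f}, "
    f"analytic lift = {analytic_lift(spec):.4f}\n"
    "Across replicates the mined confidence and lift of each single-marker\n"
    "rule should match these closed forms within Monte-Carlo error, showing\n"
    "the pipeline recovers the generative parameters end to end (including\n"
    "intensity-based resolution of the 10% of scores emitted as the\n"
    "ambiguous 21–50% bin)."
)
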