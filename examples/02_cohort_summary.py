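"""Cohort-level summary: mean similar counts and cross-side correlations.

Runs the C-alpha analysis over 30 synthetic pairs with planted
homologous-side similarity and independent B/C labels, then prints the
per-category mean similar counts (homologous vs non-homologous side),
their ratio, and the fraction of significant sites per side.
"""

from sitesim import (
    MatchParams,
    SyntheticPairSpec,
    compute_similarity,
    generate_cohort,
    summarize,
    superpose_synthetic,
)

pairs = generate_cohort(30, SyntheticPairSpec(), seed=2024)
results = []
for pair in pairs:
    spair = superpose_synthetic(pair)
    results.append(
        compute_similarity(spair, "CA", MatchParams(rng_seed=pair.spec.seed))
    )

summary = summarize(results)
print("mean similar residues per side:")
print(summary["means"].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print("\nfraction of sites with P < 0.05:")
print(summary["significance"].to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(
    "\nThe homologous (AA) side carries several times more similar"
    "\nresidues than the unrelated (BC) side, and only the AA side is"
    "\nconsistently significant against the label-shuffling null."
)
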