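"""Compare the binding sites of one synthetic pair of complexes.

Generates a pair AB / A'C in which A and A' are close homologs (90%
class identity) while B and C carry independent residue compositions,
superimposes A' onto A, and quantifies binding-site similarity at the
all-atom, coarse-grain and C-alpha levels.
"""

from sitesim import (
    MatchParams,
    SyntheticPairSpec,
    compute_similarity,
    generate_pair,
    superpose_synthetic,
)

pair = generate_pair(SyntheticPairSpec(seed=1))
spair = superpose_synthetic(pair)
print(f"superposition rmsd {spair.alignment.rmsd:.3f} A, "
      f"irmsd {spair.alignment.irmsd:.3f} A over "
      f"{len(spair.alignment.matched_pairs)} matched residues\n")

params = MatchParams(n_bootstrap=500, rng_seed=7)
for level in ("ATOM", "CG", "CA"):
    res = compute_similarity(spair, level, params)
    print(f"level {level}")
    for role, s in res.sites.items():
        ratio = f"{s.similarity_ratio:.2f}" if s.similarity_ratio is not None else "NA"
        print(f"  {role:>6s}: {s.n_elements:3d} elements, "
              f"{s.n_superimposed:3d} superimposed, {s.n_similar:3d} similar "
              f"(ratio {ratio}), P = {s.p_value:.3f}")
print(
    "\nA low P-value means the observed number of similar elements is"
    "\nrarely reached when class labels are shuffled over the overlap:"
    "\nthe homologous A/A' sites are significantly similar, while the"
    "\nunrelated B/C sites are generally not (their labels are random)."
)
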