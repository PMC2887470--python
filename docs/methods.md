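# Methods

## Model and procedure

`sitesim` analyzes pairs of binary protein complexes AB / A′C in which A and
A′ are homologous domains binding the unrelated domains B and C at equivalent
sites.  The question addressed is whether the B and C binding sites present
similar physico-chemical groups in similar spatial positions, beyond what
label shuffling would produce.

**Interface definition.** An atom is interfacial when it is a heavy atom and
some heavy atom of the partner chain lies at Euclidean distance strictly below
the contact cutoff (default 5.0 Å).  A residue is interfacial when it owns at
least one interfacial atom.  Strict inequality at the cutoff is a fixed,
tested convention; boundary ties are measure-zero on real coordinates.
Hydrogens are parsed and retained but never participate in any distance
computation.

**Representations.** Binding sites are converted to typed point sets at three
levels:

* *all-atom* — one element per interfacial heavy atom;
* *coarse-grain* — per interfacial residue, a Cα pseudo-atom plus one
  side-chain pseudo-atom (ALA, SER, THR, VAL, LEU, ILE, ASN, ASP, CYS) or two
  (PHE, MET, PRO, TRP, HIS, TYR, GLN, GLU, LYS, ARG); glycine is Cα only.
  Side-chain pseudo-atoms sit at the centroid of their member heavy atoms
  (two-bead residues: the whole side chain; three-bead residues: split at the
  first branch/functional group).  Centroid placement is deterministic and
  testable; no force-field parameters are attached;
* *Cα* — one element per interfacial residue at its Cα.

Every element carries one of five classes: positive, negative, polar,
non-polar, hydrophobic.  The atom-level table partitions all canonical heavy
atoms of the 20 standard residues by side-chain chemistry (charged amine /
guanidinium / imidazole groups positive; carboxylates and terminal OXT
negative; backbone N/O and side-chain hydroxyl/amide/thioether polar;
Cα/C and carbons adjacent to polar or charged groups non-polar; remaining
aliphatic and aromatic carbons hydrophobic).  The residue table assigns each
residue the class of its dominant side-chain chemistry; each bead takes the
majority class of its member atoms, ties resolved toward the more polar class
(order: positive, negative, polar, non-polar, hydrophobic).  All three tables
ship as TSV data files and can be replaced wholesale (`sitesim tables`,
`--atom-table/--residue-table/--bead-table`); the pipeline's correctness does
not depend on the particular partition.

**Superposition.** Rather than depending on an external structural-alignment
binary, correspondence between A and A′ comes from a global sequence
alignment (BLOSUM62, gap open 11 / extend 1, the opening charge applied to a
gap's first position), and the rigid transform is the Kabsch least-squares
fit (SVD with a determinant guard, proper rotations only) over all matched Cα
pairs of the whole domains, not interface-only.  The fitted transform is
applied once to every atom of A′ and of C — a flag on transformed residues
guards against double application.  Reported quality measures are the rmsd
over matched Cα and the irmsd over the matched pairs whose A-side residue is
interfacial.  The sequence-guided approach is reliable for same-family
homologs (>30% identity); on structurally divergent pairs (alternate
interface conformations, insertions, poor global similarity) it can produce
different superpositions than a sequence-independent structural aligner, and
downstream counts inherit that difference.  Degenerate (collinear) Cα sets
raise an error rather than returning an arbitrary rotation.

**Counting.** After superposition, an element of one site is *superimposed*
when any element of the compared site (same representation level) lies
strictly within the match cutoff — an existence test, deliberately not a
bijection, so several elements may be matched by the same partner point.  It
is *similar* when some within-cutoff partner element carries the same class.
Match cutoffs default to 3.0 Å at the all-atom level and 4.0 Å at the
coarse-grain and Cα levels (the reduced representations describe a residue by
fewer points, so a looser criterion compensates).

**Bootstrap significance.** For each of the four binding sites in turn, the
class labels are permuted uniformly at random among that site's overlapping
(superimposed) elements — the partner's labels and all coordinates stay fixed,
so the sizes of the compared objects are preserved and the per-site geometry
(hence `n_superimposed`) is invariant by construction.  With 500 replicates
(default), the P-value is the plain proportion `#{N_rand ≥ N_obs}/n_reps`,
with no +1 smoothing: a site with `N_obs = 0` therefore reports exactly
P = 1, and a site with no superimposed element reports P = 1 without
sampling.  Permutation (composition-preserving) shuffling is the default; an
i.i.d.-redraw mode (`shuffle_mode="redraw"`, labels drawn from the overlap's
empirical class frequencies) is available for sensitivity analysis.  One
P-value is produced per site because labels are shuffled one side at a time;
shuffling both sides jointly would test a different (exchangeable-pair) null
and would not yield per-site attribution.

**Randomness.** All bootstrap streams derive from `numpy` `SeedSequence`
entropy lists `[rng_seed, level_index, role_index]`, so the four per-site
streams are independent and the whole analysis is bit-reproducible.  In
manifest-driven runs the per-pair `rng_seed` is `crc32("{run_seed}:{pair_id}")
mod 2^31`, stable under manifest reordering.

**Conservation co-localization.** The Cα-level analysis re-run with binary
labels: a residue is conserved when its normalized conservation score is
strictly below −1.0; residues without scores (e.g. chains with too few
homologs for a reliable estimate) count as unconserved.  Only conserved
residues are candidates: a conserved residue is co-localized when a conserved
partner-site residue lies within the Cα cutoff.  The bootstrap permutes the
binary labels over the overlapping positions and counts co-localized
conserved residues.  Sites with zero superimposed conserved residues are
flagged `excluded` (P = 1); such sites reduce the effective data set of the
conservation analysis and are reported rather than silently dropped.

## Pair validity filters

* both partners of a complex must come from different chains (intra-chain
  contacts are out of scope);
* "missing atomic coordinates at the binding site" is operationalized as an
  interfacial residue lacking its Cα or more than half of its canonical heavy
  atoms (the fraction is configurable); this proxy is deliberately
  conservative since no standard definition exists;
* after superposition, the B and C sites must retain at least one
  superimposed Cα-level element each — pairs whose sites barely overlap carry
  no comparable signal.

Rejections are logged per pair with their reason; every manifest entry ends
up exactly once in either the results or the rejection table.  Pair
categories (O/M/E/I/S, reflecting superposition quality and interface
mimicry) are accepted as input metadata and used only to stratify summaries;
they encode a visual assessment and are never computed.

## Synthetic data

The generator emulates the geometry the analysis cares about while making no
attempt at physical realism (no rotamers, no sterics, no energetics):

* chains are extended strands with 3.8 Å Cα spacing and a ±0.4 Å zig-zag in
  the out-of-plane axis (a perfectly straight trace would make the rigid fit
  degenerate), facing each other at 4.5 Å — inside the 5 Å contact cutoff, so
  facing residues are interfacial by construction;
* side-chain atoms are placed by fixed idealized offsets, so every residue
  carries its full canonical heavy-atom set;
* classes are controlled through residue identity: A′ copies each A residue
  with probability `similarity_aa`, otherwise redraws class and residue from
  the background composition (default (0.13, 0.12, 0.25, 0.20, 0.30) for
  positive/negative/polar/non-polar/hydrophobic, matching typical amino-acid
  frequencies grouped by the default residue table).  C copies the facing B
  residue's class with probability `similarity_bc` on the overlapping part of
  the footprint; the remaining `1 − overlap_fraction` of C faces A′ from the
  opposite side, interfacial with A′ but ≥9 Å from B — outside the B/C
  overlap.  `class_frequencies_c` optionally overrides C's composition, which
  permits disjoint-class constructions with a guaranteed zero similar count;
* Gaussian coordinate noise (default σ = 0.3 Å, roughly crystallographic
  coordinate uncertainty) and an arbitrary planted rigid transform are
  applied to complex 2; conservation labels are drawn at `conserved_fraction`
  (default 0.3, a typical interface conservation level) with A′ inheriting
  A's pattern and B, C independent, and are emitted as a ConSurf-style TSV
  with scores −1.5 / 0.0 to exercise the threshold rule exactly.

Ground truth records the planted transform, conserved residue keys, and
cross-side Cα class-agreement counts obtained by a direct geometric recount
of the emitted coordinates in the common frame (adjacent Cα sit 3.88 Å apart,
inside the 4 Å cutoff, so agreement is genuinely geometric, not positional
bookkeeping).

Because the generator's defaults are simple strands with independent or
copied labels, passing tests demonstrate the correctness and calibration of
the machinery — interface detection, representations, superposition, counting
and bootstrap — not the biological conclusions one would draw on real
complexes, where side-chain flexibility, correlated compositions and
non-ideal superpositions all matter.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| contact cutoff | 5.0 Å | heavy-atom interface definition (strict) |
| match cutoff, all-atom | 3.0 Å | superimposed/similar test after superposition |
| match cutoff, CG and Cα | 4.0 Å | looser for reduced representations |
| bootstrap replicates | 500 | resolution 1/500 on P-values |
| conservation threshold | −1.0 | normalized score strictly below ⇒ conserved |
| alignment | BLOSUM62, 11/1 | correspondence for the Kabsch fit |
| missing-atom fraction | 0.5 | interfacial-residue completeness filter |

## Test problem sizes

The statistical suites run on synthetic cohorts sized for sharp oracles: the
calibration and enumeration suites use 200 and 50 pairs with ≤8-element
overlaps, where the permutation null is exhaustively enumerable, and compare
the bootstrap to it (pooled KS at α = 0.01; per-instance three Monte-Carlo
standard errors).  The power suite uses 20 pairs per planted-similarity arm
with ~18-element overlaps: a power analysis of the permutation null shows the
all-similar probability can reach ~10⁻² for skewed compositions at the
minimum overlap of 10, whereas at ~18 diverse labels it is far below the
1/500 resolution, so the planted-copy arm must reach the minimal P-value
whenever the overlap spans at least two classes.

## Known limitations

* The five-class tables are a declared, configurable default partition, not a
  statistically optimized one; absolute similar counts (though not the
  machinery's calibration) depend on the partition chosen.
* Sequence-guided superposition can diverge from structural aligners on
  distant or conformationally variable homolog pairs.
* The all-atom null is conservative on real structures: atoms of one class
  cluster within residues and a single point can match several atoms, which
  inflates random similar counts; the coarse-grain and Cα levels are the
  more reliable readouts.
* Interface definition is distance-based only; buried-surface-area
  definitions, core/rim structure, shape complementarity and energetics are
  out of scope, so shape-driven interface mimicry is invisible to these
  representations.
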