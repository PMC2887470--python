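# sitesim

Quantify the physico-chemical similarity between protein–protein binding
sites that share a homologous binding partner, and test its significance
against a label-shuffling null.

## The problem

Homologous proteins A and A′ (same family) are sometimes observed binding two
completely unrelated proteins B and C at equivalent sites, in two binary
complexes AB and A′C.  Do B and C achieve recognition with *similar* chemistry
at the interface (suggesting convergent reuse of binding determinants), or
does each partner use its own solution?  `sitesim` answers this for a cohort of
such pairs:

1. **Interfaces.** The binding site of each domain is the set of its heavy
   atoms within 5 Å of the partner chain; a residue is interfacial when it has
   at least one such atom.
2. **Representations.** Each binding site becomes a typed point set at three
   levels of detail — every heavy atom, a reduced model (Cα plus one or two
   side-chain pseudo-atoms per residue; glycine is Cα only), or one Cα per
   residue — with every point labelled by one of five physico-chemical classes
   (positive / negative / polar / non-polar / hydrophobic).  The class tables
   are editable TSV files.
3. **Superposition.** A′ is rigidly superimposed onto A (sequence-guided
   correspondence, BLOSUM62 affine-gap alignment, then a Kabsch least-squares
   fit on matched Cα); the fitted transform carries C into the common frame.
4. **Counting.** An element of one site is *superimposed* when any element of
   the compared site lies strictly within the match cutoff (3 Å at the atomic
   level, 4 Å for the reduced and Cα levels), and *similar* when a
   within-cutoff element carries the same class.  The similarity ratio of a
   site is `n_similar / n_superimposed`.
5. **Significance.** The class labels of the site under test are permuted
   uniformly at random over its overlapping elements (500 replicates,
   partner's labels fixed), and

   ```
   P = #{ N_rand ≥ N_obs } / n_reps
   ```

   where `N` is the number of similar elements.  A site with zero observed
   similar elements has P = 1 by construction.  Four P-values result per pair:
   one per binding site (A, A′, B, C).
6. **Conservation variant.** The same machinery run with binary
   conserved/unconserved labels (normalized conservation score < −1) asks
   whether conserved interface residues of the two compared sites co-localize.

A seeded synthetic-data generator builds pairs of complexes with controllable
overlap, class composition, planted cross-side similarity, noise and a planted
rigid transform — with stored ground truth — so the entire pipeline is testable
without any structure download.

## Worked example

`python examples/01_single_pair.py` generates one synthetic pair (A′ copies
90% of A's residue classes, B and C are independent), superimposes it, and
compares the sites at all three levels:

```
superposition rmsd 0.519 A, irmsd 0.471 A over 30 matched residues

level CA
       A:  22 elements,  22 superimposed,  22 similar (ratio 1.00), P = 0.000
  Aprime:  22 elements,  22 superimposed,  22 similar (ratio 1.00), P = 0.000
       B:  20 elements,  15 superimposed,   3 similar (ratio 0.20), P = 0.886
       C:  20 elements,  14 superimposed,   3 similar (ratio 0.21), P = 0.950
```

The homologous sides are maximally similar and highly significant; the
unrelated B/C sides superimpose spatially (15 of 20 residues) yet share only
3 similar residues, a level fully compatible with the shuffled null
(P ≈ 0.9) — precisely the signature of partners using their own binding
strategies.  `examples/02_cohort_summary.py` aggregates 30 pairs and prints
the per-side mean similar counts (20.7 vs 5.6 at the Cα level, ratio 3.7) and
the fraction of significant sites per side (1.00 vs 0.03).

Other entry points: `examples/03_conservation.py` (conservation
co-localization), `examples/04_file_pipeline.py` (file-driven run), and the
`sitesim` command (`run`, `simulate`, `pair`, `tables` subcommands) for
manifest-driven analyses of real PDB files.

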