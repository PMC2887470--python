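"""Seeded generator of synthetic pairs of complexes with known ground truth.

Each synthetic pair emulates the situation under study: two binary
complexes AB and A'C in which the homologous domains A and A' bind the
unrelated domains B and C at partially overlapping sites.  The geometry
is deliberately schematic -- two parallel extended strands whose
C-alpha traces run 3.8 A apart along the chain and 4.5 A across the
interface (inside the 5 A contact cutoff), with side-chain atoms placed
by idealized offsets.  Physico-chemical classes are controlled through
the *residue identity* (and hence through the representation tables),
so the pipeline is exercised end-to-end through real PDB records rather
than through injected labels.

Controllable knobs: site sizes, the fraction of the B/C binding sites
that overlaps in space, the probability that A' (resp. C) copies the
class of its A (resp. B) counterpart, the five-class composition,
coordinate noise, a planted rigid transform on the second complex, and
the fraction of conserved residues.  The generator records ground truth
(class-agreement counts, the transform, conserved residues) alongside
the emitted structures.

Everything derives from a single integer seed; identical seeds give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .interface_detection import InterfaceParams, detect_interface
from .representations import ElementClass, RepresentationTables, classify_residue
from .structure_model import (
    Atom,
    DomainSelection,
    PairManifestEntry,
    Residue,
    write_structure,
)
from .superposition import RigidTransform, SuperposedPair, superpose_pair

#: canonical side-chain heavy atoms, in build order
SIDE_CHAIN_ATOMS = {
    "ALA": ["CB"],
    "ARG": ["CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "ASN": ["CB", "CG", "OD1", "ND2"],
    "ASP": ["CB", "CG", "OD1", "OD2"],
    "CYS": ["CB", "SG"],
    "GLN": ["CB", "CG", "CD", "OE1", "NE2"],
    "GLU": ["CB", "CG", "CD", "OE1", "OE2"],
    "GLY": [],
    "HIS": ["CB", "CG", "ND1", "CD2", "CE1", "NE2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "MET": ["CB", "CG", "SD", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "PRO": ["CB", "CG", "CD"],
    "SER": ["CB", "OG"],
    "THR": ["CB", "OG1", "CG2"],
    "TRP": ["CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "VAL": ["CB", "CG1", "CG2"],
}

CA_SPACING = 3.8  # A between consecutive C-alpha along a strand
CHAIN_SEPARATION = 4.5  # A between facing strands, inside the 5 A contact cutoff


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Generator parameters; defaults emulate a typical mid-size interface.

    ``class_frequencies`` is the background five-class composition
    (order: positive, negative, polar, nonpolar, hydrophobic) matching
    typical amino-acid frequencies grouped by the default residue
    table.  ``class_frequencies_c`` optionally overrides the draw for
    the C domain (e.g. to construct zero-agreement null pairs).
    """

    n_residues_a: int = 30
    n_residues_b: int = 20
    overlap_fraction: float = 0.7
    similarity_aa: float = 0.9
    similarity_bc: float = 0.0
    class_frequencies: tuple[float, ...] = (0.13, 0.12, 0.25, 0.20, 0.30)
    class_frequencies_c: tuple[float, ...] | None = None
    coordinate_noise_sigma: float = 0.3
    planted_transform: RigidTransform | None = None
    conserved_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap_fraction", "similarity_aa", "similarity_bc", "conserved_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for freqs in (self.class_frequencies, self.class_frequencies_c):
            if freqs is None:
                continue
            if len(freqs) != 5 or any(f < 0 for f in freqs):
                raise ValueError("class frequencies must be 5 non-negative values")
            if abs(sum(freqs) - 1.0) > 1e-9:
                raise ValueError("class frequencies must sum to 1 within 1e-9")
        if self.n_residues_b > self.n_residues_a:
            raise ValueError(
                "infeasible geometry: the B footprint cannot exceed the A scaffold "
                f"(n_residues_b={self.n_residues_b} > n_residues_a={self.n_residues_a})"
            )
        if self.coordinate_noise_sigma < 0:
            raise ValueError("coordinate_noise_sigma must be non-negative")


@dataclass
class SyntheticTruth:
    """Ground truth stored with each generated pair."""

    #: per-role count of interfacial residues whose class agrees with a
    #: partner-site residue within the C-alpha match cutoff (complex-1 frame)
    agreement_counts: dict[str, int]
    planted_transform: RigidTransform
    #: structure_id -> set of (chain_id, seq_id) of conserved residues
    conserved_keys: dict[str, set[tuple[str, str]]]


@dataclass
class SyntheticPair:
    spec: SyntheticPairSpec
    pair_id: str
    structure1: dict[str, list[Residue]]
    structure2: dict[str, list[Residue]]
    entry: PairManifestEntry
    truth: SyntheticTruth

    @property
    def structure_ids(self) -> tuple[str, str]:
        return (self.entry.a.structure_id, self.entry.aprime.structure_id)

    def conservation_frame(self) -> pd.DataFrame:
        rows = []
        for sid, structure in zip(self.structure_ids, (self.structure1, self.structure2)):
            conserved = self.truth.conserved_keys[sid]
            for chain_id, residues in structure.items():
                for res in residues:
                    rows.append(
                        {
                            "structure_id": sid,
                            "chain_id": chain_id,
                            "seq_id": res.seq_id,
                            "normalized_score": -1.5 if (chain_id, res.seq_id) in conserved else 0.0,
                        }
                    )
        return pd.DataFrame(rows)


def _class_members(tables: RepresentationTables) -> dict[ElementClass, list[str]]:
    members: dict[ElementClass, list[str]] = {k: [] for k in ElementClass}
    for aa3 in sorted(tables.residue_class):
        members[tables.residue_class[aa3]].append(aa3)
    return members


def _build_residue(aa3: str, chain_id: str, seq_num: int, ca_pos: np.ndarray) -> Residue:
    """One residue with idealized heavy-atom offsets around its C-alpha.

    All atoms stay in the strand's y-plane so facing strands keep their
    nominal separation; side chains stack outward in z.
    """
    offsets = {
        "N": np.array([-1.2, 0.0, -0.4]),
        "CA": np.array([0.0, 0.0, 0.0]),
        "C": np.array([1.2, 0.0, -0.4]),
        "O": np.array([1.8, 0.0, -1.4]),
    }
    atoms = [
        Atom(name=n, element=n[0], coord=ca_pos + offsets[n])
        for n in ("N", "CA", "C", "O")
    ]
    for j, name in enumerate(SIDE_CHAIN_ATOMS[aa3]):
        off = np.array([0.5 * (-1.0) ** j, 0.0, 1.4 + 0.65 * j])
        atoms.append(Atom(name=name, element=name[0], coord=ca_pos + off))
    return Residue(chain_id=chain_id, seq_num=seq_num, icode="", aa3=aa3, atoms=atoms)


def _build_chain(
    chain_id: str, aa3_list: list[str], ca_positions: np.ndarray
) -> list[Residue]:
    return [
        _build_residue(aa3, chain_id, i + 1, ca_positions[i])
        for i, aa3 in enumerate(aa3_list)
    ]


def _draw_residue(rng: np.random.Generator, klass: ElementClass, members) -> str:
    options = members[klass]
    return options[int(rng.integers(len(options)))]


def _ca_agreements(
    site_self, site_other, tables: RepresentationTables, cutoff: float = 4.0
) -> int:
    """Interfacial residues of one site whose class matches a partner-site
    residue with C-alpha strictly within the cutoff (complex-1 frame)."""
    count = 0
    other = [
        (r.ca.coord, classify_residue(r.aa3, tables))
        for r in site_other.residues
        if r.ca is not None
    ]
    for res in site_self.residues:
        if res.ca is None:
            continue
        klass = classify_residue(res.aa3, tables)
        for coord, oklass in other:
            if oklass == klass and float(np.linalg.norm(res.ca.coord - coord)) < cutoff:
                count += 1
                break
    return count


def generate_pair(
    spec: SyntheticPairSpec,
    pair_id: str = "pair0000",
    category: str = "O",
    tables: RepresentationTables | None = None,
) -> SyntheticPair:
    """Generate one synthetic pair of complexes with ground truth.

    Complex 1 holds chains A and B as facing strands; complex 2 holds
    A' (a noisy copy of A, classes copied with probability
    ``similarity_aa``) and C, whose first ``overlap_fraction`` of the B
    footprint coincides with B's positions while the rest faces A' from
    the opposite side (outside the B/C overlap).  The planted transform
    is applied to every atom of complex 2.
    """
    tables = tables or RepresentationTables.default()
    rng = np.random.default_rng(spec.seed)
    members = _class_members(tables)
    freqs = np.asarray(spec.class_frequencies, dtype=float)
    freqs_c = (
        np.asarray(spec.class_frequencies_c, dtype=float)
        if spec.class_frequencies_c is not None
        else freqs
    )
    classes = list(ElementClass)

    n_a, n_b = spec.n_residues_a, spec.n_residues_b

    # --- chain A: scaffold along x at y=0
    a_classes = [classes[int(k)] for k in rng.choice(5, size=n_a, p=freqs)]
    a_aa3 = [_draw_residue(rng, k, members) for k in a_classes]
    # slight zig-zag in z so the C-alpha trace is not collinear (a straight
    # line would make the rigid fit degenerate); adjacent C-alpha stay 3.88 A
    # apart, inside the 4 A match cutoff
    a_pos = np.stack(
        [
            np.arange(n_a) * CA_SPACING,
            np.zeros(n_a),
            0.4 * (-1.0) ** np.arange(n_a),
        ],
        axis=1,
    )

    # --- chain B: facing strand over the central footprint of A
    start = (n_a - n_b) // 2
    b_classes = [classes[int(k)] for k in rng.choice(5, size=n_b, p=freqs)]
    b_aa3 = [_draw_residue(rng, k, members) for k in b_classes]
    b_pos = a_pos[start : start + n_b] + np.array([0.0, CHAIN_SEPARATION, 0.0])

    # --- chain A': copy of A, classes re-drawn with prob 1 - similarity_aa
    ap_aa3 = []
    for i in range(n_a):
        if rng.random() < spec.similarity_aa:
            ap_aa3.append(a_aa3[i])
        else:
            k = classes[int(rng.choice(5, p=freqs))]
            ap_aa3.append(_draw_residue(rng, k, members))

    # --- chain C: overlapping part on B's footprint, remainder on the far side
    n_overlap = int(round(spec.overlap_fraction * n_b))
    c_aa3, c_pos_rows = [], []
    for i in range(n_b):
        if i < n_overlap:
            pos = b_pos[i]
            if rng.random() < spec.similarity_bc:
                c_aa3.append(_draw_residue(rng, b_classes[i], members))
            else:
                k = classes[int(rng.choice(5, p=freqs_c))]
                c_aa3.append(_draw_residue(rng, k, members))
        else:
            pos = b_pos[i] - np.array([0.0, 2 * CHAIN_SEPARATION, 0.0])
            k = classes[int(rng.choice(5, p=freqs_c))]
            c_aa3.append(_draw_residue(rng, k, members))
        c_pos_rows.append(pos)
    c_pos = np.stack(c_pos_rows)

    chain_a = _build_chain("A", a_aa3, a_pos)
    chain_b = _build_chain("B", b_aa3, b_pos)
    chain_ap = _build_chain("A", ap_aa3, a_pos.copy())
    chain_c = _build_chain("C", c_aa3, c_pos)

    # coordinate noise on every atom of complex 2 (deterministic order)
    if spec.coordinate_noise_sigma > 0:
        for res in chain_ap + chain_c:
            for atom in res.atoms:
                atom.coord = atom.coord + rng.normal(
                    0.0, spec.coordinate_noise_sigma, size=3
                )

    # conservation: A' inherits A's pattern (homologs), B and C independent
    a_cons = rng.random(n_a) < spec.conserved_fraction
    b_cons = rng.random(n_b) < spec.conserved_fraction
    c_cons = rng.random(n_b) < spec.conserved_fraction
    sid1, sid2 = f"{pair_id}_1", f"{pair_id}_2"
    conserved_keys = {
        sid1: {("A", chain_a[i].seq_id) for i in range(n_a) if a_cons[i]}
        | {("B", chain_b[i].seq_id) for i in range(n_b) if b_cons[i]},
        sid2: {("A", chain_ap[i].seq_id) for i in range(n_a) if a_cons[i]}
        | {("C", chain_c[i].seq_id) for i in range(n_b) if c_cons[i]},
    }

    # ground truth in the complex-1 frame (before the planted transform)
    site_a, site_b = detect_interface(chain_a, chain_b, roles=("A", "B"))
    site_ap, site_c = detect_interface(chain_ap, chain_c, roles=("Aprime", "C"))
    agreement = {
        "A": _ca_agreements(site_a, site_ap, tables),
        "Aprime": _ca_agreements(site_ap, site_a, tables),
        "B": _ca_agreements(site_b, site_c, tables),
        "C": _ca_agreements(site_c, site_b, tables),
    }

    transform = spec.planted_transform or RigidTransform.identity()
    for res in chain_ap + chain_c:
        for atom in res.atoms:
            atom.coord = transform.apply(atom.coord)

    entry = PairManifestEntry(
        pair_id=pair_id,
        a=DomainSelection(sid1, "A", "A"),
        b=DomainSelection(sid1, "B", "B"),
        aprime=DomainSelection(sid2, "A", "Aprime"),
        c=DomainSelection(sid2, "C", "C"),
        category=category,
    )
    truth = SyntheticTruth(
        agreement_counts=agreement,
        planted_transform=transform,
        conserved_keys=conserved_keys,
    )
    return SyntheticPair(
        spec=spec,
        pair_id=pair_id,
        structure1={"A": chain_a, "B": chain_b},
        structure2={"A": chain_ap, "C": chain_c},
        entry=entry,
        truth=truth,
    )


def generate_cohort(
    n_pairs: int,
    base_spec: SyntheticPairSpec | None = None,
    seed: int = 0,
    spec_sampler=None,
    tables: RepresentationTables | None = None,
) -> list[SyntheticPair]:
    """Generate ``n_pairs`` pairs with per-pair seeds derived from ``seed``.

    ``spec_sampler(rng, index, base_spec) -> SyntheticPairSpec`` may vary
    the parameters across the cohort; by default only the seed varies.
    """
    base_spec = base_spec or SyntheticPairSpec()
    pairs = []
    for i in range(n_pairs):
        child = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        if spec_sampler is not None:
            rng = np.random.default_rng(child)
            spec = spec_sampler(rng, i, base_spec)
            spec = replace(spec, seed=child)
        else:
            spec = replace(base_spec, seed=child)
        pairs.append(generate_pair(spec, pair_id=f"pair{i:04d}", tables=tables))
    return pairs


def attach_conservation(pair: SyntheticPair) -> None:
    """Set residue conservation scores in place from the stored truth."""
    for sid, structure in zip(pair.structure_ids, (pair.structure1, pair.structure2)):
        conserved = pair.truth.conserved_keys[sid]
        for chain_id, residues in structure.items():
            for res in residues:
                res.conservation_score = (
                    -1.5 if (chain_id, res.seq_id) in conserved else 0.0
                )


def superpose_synthetic(
    pair: SyntheticPair, interface_params: InterfaceParams | None = None
) -> SuperposedPair:
    """Convenience: superpose a generated pair's domains in memory."""
    return superpose_pair(
        pair.structure1["A"],
        pair.structure1["B"],
        pair.structure2["A"],
        pair.structure2["C"],
        interface_params=interface_params,
        pair_id=pair.pair_id,
        category=pair.entry.category,
    )


def write_pair(pair: SyntheticPair, directory: str | Path) -> tuple[Path, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p1 = directory / f"{pair.structure_ids[0]}.pdb"
    p2 = directory / f"{pair.structure_ids[1]}.pdb"
    write_structure(pair.structure1, p1)
    write_structure(pair.structure2, p2)
    return p1, p2


def write_cohort(pairs: list[SyntheticPair], directory: str | Path) -> dict[str, Path]:
    """Write PDB files, pair manifest, conservation table and truth table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_rows, cons_frames, truth_rows = [], [], []
    for pair in pairs:
        write_pair(pair, directory)
        e = pair.entry
        manifest_rows.append(
            {
                "pair_id": e.pair_id,
                "pdb1": e.a.structure_id,
                "chainA": e.a.chain_id,
                "chainB": e.b.chain_id,
                "pdb2": e.aprime.structure_id,
                "chainAprime": e.aprime.chain_id,
                "chainC": e.c.chain_id,
                "category": e.category,
            }
        )
        cons_frames.append(pair.conservation_frame())
        for role, count in pair.truth.agreement_counts.items():
            truth_rows.append({"pair_id": pair.pair_id, "role": role, "ca_agreements": count})
    manifest = directory / "manifest.tsv"
    pd.DataFrame(manifest_rows).to_csv(manifest, sep="\t", index=False)
    conservation = directory / "conservation.tsv"
    if cons_frames:
        pd.concat(cons_frames, ignore_index=True).to_csv(conservation, sep="\t", index=False)
    else:
        pd.DataFrame(
            columns=["structure_id", "chain_id", "seq_id", "normalized_score"]
        ).to_csv(conservation, sep="\t", index=False)
    truth = directory / "truth.tsv"
    pd.DataFrame(truth_rows, columns=["pair_id", "role", "ca_agreements"]).to_csv(
        truth, sep="\t", index=False
    )
    return {"manifest": manifest, "conservation": conservation, "truth": truth}
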