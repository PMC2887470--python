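"""Rigid superposition of homologous domains.

The homologous partners A and A' of a pair of complexes are brought into
a common frame by (1) globally aligning their amino-acid sequences
(BLOSUM62, affine gaps) to establish residue correspondence, and
(2) least-squares fitting a proper rotation + translation (Kabsch) on
the matched C-alpha coordinates.  The fitted transform is then applied
to every atom of A' *and* of its partner C, while complex AB stays
fixed.

This sequence-guided approach assumes the two domains are close
homologs (same family, >30% identity), where sequence alignment gives a
reliable correspondence; structurally divergent pairs may superimpose
differently than a sequence-independent structural aligner would.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .interface_detection import InterfaceParams, detect_interface
from .structure_model import Residue

logger = logging.getLogger(__name__)


class SuperpositionError(ValueError):
    """Raised when two domains cannot be superimposed."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: x -> R_self (R_other x + t_other) + t_self."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))


@dataclass
class DomainAlignment:
    """Residue correspondence between A and A' plus fit quality."""

    matched_pairs: list[tuple[tuple[str, str], tuple[str, str]]]
    rmsd: float
    irmsd: float | None = None


AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def _make_aligner(open_gap: float, extend_gap: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    aligner.mode = "global"
    return aligner


def align_sequences(
    dom_a: list[Residue],
    dom_aprime: list[Residue],
    matrix: str = "BLOSUM62",
    open_gap: float = 11.0,
    extend_gap: float = 1.0,
) -> list[tuple[Residue, Residue]]:
    """Global sequence alignment of two domains; returns matched residue pairs.

    Gap positions are excluded.  Raises :class:`SuperpositionError` when
    fewer than three positions align (no superposition possible).
    """
    if len(dom_a) < 3 or len(dom_aprime) < 3:
        raise SuperpositionError("both domains need at least 3 residues")
    s1 = "".join(AA3_TO_1.get(r.aa3, "X") for r in dom_a)
    s2 = "".join(AA3_TO_1.get(r.aa3, "X") for r in dom_aprime)
    aligner = _make_aligner(open_gap, extend_gap, matrix)
    aln = aligner.align(s1, s2)[0]
    pairs: list[tuple[Residue, Residue]] = []
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for off in range(a_end - a_start):
            pairs.append((dom_a[a_start + off], dom_aprime[b_start + off]))
    if len(pairs) < 3:
        raise SuperpositionError(f"only {len(pairs)} residues aligned; need >= 3")
    return pairs


def fit_transform(
    ref_coords: np.ndarray, mov_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Kabsch least-squares fit of ``mov_coords`` onto ``ref_coords``.

    Both arrays are (n, 3) in correspondence order.  Returns the proper
    rigid transform minimizing the RMSD and the achieved RMSD.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mov = np.asarray(mov_coords, dtype=float)
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = ref.shape[0]
    if n < 3:
        raise SuperpositionError("need at least 3 points to fit a transform")
    ref_mean = ref.mean(axis=0)
    mov_mean = mov.mean(axis=0)
    P = mov - mov_mean
    Q = ref - ref_mean
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[0] > 0 and S[1] / S[0] < 1e-8:
        raise SuperpositionError("degenerate (collinear) point set; transform not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_mean - R @ mov_mean
    transform = RigidTransform(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((transform.apply(mov) - ref) ** 2, axis=1))))
    return transform, rmsd


def apply_transform(residues: list[Residue], transform: RigidTransform) -> list[Residue]:
    """Return transformed deep copies; refuses residues already transformed once."""
    if any(r.transformed for r in residues):
        raise SuperpositionError("residues were already transformed once")
    out = []
    for res in residues:
        new = res.copy()
        for atom in new.atoms:
            atom.coord = transform.apply(atom.coord)
        new.transformed = True
        out.append(new)
    return out


@dataclass
class SuperposedPair:
    """Two binary complexes in a common frame (A/B fixed, A'/C transformed)."""

    a: list[Residue]
    b: list[Residue]
    aprime: list[Residue]
    c: list[Residue]
    transform: RigidTransform
    alignment: DomainAlignment
    pair_id: str | None = None
    category: str = "unknown"


def superpose_pair(
    dom_a: list[Residue],
    dom_b: list[Residue],
    dom_aprime: list[Residue],
    dom_c: list[Residue],
    interface_params: InterfaceParams | None = None,
    pair_id: str | None = None,
    category: str = "unknown",
    **align_kwargs,
) -> SuperposedPair:
    """Superimpose A' onto A and carry C along.

    The transform is fitted on matched C-alpha pairs over the whole
    domains; ``rmsd`` is reported over all matched pairs and ``irmsd``
    over the matched pairs whose A-side residue is interfacial with B.
    """
    matched = align_sequences(dom_a, dom_aprime, **align_kwargs)
    with_ca = [(ra, rb) for ra, rb in matched if ra.ca is not None and rb.ca is not None]
    if len(with_ca) < 3:
        raise SuperpositionError("fewer than 3 matched residues have C-alpha atoms")
    ref = np.asarray([ra.ca.coord for ra, _ in with_ca])
    mov = np.asarray([rb.ca.coord for _, rb in with_ca])
    transform, rmsd = fit_transform(ref, mov)

    site_a, _site_b = detect_interface(dom_a, dom_b, interface_params, roles=("A", "B"))
    interfacial = set(site_a.residue_keys)
    moved = transform.apply(mov)
    sq = np.sum((moved - ref) ** 2, axis=1)
    imask = np.asarray([ra.key in interfacial for ra, _ in with_ca])
    irmsd = float(np.sqrt(np.mean(sq[imask]))) if imask.any() else None

    alignment = DomainAlignment(
        matched_pairs=[(ra.key, rb.key) for ra, rb in matched],
        rmsd=rmsd,
        irmsd=irmsd,
    )
    return SuperposedPair(
        a=dom_a,
        b=dom_b,
        aprime=apply_transform(dom_aprime, transform),
        c=apply_transform(dom_c, transform),
        transform=transform,
        alignment=alignment,
        pair_id=pair_id,
        category=category,
    )
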