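"""Coordinate-file handling and the atom/residue/chain data model.

Structures are read from PDB-format files and held as a plain mapping
``chain_id -> list of Residue``.  Parsing applies the conventions used
throughout the package:

* water and non-amino-acid HETATM groups are excluded;
* selenomethionine (MSE) is mapped to MET (SE renamed to SD); other
  non-standard residues are dropped with a logged warning;
* alternate locations are resolved to the highest-occupancy conformer
  (ties broken in favour of the first record encountered, i.e. altloc
  'A' in conventional files);
* hydrogens are retained but flagged, so that downstream distance
  computations can restrict themselves to heavy atoms;
* only one model of a multi-model file is used (the first by default).

Residues keep their author identifiers (chain, number, insertion code);
nothing is renumbered, so external tables such as per-residue
conservation scores can be joined directly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: Non-standard residues mapped onto a standard parent (residue, atom renames).
NONSTANDARD_MAP = {"MSE": ("MET", {"SE": "SD"})}

ROLES = ("A", "Aprime", "B", "C")


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


class ChainNotFoundError(KeyError):
    """Raised when a manifest names a chain absent from the structure."""


@dataclass
class Atom:
    """A single atom: name, element and Cartesian coordinate in Angstrom."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coord must be 3 finite components")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass
class Residue:
    """One residue identified by author chain / number / insertion code."""

    chain_id: str
    seq_num: int
    icode: str
    aa3: str
    atoms: list[Atom] = field(default_factory=list)
    conservation_score: float | None = None
    #: set once a rigid transform has been applied (guards double application)
    transformed: bool = False

    @property
    def seq_id(self) -> str:
        """Author residue number plus insertion code, e.g. ``'42'`` or ``'42A'``."""
        return f"{self.seq_num}{self.icode}"

    @property
    def key(self) -> tuple[str, str]:
        return (self.chain_id, self.seq_id)

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_AA3

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def copy(self) -> "Residue":
        return replace(
            self,
            atoms=[replace(a, coord=a.coord.copy()) for a in self.atoms],
        )


@dataclass(frozen=True)
class DomainSelection:
    """Names one domain of a binary complex: structure, chain and ABAC role."""

    structure_id: str
    chain_id: str
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class PairManifestEntry:
    """One row of the pair manifest: complexes AB and A'C plus metadata.

    The category label (O/M/E/I/S) is carried as metadata only and used
    to stratify summaries; it is never computed.
    """

    pair_id: str
    a: DomainSelection
    b: DomainSelection
    aprime: DomainSelection
    c: DomainSelection
    category: str = "unknown"

    def __post_init__(self) -> None:
        roles = (self.a.role, self.b.role, self.aprime.role, self.c.role)
        if roles != ("A", "B", "Aprime", "C"):
            raise ValueError(f"manifest entry {self.pair_id}: roles {roles} malformed")

    @property
    def complex1(self) -> tuple[DomainSelection, DomainSelection]:
        return (self.a, self.b)

    @property
    def complex2(self) -> tuple[DomainSelection, DomainSelection]:
        return (self.aprime, self.c)


def _resolve_altlocs(raw_atoms: list[tuple[str, str, float, np.ndarray, str]]) -> list[Atom]:
    """Keep one atom per name: the highest-occupancy altloc, ties -> first seen."""
    best: dict[str, tuple[float, int]] = {}
    out: dict[str, Atom] = {}
    for i, (name, element, occ, coord, _altloc) in enumerate(raw_atoms):
        if name not in best or occ > best[name][0]:
            best[name] = (occ, i)
            out[name] = Atom(name=name, element=element, coord=coord, occupancy=occ)
    # preserve first-encounter order of atom names
    seen: list[str] = []
    for name, *_ in raw_atoms:
        if name not in seen:
            seen.append(name)
    return [out[n] for n in seen]


def read_structure(path: str | Path, model_index: int = 0) -> dict[str, list[Residue]]:
    """Parse a PDB file into ``chain_id -> [Residue, ...]``.

    Waters and non-amino-acid ligands are excluded; chains left empty by
    the filters are absent from the mapping.  Only ``model_index`` (the
    first model by default) is read.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise StructureParseError(f"could not parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"structure file {path} contains no models")
    if model_index >= len(st):
        raise StructureParseError(
            f"{path}: model index {model_index} out of range ({len(st)} models)"
        )
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water():
                continue
            name = res.name
            renames: dict[str, str] = {}
            if name in NONSTANDARD_MAP:
                name, renames = NONSTANDARD_MAP[res.name]
            if name not in STANDARD_AA3:
                logger.warning(
                    "%s: dropping non-amino-acid residue %s %s%s%s",
                    path.name, res.name, chain.name, res.seqid.num,
                    res.seqid.icode.strip(),
                )
                continue
            raw = []
            for atom in res:
                aname = renames.get(atom.name, atom.name)
                element = atom.element.name
                if atom.name in renames:
                    element = "S"
                raw.append(
                    (aname, element, float(atom.occ),
                     np.array([atom.pos.x, atom.pos.y, atom.pos.z]), atom.altloc)
                )
            atoms = _resolve_altlocs(raw)
            if not atoms:
                continue
            residues.append(
                Residue(
                    chain_id=chain.name,
                    seq_num=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    aa3=name,
                    atoms=atoms,
                )
            )
        if residues:
            chains.setdefault(chain.name, []).extend(residues)
    return chains


def write_structure(chains: Mapping[str, Sequence[Residue]], path: str | Path) -> None:
    """Write the in-memory model back to standard PDB ATOM records."""
    serial = 0
    lines: list[str] = []
    for chain_id in chains:
        for res in chains[chain_id]:
            for atom in res.atoms:
                serial += 1
                name = atom.name
                if len(name) < 4 and len(atom.element) == 1:
                    name = " " + name
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.aa3:<3s} {chain_id:1s}"
                    f"{res.seq_num:4d}{res.icode or ' ':1s}   "
                    f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
                    f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_domain(structure: Mapping[str, list[Residue]], sel: DomainSelection) -> list[Residue]:
    """Return the residues of the chain named by ``sel``, in author order."""
    if sel.chain_id not in structure:
        raise ChainNotFoundError(
            f"{sel.structure_id}: chain {sel.chain_id!r} not found; "
            f"available chains: {sorted(structure)}"
        )
    return structure[sel.chain_id]


MANIFEST_COLUMNS = [
    "pair_id", "pdb1", "chainA", "chainB", "pdb2", "chainAprime", "chainC", "category",
]


def read_manifest(path: str | Path) -> list[PairManifestEntry]:
    """Read the pair manifest (TSV) into manifest entries."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = [c for c in MANIFEST_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            PairManifestEntry(
                pair_id=row.pair_id,
                a=DomainSelection(row.pdb1, row.chainA, "A"),
                b=DomainSelection(row.pdb1, row.chainB, "B"),
                aprime=DomainSelection(row.pdb2, row.chainAprime, "Aprime"),
                c=DomainSelection(row.pdb2, row.chainC, "C"),
                category=getattr(row, "category", "unknown"),
            )
        )
    return entries


def read_conservation(path: str | Path) -> dict[tuple[str, str, str], float]:
    """Read a normalized per-residue conservation table.

    Expected TSV columns: structure_id, chain_id, seq_id, normalized_score.
    """
    df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain_id": str, "seq_id": str})
    table: dict[tuple[str, str, str], float] = {}
    for row in df.itertuples(index=False):
        table[(row.structure_id, row.chain_id, str(row.seq_id))] = float(row.normalized_score)
    return table


def apply_conservation(
    structure: Mapping[str, list[Residue]],
    structure_id: str,
    table: Mapping[tuple[str, str, str], float],
) -> None:
    """Attach conservation scores to residues in place.

    Residues without an entry keep ``conservation_score = None``, which the
    statistics layer treats as unconserved.
    """
    for chain_id, residues in structure.items():
        for res in residues:
            score = table.get((structure_id, chain_id, res.seq_id))
            if score is not None:
                res.conservation_score = score


_SEQ_ID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def split_seq_id(seq_id: str) -> tuple[int, str]:
    """Split an author seq_id string like ``'42A'`` into (42, 'A')."""
    m = _SEQ_ID_RE.match(seq_id)
    if not m:
        raise ValueError(f"malformed residue identifier {seq_id!r}")
    return int(m.group(1)), m.group(2)
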