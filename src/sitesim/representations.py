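"""Typed point-set representations of binding sites.

A binding site can be expressed at three levels of detail, each as a set
of 3-D points carrying one of five physico-chemical class labels
(positive, negative, polar, non-polar, hydrophobic):

* ``ATOM`` -- one element per interfacial heavy atom, class from a
  per-(residue, atom) lookup table;
* ``CG`` -- a reduced model with one pseudo-atom at the C-alpha plus one
  or two side-chain pseudo-atoms placed at the centroid of their member
  heavy atoms (glycine is C-alpha only);
* ``CA`` -- one element per interfacial residue at its C-alpha, class
  from a per-residue table.

The class tables ship as editable TSV files under ``sitesim/data`` so a
user can substitute their own partition without touching code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum, IntEnum
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .interface_detection import BindingSite
from .structure_model import Residue

logger = logging.getLogger(__name__)


class ElementClass(IntEnum):
    """The five physico-chemical groups, ordered from most to least polar."""

    POSITIVE = 0
    NEGATIVE = 1
    POLAR = 2
    NONPOLAR = 3
    HYDROPHOBIC = 4


N_CLASSES = len(ElementClass)


class Level(str, Enum):
    ATOM = "ATOM"
    CG = "CG"
    CA = "CA"


@dataclass(frozen=True)
class TypedElement:
    """A 3-D point with a class label and provenance."""

    coord: tuple[float, float, float]
    klass: ElementClass
    level: Level
    residue_key: tuple[str, str]
    atom_name: str | None = None
    bead_index: int | None = None


@dataclass(frozen=True)
class RepresentationTables:
    """The three class tables driving every representation level."""

    atom_class: dict[tuple[str, str], ElementClass]
    residue_class: dict[str, ElementClass]
    cg_beads: dict[str, list[tuple[int, tuple[str, ...], ElementClass]]]

    @classmethod
    def from_files(
        cls, atom_tsv: str | Path, residue_tsv: str | Path, bead_tsv: str | Path
    ) -> "RepresentationTables":
        adf = pd.read_csv(atom_tsv, sep="\t")
        atom_class = {
            (r.aa3, r.atom): ElementClass[r.klass]
            for r in adf.rename(columns={"class": "klass"}).itertuples(index=False)
        }
        rdf = pd.read_csv(residue_tsv, sep="\t")
        residue_class = {
            r.aa3: ElementClass[r.klass]
            for r in rdf.rename(columns={"class": "klass"}).itertuples(index=False)
        }
        bdf = pd.read_csv(bead_tsv, sep="\t")
        cg_beads: dict[str, list[tuple[int, tuple[str, ...], ElementClass]]] = {}
        for r in bdf.rename(columns={"class": "klass"}).itertuples(index=False):
            cg_beads.setdefault(r.aa3, []).append(
                (int(r.bead_index), tuple(r.members.split(",")), ElementClass[r.klass])
            )
        for aa3 in cg_beads:
            cg_beads[aa3].sort(key=lambda b: b[0])
        return cls(atom_class=atom_class, residue_class=residue_class, cg_beads=cg_beads)

    @classmethod
    def default(cls) -> "RepresentationTables":
        return _default_tables()


@lru_cache(maxsize=1)
def _default_tables() -> RepresentationTables:
    data = resources.files("sitesim") / "data"
    return RepresentationTables.from_files(
        str(data / "atom_classes.tsv"),
        str(data / "residue_classes.tsv"),
        str(data / "cg_beads.tsv"),
    )


def classify_atom(aa3: str, atom_name: str, tables: RepresentationTables | None = None) -> ElementClass:
    """Class of one heavy atom.  Terminal OXT is negative for every residue."""
    tables = tables or RepresentationTables.default()
    if atom_name == "OXT":
        return ElementClass.NEGATIVE
    try:
        return tables.atom_class[(aa3, atom_name)]
    except KeyError:
        raise KeyError(f"no atom class for residue {aa3!r} atom {atom_name!r}") from None


def classify_residue(aa3: str, tables: RepresentationTables | None = None) -> ElementClass:
    tables = tables or RepresentationTables.default()
    try:
        return tables.residue_class[aa3]
    except KeyError:
        raise KeyError(f"no residue class for {aa3!r}") from None


def canonical_heavy_atoms(aa3: str, tables: RepresentationTables | None = None) -> set[str]:
    """Canonical heavy-atom names of a standard residue (OXT excluded)."""
    tables = tables or RepresentationTables.default()
    names = {atom for (res, atom) in tables.atom_class if res == aa3}
    if not names:
        raise KeyError(f"unknown residue {aa3!r}")
    return names


#: tie-break order for deriving a bead class from its member atoms
_POLARITY_ORDER = [
    ElementClass.POSITIVE,
    ElementClass.NEGATIVE,
    ElementClass.POLAR,
    ElementClass.NONPOLAR,
    ElementClass.HYDROPHOBIC,
]


def derive_bead_class(member_classes: list[ElementClass]) -> ElementClass:
    """Majority class of the member atoms; ties go to the more polar class."""
    if not member_classes:
        raise ValueError("bead with no member atoms")
    counts = {k: 0 for k in ElementClass}
    for k in member_classes:
        counts[k] += 1
    best = max(counts.values())
    for k in _POLARITY_ORDER:
        if counts[k] == best:
            return k
    raise AssertionError("unreachable")


def _atom_elements(site: BindingSite, tables: RepresentationTables) -> list[TypedElement]:
    out = []
    for res, atom in site.atoms:
        klass = classify_atom(res.aa3, atom.name, tables)
        out.append(
            TypedElement(
                coord=tuple(atom.coord),
                klass=klass,
                level=Level.ATOM,
                residue_key=res.key,
                atom_name=atom.name,
            )
        )
    return out


def _ca_element(res: Residue, tables: RepresentationTables) -> TypedElement | None:
    ca = res.ca
    if ca is None:
        logger.warning("residue %s/%s lacks CA; skipped at CA level", res.chain_id, res.seq_id)
        return None
    return TypedElement(
        coord=tuple(ca.coord),
        klass=classify_residue(res.aa3, tables),
        level=Level.CA,
        residue_key=res.key,
    )


def _cg_elements(res: Residue, tables: RepresentationTables) -> list[TypedElement]:
    if res.ca is None:
        logger.warning("residue %s/%s lacks CA; skipped at CG level", res.chain_id, res.seq_id)
        return []
    beads = tables.cg_beads.get(res.aa3)
    if beads is None:
        logger.warning("no bead definition for %s; residue skipped", res.aa3)
        return []
    out = []
    for bead_index, members, klass in beads:
        coords = [res.atom(m).coord for m in members if res.atom(m) is not None]
        if not coords:
            logger.warning(
                "residue %s/%s: bead %d has no member atoms present; skipped",
                res.chain_id, res.seq_id, bead_index,
            )
            continue
        centroid = np.mean(np.asarray(coords), axis=0)
        out.append(
            TypedElement(
                coord=tuple(centroid),
                klass=klass,
                level=Level.CG,
                residue_key=res.key,
                bead_index=bead_index,
            )
        )
    return out


def build_representation(
    site: BindingSite, level: Level, tables: RepresentationTables | None = None
) -> list[TypedElement]:
    """Convert a binding site into typed elements at the requested level."""
    tables = tables or RepresentationTables.default()
    level = Level(level)
    if level is Level.ATOM:
        return _atom_elements(site, tables)
    out: list[TypedElement] = []
    for res in site.residues:
        if level is Level.CA:
            el = _ca_element(res, tables)
            if el is not None:
                out.append(el)
        else:
            out.extend(_cg_elements(res, tables))
    return out


def elements_to_arrays(elements: list[TypedElement]) -> tuple[np.ndarray, np.ndarray]:
    """Split elements into an (n, 3) coordinate array and an (n,) label array."""
    if not elements:
        return np.empty((0, 3)), np.empty((0,), dtype=int)
    coords = np.asarray([e.coord for e in elements], dtype=float)
    labels = np.asarray([int(e.klass) for e in elements], dtype=int)
    return coords, labels
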