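"""End-to-end orchestration: validate pairs, superpose, compare, summarize.

The pipeline consumes a pair manifest plus a directory of PDB files
(and optionally a conservation table), applies the validity filters,
and emits one similarity row per (pair, level, binding site) together
with cohort summaries and a plain-text run report.  Re-running with an
identical configuration is bit-identical.

Validity filters applied to each pair:

* the two partners of each complex must come from different chains
  (intra-chain interactions are not considered);
* no interfacial residue may be grossly incomplete -- the "missing
  atomic coordinates at the binding site" rule is operationalized as
  missing C-alpha, or missing more than half of the canonical heavy
  atoms (the fraction is configurable);
* after superposition the B/C side must retain at least one
  superimposed element at the C-alpha level (pairs whose binding sites
  barely overlap carry no comparable signal).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__
from .interface_detection import InterfaceParams, detect_interface
from .representations import (
    Level,
    RepresentationTables,
    build_representation,
    canonical_heavy_atoms,
)
from .similarity_stats import (
    MatchParams,
    SimilarityResult,
    compute_similarity,
    conservation_colocalization,
    count_matches,
    results_to_frame,
    summarize,
)
from .structure_model import (
    ChainNotFoundError,
    PairManifestEntry,
    Residue,
    StructureParseError,
    apply_conservation,
    read_conservation,
    read_manifest,
    read_structure,
    select_domain,
    write_structure,
)
from .superposition import SuperposedPair, SuperpositionError, superpose_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    manifest: Path
    structure_dir: Path
    out_dir: Path
    conservation: Path | None = None
    interface_params: InterfaceParams = field(default_factory=InterfaceParams)
    match_params: MatchParams = field(default_factory=MatchParams)
    tables: RepresentationTables | None = None
    seed: int = 0
    levels: tuple[str, ...] = ("ATOM", "CG", "CA")
    missing_atom_fraction: float = 0.5
    write_superposed: bool = False

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.structure_dir = Path(self.structure_dir)
        self.out_dir = Path(self.out_dir)
        for p, desc in ((self.manifest, "manifest"), (self.structure_dir, "structure_dir")):
            if not p.exists():
                raise FileNotFoundError(f"{desc} not found: {p}")
        if self.conservation is not None:
            self.conservation = Path(self.conservation)
            if not self.conservation.exists():
                raise FileNotFoundError(f"conservation table not found: {self.conservation}")


def pair_seed(run_seed: int, pair_id: str) -> int:
    """Stable per-pair bootstrap seed (CRC32 of run seed + pair id)."""
    return zlib.crc32(f"{run_seed}:{pair_id}".encode()) % (2**31)


def _incomplete_interfacial_residues(
    residues: list[Residue], fraction: float
) -> list[str]:
    bad = []
    for res in residues:
        if res.ca is None:
            bad.append(f"{res.chain_id}/{res.seq_id} (no CA)")
            continue
        try:
            canonical = canonical_heavy_atoms(res.aa3)
        except KeyError:
            continue
        present = {a.name for a in res.heavy_atoms if a.name in canonical}
        if len(present) < (1.0 - fraction) * len(canonical):
            bad.append(f"{res.chain_id}/{res.seq_id} ({len(present)}/{len(canonical)} atoms)")
    return bad


def validate_pair(
    entry: PairManifestEntry,
    structures: dict[str, dict[str, list[Residue]]],
    interface_params: InterfaceParams | None = None,
    match_params: MatchParams | None = None,
    missing_atom_fraction: float = 0.5,
) -> tuple[SuperposedPair | None, str | None]:
    """Apply the pair validity filters.

    Returns ``(superposed_pair, None)`` on acceptance or
    ``(None, reason)`` on rejection.  The superposition computed for
    the overlap check is returned so callers do not repeat it.
    """
    interface_params = interface_params or InterfaceParams()
    match_params = match_params or MatchParams()

    if entry.a.chain_id == entry.b.chain_id:
        return None, "intra-chain interaction in complex AB"
    if entry.aprime.chain_id == entry.c.chain_id:
        return None, "intra-chain interaction in complex A'C"

    try:
        dom = {
            "A": select_domain(structures[entry.a.structure_id], entry.a),
            "B": select_domain(structures[entry.b.structure_id], entry.b),
            "Aprime": select_domain(structures[entry.aprime.structure_id], entry.aprime),
            "C": select_domain(structures[entry.c.structure_id], entry.c),
        }
    except ChainNotFoundError as exc:
        return None, f"chain selection failed: {exc}"

    for (d1, d2, label) in (("A", "B", "AB"), ("Aprime", "C", "A'C")):
        try:
            s1, s2 = detect_interface(dom[d1], dom[d2], interface_params)
        except ValueError as exc:
            return None, f"interface detection failed for {label}: {exc}"
        if s1.is_empty or s2.is_empty:
            return None, f"no interface found in complex {label}"
        bad = _incomplete_interfacial_residues(
            s1.residues + s2.residues, missing_atom_fraction
        )
        if bad:
            return None, f"missing atomic coordinates at the {label} binding site: " + "; ".join(bad[:3])

    try:
        spair = superpose_pair(
            dom["A"], dom["B"], dom["Aprime"], dom["C"],
            interface_params=interface_params,
            pair_id=entry.pair_id,
            category=entry.category,
        )
    except SuperpositionError as exc:
        return None, f"superposition failed: {exc}"

    site_b = detect_interface(spair.a, spair.b, interface_params, roles=("A", "B"))[1]
    site_c = detect_interface(spair.aprime, spair.c, interface_params, roles=("Aprime", "C"))[1]
    tables = RepresentationTables.default()
    eb = build_representation(site_b, Level.CA, tables)
    ec = build_representation(site_c, Level.CA, tables)
    n_sup_b, _, n_sup_c, _ = count_matches(eb, ec, match_params.match_cutoff_ca)
    if n_sup_b == 0 or n_sup_c == 0:
        return None, "no superimposed elements on the B/C side"
    return spair, None


@dataclass
class RunResult:
    results: pd.DataFrame
    summary: dict[str, pd.DataFrame]
    rejections: pd.DataFrame
    report: str


def run_pipeline(config: RunConfig) -> RunResult:
    """Run the full analysis described by ``config`` and write outputs."""
    entries = read_manifest(config.manifest)
    if not entries:
        raise ValueError(f"manifest {config.manifest} contains no pairs")
    tables = config.tables or RepresentationTables.default()
    conservation = (
        read_conservation(config.conservation) if config.conservation else None
    )

    structures: dict[str, dict[str, list[Residue]]] = {}
    rejection_rows = []
    results: list[SimilarityResult] = []
    report_lines = [
        f"sitesim {__version__}",
        f"manifest: {config.manifest}",
        f"structures: {config.structure_dir}",
        f"conservation: {config.conservation or '(none)'}",
        f"seed: {config.seed}",
        f"levels: {','.join(config.levels)}",
        f"contact_cutoff: {config.interface_params.contact_cutoff}",
        f"match_cutoffs: atom={config.match_params.match_cutoff_atom} "
        f"cg={config.match_params.match_cutoff_cg} ca={config.match_params.match_cutoff_ca}",
        f"n_bootstrap: {config.match_params.n_bootstrap}",
        f"shuffle_mode: {config.match_params.shuffle_mode}",
        "alignment: BLOSUM62, gap open 11, gap extend 1",
        "",
    ]

    n_accepted = 0
    for entry in entries:
        reason = None
        for sel in (entry.a, entry.b, entry.aprime, entry.c):
            sid = sel.structure_id
            if sid in structures:
                continue
            path = config.structure_dir / f"{sid}.pdb"
            try:
                structures[sid] = read_structure(path)
                if conservation:
                    apply_conservation(structures[sid], sid, conservation)
            except StructureParseError as exc:
                reason = f"unloadable structure: {exc}"
                structures.pop(sid, None)
                break
        spair = None
        if reason is None:
            spair, reason = validate_pair(
                entry,
                structures,
                config.interface_params,
                config.match_params,
                config.missing_atom_fraction,
            )
        if spair is None:
            rejection_rows.append({"pair_id": entry.pair_id, "reason": reason})
            report_lines.append(f"REJECT {entry.pair_id}: {reason}")
            logger.info("rejected pair %s: %s", entry.pair_id, reason)
            continue

        n_accepted += 1
        params = replace(config.match_params, rng_seed=pair_seed(config.seed, entry.pair_id))
        for level in config.levels:
            results.append(
                compute_similarity(
                    spair, level, params, tables, config.interface_params
                )
            )
        if conservation is not None:
            results.append(
                conservation_colocalization(
                    spair, params, interface_params=config.interface_params
                )
            )
        t = spair.transform
        report_lines.append(
            f"ACCEPT {entry.pair_id}: rmsd={spair.alignment.rmsd:.3f} "
            f"irmsd={'%.3f' % spair.alignment.irmsd if spair.alignment.irmsd is not None else 'NA'} "
            f"matched={len(spair.alignment.matched_pairs)}"
        )
        report_lines.append(
            "  transform: "
            + " ".join(
                f"{v: .6f}"
                for row in (t.rotation.tolist() + [t.translation.tolist()])
                for v in row
            )
        )
        if config.write_superposed:
            sup_dir = config.out_dir / "superposed"
            sup_dir.mkdir(parents=True, exist_ok=True)
            write_structure(
                {"A": spair.aprime, "C": spair.c},
                sup_dir / f"{entry.aprime.structure_id}_superposed.pdb",
            )

    if n_accepted == 0:
        raise ValueError("no pair passed validation; nothing to analyze")

    frame = results_to_frame(results)
    rejections = pd.DataFrame(rejection_rows, columns=["pair_id", "reason"])
    try:
        summary = summarize(frame)
    except ValueError:
        summary = {}

    config.out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(config.out_dir / "results.tsv", sep="\t", index=False)
    rejections.to_csv(config.out_dir / "rejections.tsv", sep="\t", index=False)
    for name, df in summary.items():
        df.to_csv(config.out_dir / f"summary_{name}.tsv", sep="\t", index=False)
    report_lines.append("")
    report_lines.append(f"accepted: {n_accepted} / {len(entries)} pairs")
    report = "\n".join(report_lines) + "\n"
    (config.out_dir / "report.txt").write_text(report)
    return RunResult(results=frame, summary=summary, rejections=rejections, report=report)
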