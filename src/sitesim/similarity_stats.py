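"""Superimposed/similar element counting and bootstrap significance.

After rigid superposition of the homologous domains, an element (atom,
pseudo-atom or C-alpha) of one binding site is

* *superimposed* when ANY element of the compared site lies strictly
  within the match cutoff (an existence test, not a one-to-one
  matching: several elements may be matched by the same point), and
* *similar* when some within-cutoff element carries the same
  physico-chemical class.

The similarity ratio of a site is n_similar / n_superimposed.

Significance is assessed with a label-shuffling bootstrap: the class
labels of the site under test are permuted uniformly at random among
its *overlapping* (superimposed) elements, the partner site's labels
staying fixed, and the number of similar elements is recounted.  The
P-value is the plain proportion of replicates whose count reaches the
observed one, #{N_rand >= N_obs} / n_reps, so a site with zero observed
similar elements has P = 1 by construction (the null cannot produce a
smaller count).  Geometry is untouched by the shuffle, so the sizes of
the compared objects are preserved.  Four P-values are produced per
pair of complexes: one per binding site (A, A', B, C).

The same machinery, with binary conserved/unconserved labels and
counting restricted to the conserved class, drives the conservation
co-localization analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .interface_detection import InterfaceParams, detect_interface
from .representations import (
    Level,
    N_CLASSES,
    RepresentationTables,
    TypedElement,
    build_representation,
    elements_to_arrays,
)
from .superposition import SuperposedPair

ROLE_INDEX = {"A": 0, "Aprime": 1, "B": 2, "C": 3}
LEVEL_INDEX = {"ATOM": 0, "CG": 1, "CA": 2, "CONS": 3}

#: roles belonging to the homologous (A/A') and non-homologous (B/C) sides
SIDE_OF_ROLE = {"A": "AA", "Aprime": "AA", "B": "BC", "C": "BC"}


@dataclass(frozen=True)
class MatchParams:
    """Match cutoffs (strict, Angstrom) and bootstrap settings."""

    match_cutoff_atom: float = 3.0
    match_cutoff_cg: float = 4.0
    match_cutoff_ca: float = 4.0
    n_bootstrap: int = 500
    rng_seed: int = 0
    shuffle_mode: str = "permute"  # or "redraw" (i.i.d. from label frequencies)

    def __post_init__(self) -> None:
        for c in (self.match_cutoff_atom, self.match_cutoff_cg, self.match_cutoff_ca):
            if c <= 0:
                raise ValueError("match cutoffs must be positive")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if self.shuffle_mode not in ("permute", "redraw"):
            raise ValueError("shuffle_mode must be 'permute' or 'redraw'")

    def cutoff_for(self, level: Level | str) -> float:
        level = Level(level)
        return {
            Level.ATOM: self.match_cutoff_atom,
            Level.CG: self.match_cutoff_cg,
            Level.CA: self.match_cutoff_ca,
        }[level]


@dataclass
class SiteSimilarity:
    """Counts, ratio and bootstrap P-value for one binding site."""

    role: str
    n_elements: int
    n_superimposed: int
    n_similar: int
    p_value: float
    excluded: bool = False

    @property
    def similarity_ratio(self) -> float | None:
        if self.n_superimposed == 0:
            return None
        return self.n_similar / self.n_superimposed

    def __post_init__(self) -> None:
        if not 0 <= self.n_similar <= self.n_superimposed <= self.n_elements:
            raise ValueError(
                f"count sanity violated for site {self.role}: "
                f"{self.n_similar} <= {self.n_superimposed} <= {self.n_elements}"
            )


@dataclass
class SimilarityResult:
    """Per-site similarity statistics of one pair at one representation level."""

    level: str
    sites: dict[str, SiteSimilarity]
    pair_id: str | None = None
    category: str = "unknown"


def match_profile(
    coords_self: np.ndarray,
    coords_other: np.ndarray,
    labels_other: np.ndarray,
    cutoff: float,
    n_classes: int = N_CLASSES,
) -> tuple[np.ndarray, np.ndarray]:
    """For each self element: is it superimposed, and which partner classes
    are present strictly within the cutoff.

    Returns ``(superimposed (n,), class_present (n, n_classes))``.
    """
    n = len(coords_self)
    if n == 0 or len(coords_other) == 0:
        return np.zeros(n, dtype=bool), np.zeros((n, n_classes), dtype=bool)
    within = cdist(coords_self, coords_other) < cutoff
    superimposed = within.any(axis=1)
    class_present = np.zeros((n, n_classes), dtype=bool)
    for k in range(n_classes):
        cols = labels_other == k
        if cols.any():
            class_present[:, k] = within[:, cols].any(axis=1)
    return superimposed, class_present


def _n_similar(
    labels: np.ndarray, class_present: np.ndarray, counted: np.ndarray | None = None
) -> int:
    """Number of elements whose own label is present among its within-cutoff
    partner elements; optionally only labels flagged in ``counted`` count."""
    if len(labels) == 0:
        return 0
    hit = class_present[np.arange(len(labels)), labels]
    if counted is not None:
        hit = hit & counted[labels]
    return int(hit.sum())


def count_matches(
    site1: Sequence[TypedElement], site2: Sequence[TypedElement], cutoff: float
) -> tuple[int, int, int, int]:
    """Superimposed/similar counts for both sites of a compared pair.

    Returns ``(n_superimposed_1, n_similar_1, n_superimposed_2, n_similar_2)``.
    """
    c1, l1 = elements_to_arrays(list(site1))
    c2, l2 = elements_to_arrays(list(site2))
    sup1, cp1 = match_profile(c1, c2, l2, cutoff)
    sup2, cp2 = match_profile(c2, c1, l1, cutoff)
    return (
        int(sup1.sum()),
        _n_similar(l1, cp1),
        int(sup2.sum()),
        _n_similar(l2, cp2),
    )


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _bootstrap_counts(
    overlap_labels: np.ndarray,
    overlap_profile: np.ndarray,
    n_reps: int,
    rng: np.random.Generator,
    mode: str = "permute",
    counted: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized null counts: permute (or redraw) labels over the overlap."""
    n = len(overlap_labels)
    if mode == "permute":
        reps = rng.permuted(np.tile(overlap_labels, (n_reps, 1)), axis=1)
    else:  # redraw i.i.d. from the empirical overlap label frequencies
        freqs = np.bincount(overlap_labels, minlength=overlap_profile.shape[1])
        reps = rng.choice(
            overlap_profile.shape[1], size=(n_reps, n), p=freqs / freqs.sum()
        )
    hit = overlap_profile[np.arange(n)[None, :], reps]
    if counted is not None:
        hit = hit & counted[reps]
    return hit.sum(axis=1)


def bootstrap_pvalue(
    site_self: Sequence[TypedElement],
    site_other: Sequence[TypedElement],
    cutoff: float,
    n_reps: int = 500,
    seed=0,
    mode: str = "permute",
) -> float:
    """Bootstrap P-value of the similarity of ``site_self`` against
    ``site_other`` (labels of the partner held fixed).

    With no superimposed element the P-value is 1 without sampling.
    """
    c1, l1 = elements_to_arrays(list(site_self))
    c2, l2 = elements_to_arrays(list(site_other))
    sup, cp = match_profile(c1, c2, l2, cutoff)
    return _pvalue_from_profile(sup, cp, l1, n_reps, seed, mode)


def _pvalue_from_profile(
    superimposed: np.ndarray,
    class_present: np.ndarray,
    labels: np.ndarray,
    n_reps: int,
    seed,
    mode: str = "permute",
    counted: np.ndarray | None = None,
) -> float:
    if superimposed.sum() == 0:
        return 1.0
    n_obs = _n_similar(labels, class_present, counted)
    overlap_labels = labels[superimposed]
    overlap_profile = class_present[superimposed]
    rng = _resolve_rng(seed)
    counts = _bootstrap_counts(overlap_labels, overlap_profile, n_reps, rng, mode, counted)
    return float(np.mean(counts >= n_obs))


def site_seed(rng_seed: int, level: str, role: str) -> np.random.SeedSequence:
    """Independent, reproducible stream per (run seed, level, site role)."""
    return np.random.SeedSequence([int(rng_seed), LEVEL_INDEX[level], ROLE_INDEX[role]])


def compute_similarity(
    pair: SuperposedPair,
    level: Level | str,
    params: MatchParams | None = None,
    tables: RepresentationTables | None = None,
    interface_params: InterfaceParams | None = None,
) -> SimilarityResult:
    """Full similarity analysis of one superposed pair at one level.

    Builds the four binding-site representations, counts matches for
    A vs A' and B vs C, and bootstraps one P-value per site (each
    site's labels shuffled in turn while the partner's stay fixed).
    """
    params = params or MatchParams()
    tables = tables or RepresentationTables.default()
    level = Level(level)
    cutoff = params.cutoff_for(level)

    site_a, site_b = detect_interface(pair.a, pair.b, interface_params, roles=("A", "B"))
    site_ap, site_c = detect_interface(
        pair.aprime, pair.c, interface_params, roles=("Aprime", "C")
    )
    elements = {
        "A": build_representation(site_a, level, tables),
        "Aprime": build_representation(site_ap, level, tables),
        "B": build_representation(site_b, level, tables),
        "C": build_representation(site_c, level, tables),
    }
    partner = {"A": "Aprime", "Aprime": "A", "B": "C", "C": "B"}

    sites: dict[str, SiteSimilarity] = {}
    for role in ("A", "Aprime", "B", "C"):
        c_self, l_self = elements_to_arrays(elements[role])
        c_oth, l_oth = elements_to_arrays(elements[partner[role]])
        sup, cp = match_profile(c_self, c_oth, l_oth, cutoff)
        n_sup = int(sup.sum())
        n_sim = _n_similar(l_self, cp)
        seed = np.random.SeedSequence(
            [int(params.rng_seed), LEVEL_INDEX[level.value], ROLE_INDEX[role]]
        )
        p = _pvalue_from_profile(sup, cp, l_self, params.n_bootstrap, seed, params.shuffle_mode)
        sites[role] = SiteSimilarity(
            role=role,
            n_elements=len(elements[role]),
            n_superimposed=n_sup,
            n_similar=n_sim,
            p_value=p,
        )
    return SimilarityResult(
        level=level.value, sites=sites, pair_id=pair.pair_id, category=pair.category
    )


def conservation_colocalization(
    pair: SuperposedPair,
    params: MatchParams | None = None,
    threshold: float = -1.0,
    interface_params: InterfaceParams | None = None,
) -> SimilarityResult:
    """Co-localization of evolutionarily conserved interface residues.

    Interfacial residues are labelled conserved (normalized score
    strictly below ``threshold``) or unconserved (including every
    residue of chains with no scores).  Only conserved residues are
    candidates: a conserved residue is co-localized when a conserved
    residue of the partner site lies within the C-alpha match cutoff.
    The bootstrap permutes the binary labels over the overlapping
    interface positions.  A site with zero superimposed conserved
    residues is flagged excluded (P = 1): such sites shrink the data
    set available to the P-value analysis.
    """
    params = params or MatchParams()
    cutoff = params.match_cutoff_ca

    site_a, site_b = detect_interface(pair.a, pair.b, interface_params, roles=("A", "B"))
    site_ap, site_c = detect_interface(
        pair.aprime, pair.c, interface_params, roles=("Aprime", "C")
    )

    def _ca_arrays(site):
        residues = [r for r in site.residues if r.ca is not None]
        coords = (
            np.asarray([r.ca.coord for r in residues])
            if residues
            else np.empty((0, 3))
        )
        labels = np.asarray(
            [
                int(r.conservation_score is not None and r.conservation_score < threshold)
                for r in residues
            ],
            dtype=int,
        )
        return coords, labels

    data = {
        "A": _ca_arrays(site_a),
        "Aprime": _ca_arrays(site_ap),
        "B": _ca_arrays(site_b),
        "C": _ca_arrays(site_c),
    }
    partner = {"A": "Aprime", "Aprime": "A", "B": "C", "C": "B"}
    counted = np.array([False, True])  # only the conserved label is counted

    sites: dict[str, SiteSimilarity] = {}
    for role in ("A", "Aprime", "B", "C"):
        c_self, l_self = data[role]
        c_oth, l_oth = data[partner[role]]
        sup, cp = match_profile(c_self, c_oth, l_oth, cutoff, n_classes=2)
        n_sup_conserved = int((sup & (l_self == 1)).sum())
        n_coloc = _n_similar(l_self, cp, counted)
        excluded = n_sup_conserved == 0
        if excluded:
            p = 1.0
        else:
            seed = np.random.SeedSequence(
                [int(params.rng_seed), LEVEL_INDEX["CONS"], ROLE_INDEX[role]]
            )
            p = _pvalue_from_profile(
                sup, cp, l_self, params.n_bootstrap, seed, params.shuffle_mode, counted
            )
        sites[role] = SiteSimilarity(
            role=role,
            n_elements=len(l_self),
            n_superimposed=n_sup_conserved,
            n_similar=n_coloc,
            p_value=p,
            excluded=excluded,
        )
    return SimilarityResult(
        level="CONS", sites=sites, pair_id=pair.pair_id, category=pair.category
    )


RESULT_COLUMNS = [
    "pair_id", "category", "level", "role", "side",
    "n_elements", "n_superimposed", "n_similar", "similarity_ratio",
    "p_value", "excluded",
]


def results_to_frame(results: Iterable[SimilarityResult]) -> pd.DataFrame:
    """One row per (pair, level, site)."""
    rows = []
    for res in results:
        for role, s in res.sites.items():
            rows.append(
                {
                    "pair_id": res.pair_id,
                    "category": res.category,
                    "level": res.level,
                    "role": role,
                    "side": SIDE_OF_ROLE[role],
                    "n_elements": s.n_elements,
                    "n_superimposed": s.n_superimposed,
                    "n_similar": s.n_similar,
                    "similarity_ratio": s.similarity_ratio,
                    "p_value": s.p_value,
                    "excluded": s.excluded,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(pearsonr(x, y)[0])


def summarize(results: Iterable[SimilarityResult] | pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Cohort summary: per-category mean similar counts and their A/A' over
    B/C ratio, cross-side correlations, and significance fractions.

    Degenerate correlations (fewer than two points, or zero variance)
    are reported as NaN.
    """
    frame = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    if frame["pair_id"].nunique() < 2:
        raise ValueError("summarize needs results from at least 2 pairs")

    mean_rows = []
    for (level, category), grp in frame.groupby(["level", "category"]):
        mean_rows.append(_mean_row(level, category, grp))
    for level, grp in frame.groupby("level"):
        mean_rows.append(_mean_row(level, "Total", grp))
    means = pd.DataFrame(mean_rows)

    corr_rows = []
    for level, grp in frame.groupby("level"):
        # one point per complex: (AB) -> (A, B) counts, (A'C) -> (A', C)
        piv = grp.pivot_table(
            index="pair_id", columns="role", values=["n_similar", "similarity_ratio"]
        )
        try:
            n_aa = np.concatenate(
                [piv["n_similar"]["A"].values, piv["n_similar"]["Aprime"].values]
            )
            n_bc = np.concatenate(
                [piv["n_similar"]["B"].values, piv["n_similar"]["C"].values]
            )
            r_aa = np.concatenate(
                [piv["similarity_ratio"]["A"].values, piv["similarity_ratio"]["Aprime"].values]
            )
            r_bc = np.concatenate(
                [piv["similarity_ratio"]["B"].values, piv["similarity_ratio"]["C"].values]
            )
        except KeyError:
            continue
        ok = ~(np.isnan(n_aa) | np.isnan(n_bc))
        okr = ~(np.isnan(r_aa.astype(float)) | np.isnan(r_bc.astype(float)))
        with_sup = grp[grp["n_superimposed"] > 0]
        overlap_frac = with_sup["n_superimposed"] / with_sup["n_elements"]
        similar_frac = with_sup["n_similar"] / with_sup["n_superimposed"]
        corr_rows.append(
            {
                "level": level,
                "r_similar_counts": _safe_pearson(n_aa[ok], n_bc[ok]),
                "r_similarity_ratios": _safe_pearson(
                    r_aa[okr].astype(float), r_bc[okr].astype(float)
                ),
                "r_overlap_vs_similar_fraction": _safe_pearson(
                    overlap_frac.values, similar_frac.values
                ),
            }
        )
    correlations = pd.DataFrame(corr_rows)

    sig_rows = []
    for (level, side), grp in frame.groupby(["level", "side"]):
        used = grp[~grp["excluded"]]
        sig_rows.append(
            {
                "level": level,
                "side": side,
                "n_sites": len(used),
                "frac_p_below_0.05": float((used["p_value"] < 0.05).mean())
                if len(used)
                else float("nan"),
            }
        )
    significance = pd.DataFrame(sig_rows)
    return {"means": means, "correlations": correlations, "significance": significance}


def _mean_row(level: str, category: str, grp: pd.DataFrame) -> dict:
    aa = grp[grp["side"] == "AA"]["n_similar"].mean()
    bc = grp[grp["side"] == "BC"]["n_similar"].mean()
    return {
        "level": level,
        "category": category,
        "n_pairs": grp["pair_id"].nunique(),
        "mean_similar_AA": aa,
        "mean_similar_BC": bc,
        "ratio": aa / bc if bc else float("nan"),
    }
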