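"""Superimposed/similar counting, bootstrap P-values and summaries."""

import numpy as np
import pytest
from sympy.utilities.iterables import multiset_permutations

from sitesim import (
    ElementClass,
    Level,
    MatchParams,
    SimilarityResult,
    SiteSimilarity,
    SyntheticPairSpec,
    bootstrap_pvalue,
    compute_similarity,
    conservation_colocalization,
    count_matches,
    generate_pair,
    summarize,
    superpose_synthetic,
)
from sitesim.representations import TypedElement
from sitesim.synthetic_data import attach_conservation


def _el(x, y, z, klass, key=("A", "1")):
    return TypedElement(coord=(x, y, z), klass=ElementClass(klass), level=Level.CA,
                        residue_key=key)


def brute_force_counts(site1, site2, cutoff):
    """Pure-Python double-loop oracle for the existence-test counting."""
    def one_side(s, o):
        n_sup = n_sim = 0
        for e in s:
            within = [
                f for f in o
                if np.linalg.norm(np.subtract(e.coord, f.coord)) < cutoff
            ]
            if within:
                n_sup += 1
                if any(f.klass == e.klass for f in within):
                    n_sim += 1
        return n_sup, n_sim
    a, b = one_side(site1, site2)
    c, d = one_side(site2, site1)
    return a, b, c, d


@pytest.mark.parametrize(
    "d,k1,k2,expected",
    [
        (2.9, 0, 0, (1, 1, 1, 1)),  # below cutoff, same class
        (2.9, 0, 1, (1, 0, 1, 0)),  # superimposed but dissimilar
        (3.0, 0, 0, (0, 0, 0, 0)),  # strict inequality at the cutoff
        (3.1, 0, 0, (0, 0, 0, 0)),
    ],
)
def test_count_matches_single_pair(d, k1, k2, expected):
    assert count_matches([_el(0, 0, 0, k1)], [_el(d, 0, 0, k2)], 3.0) == expected


def test_one_partner_element_matches_many():
    """Several elements may be matched by the same point: no bijection."""
    site1 = [_el(0, 0, 0, 2), _el(1.0, 0, 0, 2)]
    site2 = [_el(0.5, 0, 0, 2)]
    n_sup1, n_sim1, n_sup2, n_sim2 = count_matches(site1, site2, 3.0)
    assert (n_sup1, n_sim1) == (2, 2)
    assert (n_sup2, n_sim2) == (1, 1)


def test_empty_sites_yield_zeros():
    assert count_matches([], [_el(0, 0, 0, 0)], 3.0) == (0, 0, 0, 0)
    assert count_matches([], [], 3.0) == (0, 0, 0, 0)


def test_random_sites_match_brute_force_oracle():
    rng = np.random.default_rng(5)
    for _ in range(5):
        site1 = [
            _el(*rng.uniform(0, 10, 3), int(rng.integers(5))) for _ in range(50)
        ]
        site2 = [
            _el(*rng.uniform(0, 10, 3), int(rng.integers(5))) for _ in range(50)
        ]
        assert count_matches(site1, site2, 4.0) == brute_force_counts(site1, site2, 4.0)


def test_pvalue_one_when_no_similar_elements():
    """N_obs = 0: the null cannot produce fewer, so P = 1 exactly."""
    site1 = [_el(0, 0, 0, 0), _el(1, 0, 0, 1)]
    site2 = [_el(0.5, 0, 0, 2), _el(1.5, 0, 0, 3)]
    assert bootstrap_pvalue(site1, site2, 3.0, n_reps=500, seed=1) == 1.0


def test_pvalue_one_when_no_overlap():
    site1 = [_el(0, 0, 0, 0)]
    site2 = [_el(100, 0, 0, 0)]
    assert bootstrap_pvalue(site1, site2, 3.0, n_reps=500, seed=1) == 1.0


def test_pvalue_one_for_single_class_labels():
    """All labels identical: every permutation reproduces N_obs."""
    site1 = [_el(i * 0.5, 0, 0, 2) for i in range(6)]
    site2 = [_el(i * 0.5 + 0.1, 0, 0, 2) for i in range(6)]
    assert bootstrap_pvalue(site1, site2, 3.0, n_reps=200, seed=3) == 1.0


def test_pvalue_deterministic_under_seed():
    rng = np.random.default_rng(8)
    site1 = [_el(*rng.uniform(0, 6, 3), int(rng.integers(5))) for _ in range(20)]
    site2 = [_el(*rng.uniform(0, 6, 3), int(rng.integers(5))) for _ in range(20)]
    p1 = bootstrap_pvalue(site1, site2, 4.0, n_reps=300, seed=77)
    p2 = bootstrap_pvalue(site1, site2, 4.0, n_reps=300, seed=77)
    assert p1 == p2
    assert 0.0 <= p1 <= 1.0


def exact_permutation_pvalue(site_self, site_other, cutoff, counted=None):
    """Exhaustive enumeration over distinct label arrangements (<= 8 elements)."""
    from sitesim.representations import elements_to_arrays
    from sitesim.similarity_stats import _n_similar, match_profile

    c1, l1 = elements_to_arrays(list(site_self))
    c2, l2 = elements_to_arrays(list(site_other))
    sup, cp = match_profile(c1, c2, l2, cutoff)
    if sup.sum() == 0:
        return 1.0
    n_obs = _n_similar(l1, cp, counted)
    labels = l1[sup]
    profile = cp[sup]
    total = hits = 0
    for perm in multiset_permutations(list(labels)):
        perm = np.asarray(perm)
        hit = profile[np.arange(len(perm)), perm]
        if counted is not None:
            hit = hit & counted[perm]
        total += 1
        if hit.sum() >= n_obs:
            hits += 1
    return hits / total


def test_bootstrap_matches_exact_enumeration_small_overlap():
    """Bootstrap p within 3 Monte-Carlo standard errors of the exact
    permutation p for 6-element mixed-label overlaps."""
    rng = np.random.default_rng(13)
    n_reps = 500
    for trial in range(10):
        site1 = [_el(i * 1.0, 0, 0, int(rng.integers(5))) for i in range(6)]
        site2 = [
            _el(i * 1.0 + rng.uniform(-0.5, 0.5), 0.5, 0, int(rng.integers(5)))
            for i in range(6)
        ]
        p_exact = exact_permutation_pvalue(site1, site2, 3.0)
        p_boot = bootstrap_pvalue(site1, site2, 3.0, n_reps=n_reps, seed=trial)
        se = np.sqrt(p_exact * (1 - p_exact) / n_reps)
        assert abs(p_boot - p_exact) <= 3 * se + 1e-12


def test_redraw_mode_valid_and_deterministic():
    rng = np.random.default_rng(4)
    site1 = [_el(*rng.uniform(0, 5, 3), int(rng.integers(5))) for _ in range(15)]
    site2 = [_el(*rng.uniform(0, 5, 3), int(rng.integers(5))) for _ in range(15)]
    p1 = bootstrap_pvalue(site1, site2, 4.0, n_reps=200, seed=9, mode="redraw")
    p2 = bootstrap_pvalue(site1, site2, 4.0, n_reps=200, seed=9, mode="redraw")
    assert p1 == p2 and 0.0 <= p1 <= 1.0


def test_self_comparison_gives_ratio_one_and_minimal_p(clean_pair):
    """Complex 2 an exact copy of complex 1: every ratio is 1 and the four
    P-values are minimal for the mixed label composition."""
    from sitesim import superpose_pair

    s1 = clean_pair.structure1
    copy_a = [r.copy() for r in s1["A"]]
    copy_b = [r.copy() for r in s1["B"]]
    spair = superpose_pair(s1["A"], s1["B"], copy_a, copy_b, pair_id="selfcopy")
    for level in ("ATOM", "CG", "CA"):
        res = compute_similarity(spair, level, MatchParams(rng_seed=5))
        for role, s in res.sites.items():
            assert s.similarity_ratio == 1.0, (level, role)
            assert s.n_superimposed == s.n_elements
        # mixed-class overlaps of this size: all-similar is essentially
        # unreachable under the shuffle
        assert all(s.p_value <= 1 / 500 for s in res.sites.values())


def test_count_sanity_all_levels_all_sites(superposed_noisy):
    for level in ("ATOM", "CG", "CA"):
        res = compute_similarity(superposed_noisy, level, MatchParams(rng_seed=2))
        for s in res.sites.values():
            assert 0 <= s.n_similar <= s.n_superimposed <= s.n_elements
            assert 0.0 <= s.p_value <= 1.0


def test_site_similarity_rejects_inconsistent_counts():
    with pytest.raises(ValueError, match="sanity"):
        SiteSimilarity(role="A", n_elements=5, n_superimposed=6, n_similar=2, p_value=1.0)


# ---------------------------------------------------------------- conservation


def _conserved_pair(conserved_fraction=0.4, seed=21):
    pair = generate_pair(
        SyntheticPairSpec(conserved_fraction=conserved_fraction, seed=seed)
    )
    attach_conservation(pair)
    return pair


def test_no_conservation_data_means_excluded():
    """Chains without scores are entirely unconserved -> excluded, P = 1."""
    pair = generate_pair(SyntheticPairSpec(seed=31))  # scores never attached
    spair = superpose_synthetic(pair)
    res = conservation_colocalization(spair, MatchParams(rng_seed=1))
    for s in res.sites.values():
        assert s.excluded and s.p_value == 1.0 and s.n_similar == 0


def test_identical_sites_with_identical_labels_fully_colocalized():
    pair = generate_pair(
        SyntheticPairSpec(
            similarity_aa=1.0, coordinate_noise_sigma=0.0,
            conserved_fraction=0.5, seed=41,
        )
    )
    attach_conservation(pair)
    spair = superpose_synthetic(pair)
    res = conservation_colocalization(spair, MatchParams(rng_seed=1))
    # A and A' carry the same conservation pattern at identical positions:
    # every superimposed conserved residue co-localizes
    for role in ("A", "Aprime"):
        s = res.sites[role]
        assert s.n_similar == s.n_superimposed
        if s.n_superimposed > 0:
            assert not s.excluded


def test_conservation_bootstrap_matches_exact_enumeration():
    """Binary-label bootstrap agrees with exhaustive enumeration on a
    5-conserved-of-12 overlap."""
    rng = np.random.default_rng(55)
    conserved = np.array([1] * 5 + [0] * 7)
    site1 = [
        _el(i * 1.0, 0, 0, int(conserved[i]), key=("A", str(i))) for i in range(12)
    ]
    labels2 = rng.permutation(conserved)
    site2 = [
        _el(i * 1.0 + 0.3, 0.4, 0, int(labels2[i]), key=("B", str(i)))
        for i in range(12)
    ]
    counted = np.array([False, True])

    from sitesim.representations import elements_to_arrays
    from sitesim.similarity_stats import _pvalue_from_profile, match_profile

    c1, l1 = elements_to_arrays(site1)
    c2, l2 = elements_to_arrays(site2)
    sup, cp = match_profile(c1, c2, l2, 4.0, n_classes=2)
    p_boot = _pvalue_from_profile(sup, cp, l1, 500, seed=6, counted=counted)
    p_exact = exact_permutation_pvalue(site1, site2, 4.0, counted=counted)
    se = np.sqrt(p_exact * (1 - p_exact) / 500)
    assert abs(p_boot - p_exact) <= 3 * se + 1e-12


def test_conservation_count_sanity(superposed_noisy):
    pass_pair = generate_pair(SyntheticPairSpec(seed=61, conserved_fraction=0.5))
    attach_conservation(pass_pair)
    spair = superpose_synthetic(pass_pair)
    res = conservation_colocalization(spair, MatchParams(rng_seed=3))
    for s in res.sites.values():
        assert 0 <= s.n_similar <= s.n_superimposed <= s.n_elements


# ------------------------------------------------------------------- summaries


def _result(pair_id, level="CA", category="O", counts=(5, 4, 3, 2), p=0.01):
    sites = {}
    for role, n_sim in zip(("A", "Aprime", "B", "C"), counts):
        sites[role] = SiteSimilarity(
            role=role, n_elements=20, n_superimposed=10, n_similar=n_sim, p_value=p
        )
    return SimilarityResult(level=level, sites=sites, pair_id=pair_id, category=category)


def test_summarize_hand_arithmetic():
    results = [
        _result("p1", counts=(6, 6, 2, 2)),
        _result("p2", counts=(4, 4, 1, 1)),
        _result("p3", counts=(8, 8, 3, 3)),
    ]
    summary = summarize(results)
    total = summary["means"][summary["means"]["category"] == "Total"].iloc[0]
    assert total["mean_similar_AA"] == pytest.approx(6.0)
    assert total["mean_similar_BC"] == pytest.approx(2.0)
    assert total["ratio"] == pytest.approx(3.0)
    sig = summary["significance"]
    assert (sig["frac_p_below_0.05"] == 1.0).all()


def test_summarize_degenerate_correlation_flagged_nan():
    # identical results with equal counts on each side: zero variance
    results = [_result("p1", counts=(5, 5, 3, 3)), _result("p2", counts=(5, 5, 3, 3))]
    summary = summarize(results)
    assert np.isnan(summary["correlations"]["r_similar_counts"].iloc[0])


def test_summarize_requires_two_pairs():
    with pytest.raises(ValueError, match="at least 2"):
        summarize([_result("p1")])


def test_planted_cohort_separates_sides():
    """Planted A/A' similarity with independent B/C labels: higher mean
    similar count and stronger significance on the homologous side."""
    from sitesim import generate_cohort, results_to_frame

    pairs = generate_cohort(25, SyntheticPairSpec(), seed=101)
    results = []
    for pair in pairs:
        spair = superpose_synthetic(pair)
        results.append(compute_similarity(spair, "CA", MatchParams(rng_seed=pair.spec.seed)))
    summary = summarize(results)
    total = summary["means"][summary["means"]["category"] == "Total"].iloc[0]
    assert total["mean_similar_AA"] > total["mean_similar_BC"]
    sig = summary["significance"].set_index("side")["frac_p_below_0.05"]
    assert sig["AA"] > 0.9
    assert sig["BC"] < 0.5
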