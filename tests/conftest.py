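import numpy as np
import pytest

from sitesim import (
    RepresentationTables,
    SyntheticPairSpec,
    generate_pair,
    superpose_synthetic,
)


@pytest.fixture(scope="session")
def tables():
    return RepresentationTables.default()


@pytest.fixture(scope="session")
def clean_pair():
    """A well-behaved synthetic pair: exact A/A' copy, no noise, identity."""
    spec = SyntheticPairSpec(
        similarity_aa=1.0, coordinate_noise_sigma=0.0, seed=11
    )
    return generate_pair(spec)


@pytest.fixture(scope="session")
def noisy_pair():
    """Default study conditions, moderate noise, non-trivial transform."""
    from sitesim import RigidTransform

    spec = SyntheticPairSpec(
        planted_transform=RigidTransform.from_axis_angle(
            (1.0, 2.0, 0.5), 35.0, (8.0, -4.0, 2.0)
        ),
        seed=23,
    )
    return generate_pair(spec)


@pytest.fixture()
def superposed_noisy(noisy_pair):
    return superpose_synthetic(noisy_pair)


def brute_force_interface(domain1, domain2, cutoff=5.0):
    """Independent O(n*m) double-loop oracle for interface detection."""
    atoms1, atoms2 = set(), set()
    res1, res2 = set(), set()
    for r1 in domain1:
        for a1 in r1.atoms:
            if not a1.is_heavy:
                continue
            for r2 in domain2:
                for a2 in r2.atoms:
                    if not a2.is_heavy:
                        continue
                    d = float(np.linalg.norm(a1.coord - a2.coord))
                    if d < cutoff:
                        atoms1.add((r1.key, a1.name))
                        atoms2.add((r2.key, a2.name))
                        res1.add(r1.key)
                        res2.add(r2.key)
    return atoms1, res1, atoms2, res2
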