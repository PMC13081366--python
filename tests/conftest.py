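"""Shared fixtures: a small planted genome and its (blast-backed) annotation.

Session-scoped so the external alignment engine runs once for the whole
suite; all fixture data is generated programmatically.
"""

from __future__ import annotations

import numpy as np
import pytest

from satarch import annotate, arrays
from satarch.simulate import ArchitectureSpec, plant_architecture


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec() -> ArchitectureSpec:
    return ArchitectureSpec(
        genome_length=700_000,
        n_major_arrays=2,
        n_minor_standalone=1,
        n_ac_arrays=1,
        n_cassettes=3,
        n_ac_decoys=8,
    )


@pytest.fixture(scope="session")
def small_sim(small_spec):
    genome, truth = plant_architecture(small_spec, 11)
    return genome, truth


@pytest.fixture(scope="session")
def small_families(small_sim):
    _, truth = small_sim
    return list(truth.families.values())


@pytest.fixture(scope="session")
def small_hits(small_sim, small_families):
    genome, _ = small_sim
    raw = annotate.search_monomers(genome, small_families)
    return annotate.resolve_overlaps(raw)


@pytest.fixture(scope="session")
def small_arrays(small_hits, small_families):
    return arrays.build_arrays(small_hits, small_families)
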