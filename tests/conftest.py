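"""Shared fixtures: tiny deterministic gene sets and a lenient config.

All alignment-heavy fixtures use short genes so the quadratic DP stays cheap;
``lenient_cfg`` drops min_bbh to 1 so small examples report ANI.
"""

from __future__ import annotations

import numpy as np
import pytest

from misig import (
    EvolveParams,
    Gene,
    GeneSet,
    MisiConfig,
    evolve_genome,
    make_reference_genome,
)


@pytest.fixture(scope="session")
def lenient_cfg() -> MisiConfig:
    return MisiConfig(min_bbh=1)


@pytest.fixture(scope="session")
def small_ref() -> GeneSet:
    return make_reference_genome(5, (60, 120), 0.5, seed=42, genome_id="refA")


@pytest.fixture(scope="session")
def small_pair(small_ref):
    """A reference and a moderately diverged relative (p=0.08, all genes kept)."""
    evolved = evolve_genome(
        small_ref,
        EvolveParams(per_site_substitution_prob=0.08, seed=7),
        genome_id="evoA",
    )
    return small_ref, evolved


def random_gene(rng: np.random.Generator, gene_id: str, length: int) -> Gene:
    return Gene(gene_id, "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
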