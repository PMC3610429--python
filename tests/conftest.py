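from __future__ import annotations

import numpy as np
import pytest

from orthotrace.records import GenomeAnnotation, OrthologyGroups
from orthotrace.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def duplicated_genome():
    """A 30-gene genome duplicated verbatim into a second species, with two
    agreeing orthogroup methods (every gene paired with its copy)."""
    n = 30
    a_genes = [f"a{i:02d}" for i in range(n)]
    b_genes = [f"b{i:02d}" for i in range(n)]
    annotation = GenomeAnnotation({"at": {"chr1": a_genes}, "sl": {"chr1": b_genes}})
    pairs = [
        [("at", a), ("sl", b)] for a, b in zip(a_genes, b_genes)
    ]
    groups = {
        "m1": OrthologyGroups("m1", pairs),
        "m2": OrthologyGroups("m2", pairs),
    }
    return annotation, groups, a_genes, b_genes


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition simulated genome pair, reused across tests."""
    return generate_dataset(SimConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260101)
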