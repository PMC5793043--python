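"""Shared fixtures: small simulated genomes, generated at session start."""

import pytest

from mutrace import AnnotatedGenome, CdsFeature, generate_ancestor


@pytest.fixture(scope="session")
def ancestor_50k():
    """50 kb / 40-gene ancestor used by calling and spectrum tests."""
    return generate_ancestor(50_000, 0.5, 40, 900, seed=1)


@pytest.fixture(scope="session")
def ancestor_30k():
    """Smaller ancestor for cgMLST / screening tests."""
    return generate_ancestor(30_000, 0.5, 25, 900, seed=11)


@pytest.fixture()
def toy_cds_genome():
    """Single two-codon gene: ATG AAA TAA (the Ka/Ks hand-enumeration toy)."""
    return AnnotatedGenome(id="toy", sequence="ATGAAATAA",
                           features=[CdsFeature("g1", 1, 9)])
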