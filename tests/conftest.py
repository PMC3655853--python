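import numpy as np
import pytest

from sagkit import (
    AnnotatedTree,
    CompositionSpec,
    ContigSet,
    PhyleticMatrix,
    fragment_genome,
    simulate_composition_genome,
)


@pytest.fixture(scope="session")
def toy_matrix():
    """Patterns {A: 111, B: 110, C: 011} over genomes g1..g3."""
    return PhyleticMatrix(
        families=["A", "B", "C"],
        genomes=["g1", "g2", "g3"],
        counts=[[1, 1, 1], [1, 1, 0], [0, 1, 1]],
    )


@pytest.fixture(scope="session")
def balanced_tree():
    return AnnotatedTree.from_newick("((a:1,b:1)n1:1,(c:1,d:1)n2:1)root;")


@pytest.fixture(scope="session")
def small_mixture():
    """Two compositionally distinct 120-kb genomes cut into 5 contigs each.

    Returns (ContigSet, truth labels); small enough for fast unit tests
    while preserving the G+C separation of the full-scale presets.
    """
    lo = simulate_composition_genome(
        CompositionSpec(label="lo", length=120_000, gc_target=0.24), seed=101
    )
    hi = simulate_composition_genome(
        CompositionSpec(label="hi", length=120_000, gc_target=0.52), seed=202
    )
    contigs_lo, truth_lo = fragment_genome(lo, 5, 5000, seed=11, label="lo")
    contigs_hi, truth_hi = fragment_genome(hi, 5, 5000, seed=22, label="hi")
    contigs = ContigSet(contigs_lo.entries + contigs_hi.entries)
    truth = {**truth_lo, **truth_hi}
    return contigs, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
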