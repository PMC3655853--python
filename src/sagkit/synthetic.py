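"""Synthetic inputs with the statistical structure the analyses assume.

Three generators:

* a compositional genome simulator — an order-k Markov chain over
  {A, C, G, T} whose per-context G+C probability is pinned exactly at a
  target, with a tunable random perturbation of the transition rows that
  creates genome-specific tetranucleotide signatures (two such genomes with
  well-separated G+C mimic a mixed single-cell assembly of a nanoarchaeon
  and its crenarchaeal host);
* a marker-census simulator — uniform subsampling without replacement of a
  gene complement that carries ``F`` single-copy universal marker families,
  producing the (N, f, F) census consumed by the completeness estimator;
* a gene-content evolution simulator — binary family presence evolved from
  the root of a tree toward its tips under per-branch loss probabilities
  ``1 - exp(-loss_rate * branch_length)`` and Poisson gains of novel
  families at rate ``gain_rate`` per unit branch length, with the true
  state recorded at every node.

All randomness flows through one explicit integer seed (or an injected
numpy Generator); there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trees import AnnotatedTree
from .phyletics import PhyleticMatrix

__all__ = [
    "CompositionSpec",
    "CensusTruth",
    "EvolutionSpec",
    "MarkerCensusSample",
    "GeneContentSimulation",
    "NANO_LIKE",
    "HOST_LIKE",
    "simulate_composition_genome",
    "expected_tetramer_distribution",
    "fragment_genome",
    "simulate_marker_census",
    "simulate_gene_content_evolution",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class CompositionSpec:
    """Parameters of one compositionally homogeneous genome.

    ``bias_strength`` controls how far the order-``markov_order`` transition
    rows deviate from the G+C-constrained uniform baseline: 0 means no
    context dependence beyond base composition (all tetramers equally
    likely at G+C = 0.5), larger values give the genome a stronger
    individual k-mer signature.
    """

    label: str
    length: int
    gc_target: float
    markov_order: int = 3
    bias_strength: float = 1.0
    n_contigs: int = 1
    min_contig_len: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"gc_target must be in (0, 1), got {self.gc_target}")
        if self.length < 1:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.markov_order < 0:
            raise ValueError(f"markov_order must be >= 0, got {self.markov_order}")
        if self.bias_strength < 0:
            raise ValueError(f"bias_strength must be >= 0, got {self.bias_strength}")
        if self.n_contigs < 1:
            raise ValueError(f"n_contigs must be >= 1, got {self.n_contigs}")
        if self.n_contigs * self.min_contig_len > self.length:
            raise ValueError(
                f"n_contigs ({self.n_contigs}) x min_contig_len "
                f"({self.min_contig_len}) exceeds length ({self.length})"
            )


# Presets emulating a two-population single-cell assembly: a low-G+C
# nanoarchaeon-like genome (0.59 Mb in 7 contigs, 24% G+C) mixed with a
# higher-G+C crenarchaeal-host-like genome (1.51 Mb in 8 contigs, 52% G+C).
NANO_LIKE = CompositionSpec(
    label="nano", length=593_000, gc_target=0.24, n_contigs=7, min_contig_len=10_000
)
HOST_LIKE = CompositionSpec(
    label="host", length=1_510_000, gc_target=0.52, n_contigs=8, min_contig_len=10_000
)


@dataclass(frozen=True)
class CensusTruth:
    """Ground truth for the marker-census sampling model.

    The true gene complement has ``N_total`` genes of which the first ``F``
    are single-copy universal markers; a fraction ``completeness_true`` of
    the complement is observed.
    """

    N_total: int
    F: int
    completeness_true: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F > self.N_total:
            raise ValueError(f"F ({self.F}) must be <= N_total ({self.N_total})")
        if not 0.0 < self.completeness_true <= 1.0:
            raise ValueError(
                f"completeness_true must be in (0, 1], got {self.completeness_true}"
            )


@dataclass(frozen=True)
class MarkerCensusSample:
    """One realized census plus the hidden truth, for coverage testing."""

    census: "MarkerCensus"  # noqa: F821 - sagkit.completeness.MarkerCensus
    n_total_true: int
    genes_drawn: tuple


@dataclass(frozen=True)
class EvolutionSpec:
    """Parameters of the gene-content gain/loss simulation on a tree."""

    tree: AnnotatedTree
    root_family_count: int
    gain_rate: float = 0.0
    loss_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_family_count < 1:
            raise ValueError("root_family_count must be positive")
        for name, rate in (("gain_rate", self.gain_rate), ("loss_rate", self.loss_rate)):
            if not np.isfinite(rate) or rate < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {rate}")
        if len(self.tree.leaf_names()) < 2:
            raise ValueError("tree must have at least 2 leaves")


def _transition_rows(spec: CompositionSpec, rng: np.random.Generator) -> np.ndarray:
    """Transition probability rows, one per order-k context.

    Each row starts from the G+C-constrained uniform baseline
    (P(A)=P(T)=(1-gc)/2, P(C)=P(G)=gc/2), is perturbed multiplicatively by
    exp(bias_strength * N(0,1)) per cell, and is then renormalized so that
    P(C)+P(G) equals gc_target exactly in every context.  Pinning the
    per-context G+C keeps the realized genome-wide G+C binomially tight
    around the target while leaving the A/T and C/G balance and all
    longer-range k-mer structure free to vary between genomes.
    """
    n_ctx = 4 ** spec.markov_order
    gc, at = spec.gc_target, 1.0 - spec.gc_target
    base = np.array([at / 2, gc / 2, gc / 2, at / 2])
    rows = base * np.exp(spec.bias_strength * rng.standard_normal((n_ctx, 4)))
    gc_mass = rows[:, 1] + rows[:, 2]
    at_mass = rows[:, 0] + rows[:, 3]
    rows[:, [1, 2]] *= (gc / gc_mass)[:, None]
    rows[:, [0, 3]] *= (at / at_mass)[:, None]
    return rows


def _transition_cumulatives(spec: CompositionSpec, rng: np.random.Generator):
    return np.cumsum(_transition_rows(spec, rng), axis=1)


def expected_tetramer_distribution(spec: CompositionSpec, seed: int) -> np.ndarray:
    """Exact stationary tetramer distribution of the generator's chain.

    For the default order-3 model, a tetramer is one (context, next base)
    step, so its stationary probability is pi(context) * P(base | context)
    with pi the stationary distribution of the context chain.  Serves as
    the analytic target against which realized tetramer frequencies
    converge as sequence length grows.  Only defined for markov_order=3.
    """
    if spec.markov_order != 3:
        raise ValueError("expected tetramer distribution requires markov_order=3")
    rng = np.random.default_rng(seed)
    rows = _transition_rows(spec, rng)
    n_ctx = rows.shape[0]
    mask = n_ctx - 1
    transition = np.zeros((n_ctx, n_ctx))
    for ctx in range(n_ctx):
        for b in range(4):
            transition[ctx, ((ctx << 2) | b) & mask] += rows[ctx, b]
    pi = np.full(n_ctx, 1.0 / n_ctx)
    for _ in range(10_000):
        nxt = pi @ transition
        if np.abs(nxt - pi).max() < 1e-14:
            pi = nxt
            break
        pi = nxt
    out = np.zeros(256)
    for ctx in range(n_ctx):
        for b in range(4):
            out[(ctx << 2) | b] = pi[ctx] * rows[ctx, b]
    return out


def simulate_composition_genome(spec: CompositionSpec, seed: int) -> str:
    """Simulate one genome sequence from an order-k Markov composition model.

    Deterministic given (spec, seed); realized G+C lands within about one
    binomial standard deviation of ``gc_target`` because every transition
    row carries exactly that G+C probability.
    """
    rng = np.random.default_rng(seed)
    cum = _transition_cumulatives(spec, rng)
    cum_rows = [(float(row[0]), float(row[1]), float(row[2])) for row in cum]
    n_ctx = len(cum_rows)
    mask = n_ctx - 1
    u = rng.random(spec.length).tolist()
    state = int(rng.integers(n_ctx))
    out = bytearray(spec.length)
    bases = b"ACGT"
    for i in range(spec.length):
        c = cum_rows[state]
        r = u[i]
        b = (r > c[0]) + (r > c[1]) + (r > c[2])
        state = ((state << 2) | b) & mask
        out[i] = bases[b]
    return out.decode("ascii")


def fragment_genome(
    sequence: str,
    n_contigs: int,
    min_len: int,
    seed: int,
    label: str = "genome",
):
    """Cut a sequence into ``n_contigs`` contiguous pieces of >= ``min_len`` bp.

    The pieces partition the input (their in-order concatenation
    reconstructs it exactly).  Returns ``(ContigSet, truth)`` where truth
    maps each contig id to the source ``label``.
    """
    from .binning import ContigSet

    length = len(sequence)
    if n_contigs * min_len > length:
        raise ValueError(
            f"cannot cut {length} bp into {n_contigs} contigs of >= {min_len} bp"
        )
    rng = np.random.default_rng(seed)
    extra = length - n_contigs * min_len
    # n_contigs-1 sorted cut offsets within the distributable surplus
    cuts = np.sort(rng.integers(0, extra + 1, size=n_contigs - 1))
    surpluses = np.diff(np.concatenate(([0], cuts, [extra])))
    lengths = surpluses + min_len
    entries = []
    truth = {}
    pos = 0
    for i, piece_len in enumerate(lengths):
        contig_id = f"{label}_c{i + 1}"
        entries.append((contig_id, sequence[pos : pos + int(piece_len)]))
        truth[contig_id] = label
        pos += int(piece_len)
    assert pos == length
    return ContigSet(entries), truth


def simulate_marker_census(
    truth: CensusTruth, rng: np.random.Generator | None = None
) -> MarkerCensusSample:
    """Draw a marker census by uniform gene subsampling without replacement.

    ``N = round(completeness_true * N_total)`` genes are drawn uniformly
    without replacement from the true complement; ``f`` counts how many of
    the ``F`` marker genes (one gene per marker family) were drawn, so f is
    hypergeometric(N_total, F, N).
    """
    from .completeness import MarkerCensus

    if rng is None:
        rng = np.random.default_rng(truth.seed)
    n_drawn = int(round(truth.completeness_true * truth.N_total))
    drawn = rng.choice(truth.N_total, size=n_drawn, replace=False)
    f = int(np.count_nonzero(drawn < truth.F))
    census = MarkerCensus(N=n_drawn, F=truth.F, f=f)
    return MarkerCensusSample(
        census=census, n_total_true=truth.N_total, genes_drawn=tuple(int(g) for g in drawn)
    )


@dataclass
class GeneContentSimulation:
    """Output of the gain/loss simulation.

    ``matrix`` holds binary presence at the leaves; ``tree`` carries the
    true presence set at every node; ``branch_gains``/``branch_losses``
    record the families gained and lost on the branch leading *into* each
    non-root node.
    """

    matrix: PhyleticMatrix
    tree: AnnotatedTree
    branch_gains: dict = field(default_factory=dict)
    branch_losses: dict = field(default_factory=dict)


def simulate_gene_content_evolution(spec: EvolutionSpec) -> GeneContentSimulation:
    """Evolve binary family presence from the root of a tree to its tips.

    On the branch into each node, every family present in the parent is
    lost independently with probability ``1 - exp(-loss_rate * bl)``, and
    ``Poisson(gain_rate * bl)`` previously unseen families are gained.
    Gained families are present in the child and evolve normally below it.
    """
    rng = np.random.default_rng(spec.seed)
    tree = spec.tree
    root_families = [f"fam{i + 1:05d}" for i in range(spec.root_family_count)]
    states: dict[str, frozenset] = {tree.root_id(): frozenset(root_families)}
    branch_gains: dict[str, frozenset] = {}
    branch_losses: dict[str, frozenset] = {}
    gain_counter = 0

    for node_id, parent_id, bl in tree.preorder_edges():
        parent_set = states[parent_id]
        p_loss = 1.0 - np.exp(-spec.loss_rate * bl)
        if parent_set and p_loss > 0:
            keep = rng.random(len(parent_set)) >= p_loss
            parent_list = sorted(parent_set)
            lost = frozenset(fam for fam, k in zip(parent_list, keep) if not k)
        else:
            lost = frozenset()
        n_gain = int(rng.poisson(spec.gain_rate * bl)) if spec.gain_rate > 0 else 0
        gained = frozenset(
            f"gain{gain_counter + j + 1:05d}" for j in range(n_gain)
        )
        gain_counter += n_gain
        states[node_id] = (parent_set - lost) | gained
        branch_gains[node_id] = gained
        branch_losses[node_id] = lost

    all_families = sorted(set().union(root_families, *states.values()))
    leaf_names = tree.leaf_names()
    counts = np.zeros((len(all_families), len(leaf_names)), dtype=int)
    fam_index = {fam: i for i, fam in enumerate(all_families)}
    for j, leaf in enumerate(leaf_names):
        for fam in states[leaf]:
            counts[fam_index[fam], j] = 1
    matrix = PhyleticMatrix(families=all_families, genomes=list(leaf_names), counts=counts)
    annotated = tree.with_states(states)
    return GeneContentSimulation(
        matrix=matrix,
        tree=annotated,
        branch_gains=branch_gains,
        branch_losses=branch_losses,
    )
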