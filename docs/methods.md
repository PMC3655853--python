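# Methods

`sagkit` implements the desk-side computations needed to resolve two genomes
from a mixed single-cell amplified genome (SAG) co-assembly — such as an
ectosymbiotic nanoarchaeon and its crenarchaeal host — and to characterize
them comparatively: compositional contig binning, marker-based completeness
estimation with exact binomial confidence bounds, and phyletic-pattern
analytics. A synthetic-data layer generates every input the analyses
consume, so the whole pipeline is testable without sequencing data.

## Completeness and total-gene-complement estimation

Let a partial assembly contain `N` predicted genes, among them members of
`f` out of `F` gene families expected to occur exactly once in every
complete genome of the reference clade. Under the model that each gene of
the complete genome is equally and independently likely to be present in
the sequenced fraction, the detected marker count is Binomial(F, p') in the
true completeness p', and:

- point completeness: `p = f/F`;
- point gene complement: `N' = N/p = N·F/f`;
- upper completeness bound `p⁺`: the unique root of
  `Σ_{i=0}^{f} C(F,i) p^i (1−p)^{F−i} = α` on `(f/F, 1)`;
- lower completeness bound `p⁻`: the unique root of
  `Σ_{i=f}^{F} C(F,i) p^i (1−p)^{F−i} = α` on `(0, f/F)`;
- the `1−α` confidence interval for the full gene complement is
  `[N/p⁺, N/p⁻]`.

These are the classical one-sided Clopper–Pearson bounds. Each bound holds
marginally with confidence `1−α`; the two-sided interval therefore has
joint coverage of at least `1−2α` (the default `α = 0.05` per side gives a
"95% confidence" label per bound and ≥ 90% joint nominal coverage). The
tails are computed exactly (`scipy.stats.binom`, no normal or Poisson
approximation) and inverted by plain bisection to an absolute tolerance of
1e-12; both tails are strictly monotone in `p` on their bracket, so the
roots are unique. Boundaries are handled explicitly: `f = F` gives
`p⁺ = 1`, `f = 0` gives `p⁻ = 0` and makes the complement estimate
undefined (an error, not a number).

**Integer endpoints.** The real-valued endpoints `N/p⁺` and `N/p⁻` are
reported as integers by taking the ceiling — the smallest whole gene count
consistent with each real-valued bound. For the two bundled worked
examples (N=656, f=126, F=138 and N=1692, f=349, F=352) this yields
[692, 761] and [1696, 1730]. The unrounded values are exposed alongside
(`ci_low_raw`, `ci_high_raw`; `--raw` on the CLI).

**Coverage in practice.** `coverage_experiment` draws censuses from the
package's own sampling model — genes drawn uniformly *without replacement*
from a complement of `N_total` genes containing `F` single-copy markers,
so `f` is hypergeometric rather than binomial — and measures how often the
interval contains `N_total` (inclusive endpoints). The without-replacement
sampling is deliberate: it is the more physically faithful model, and it
probes the estimator's robustness to its own independence assumption. The
hypergeometric distribution of `f` is narrower than the binomial the
bounds assume, so observed joint coverage (≈ 0.96 at `N_total=720, F=138`,
90% sampling, α=0.05 in the test conditions) sits above the `1−2α`
nominal floor; discreteness of the exact bounds pushes in the same
conservative direction, which is also why coverage at α=0.25 lands nearer
0.65 than 0.5.

## Compositional binning

Each contig is profiled in sliding windows: G+C fraction (ambiguous bases
excluded from numerator and denominator) and the normalized frequency
vector of the 256 overlapping tetranucleotides (4-mers containing an
ambiguous base are skipped; a window with no valid 4-mer is flagged and
excluded from embedding). Windows start at 0, `step`, `2·step`, … while
they fit, plus one final window flush with the contig end; contigs shorter
than one window contribute a single whole-contig window. Coordinates are
0-based half-open throughout.

Defaults are `window = 5000` bp, `step = 1000` bp: a 5-kb window holds
about 5000 tetramer observations, which keeps per-window frequency noise
(~1/√5000 per coordinate) far below the compositional distance between
two genomes separated by ~28 G+C points. 4-mers are counted on the given
strand only (256 states); reverse-complement canonicalization is available
(`canonical=True`) but off by default, the simpler reproducible choice.

Window profiles are embedded by classical principal coordinates analysis
(metric MDS) of their Euclidean distance matrix (via
`skbio.stats.ordination.pcoa`, exact `eigh` solver). Axes are ordered by
decreasing eigenvalue; each axis's sign is fixed by making its
largest-magnitude coordinate positive, so embeddings are reproducible. For
Euclidean input the embedding is an isometry up to rank, which the tests
check at 1e-9.

Windows are partitioned by k-means (k = 2 by default, 10 restarts, fixed
seed, best inertia) on the first two principal coordinates — the minimal
deterministic choice for a 2-way partition. Cluster labels are renumbered
so that label 0 is the cluster with the lower mean window G+C (ties broken
by the lower mean first coordinate), making "bin 0 = the low-G+C genome" a
stable convention. Contigs are assigned by majority vote over their
windows; an exact tie goes to label 0 with confidence 0.5 and a `tie`
flag, and contigs with no valid window are returned unassigned rather
than guessed.

The whole procedure is packaged as `CompositionBinner`, a
scikit-learn-compatible clustering estimator (`fit`, `fit_predict`,
`labels_`, `get_params`/`set_params`).

## Phyletic-pattern analytics

The substrate is a family × genome copy-count matrix; presence is strictly
count ≥ 1, copy numbers are used only by the paralog statistic.

- **Core families** of a taxon set: present in every listed genome
  (antitone in the taxon set).
- **Signature families** of a clade: present in ≥ `min_clade_fraction`
  (default 1.0) of clade genomes and in zero background genomes.
- **Shared-exclusive families**: present in all of one genome set, absent
  from all of a second, present in > `majority_threshold` (default 0.5,
  i.e. a strict majority) of a third.
- **Paralog density** of a genome: mean gene count per present family,
  `Σ counts / #{count ≥ 1}`. No canonical formula exists for this
  statistic; the mean-copies-per-present-family definition is the simplest
  one with the right behavior (≥ 1 always, = 1 iff all present families
  are single-copy).
- **Paralog clustering**: single-linkage connected components of a
  precomputed pairwise percent-identity edge list at a chosen threshold.
  Identities are consumed as data, keeping sequence-search engines out of
  the package; raising the threshold provably refines the clustering.
- **Parsimony gain/loss placement**: with the ancestral presence state
  fixed at a user-chosen attachment node (the node is not re-optimized —
  the species' position is taken as given, e.g. from a ribosomal-protein
  tree), gains are families present in the genome but absent at the node
  and losses the converse, the most parsimonious single-event explanation
  per family. The identity |genome| = |ancestor| + gains − losses holds by
  construction and is asserted in tests.
- **Dollo ancestral states**: when externally inferred ancestral states
  are unavailable, each family is assumed to originate exactly once, at
  the most recent common ancestor of its carrier leaves, and to be present
  on all paths from that origin to those leaves. Dollo reconstruction is a
  deliberately simple, deterministic stand-in; it is *not* a
  maximum-likelihood birth–death reconstruction, and external states and
  Dollo states are never mixed within one run.

## Synthetic data generators

- **Composition model**: an order-3 Markov chain over {A,C,G,T}. Each
  context's transition row starts from the G+C-constrained uniform
  baseline (P(A)=P(T)=(1−gc)/2, P(C)=P(G)=gc/2), is perturbed
  multiplicatively by `exp(bias_strength · N(0,1))` per cell, then
  renormalized so every row's P(C)+P(G) equals `gc_target` exactly. This
  pins the realized G+C within binomial fluctuation of the target while
  leaving tetramer structure free — order 3 is the minimal order with
  unconstrained tetramer statistics. At `bias_strength = 0` and G+C 0.5
  the chain is i.i.d. uniform (all 256 tetramers ≈ 1/256). The exact
  stationary tetramer distribution of the chain is computable
  (`expected_tetramer_distribution`) and serves as the convergence target
  in tests. Presets `NANO_LIKE` (0.593 Mb, 24% G+C, 7 contigs) and
  `HOST_LIKE` (1.51 Mb, 52% G+C, 8 contigs) emulate the mixed two-genome
  assembly the binner is designed for. `bias_strength` defaults to 1.0,
  strong enough to give each genome an individual signature without
  overwhelming the G+C constraint.
- **Fragmentation** cuts a genome into n contiguous pieces ≥ a minimum
  length (cut points uniform over feasible placements); concatenating the
  pieces in order reconstructs the genome, and truth labels record each
  contig's source.
- **Marker census**: `N = round(completeness_true · N_total)` genes drawn
  uniformly without replacement; `f` counts drawn marker genes (one gene
  per marker family), i.e. hypergeometric — see the coverage discussion
  above for why this deliberately departs from the estimator's binomial
  assumption.
- **Gene-content evolution**: presence/absence evolved root→tips; on a
  branch of length `b` each present family is lost with probability
  `1 − exp(−loss_rate·b)` and `Poisson(gain_rate·b)` novel families are
  gained. True states are recorded at every node and per-branch event sets
  are returned, so parsimony inference can be validated against exact
  truth. This is a test-data source, not an inference engine.

All generators take one explicit integer seed (or an injected numpy
`Generator`); there is no global random state, and identical spec + seed
gives byte-identical output.

**What the generators do not model**: MDA amplification bias and coverage
unevenness, read-level error and assembly artifacts, contaminant contigs,
protein sequences, and paralog-aware gene sampling. Passing tests on this
synthetic data therefore demonstrate correctness of the *computations*
under their stated models — not that real SAG co-assemblies will separate
as cleanly as the presets do.

## Problem sizes and numerical choices

The bundled test and demo conditions are chosen to be decisive yet small:
binning separation is verified on the full-scale two-genome mixture
(2.1 Mb) across 20 seeds; estimator coverage uses 2000 replicates;
bound-inversion exactness is sworn against an independently coded
exhaustive tail sum for every `F ≤ 30`, every admissible `f`, and
`α ∈ {0.01, 0.05, 0.1}`; structural properties (Dollo connectivity,
clustering refinement) use ≥ 200 random instances each. Bisection
tolerance is 1e-12 on the bounds; PCoA isometry is asserted at 1e-9;
tetramer normalization at 1e-12.

The demo pipeline, lacking real gene predictions, sizes each bin's marker
census from the bin's length at 1 gene per 900 bp (a typical archaeal
coding density), with F = 138 universal families and 90% sampling — these
numbers only feed the bundled demonstration, not the estimator itself.

## Known limitations

- Dollo reconstruction understates gains for families with multiple true
  origins (convergent acquisition, horizontal transfer).
- The binner assumes exactly `k` compositionally homogeneous populations;
  genomes with strong intra-genomic composition heterogeneity (e.g. recent
  horizontal islands) can fragment across bins at window level even when
  the contig-level majority vote is still correct.
- The completeness estimator inherits the equal-sampling assumption; gene
  linkage on contigs (losing a contig loses neighboring genes together)
  makes real censuses overdispersed relative to the binomial, so real
  intervals are somewhat anti-conservative even though the hypergeometric
  simulation above is conservative.
- Window/step and the partition algorithm behind composition-based
  separation of real assemblies vary between tools; only qualitative
  agreement (two separable clouds) should be expected on real data.
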