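"""Compositional binning of mixed contig sets.

Single-cell amplified genomes sorted from an environmental sample often
co-assemble two organisms — e.g. an ectosymbiotic nanoarchaeon attached to
its crenarchaeal host.  When the two genomes differ strongly in nucleotide
composition, their contigs can be separated without reference genomes:
each contig is profiled in sliding windows by G+C fraction and normalized
tetranucleotide (4-mer) frequencies, the window profiles are embedded by
principal coordinates analysis (classical MDS) of their Euclidean
distances, windows are partitioned by k-means in the first two principal
coordinates, and each contig is assigned to the bin that wins the majority
of its windows.

:class:`CompositionBinner` packages the whole procedure as a
scikit-learn-style clustering estimator; the module-level functions expose
the individual steps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

__all__ = [
    "ContigSet",
    "WindowProfile",
    "BinAssignment",
    "CompositionBinner",
    "gc_content",
    "tetramer_profile",
    "window_profiles",
    "pcoa_embed",
    "cluster_bins",
    "assign_contigs",
]

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_RC_FOLD = np.empty(256, dtype=np.int64)
for _idx in range(256):
    _digits = [(_idx >> (2 * _k)) & 3 for _k in range(4)]  # last base first
    _rc = 0
    for _d in _digits:  # reversing + complementing: read digits last-to-first
        _rc = (_rc << 2) | (3 - _d)
    _RC_FOLD[_idx] = min(_idx, _rc)


class ContigSet:
    """Ordered collection of named nucleotide sequences over {A,C,G,T,N}."""

    def __init__(self, entries):
        self.entries = [(str(cid), str(seq)) for cid, seq in entries]
        ids = [cid for cid, _ in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})[0]
            raise ValueError(f"duplicate contig id {dup!r}")
        for cid, seq in self.entries:
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")

    def ids(self) -> list[str]:
        return [cid for cid, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, contig_id: str) -> str:
        for cid, seq in self.entries:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.entries)


@dataclass
class WindowProfile:
    """Compositional profile of one window of one contig.

    ``gc`` is NaN when the window has no unambiguous base; ``tetramer_freq``
    is the all-zero vector (and ``valid`` is False) when the window contains
    no 4-mer free of ambiguous bases.
    """

    contig_id: str
    start: int
    end: int
    gc: float
    tetramer_freq: np.ndarray

    @property
    def valid(self) -> bool:
        return bool(self.tetramer_freq.sum() > 0)


@dataclass(frozen=True)
class BinAssignment:
    """Majority-vote bin call for one contig."""

    contig_id: str
    bin_label: int | None
    confidence: float
    n_windows: int
    flags: tuple = field(default_factory=tuple)

    @property
    def tied(self) -> bool:
        return "tie" in self.flags


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def gc_content(sequence: str) -> float:
    """G+C fraction of the unambiguous bases; NaN if none; error if empty."""
    if not sequence:
        raise ValueError("empty sequence")
    codes = _encode(sequence)
    unambiguous = int(np.count_nonzero(codes < 4))
    if unambiguous == 0:
        return math.nan
    gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / unambiguous


def tetramer_profile(sequence: str, canonical: bool = False) -> np.ndarray:
    """Normalized frequencies of the 256 overlapping 4-mers.

    4-mers containing an ambiguous base are skipped.  Counting is on the
    given strand; with ``canonical=True`` each 4-mer is folded onto the
    lexicographically smaller of itself and its reverse complement.
    Returns the all-zero vector when no valid 4-mer exists.
    """
    freqs = np.zeros(256)
    if len(sequence) < 4:
        return freqs
    codes = _encode(sequence)
    c0, c1, c2, c3 = codes[:-3], codes[1:-2], codes[2:-1], codes[3:]
    valid = (c0 < 4) & (c1 < 4) & (c2 < 4) & (c3 < 4)
    if not valid.any():
        return freqs
    idx = (c0[valid] << 6) | (c1[valid] << 4) | (c2[valid] << 2) | c3[valid]
    if canonical:
        idx = _RC_FOLD[idx]
    counts = np.bincount(idx, minlength=256).astype(float)
    return counts / counts.sum()


def _window_spans(length: int, window: int, step: int) -> list[tuple[int, int]]:
    if length <= window:
        return [(0, length)]
    starts = list(range(0, length - window + 1, step))
    if starts[-1] + window < length:
        starts.append(length - window)
    return [(s, s + window) for s in starts]


def window_profiles(
    contig_id: str,
    sequence: str,
    window: int = 5000,
    step: int = 1000,
    canonical: bool = False,
) -> list[WindowProfile]:
    """Sliding-window G+C and tetramer profiles of one contig.

    Windows start at 0, step, 2*step, ... while they fit; a final window
    flush with the contig end is added if the regular grid stops short.  A
    contig shorter than the window yields a single whole-contig window.
    """
    if window < 4:
        raise ValueError(f"window must be >= 4, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    profiles = []
    for start, end in _window_spans(len(sequence), window, step):
        sub = sequence[start:end]
        profiles.append(
            WindowProfile(
                contig_id=contig_id,
                start=start,
                end=end,
                gc=gc_content(sub),
                tetramer_freq=tetramer_profile(sub, canonical=canonical),
            )
        )
    return profiles


def pcoa_embed(profiles: list[WindowProfile], dims: int = 2) -> np.ndarray:
    """Classical principal-coordinates embedding of window tetramer profiles.

    Embeds the Euclidean distance matrix among the (valid) profiles'
    tetramer frequency vectors; axes are ordered by decreasing eigenvalue
    and the sign of each axis is fixed by making its largest-magnitude
    coordinate positive.  Raises if fewer than ``dims + 1`` valid profiles
    are supplied.
    """
    valid = [p for p in profiles if p.valid]
    if len(valid) < dims + 1:
        raise ValueError(
            f"need at least dims+1 = {dims + 1} valid profiles, got {len(valid)}"
        )
    X = np.vstack([p.tetramer_freq for p in valid])
    from scipy.spatial.distance import pdist, squareform

    dm = DistanceMatrix(squareform(pdist(X)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-zero negative eigenvalues
        ordination = _skbio_pcoa(dm, method="eigh", number_of_dimensions=dims)
    coords = ordination.samples.to_numpy()[:, :dims]
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords


def cluster_bins(
    coords: np.ndarray,
    gc: np.ndarray | None = None,
    k: int = 2,
    seed: int = 0,
) -> np.ndarray:
    """k-means partition of embedded windows into ``k`` bins.

    Runs k-means (10 restarts, best inertia) on the first two embedding
    axes and renumbers clusters so that label 0 has the lowest mean G+C
    (falling back to the lowest mean first coordinate when G+C values are
    not supplied or tie).  Degenerate all-identical input yields a single
    populated cluster and a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = coords.shape[0]
    if n < k:
        raise ValueError(f"need at least k={k} windows, got {n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    X = coords[:, : min(2, coords.shape[1])]
    if np.allclose(X, X[0]):
        warnings.warn("all windows identical; assigning a single bin", stacklevel=2)
        return np.zeros(n, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = km.fit_predict(X)
    # stable relabelling: ascending mean G+C, ties broken by mean first axis
    keys = []
    for label in range(k):
        members = raw == label
        mean_axis0 = float(X[members, 0].mean()) if members.any() else math.inf
        if gc is not None:
            member_gc = np.asarray(gc, dtype=float)[members]
            member_gc = member_gc[~np.isnan(member_gc)]
            mean_gc = float(member_gc.mean()) if member_gc.size else math.inf
        else:
            mean_gc = 0.0
        keys.append((mean_gc, mean_axis0, label))
    order = [label for _, _, label in sorted(keys)]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[r] for r in raw], dtype=int)


def assign_contigs(window_labels: dict[str, list[int]]) -> list[BinAssignment]:
    """Majority-vote contig assignment from per-window bin labels.

    An exact tie goes to the smallest tied label with confidence equal to
    its vote share and a ``tie`` flag; a contig with no labeled window is
    returned unassigned with an ``unassigned`` flag.
    """
    assignments = []
    for contig_id, labels in window_labels.items():
        if not labels:
            assignments.append(
                BinAssignment(contig_id, None, 0.0, 0, flags=("unassigned",))
            )
            continue
        values, counts = np.unique(np.asarray(labels, dtype=int), return_counts=True)
        top = counts.max()
        winners = values[counts == top]
        label = int(winners.min())
        flags = ("tie",) if len(winners) > 1 else ()
        assignments.append(
            BinAssignment(
                contig_id,
                label,
                float(top) / len(labels),
                len(labels),
                flags=flags,
            )
        )
    return assignments


class CompositionBinner(BaseEstimator, ClusterMixin):
    """Two-way (or k-way) compositional binner for mixed contig sets.

    Parameters
    ----------
    window, step : int
        Sliding-window size and stride in bp.  The defaults (5000/1000)
        give >= 1000 tetramer observations per window, keeping frequency
        noise well below the between-genome signal for strongly divergent
        compositions.
    k : int
        Number of bins.
    dims : int
        Number of principal coordinates to compute (clustering always uses
        the first two).
    canonical : bool
        Fold 4-mers onto reverse-complement-canonical forms before
        normalizing.
    random_state : int
        Seed for k-means restarts.

    Attributes
    ----------
    profiles_ : list of WindowProfile
    embedding_ : ndarray of shape (n_valid_windows, dims)
    window_labels_ : ndarray of per-valid-window bin labels
    assignments_ : list of BinAssignment, one per contig
    labels_ : ndarray of per-contig bin labels (-1 where unassigned)
    contig_ids_ : list of str
    """

    def __init__(
        self,
        window: int = 5000,
        step: int = 1000,
        k: int = 2,
        dims: int = 2,
        canonical: bool = False,
        random_state: int = 0,
    ):
        self.window = window
        self.step = step
        self.k = k
        self.dims = dims
        self.canonical = canonical
        self.random_state = random_state

    def fit(self, X, y=None) -> "CompositionBinner":
        """Profile, embed, cluster and assign a contig set.

        ``X`` is a :class:`ContigSet` or an iterable of (id, sequence)
        pairs; ``y`` is ignored (present for API compatibility).
        """
        contigs = X if isinstance(X, ContigSet) else ContigSet(X)
        profiles: list[WindowProfile] = []
        for cid, seq in contigs:
            profiles.extend(
                window_profiles(cid, seq, self.window, self.step, self.canonical)
            )
        valid = [p for p in profiles if p.valid]
        coords = pcoa_embed(profiles, dims=self.dims)
        gc = np.array([p.gc for p in valid])
        labels = cluster_bins(coords, gc=gc, k=self.k, seed=self.random_state)
        per_contig: dict[str, list[int]] = {cid: [] for cid in contigs.ids()}
        for profile, label in zip(valid, labels):
            per_contig[profile.contig_id].append(int(label))
        assignments = assign_contigs(per_contig)
        self.contig_ids_ = contigs.ids()
        self.profiles_ = profiles
        self.embedding_ = coords
        self.window_labels_ = labels
        self.assignments_ = assignments
        by_id = {a.contig_id: a for a in assignments}
        self.labels_ = np.array(
            [
                by_id[cid].bin_label if by_id[cid].bin_label is not None else -1
                for cid in self.contig_ids_
            ],
            dtype=int,
        )
        return self
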