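"""Genome completeness and total-gene-complement estimation from universal markers.

Given an incomplete genome assembly with ``N`` predicted genes that contains
``f`` out of ``F`` gene families expected to be present exactly once in every
complete genome of the reference clade, the completeness of the assembly is
estimated as ``p = f/F`` and the full gene complement as ``N' = N/p = N*F/f``.

Under the model that every gene of the complete genome is equally and
independently likely to appear in the sequenced fraction, the number of
detected marker families is Binomial(F, p'), where p' is the true (unknown)
completeness.  One-sided confidence bounds on p' are obtained by exact
inversion of the binomial tail probabilities:

* ``p_plus`` is the unique p >= f/F such that P(X <= f | F, p) = alpha
  (upper completeness bound, hence *lower* gene-complement bound), and
* ``p_minus`` is the unique p <= f/F such that P(X >= f | F, p) = alpha
  (lower completeness bound, hence *upper* gene-complement bound).

The 1-alpha confidence interval for the full gene complement is then
``[N/p_plus, N/p_minus]``.  These are the classical one-sided
Clopper-Pearson bounds; each holds with confidence 1-alpha separately, so
the two-sided interval has joint coverage of at least 1-2*alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import binom

__all__ = [
    "MarkerCensus",
    "CompletenessEstimate",
    "MarkerCompletenessEstimator",
    "point_completeness",
    "point_gene_complement",
    "invert_binomial_upper",
    "invert_binomial_lower",
    "gene_complement_interval",
    "coverage_experiment",
]

#: absolute bisection tolerance on the completeness bounds
BISECTION_TOL = 1e-12


@dataclass(frozen=True)
class MarkerCensus:
    """Observed marker census of a (possibly partial) genome assembly.

    Parameters
    ----------
    N : int
        Number of predicted genes in the assembly.
    F : int
        Number of single-copy families expected in every complete genome
        of the reference clade ("universal" marker families).
    f : int
        Number of those families detected in the assembly.
    alpha : float
        One-sided significance level for each confidence bound, in (0, 0.5).
    """

    N: int
    F: int
    f: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.F < 1:
            raise ValueError(f"F must be >= 1, got {self.F}")
        if not 0 <= self.f <= self.F:
            raise ValueError(f"f must satisfy 0 <= f <= F, got f={self.f}, F={self.F}")
        if self.N < self.f:
            raise ValueError(f"N must be >= f, got N={self.N}, f={self.f}")
        _check_alpha(self.alpha)


@dataclass(frozen=True)
class CompletenessEstimate:
    """Point and interval estimates of completeness and gene complement.

    ``ci_low``/``ci_high`` are the integer gene-complement bounds, obtained
    as the ceiling of the real-valued bounds ``N/p_plus`` and ``N/p_minus``
    (the smallest integer gene count consistent with each bound); the raw
    real values are kept in ``ci_low_raw``/``ci_high_raw``.
    """

    p: float
    N_point: float
    p_plus: float
    p_minus: float
    ci_low: int
    ci_high: int
    ci_low_raw: float
    ci_high_raw: float
    alpha: float


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")


def point_completeness(f: int, F: int) -> float:
    """Point estimate of assembly completeness, p = f/F."""
    if F < 1:
        raise ValueError(f"F must be >= 1, got {F}")
    if not 0 <= f <= F:
        raise ValueError(f"f must satisfy 0 <= f <= F, got f={f}, F={F}")
    return f / F


def point_gene_complement(N: int, f: int, F: int) -> float:
    """Point estimate of the full gene complement, N' = N*F/f."""
    if f < 1:
        raise ValueError("no markers detected (f = 0); gene complement is undefined")
    return N * F / f


def _bisect(tail, lo: float, hi: float, alpha: float) -> float:
    """Solve tail(p) = alpha for p in [lo, hi] where tail is monotone."""
    f_lo = tail(lo) - alpha
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = tail(mid) - alpha
        if f_mid == 0.0:
            return mid
        if (f_mid > 0) == (f_lo > 0):
            lo, f_lo = mid, f_mid
        else:
            hi = mid
        if hi - lo <= BISECTION_TOL:
            break
    return 0.5 * (lo + hi)


def invert_binomial_upper(f: int, F: int, alpha: float) -> float:
    """Upper completeness bound p_plus: solves P(X <= f | F, p) = alpha.

    The lower-tail probability is strictly decreasing in p on (f/F, 1),
    so the root is unique; it is located by bisection to within 1e-12.
    For the boundary f = F the lower tail equals 1 for every p and the
    bound is 1.0.
    """
    _check_alpha(alpha)
    if not 0 <= f <= F:
        raise ValueError(f"f must satisfy 0 <= f <= F, got f={f}, F={F}")
    if f == F:
        return 1.0
    return _bisect(lambda p: binom.cdf(f, F, p), f / F, 1.0, alpha)


def invert_binomial_lower(f: int, F: int, alpha: float) -> float:
    """Lower completeness bound p_minus: solves P(X >= f | F, p) = alpha.

    The upper-tail probability is strictly increasing in p on (0, f/F);
    bisection to within 1e-12.  For f = 0 the upper tail is 1 for every p
    and the bound is 0.0.
    """
    _check_alpha(alpha)
    if not 0 <= f <= F:
        raise ValueError(f"f must satisfy 0 <= f <= F, got f={f}, F={F}")
    if f == 0:
        return 0.0
    # P(X >= f) = sf(f-1); increasing in p, so negate for the solver's sign
    return _bisect(lambda p: -binom.sf(f - 1, F, p), 0.0, f / F, -alpha)


def gene_complement_interval(census: MarkerCensus) -> CompletenessEstimate:
    """Assemble the full completeness/gene-complement estimate for a census.

    Raises if no marker was detected (f = 0), since the point complement
    N*F/f is then undefined.
    """
    if census.f < 1:
        raise ValueError("no markers detected (f = 0); gene complement is undefined")
    p = point_completeness(census.f, census.F)
    n_point = point_gene_complement(census.N, census.f, census.F)
    p_plus = invert_binomial_upper(census.f, census.F, census.alpha)
    p_minus = invert_binomial_lower(census.f, census.F, census.alpha)
    low_raw = census.N / p_plus
    high_raw = census.N / p_minus
    return CompletenessEstimate(
        p=p,
        N_point=n_point,
        p_plus=p_plus,
        p_minus=p_minus,
        ci_low=math.ceil(low_raw - 1e-9),
        ci_high=math.ceil(high_raw - 1e-9),
        ci_low_raw=low_raw,
        ci_high_raw=high_raw,
        alpha=census.alpha,
    )


class MarkerCompletenessEstimator:
    """Scikit-learn-style wrapper around the marker completeness estimator.

    Parameters
    ----------
    alpha : float, default 0.05
        One-sided significance level per confidence bound.

    Attributes (after :meth:`fit`)
    ------------------------------
    p_ : float
        Point completeness f/F.
    n_point_ : float
        Point estimate of the full gene complement.
    p_plus_, p_minus_ : float
        Upper and lower completeness bounds.
    ci_ : tuple of int
        Integer gene-complement confidence interval (low, high).
    estimate_ : CompletenessEstimate
        The full estimate record.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"alpha": self.alpha}

    def set_params(self, **params) -> "MarkerCompletenessEstimator":
        for key, value in params.items():
            if key not in {"alpha"}:
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, census: MarkerCensus | None = None, *, N: int | None = None,
            f: int | None = None, F: int | None = None) -> "MarkerCompletenessEstimator":
        """Fit from a :class:`MarkerCensus` or from raw counts N, f, F."""
        if census is None:
            if None in (N, f, F):
                raise ValueError("provide either a MarkerCensus or all of N, f, F")
            census = MarkerCensus(N=N, F=F, f=f, alpha=self.alpha)
        elif census.alpha != self.alpha:
            census = MarkerCensus(N=census.N, F=census.F, f=census.f, alpha=self.alpha)
        est = gene_complement_interval(census)
        self.census_ = census
        self.estimate_ = est
        self.p_ = est.p
        self.n_point_ = est.N_point
        self.p_plus_ = est.p_plus
        self.p_minus_ = est.p_minus
        self.ci_ = (est.ci_low, est.ci_high)
        return self


def coverage_experiment(truth, reps: int, alpha: float = 0.05) -> float:
    """Joint coverage of the gene-complement interval under gene subsampling.

    Repeatedly simulates a marker census from ``truth`` (a
    :class:`sagkit.synthetic.CensusTruth`: genes drawn uniformly without
    replacement from a complement of ``N_total`` genes containing ``F``
    single-copy markers), computes the real-valued interval
    ``[N/p_plus, N/p_minus]`` at the given alpha, and returns the fraction
    of replicates whose interval contains ``N_total`` (inclusive at both
    endpoints).  Expected coverage is at least 1 - 2*alpha up to
    Monte-Carlo error and the discreteness of the binomial.
    """
    from .synthetic import simulate_marker_census

    if reps < 100:
        raise ValueError(f"reps must be >= 100, got {reps}")
    _check_alpha(alpha)
    import numpy as np

    rng = np.random.default_rng(truth.seed)
    hits = 0
    for _ in range(reps):
        sample = simulate_marker_census(truth, rng=rng)
        census = sample.census
        if census.f == 0:
            continue
        p_plus = invert_binomial_upper(census.f, census.F, alpha)
        p_minus = invert_binomial_lower(census.f, census.F, alpha)
        low = census.N / p_plus
        high = census.N / p_minus if p_minus > 0 else math.inf
        if low <= sample.n_total_true <= high:
            hits += 1
    return hits / reps
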