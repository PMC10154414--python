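"""Isoform repertoire overlap statistics.

Two neurons each express ``k`` isoforms drawn uniformly without replacement
from a common pool of ``N``. The number of isoforms they share is then
hypergeometric, and the probability of at least one shared isoform is

    p = 1 - C(N - k, k) / C(N, k)

For the canonical parameters of the system (N = 20,000, k = 50) this overlap
probability is about 12% — high enough that a recognition mechanism must
tolerate some isoform sharing between distinct neurons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom


@dataclass(frozen=True)
class IsoformRepertoire:
    """The set of isoform identities expressed by one cell.

    Identities are integers in ``{0, ..., pool_size - 1}``.
    """

    cell_id: str
    isoforms: frozenset[int]
    pool_size: int

    def __post_init__(self) -> None:
        if len(self.isoforms) > self.pool_size:
            raise ValueError("repertoire larger than pool")
        if self.isoforms and not all(
            0 <= i < self.pool_size for i in self.isoforms
        ):
            raise ValueError("isoform identities must lie in [0, pool_size)")

    @property
    def k(self) -> int:
        return len(self.isoforms)

    def shared_with(self, other: "IsoformRepertoire") -> int:
        return len(self.isoforms & other.isoforms)


@dataclass(frozen=True)
class OverlapStats:
    """Overlap probability and shared-count distribution for a repertoire pair.

    ``p_overlap`` is the probability that two independent repertoires share at
    least one isoform; ``pmf[m]`` is the probability of sharing exactly ``m``.
    """

    N: int
    k: int
    p_overlap: float
    pmf: np.ndarray
    method: str  # "analytic" | "monte_carlo"
    reps: int | None = None
    seed: int | None = None
    standard_error: float | None = None

    @property
    def mean_shared(self) -> float:
        return float(np.arange(self.k + 1) @ self.pmf)


def _check_domain(N: int, k: int) -> None:
    if k < 0 or N < 0 or k > N:
        raise ValueError(f"need 0 <= k <= N, got N={N}, k={k}")


def _log_binom(n: float, k: float) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def shared_count_distribution(N: int, k: int) -> np.ndarray:
    """Hypergeometric pmf of the shared-isoform count m = 0..k.

    Both repertoires draw k of N uniformly without replacement; conditioning
    on one of them, the other hits it m times with probability
    C(k, m) C(N-k, k-m) / C(N, k). The mean is k^2 / N.
    """
    _check_domain(N, k)
    return hypergeom.pmf(np.arange(k + 1), N, k, k)


def overlap_probability_analytic(N: int, k: int) -> OverlapStats:
    """Exact probability that two size-k repertoires from a pool of N overlap.

    Evaluates 1 - C(N-k, k)/C(N, k) through log-gamma arithmetic so the
    N = 20,000 regime does not overflow.
    """
    _check_domain(N, k)
    if k == 0:
        p = 0.0
    elif 2 * k > N:
        p = 1.0  # pigeonhole: repertoires must intersect
    else:
        log_p0 = _log_binom(N - k, k) - _log_binom(N, k)
        p = float(-np.expm1(log_p0))
    return OverlapStats(
        N=N, k=k, p_overlap=p, pmf=shared_count_distribution(N, k),
        method="analytic",
    )


def sample_repertoire_pair(
    N: int, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw two independent uniform-without-replacement repertoires."""
    a = rng.choice(N, size=k, replace=False)
    b = rng.choice(N, size=k, replace=False)
    return a, b


def overlap_probability_mc(
    N: int, k: int, reps: int, seed: int
) -> OverlapStats:
    """Monte-Carlo estimate of the overlap probability.

    Draws ``reps`` independent repertoire pairs and reports the fraction with
    a nonempty intersection, with its binomial standard error.
    """
    _check_domain(N, k)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    hits = 0
    counts = np.zeros(k + 1, dtype=np.int64)
    for _ in range(reps):
        a, b = sample_repertoire_pair(N, k, rng)
        m = len(np.intersect1d(a, b, assume_unique=True))
        counts[m] += 1
        if m > 0:
            hits += 1
    p = hits / reps
    se = float(np.sqrt(p * (1.0 - p) / reps))
    return OverlapStats(
        N=N, k=k, p_overlap=p, pmf=counts / reps,
        method="monte_carlo", reps=reps, seed=seed, standard_error=se,
    )
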