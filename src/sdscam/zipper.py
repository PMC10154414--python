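"""Zipper chain-termination model of self/non-self recognition.

sDscam molecules assemble between two apposed membranes into a linear
zipper of alternating cis (FNIII, same membrane) and trans (Ig1, across
membranes) links. Each incoming cis-dimer must carry an isoform matching
the one exposed at the growing end; the chain terminates at the first
mismatch. Recognition (a switch-like repulsion response) fires only when
the chain reaches a threshold length L*.

Quantitatively, under the availability model used here each extension
exposes an arm isoform drawn uniformly from the extending cell's repertoire
of k isoforms and succeeds iff the apposed cell's repertoire contains it
(copy numbers unlimited), so extensions are i.i.d. gates with per-step
success probability q = |A ∩ B| / k. The chain survives L* gates with
probability q^L*: identical repertoires (q = 1) are always recognized,
while two random neurons sharing a few isoforms almost never are — the
chain-termination tolerance that lets a small isoform pool encode cell
identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sdscam.repertoire_stats import IsoformRepertoire, shared_count_distribution


@dataclass(frozen=True)
class ZipperParams:
    """Parameters of one zipper simulation."""

    repertoire_a: IsoformRepertoire
    repertoire_b: IsoformRepertoire
    threshold_links: int        # L*, chain length triggering recognition
    max_links: int = 10_000     # molecule-supply cap on chain length
    reps: int = 10_000          # independent nucleation attempts simulated
    seed: int = 0
    #: fraction of arms that can never form a trans link (models isoforms,
    #: e.g. many sDscamβ, that fail to trans-dimerize); 0 disables
    inert_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.repertoire_a.pool_size != self.repertoire_b.pool_size:
            raise ValueError("repertoires drawn from different pools")
        if self.repertoire_a.k != self.repertoire_b.k:
            raise ValueError("repertoires of unequal size k")
        if not (1 <= self.threshold_links <= self.max_links):
            raise ValueError("need 1 <= threshold_links <= max_links")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0.0 <= self.inert_fraction <= 1.0):
            raise ValueError("inert_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ZipperResult:
    """Simulated chain lengths and the recognition outcome."""

    chain_lengths: np.ndarray       # successful trans links per run
    recognition_fraction: float     # fraction of runs reaching L*
    q: float                        # per-step extension probability used
    closed_form: float              # q^L* prediction
    threshold_links: int
    standard_error: float           # binomial SE of the recognition fraction


def extension_probability(
    rep_a: IsoformRepertoire, rep_b: IsoformRepertoire
) -> float:
    """Per-step probability q that a zipper between A and B extends.

    The exposed arm isoform is uniform over the extending cell's k
    isoforms and must be present in the apposed repertoire, so
    q = |A ∩ B| / k regardless of which side extends.
    """
    if rep_a.pool_size != rep_b.pool_size:
        raise ValueError("repertoires drawn from different pools")
    if rep_a.k != rep_b.k:
        raise ValueError("repertoires of unequal size k")
    if rep_a.k == 0:
        return 0.0
    return rep_a.shared_with(rep_b) / rep_a.k


def recognition_probability_closed_form(
    q: float, L_star: int
) -> tuple[float, float]:
    """(q^L*, expected chain length) for i.i.d. gates of success q.

    q^L* is the probability a chain survives L* consecutive extension
    gates; the expected terminated chain length is q/(1−q) (infinite when
    q = 1).
    """
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must lie in [0, 1]")
    if L_star < 1:
        raise ValueError("L_star must be >= 1")
    expected = np.inf if q == 1.0 else q / (1.0 - q)
    return q**L_star, expected


def simulate_zipper_growth(params: ZipperParams) -> ZipperResult:
    """Simulate ``reps`` independent zipper nucleations.

    Each run alternates the extending side (bookkeeping only under the
    i.i.d. gate model), draws a fresh arm isoform uniformly from the
    extending repertoire each step, and extends iff the apposed repertoire
    contains it (and the arm is not inert). Runs stop at the first failure,
    at L*, or at max_links; the recognition fraction is the proportion of
    runs whose chain reached L*.
    """
    rng = np.random.default_rng(params.seed)
    a = np.fromiter(params.repertoire_a.isoforms, dtype=np.int64)
    b = np.fromiter(params.repertoire_b.isoforms, dtype=np.int64)
    k = params.repertoire_a.k
    q = extension_probability(params.repertoire_a, params.repertoire_b)
    q_eff = q * (1.0 - params.inert_fraction)

    cap = min(params.threshold_links, params.max_links)
    in_b = np.isin(a, b)
    in_a = np.isin(b, a)
    lengths = np.zeros(params.reps, dtype=np.int64)
    if k > 0:
        # step s extends from side A when s is even, from B when odd
        arm_idx = rng.integers(0, k, size=(params.reps, cap))
        success = np.where(
            (np.arange(cap) % 2 == 0)[None, :], in_b[arm_idx], in_a[arm_idx]
        )
        if params.inert_fraction > 0:
            success &= rng.random((params.reps, cap)) >= params.inert_fraction
        # chain length = number of successes before the first failure
        failed = ~success
        first_fail = np.where(
            failed.any(axis=1), failed.argmax(axis=1), cap
        )
        lengths = first_fail.astype(np.int64)
    recognized = lengths >= params.threshold_links
    frac = float(recognized.mean())
    se = float(np.sqrt(frac * (1.0 - frac) / params.reps))
    return ZipperResult(
        chain_lengths=lengths,
        recognition_fraction=frac,
        q=q_eff,
        closed_form=q_eff**params.threshold_links,
        threshold_links=params.threshold_links,
        standard_error=se,
    )


def tolerance_curve(
    N: int, k: int, L_star: int, mode: str = "conditional_on_m"
) -> np.ndarray | float:
    """Recognition probability versus isoform sharing.

    ``conditional_on_m``: returns an array of shape (k+1, 2) tabulating the
    shared fraction m/k against the recognition probability (m/k)^L* for
    m = 0..k — how much sharing the chain-termination gate tolerates.

    ``marginal``: returns the scalar false-recognition probability between
    two random neurons, Σ_m P_hypergeom(m) · (m/k)^L*. For L* of a few
    links this is orders of magnitude below the raw overlap probability —
    the model's common-isoform tolerance.
    """
    if L_star < 1:
        raise ValueError("L_star must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    m = np.arange(k + 1)
    recog = (m / k) ** L_star
    if mode == "conditional_on_m":
        return np.stack([m / k, recog], axis=1)
    if mode == "marginal":
        pmf = shared_count_distribution(N, k)
        return float(pmf @ recog)
    raise ValueError(f"unknown mode {mode!r}")
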