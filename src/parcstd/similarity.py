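"""Inter-parcellation similarity: Dice coefficient maps and adjusted
mutual information with the exact hypergeometric expected MI.

Two statistics are provided, mirroring the two standard views of atlas
agreement:

* the **Dice coefficient map** — per pair of regions (i in A, j in B),
  the coincidence index ``CI_ij = 2 h_ij / (a_i + b_j)``, a region-level
  overlap matrix;
* the **adjusted mutual information (AMI)** — a single chance-corrected
  score for the whole pair of partitions,

  .. math::

     AMI = \\frac{MI - E[MI]}{\\tfrac12(H(A)+H(B)) - E[MI]}

  where entropies and MI are computed from the voxel-count contingency
  table (natural log, so nats) and ``E[MI]`` is the exact expectation of
  MI under random permutation of one labeling with both sets of region
  sizes held fixed (the hypergeometric model over cell counts ``n_ij``).

AMI is invariant to relabeling of either side, equals 1 for identical
partitions, and is approximately 0 for independent ones — which is the
point of the chance correction: raw MI grows with region count even
between unrelated parcellations.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .core import ContingencyTable, Parcellation, contingency, Domain
from .errors import ConsistencyError, ParameterError

__all__ = [
    "DiceMap",
    "AmiResult",
    "dice_map",
    "entropy",
    "mutual_information",
    "expected_mi",
    "ami",
    "emi_monte_carlo",
    "emi_exhaustive",
    "pairwise_ami",
]

#: Below this |mean(H) - EMI| the AMI denominator is treated as degenerate.
DEGENERATE_EPS = 1e-12


@dataclasses.dataclass
class DiceMap:
    """Per-region-pair Dice coefficients between two parcellations."""

    row_labels: np.ndarray
    col_labels: np.ndarray
    values: np.ndarray


@dataclasses.dataclass
class AmiResult:
    """AMI score together with its ingredients.

    Attributes
    ----------
    ami : float
        Adjusted mutual information (dimensionless, <= 1).
    mi, emi : float
        Observed and expected mutual information, in nats.
    entropy_a, entropy_b : float
        Marginal partition entropies, in nats.
    n_voxels : int
        Size N of the comparison domain.
    domain : str
        Comparison-domain tag the contingency table was built with.
    """

    ami: float
    mi: float
    emi: float
    entropy_a: float
    entropy_b: float
    n_voxels: int
    domain: str = "union_foreground"


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice_map(t: ContingencyTable) -> DiceMap:
    """Dice coefficient ``2 h_ij / (a_i + b_j)`` for every region pair.

    Rows and columns follow the table's ascending label order.  Every
    entry lies in [0, 1]; an entry of exactly 1 means regions i and j
    occupy identical voxel sets.
    """
    a = t.row_marginals.astype(float)
    b = t.col_marginals.astype(float)
    values = 2.0 * t.counts / (a[:, None] + b[None, :])
    return DiceMap(
        row_labels=t.row_labels.copy(),
        col_labels=t.col_labels.copy(),
        values=values,
    )


# ---------------------------------------------------------------------------
# Entropy and mutual information
# ---------------------------------------------------------------------------

def entropy(marginals: Sequence[int] | np.ndarray, n: int) -> float:
    """Partition entropy ``-sum_i (a_i/N) ln(a_i/N)`` in nats.

    Only regions actually present (``a_i > 0``) contribute; a partition
    with a single region has entropy 0.
    """
    if n <= 0:
        raise ParameterError("entropy requires a positive voxel total")
    a = np.asarray(marginals, dtype=float)
    if a.min(initial=0.0) < 0:
        raise ParameterError("marginals must be non-negative")
    if not np.isclose(a.sum(), n):
        raise ConsistencyError(f"marginals sum to {a.sum()}, expected N={n}")
    p = a[a > 0] / n
    return float(-(p * np.log(p)).sum())


def mutual_information(t: ContingencyTable) -> float:
    """Mutual information of the two labelings in nats.

    ``MI = sum_{ij} (h_ij/N) ln(N h_ij / (a_i b_j))`` over nonzero cells.
    Mathematically >= 0; floating-point round-off can leave a residual of
    order -1e-16, which is returned as computed.
    """
    N = t.total
    h = t.counts
    a = t.row_marginals.astype(float)
    b = t.col_marginals.astype(float)
    nz = h > 0
    hz = h[nz].astype(float)
    outer = (a[:, None] * b[None, :])[nz]
    return float((hz / N * np.log(N * hz / outer)).sum())


# ---------------------------------------------------------------------------
# Expected mutual information (exact, hypergeometric)
# ---------------------------------------------------------------------------

def expected_mi(
    row_marginals: Sequence[int] | np.ndarray,
    col_marginals: Sequence[int] | np.ndarray,
    n: int,
) -> float:
    """Exact expected MI under random permutation with fixed marginals.

    For each region pair (i, j) the cell count ``n_ij`` follows a
    hypergeometric law; the expectation sums, over the support
    ``max(1, a_i + b_j - N) .. min(a_i, b_j)``, the MI contribution of
    ``n_ij`` weighted by its probability.  All factorial ratios are
    evaluated through log-gamma, so the computation stays finite for N
    up to at least 1e7 with ~1e3 regions per side.  Starting the support
    at 1 rather than 0 is harmless: the ``n_ij = 0`` term contributes 0.

    For large N the inner sum is restricted to a window around the
    hypergeometric mean ``a_i b_j / N`` outside which Hoeffding's
    inequality for sampling without replacement bounds the cell
    probability below 1e-40; the discarded mass contributes far less
    than double precision resolves.  On small instances the window
    covers the whole support, so tiny-N results are exact.
    """
    a = np.asarray(row_marginals, dtype=np.int64)
    b = np.asarray(col_marginals, dtype=np.int64)
    if a.min(initial=1) < 1 or b.min(initial=1) < 1:
        raise ParameterError("all marginals must be >= 1")
    if a.sum() != n or b.sum() != n:
        raise ConsistencyError(
            f"marginal sums ({a.sum()}, {b.sum()}) disagree with N={n}"
        )
    N = int(n)
    log_N = np.log(N)
    log_b = np.log(b)
    gln_b = gammaln(b + 1)
    gln_Nb = gammaln(N - b + 1)
    gln_N = gammaln(N + 1)

    # P(|n_ij - mean| >= t) <= 2 exp(-2 t^2 / min(a_i, b_j)); t for 1e-40
    half_log_inv_eps = 0.5 * 40 * np.log(10.0)

    emi = 0.0
    for ai, gln_ai, gln_Nai, log_ai in zip(
        a, gammaln(a + 1), gammaln(N - a + 1), np.log(a)
    ):
        mean_ij = ai * b / N
        t_cut = np.ceil(np.sqrt(half_log_inv_eps * np.minimum(ai, b))) + 1
        start = np.maximum(np.maximum(1, ai + b - N),
                           np.floor(mean_ij - t_cut).astype(np.int64))
        end = np.minimum(np.minimum(ai, b),
                         np.ceil(mean_ij + t_cut).astype(np.int64))
        width = int((end - start).max()) + 1
        # nij grid: one row per column-region j, padded past each support end
        nij = start[:, None] + np.arange(width)[None, :]
        valid = nij <= end[:, None]
        nij = np.where(valid, nij, 1)  # dummy value, masked out below
        contrib = nij / N * (log_N + np.log(nij) - log_ai - log_b[:, None])
        log_p = (
            gln_ai
            + gln_b[:, None]
            + gln_Nai
            + gln_Nb[:, None]
            - gln_N
            - gammaln(nij + 1)
            - gammaln(ai - nij + 1)
            - gammaln(b[:, None] - nij + 1)
            - gammaln(N - ai - b[:, None] + nij + 1)
        )
        emi += float(np.where(valid, contrib * np.exp(log_p), 0.0).sum())
    return emi


def emi_monte_carlo(
    row_marginals: Sequence[int] | np.ndarray,
    col_marginals: Sequence[int] | np.ndarray,
    n: int,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the expected MI: (mean, standard error).

    Draws ``reps`` uniform random permutations of one labeling against
    the other, both labelings expanded from the given marginals, and
    averages the MI.  Serves as an independent check of
    :func:`expected_mi`; reproducible under a fixed seed.
    """
    if reps < 100:
        raise ParameterError("reps must be >= 100 for a usable standard error")
    a = np.asarray(row_marginals, dtype=np.int64)
    b = np.asarray(col_marginals, dtype=np.int64)
    if a.sum() != n or b.sum() != n:
        raise ConsistencyError("marginal sums disagree with N")
    la = np.repeat(np.arange(a.size), a)
    lb = np.repeat(np.arange(b.size), b)
    rng = np.random.default_rng(seed)
    N = int(n)
    af = a.astype(float)
    bf = b.astype(float)
    outer = af[:, None] * bf[None, :]
    mis = np.empty(reps)
    for r in range(reps):
        perm = rng.permutation(N)
        counts = np.zeros((a.size, b.size), dtype=np.int64)
        np.add.at(counts, (la, lb[perm]), 1)
        nz = counts > 0
        h = counts[nz].astype(float)
        mis[r] = (h / N * np.log(N * h / outer[nz])).sum()
    se = float(mis.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return float(mis.mean()), se


def emi_exhaustive(
    row_marginals: Sequence[int] | np.ndarray,
    col_marginals: Sequence[int] | np.ndarray,
    n: int,
) -> float:
    """Mean MI over *all* N! voxel permutations (brute-force oracle).

    Only feasible for tiny N (<= 8 or so); exists to pin down
    :func:`expected_mi` exactly on small instances.  The permutations act
    on voxel positions, so every arrangement of the second labeling is
    counted with its correct multiplicity.
    """
    a = np.asarray(row_marginals, dtype=np.int64)
    b = np.asarray(col_marginals, dtype=np.int64)
    if a.sum() != n or b.sum() != n:
        raise ConsistencyError("marginal sums disagree with N")
    N = int(n)
    la = np.repeat(np.arange(a.size), a)
    lb = np.repeat(np.arange(b.size), b)
    perms = np.array(list(itertools.permutations(range(N))), dtype=np.int64)
    ka, kb = a.size, b.size
    codes = la[None, :] * kb + lb[perms]  # (N!, N)
    P = perms.shape[0]
    counts = np.zeros((P, ka * kb), dtype=np.int64)
    np.add.at(counts, (np.repeat(np.arange(P), N), codes.ravel()), 1)
    outer = (a.astype(float)[:, None] * b.astype(float)[None, :]).ravel()
    h = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = h / N * np.log(N * h / outer[None, :])
    terms[h == 0] = 0.0
    return float(terms.sum(axis=1).mean())


# ---------------------------------------------------------------------------
# AMI
# ---------------------------------------------------------------------------

def _partitions_identical(t: ContingencyTable) -> bool:
    # identical as partitions <=> the table is a (scaled) permutation matrix
    nz_rows = (t.counts > 0).sum(axis=1)
    nz_cols = (t.counts > 0).sum(axis=0)
    return bool(np.all(nz_rows == 1) and np.all(nz_cols == 1))


def ami(t: ContingencyTable, domain: str = "union_foreground") -> AmiResult:
    """Adjusted mutual information of a contingency table.

    Uses the arithmetic mean of the two entropies in the denominator.
    When the denominator is degenerate (|mean(H) - EMI| < 1e-12, e.g.
    both sides a single region), the score is 1.0 if the two labelings
    are identical as partitions and 0.0 otherwise.
    """
    N = t.total
    h_a = entropy(t.row_marginals, N)
    h_b = entropy(t.col_marginals, N)
    mi = mutual_information(t)
    emi = expected_mi(t.row_marginals, t.col_marginals, N)
    denom = 0.5 * (h_a + h_b) - emi
    if abs(denom) < DEGENERATE_EPS:
        score = 1.0 if _partitions_identical(t) else 0.0
    else:
        score = (mi - emi) / denom
    return AmiResult(
        ami=float(score),
        mi=mi,
        emi=emi,
        entropy_a=h_a,
        entropy_b=h_b,
        n_voxels=N,
        domain=domain,
    )


def pairwise_ami(
    atlases: Sequence[Parcellation],
    domain: Domain = "union_foreground",
    include_background: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Symmetric AMI matrix over a list of parcellations on one grid.

    Returns (names, matrix); the diagonal is exactly 1.  Each off-diagonal
    entry is computed once and mirrored, so the matrix is symmetric by
    construction (AMI itself is symmetric in its two arguments).
    """
    n = len(atlases)
    names = [p.name for p in atlases]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            t = contingency(
                atlases[i], atlases[j], domain=domain,
                include_background=include_background,
            )
            mat[i, j] = mat[j, i] = ami(t, domain=domain).ami
    return names, mat
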