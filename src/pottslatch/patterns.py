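"""Random correlated Potts patterns and their pairwise statistics.

A stored memory is an assignment, to each of ``N`` Potts units, of one of
``S`` active states (labelled 1..S) or the quiescent background state 0.
Entries are sampled i.i.d. across units and patterns: a unit is active with
probability ``a`` (the sparsity) and, if active, picks one of the ``S``
states uniformly, so each active state carries probability ``a/S``.
Patterns built this way are "randomly correlated": any two of them share
active, same-state units on a fraction of about ``a/S`` of the active
support, which is what fuels latching transitions between them.

Two correlation coefficients summarise a pair of patterns: ``C_as``, the
fraction of units active in the same state in both, and ``C_ad``, the
fraction active in both but in different states, each normalised by the
*expected* active count ``N*a``.  The semantic distance
``d = (C_ad - C_as + 1) / 2`` maps identical patterns to 0 and combines
both coefficients into a single [0, 1] index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatternSet",
    "PairStats",
    "generate_patterns",
    "correlation_as",
    "correlation_ad",
    "distance_d",
    "pair_stats",
    "distance_matrix",
    "expected_c_as",
    "expected_c_ad",
    "expected_distance",
    "save_patterns",
    "load_patterns",
]


@dataclass
class PatternSet:
    """The ``p`` stored memories over ``N`` units with ``S`` states each.

    Attributes
    ----------
    xi : ndarray of shape (p, N), integer
        ``xi[mu, i]`` is the state of unit ``i`` in pattern ``mu``;
        0 means quiescent, 1..S are the active states.
    S : int
        Number of active states per unit.
    a : float
        Sparsity: the probability that a unit is active in a pattern.
    seed : int or None
        Seed used at generation time, kept for provenance.
    """

    xi: np.ndarray
    S: int
    a: float
    seed: int | None = None

    p: int = field(init=False)
    N: int = field(init=False)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi)
        if self.xi.ndim != 2:
            raise ValueError("xi must be a (p, N) matrix")
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("sparsity a must lie in [0, 1]")
        if self.xi.size and (self.xi.min() < 0 or self.xi.max() > self.S):
            raise ValueError("pattern entries must lie in {0, ..., S}")
        self.p, self.N = self.xi.shape

    def active(self) -> np.ndarray:
        """Boolean (p, N) mask of active units."""
        return self.xi > 0


@dataclass(frozen=True)
class PairStats:
    """Correlation coefficients and distance for one pattern pair."""

    c_as: float
    c_ad: float
    d: float


def generate_patterns(
    p: int, N: int, S: int, a: float, seed: int | np.random.Generator | None = None
) -> PatternSet:
    """Draw ``p`` random Potts patterns of ``N`` units.

    Each entry is 0 with probability ``1 - a`` and ``k`` in {1..S} with
    probability ``a/S``, independently across units and patterns.  The
    number of active units per pattern is therefore binomial with mean
    ``N*a``, not fixed.

    Parameters
    ----------
    seed : int, Generator or None
        Source of randomness; an int is turned into a fresh Generator.
    """
    if p < 1 or N < 1:
        raise ValueError("p and N must be >= 1")
    if S < 1:
        raise ValueError("S must be >= 1")
    if not (0.0 <= a <= 1.0):
        raise ValueError("sparsity a must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    active = rng.random((p, N)) < a
    states = rng.integers(1, S + 1, size=(p, N))
    xi = np.where(active, states, 0).astype(np.int16)
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return PatternSet(xi=xi, S=S, a=a, seed=stored_seed)


def _check_pair(patterns: PatternSet, mu: int, nu: int) -> tuple[np.ndarray, np.ndarray]:
    xi = patterns.xi
    return xi[mu], xi[nu]  # IndexError if out of bounds, as documented


def correlation_as(patterns: PatternSet, mu: int, nu: int) -> float:
    """Active-same-state correlation ``C_as``.

    ``C_as = (1/(N a)) * sum_i [xi_i^mu > 0] * [xi_i^mu == xi_i^nu]``.
    The normaliser is the expected active count ``N*a``, not the realised
    one, so the self-correlation ``C_as(mu, mu)`` equals the realised
    active fraction divided by ``a`` and may differ slightly from 1.
    """
    x, y = _check_pair(patterns, mu, nu)
    hits = np.count_nonzero((x > 0) & (x == y))
    return hits / (patterns.N * patterns.a)


def correlation_ad(patterns: PatternSet, mu: int, nu: int) -> float:
    """Active-different-state correlation ``C_ad``.

    ``C_ad = (1/(N a)) * sum_i [xi_i^mu > 0] * [xi_i^nu > 0] *
    [xi_i^mu != xi_i^nu]``; it vanishes for identical patterns.
    """
    x, y = _check_pair(patterns, mu, nu)
    hits = np.count_nonzero((x > 0) & (y > 0) & (x != y))
    return hits / (patterns.N * patterns.a)


def distance_d(patterns: PatternSet, mu: int, nu: int) -> float:
    """Semantic distance ``d = (C_ad - C_as + 1) / 2``, in [0, 1]."""
    return (correlation_ad(patterns, mu, nu) - correlation_as(patterns, mu, nu) + 1.0) / 2.0


def pair_stats(patterns: PatternSet, mu: int, nu: int) -> PairStats:
    """All three pairwise statistics for patterns ``mu`` and ``nu``."""
    c_as = correlation_as(patterns, mu, nu)
    c_ad = correlation_ad(patterns, mu, nu)
    return PairStats(c_as=c_as, c_ad=c_ad, d=(c_ad - c_as + 1.0) / 2.0)


def distance_matrix(patterns: PatternSet) -> np.ndarray:
    """Full (p, p) matrix of pairwise distances ``d``.

    Vectorised; agrees entry-for-entry with :func:`distance_d`.
    """
    xi = patterns.xi
    act = xi > 0
    norm = patterns.N * patterns.a
    # same-state and different-state co-activation counts for all pairs
    same = np.zeros((patterns.p, patterns.p))
    both = (act.astype(np.int32) @ act.T.astype(np.int32)).astype(float)
    for k in range(1, patterns.S + 1):
        ik = (xi == k).astype(np.int32)
        same += ik @ ik.T
    c_as = same / norm
    c_ad = (both - same) / norm
    return (c_ad - c_as + 1.0) / 2.0


def expected_c_as(a: float, S: int) -> float:
    """Mean of ``C_as`` over random pattern pairs: ``a/S``."""
    return a / S


def expected_c_ad(a: float, S: int) -> float:
    """Mean of ``C_ad`` over random pattern pairs: ``a (S-1)/S``."""
    return a * (S - 1) / S


def expected_distance(a: float, S: int) -> float:
    """Mean distance over random pairs: ``(S-2) a / (2 S) + 1/2``."""
    return (S - 2) * a / (2 * S) + 0.5


def save_patterns(patterns: PatternSet, path: str | Path) -> None:
    """Write a pattern set as plain text: a metadata header plus one
    whitespace-separated integer row per pattern."""
    path = Path(path)
    header = (
        f"p={patterns.p} N={patterns.N} S={patterns.S} "
        f"a={patterns.a!r} seed={patterns.seed}"
    )
    np.savetxt(path, patterns.xi, fmt="%d", header=header)


def load_patterns(path: str | Path) -> PatternSet:
    """Load a pattern set written by :func:`save_patterns`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise ValueError("missing metadata header")
    meta = dict(tok.split("=", 1) for tok in first[1:].split())
    xi = np.loadtxt(path, dtype=np.int16, ndmin=2)
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    ps = PatternSet(xi=xi, S=int(meta["S"]), a=float(meta["a"]), seed=seed)
    if ps.p != int(meta["p"]) or ps.N != int(meta["N"]):
        raise ValueError("header does not match matrix shape")
    return ps
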