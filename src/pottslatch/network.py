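"""Dilute connectivity, Hebbian couplings and short-term-memory boosts.

Long-term memories are wired into tensor couplings between Potts units by a
one-shot covariance (Hebbian) rule over the stored patterns.  Short-term
storage of a list of ``L`` of those patterns is modelled as a transient
"boost" of one pre-existing parameter:

* Model 1 raises the local feedback ``w`` of every unit active in a listed
  pattern (attractor deepening at the patch level);
* Model 2 lowers the adaptive threshold of every (unit, state) pair used by
  a listed pattern (reduced firing-rate adaptation);
* Model 3a adds ``delta_J`` to every coupling whose state pair belongs to a
  single listed pattern (autoassociative short-term potentiation);
* Model 3b extends 3a to state pairs drawn from *any two* listed patterns
  (hetero- plus autoassociative potentiation).

Serial recall adds a separate heteroassociative tensor that links the
states of each instructed item to those of its successor with strength
``lambda``; it is driven by the adaptation thresholds, not the activations,
so it is kept apart from the autoassociative couplings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .patterns import PatternSet

__all__ = [
    "Connectivity",
    "WeightTensor",
    "HeteroWeights",
    "BoostConfig",
    "build_connectivity",
    "build_weights",
    "apply_model1",
    "model2_theta_mask",
    "model3a_mask",
    "model3b_mask",
    "apply_model3a",
    "apply_model3b",
    "build_heteroassociative",
    "sample_instruction_sequences",
]


@dataclass
class Connectivity:
    """Dilute random connectivity: unit ``i`` receives input from the
    ``c_m`` distinct units listed in ``nbr[i]`` (no self-connections;
    asymmetric in general)."""

    nbr: np.ndarray  # (N, c_m) int32, presynaptic indices per unit
    N: int = field(init=False)
    c_m: int = field(init=False)

    def __post_init__(self) -> None:
        self.nbr = np.asarray(self.nbr, dtype=np.int32)
        self.N, self.c_m = self.nbr.shape

    def as_dense(self) -> np.ndarray:
        """(N, N) binary adjacency, c[i, j] = 1 iff j feeds i."""
        c = np.zeros((self.N, self.N), dtype=np.int8)
        rows = np.repeat(np.arange(self.N), self.c_m)
        c[rows, self.nbr.ravel()] = 1
        return c


@dataclass
class WeightTensor:
    """Couplings J_{ijkl}, stored as dense S x S blocks on the dilute
    (i, j) pairs only (c_m << N in the regimes of interest).

    ``blocks[i, m, k-1, l-1]`` holds J_{i, nbr[i, m], k, l} for active
    states k, l in 1..S; components with k=0 or l=0 are identically zero
    and not stored.
    """

    nbr: np.ndarray  # (N, c_m) int32
    blocks: np.ndarray  # (N, c_m, S, S) float64
    S: int

    @property
    def N(self) -> int:
        return self.nbr.shape[0]

    @property
    def c_m(self) -> int:
        return self.nbr.shape[1]

    def entry(self, i: int, j: int, k: int, l: int) -> float:
        """J_{ijkl} with full index semantics (0 where c_ij=0 or k=0 or l=0)."""
        if k == 0 or l == 0:
            return 0.0
        pos = np.nonzero(self.nbr[i] == j)[0]
        if pos.size == 0:
            return 0.0
        return float(self.blocks[i, pos[0], k - 1, l - 1])

    def copy(self) -> "WeightTensor":
        return WeightTensor(nbr=self.nbr, blocks=self.blocks.copy(), S=self.S)


@dataclass
class HeteroWeights:
    """Heteroassociative couplings for serial recall.

    Entries are lambda wherever state ``k`` of unit ``i`` belongs to the
    successor item and state ``l`` of unit ``j`` to its predecessor, for
    some adjacent pair of the instruction; zero elsewhere (and on the
    diagonal i=j).  Stored as a CSR matrix over flattened (unit, state)
    indices so the field contribution is a single sparse mat-vec.
    """

    csr: sp.csr_matrix  # (N*S, N*S)
    lam: float
    N: int
    S: int

    def entry(self, i: int, j: int, k: int, l: int) -> float:
        if k == 0 or l == 0 or i == j:
            return 0.0
        return float(self.csr[i * self.S + (k - 1), j * self.S + (l - 1)])


@dataclass
class BoostConfig:
    """Which boost to apply, how strongly, and to which stored patterns."""

    model: str = "none"  # one of none, M1, M2, M3a, M3b
    delta: float = 0.0
    stm_list: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in ("none", "M1", "M2", "M3a", "M3b"):
            raise ValueError(f"unknown boost model {self.model!r}")
        if self.delta < 0:
            raise ValueError("boost magnitude must be >= 0")
        if len(set(self.stm_list)) != len(self.stm_list):
            raise ValueError("stm_list must not contain duplicates")
        self.stm_list = tuple(int(m) for m in self.stm_list)


def build_connectivity(
    N: int, c_m: int, seed: int | np.random.Generator | None = None
) -> Connectivity:
    """Uniform dilute connectivity: each unit receives from ``c_m``
    distinct others, chosen uniformly at random without self-loops."""
    if not (1 <= c_m <= N - 1):
        raise ValueError(f"c_m must satisfy 1 <= c_m <= N-1, got c_m={c_m}, N={N}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    nbr = np.empty((N, c_m), dtype=np.int32)
    others = np.arange(N - 1)
    for i in range(N):
        pick = rng.choice(N - 1, size=c_m, replace=False)
        # skip index i by shifting the upper range
        nbr[i] = np.where(pick >= i, pick + 1, pick)
    return Connectivity(nbr=nbr)


def build_weights(patterns: PatternSet, conn: Connectivity) -> WeightTensor:
    """Hebbian covariance couplings.

    J_{ijkl} = c_ij / (c_m a (1 - a/S)) * sum_mu
    (delta_{xi_i^mu, k} - a/S)(delta_{xi_j^mu, l} - a/S) for k, l >= 1.
    """
    if patterns.N != conn.N:
        raise ValueError("patterns and connectivity disagree on N")
    N, c_m, S, a = conn.N, conn.c_m, patterns.S, patterns.a
    blocks = np.zeros((N, c_m, S, S))
    norm = c_m * a * (1.0 - a / S)
    ks = np.arange(1, S + 1)
    for mu in range(patterns.p):
        xi = patterns.xi[mu]
        v = (xi[:, None] == ks[None, :]).astype(np.float64) - a / S  # (N, S)
        vj = v[conn.nbr]  # (N, c_m, S)
        blocks += v[:, None, :, None] * vj[:, :, None, :]
    blocks /= norm
    return WeightTensor(nbr=conn.nbr.copy(), blocks=blocks, S=S)


def _active_state_mask(patterns: PatternSet, stm_list) -> np.ndarray:
    """(N, S) boolean: state k is used at unit i by some listed pattern."""
    mask = np.zeros((patterns.N, patterns.S), dtype=bool)
    for mu in stm_list:
        xi = patterns.xi[mu]
        act = xi > 0
        mask[np.nonzero(act)[0], xi[act] - 1] = True
    return mask


def apply_model1(
    w: float, delta_w: float, patterns: PatternSet, stm_list
) -> np.ndarray:
    """Per-unit local feedback: ``w + delta_w`` for units active in any
    listed pattern, ``w`` elsewhere.  Returns an (N,) vector."""
    if delta_w < 0:
        raise ValueError("delta_w must be >= 0")
    member = np.zeros(patterns.N, dtype=bool)
    for mu in stm_list:
        member |= patterns.xi[mu] > 0
    return np.where(member, w + delta_w, w).astype(np.float64)


def model2_theta_mask(patterns: PatternSet, stm_list) -> np.ndarray:
    """(N, S) indicator of (unit, state) pairs whose adaptive threshold is
    reduced: exactly those used by at least one listed pattern."""
    return _active_state_mask(patterns, stm_list)


def model3a_mask(patterns: PatternSet, nbr: np.ndarray, stm_list) -> np.ndarray:
    """(N, c_m, S, S) boolean: coupling (i, j, k, l) belongs to a *single*
    listed pattern, i.e. (k, l) = (xi_i^mu, xi_j^mu) for some mu with both
    units active."""
    N, c_m = nbr.shape
    S = patterns.S
    mask = np.zeros((N, c_m, S, S), dtype=bool)
    for mu in stm_list:
        xi = patterns.xi[mu]
        ki = xi - 1  # (N,)
        lj = xi[nbr] - 1  # (N, c_m)
        ok = (ki[:, None] >= 0) & (lj >= 0)
        ii, mm = np.nonzero(ok)
        mask[ii, mm, ki[ii], lj[ii, mm]] = True
    return mask


def model3b_mask(patterns: PatternSet, nbr: np.ndarray, stm_list) -> np.ndarray:
    """(N, c_m, S, S) boolean: k is used at i by *some* listed pattern and
    l is used at j by *some* (possibly different) listed pattern."""
    side = _active_state_mask(patterns, stm_list)  # (N, S)
    return side[:, None, :, None] & side[nbr][:, :, None, :]


def apply_model3a(
    J: WeightTensor, delta_J: float, patterns: PatternSet, stm_list
) -> WeightTensor:
    """Autoassociative short-term potentiation (a new tensor; J unchanged)."""
    if delta_J < 0:
        raise ValueError("delta_J must be >= 0")
    out = J.copy()
    out.blocks += delta_J * model3a_mask(patterns, J.nbr, stm_list)
    return out


def apply_model3b(
    J: WeightTensor, delta_J: float, patterns: PatternSet, stm_list
) -> WeightTensor:
    """Auto- plus heteroassociative short-term potentiation across the list."""
    if delta_J < 0:
        raise ValueError("delta_J must be >= 0")
    out = J.copy()
    out.blocks += delta_J * model3b_mask(patterns, J.nbr, stm_list)
    return out


def build_heteroassociative(
    patterns: PatternSet, instruction, lam: float
) -> HeteroWeights:
    """Heteroassociative couplings encoding an instructed order.

    J^het_{ijkl} = lam iff k = xi_i^{I_{mu+1}} and l = xi_j^{I_mu} for some
    adjacent pair (I_mu, I_{mu+1}) of the instruction, with both states
    active and i != j; 0 elsewhere.  Entries are therefore in {0, lam}
    even when several transitions map onto the same (i, j, k, l).
    """
    instruction = list(instruction)
    if len(instruction) == 0:
        raise ValueError("instruction must not be empty")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    N, S = patterns.N, patterns.S
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    transitions = {(instruction[t], instruction[t + 1]) for t in range(len(instruction) - 1)}
    for pred, succ in transitions:
        xi_succ = patterns.xi[succ]
        xi_pred = patterns.xi[pred]
        ii = np.nonzero(xi_succ > 0)[0]
        jj = np.nonzero(xi_pred > 0)[0]
        if ii.size == 0 or jj.size == 0:
            continue
        I, Jx = np.meshgrid(ii, jj, indexing="ij")
        keep = I != Jx  # no self-connections in the field sum
        I, Jx = I[keep], Jx[keep]
        rows.append(I * S + (xi_succ[I] - 1))
        cols.append(Jx * S + (xi_pred[Jx] - 1))
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        data = np.ones(r.size)
        m = sp.coo_matrix((data, (r, c)), shape=(N * S, N * S)).tocsr()
        m.data[:] = 1.0  # Theta(): duplicate transitions collapse to one
        m = m * lam
    else:
        m = sp.csr_matrix((N * S, N * S))
    return HeteroWeights(csr=m, lam=lam, N=N, S=S)


def sample_instruction_sequences(
    n_seq: int,
    L: int,
    alphabet,
    seed: int | np.random.Generator | None = None,
    max_draws: int = 10**6,
) -> list[tuple[int, ...]]:
    """Draw distinct instruction sequences with no AA or ABA subsequence.

    Items are chosen sequentially, uniform over the alphabet minus the
    previous item and the one before it, which samples uniformly over
    exactly the admissible set (every valid sequence has the same number
    of choices at each step).  Repetitions of items at lag >= 3 are
    allowed.
    """
    alphabet = list(alphabet)
    n = len(alphabet)
    if L >= 3 and n < 3:
        raise ValueError("alphabet must have >= 3 items for L >= 3")
    if L >= 2 and n < 2:
        raise ValueError("alphabet must have >= 2 items for L >= 2")
    if L < 1:
        raise ValueError("L must be >= 1")
    # count of admissible sequences, to detect unsatisfiable n_seq
    n_valid = n
    for t in range(1, L):
        n_valid *= (n - 1) if t == 1 else (n - 2)
    if n_seq > n_valid:
        raise ValueError(
            f"only {n_valid} admissible sequences exist for L={L}, |alphabet|={n}"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: list[tuple[int, ...]] = []
    seen: set[tuple[int, ...]] = set()
    draws = 0
    while len(out) < n_seq:
        if draws >= max_draws:
            raise RuntimeError("exceeded draw budget while sampling instructions")
        draws += 1
        seq = [alphabet[rng.integers(n)]]
        for t in range(1, L):
            banned = {seq[-1]} if t == 1 else {seq[-1], seq[-2]}
            options = [x for x in alphabet if x not in banned]
            seq.append(options[rng.integers(len(options))])
        tup = tuple(seq)
        if tup not in seen:
            seen.add(tup)
            out.append(tup)
    return out
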