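"""Closed-form capacity estimates and null-model baselines.

Each short-term-memory boost acts on a different class of network elements
(units, unit-states, or couplings).  When ``L`` list items are boosted, the
fraction ``P_L`` of elements touched grows with ``L``; once most elements
are shared with long-term memories the boost no longer discriminates the
list, so the criterion ``P_L = 1 - 1/e`` defines a critical list length
``L_c`` per model.  These closed forms use natural logarithms.

Two null models bracket what retrieval trajectories alone can achieve:
an equal-probability random walk over ``L`` items (stochastic retrieval,
giving the classic sqrt(L) growth of distinct visits until a first revisit,
a.k.a. the birthday problem), and a deterministic greedy-similarity search
that always hops to the most similar item and therefore terminates by
entering a loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "CapacityEstimate",
    "boosted_fraction",
    "critical_length",
    "capacity_estimate",
    "random_walk_null",
    "birthday_expected_distinct",
    "greedy_similarity_baseline",
    "greedy_scaling",
]

_MODELS = ("M1", "M2", "M3a", "M3b")


@dataclass(frozen=True)
class CapacityEstimate:
    model: str
    a: float
    S: int
    L_c: float


def _check_model(model: str, a: float, S: int) -> None:
    if model not in _MODELS:
        raise ValueError(f"model must be one of {_MODELS}, got {model!r}")
    if not (0.0 <= a <= 1.0):
        raise ValueError("sparsity a must lie in [0, 1]")
    if S < 1:
        raise ValueError("S must be >= 1")


def boosted_fraction(model: str, L: float, a: float, S: int) -> float:
    """Fraction P_L of network elements touched by boosting ``L`` items.

    M1 counts units, M2 unit-states, M3a/M3b coupling state-pairs:

    * M1:  1 - (1 - a)^L
    * M2:  1 - (1 - a/S)^L
    * M3a: 1 - (1 - a^2/S^2)^L
    * M3b: (1 - (1 - a/S)^L)^2
    """
    _check_model(model, a, S)
    if L < 0:
        raise ValueError("L must be >= 0")
    if model == "M1":
        return 1.0 - (1.0 - a) ** L
    if model == "M2":
        return 1.0 - (1.0 - a / S) ** L
    if model == "M3a":
        return 1.0 - (1.0 - (a / S) ** 2) ** L
    return (1.0 - (1.0 - a / S) ** L) ** 2


def critical_length(model: str, a: float, S: int) -> float:
    """Continuous list length at which P_L reaches 1 - 1/e.

    Natural logarithms throughout:

    * M1:  -1 / ln(1 - a)
    * M2:  -1 / ln(1 - a/S)
    * M3a: -1 / ln(1 - a^2/S^2)
    * M3b: ln(1 - sqrt(1 - 1/e)) / ln(1 - a/S)
    """
    _check_model(model, a, S)
    if a == 0.0:
        raise ValueError("L_c diverges at a = 0")
    if a / S >= 1.0:
        raise ValueError("requires a/S < 1")
    if model == "M1":
        if a == 1.0:
            raise ValueError("L_c undefined at a = 1 for M1")
        return -1.0 / math.log(1.0 - a)
    if model == "M2":
        return -1.0 / math.log(1.0 - a / S)
    if model == "M3a":
        return -1.0 / math.log(1.0 - (a / S) ** 2)
    return math.log(1.0 - math.sqrt(1.0 - 1.0 / math.e)) / math.log(1.0 - a / S)


def capacity_estimate(model: str, a: float, S: int) -> CapacityEstimate:
    return CapacityEstimate(model=model, a=a, S=S, L_c=critical_length(model, a, S))


def birthday_expected_distinct(L: int) -> float:
    """Closed-form mean number of *distinct* items drawn i.i.d. uniform
    over ``L`` before the first repeat.

    The classical birthday asymptotic sqrt(pi L / 2) + 2/3 counts draws
    including the colliding one; the distinct count is one fewer.
    """
    return math.sqrt(math.pi * L / 2.0) + 2.0 / 3.0 - 1.0


_STOP_RULES = ("first_revisit", "repeated_transition", "third_occurrence", "budget")


@njit(cache=True)
def _walk_counts(L, n_runs, rule_id, forbid_immediate, seeds):  # pragma: no cover
    out = np.empty(n_runs, dtype=np.float64)
    for run in range(n_runs):
        np.random.seed(seeds[run])
        visited = np.zeros(L, dtype=np.int64)  # occurrence counts
        trans = np.zeros((L, L), dtype=np.uint8)
        distinct = 0
        prev = -1
        used = 0
        h = 0
        t = 0
        while True:
            x = np.random.randint(0, L)
            if forbid_immediate and x == prev:
                continue
            t += 1
            if rule_id == 0:  # first_revisit
                if visited[x] > 0:
                    break
            elif rule_id == 1:  # repeated_transition
                if prev >= 0:
                    if trans[prev, x] > 0:
                        break
                    trans[prev, x] = 1
            elif rule_id == 2:  # third_occurrence
                if visited[x] >= 2:
                    break
            else:  # budget: stop before consuming once used >= 2L - h
                if used >= 2 * L - h:
                    break
                used += 1
            if visited[x] == 0:
                distinct += 1
                h += 1
            visited[x] += 1
            prev = x
            if t > 100000:
                break
        out[run] = distinct
    return out


def random_walk_null(
    L: int,
    stop_rule: str = "first_revisit",
    n_runs: int = 10000,
    seed: int | None = None,
    forbid_immediate: bool = True,
) -> tuple[float, float]:
    """Equal-probability random-walk null model over ``L`` items.

    Draws items uniformly (by default forbidding immediate repeats, which
    mirrors the way adaptation suppresses AA steps in the network; pass
    ``forbid_immediate=False`` for the pure i.i.d. birthday setting),
    applies the stopping rule, and returns the mean number of distinct
    items seen before the stop, with its standard error.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if stop_rule not in _STOP_RULES:
        raise ValueError(f"stop_rule must be one of {_STOP_RULES}")
    rule_id = _STOP_RULES.index(stop_rule)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_runs).astype(np.int64)
    counts = _walk_counts(L, n_runs, rule_id, forbid_immediate, seeds)
    return float(counts.mean()), float(counts.std(ddof=1) / math.sqrt(n_runs))


def random_walk_scaling(
    L_values,
    stop_rule: str = "first_revisit",
    n_runs: int = 10000,
    seed: int | None = None,
    forbid_immediate: bool = False,
) -> tuple[float, np.ndarray]:
    """Log-log OLS slope of mean distinct count versus ``L``.

    Returns (slope, means); for the i.i.d. first-revisit rule the slope is
    about 0.5.
    """
    rng = np.random.default_rng(seed)
    means = np.array(
        [
            random_walk_null(
                L,
                stop_rule,
                n_runs,
                seed=int(rng.integers(2**31 - 1)),
                forbid_immediate=forbid_immediate,
            )[0]
            for L in L_values
        ]
    )
    x = np.log(np.asarray(L_values, dtype=float))
    y = np.log(means)
    slope = float(np.polyfit(x, y, 1)[0])
    return slope, means


def greedy_similarity_baseline(
    L: int,
    similarity: np.ndarray | int | None = None,
    symmetric: bool = True,
    seed: int | None = None,
) -> int:
    """Deterministic greedy-similarity search over ``L`` items.

    Starting from item 0, repeatedly hop to the item most similar to the
    current one (pure argmax over the others).  The dynamics are a
    deterministic map, so the search enters a loop exactly when an item is
    first revisited; returns R, the number of distinct items visited by
    then.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if isinstance(similarity, np.ndarray):
        sim = np.array(similarity, dtype=float)
        if sim.shape != (L, L):
            raise ValueError("similarity must be L x L")
    else:
        rng = np.random.default_rng(seed if similarity is None else similarity)
        sim = rng.random((L, L))
        if symmetric:
            sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, -np.inf)
    visited = np.zeros(L, dtype=bool)
    cur = 0
    visited[cur] = True
    distinct = 1
    for _ in range(2 * L + 2):
        nxt = int(np.argmax(sim[cur]))
        if visited[nxt]:
            return distinct
        visited[nxt] = True
        distinct += 1
        cur = nxt
    return distinct  # unreachable for finite L


def greedy_scaling(
    L_values,
    n_matrices: int = 1000,
    symmetric: bool = True,
    seed: int | None = None,
) -> tuple[float, np.ndarray]:
    """Log-log OLS slope of mean R versus L for random similarity matrices."""
    rng = np.random.default_rng(seed)
    means = []
    for L in L_values:
        vals = [
            greedy_similarity_baseline(
                L, seed=int(rng.integers(2**31 - 1)), symmetric=symmetric
            )
            for _ in range(n_matrices)
        ]
        means.append(np.mean(vals))
    means = np.asarray(means, dtype=float)
    slope = float(np.polyfit(np.log(np.asarray(L_values, float)), np.log(means), 1)[0])
    return slope, means
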