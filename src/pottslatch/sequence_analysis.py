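"""Digitization of overlap trajectories and recall scoring.

A continuous run is turned into a discrete retrieval string: an item is
considered recalled while its overlap is both the largest across patterns
and above a threshold ``m_star`` for at least ``min_dwell`` seconds.  The
resulting string is scored with the family of recall measures used to
quantify free and serial short-term recall:

* ``M_corr`` — distinct list (STM) items recalled until the first repeat
  of a visited item or the first extra-list (LTM) intrusion;
* ``M_it`` / ``M_i1`` / ``M_i`` — distinct items recalled, ignoring
  intrusions, until a transition repeats / an item is revisited / an item
  occurs a third time;
* ``M_u`` — distinct correct items within a fixed latch budget ``g(L)``;
* ``M_R`` and the budgeted ``M_corr`` — scored under the dynamic click
  budget ``2L - h(t|L)``, where ``h`` is the running number of correct
  novel recalls (perfect recall consumes exactly L events, errors allow
  up to 2L).

Also here: the latching-quality index ``d12 - Q``, transition statistics,
the normalised mutual-information profile over sequence separations, the
distance distribution at a given separation, the four-phase classification
of a run, and serial-recall scoring.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .dynamics import OverlapTrajectory
from .patterns import PatternSet, distance_d

__all__ = [
    "RetrievalEvent",
    "LatchingSequence",
    "RecallMetrics",
    "digitize",
    "m_corr",
    "m_it",
    "m_i1",
    "m_i",
    "m_u",
    "g_log",
    "g_linear",
    "g_const",
    "m_r_budgeted",
    "m_corr_budgeted",
    "recall_metrics",
    "quality",
    "transition_stats",
    "mutual_information_profile",
    "distance_distribution",
    "classify_phase",
    "serial_score",
    "transition_accuracy",
    "serial_capacity",
]


@dataclass(frozen=True)
class RetrievalEvent:
    pattern: int
    onset: float
    offset: float
    peak: float


@dataclass
class LatchingSequence:
    """Digitized retrieval string of one run."""

    events: list[RetrievalEvent]
    terminated_by: str = "step_cap"

    @property
    def items(self) -> list[int]:
        return [e.pattern for e in self.events]

    @property
    def n_latches(self) -> int:
        return max(len(self.events) - 1, 0)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class RecallMetrics:
    """All recall counts of one digitized run (list length L)."""

    m_corr: int
    m_it: int
    m_i1: int
    m_i: int
    m_u: int
    m_r: int
    m_corr_budgeted: int
    g_used: int
    n_latches: int


def digitize(
    traj: OverlapTrajectory, m_star: float = 0.5, min_dwell: float = 0.05
) -> LatchingSequence:
    """Extract the retrieval string from an overlap trajectory.

    An event opens when some pattern's overlap is the maximum across
    patterns *and* exceeds ``m_star``, and is kept only if that condition
    holds for at least ``min_dwell`` seconds; consecutive events with the
    same pattern merge.
    """
    if not (0.0 < m_star < 1.0):
        raise ValueError("m_star must lie in (0, 1)")
    if len(traj.times) == 0:
        raise ValueError("empty trajectory")
    winner = traj.winner
    above = traj.winner_m > m_star
    sdt = traj.sample_dt
    min_count = max(1, int(math.ceil(min_dwell / sdt)))

    raw: list[tuple[int, int, int]] = []  # (pattern, first sample, last sample)
    start = None
    for idx in range(len(winner)):
        if above[idx] and (start is None or winner[idx] == cur):
            if start is None:
                start = idx
                cur = winner[idx]
            continue
        if start is not None:
            raw.append((cur, start, idx - 1))
            start = None
        if above[idx]:
            start = idx
            cur = winner[idx]
    if start is not None:
        raw.append((cur, start, len(winner) - 1))

    events: list[RetrievalEvent] = []
    for pat, i0, i1 in raw:
        if i1 - i0 + 1 < min_count:
            continue
        onset = float(traj.times[i0])
        offset = float(traj.times[i1])
        peak = float(traj.winner_m[i0 : i1 + 1].max())
        if events and events[-1].pattern == pat:
            prev = events[-1]
            events[-1] = RetrievalEvent(
                pat, prev.onset, offset, max(prev.peak, peak)
            )
        else:
            events.append(RetrievalEvent(int(pat), onset, offset, peak))
    return LatchingSequence(events=events, terminated_by=traj.terminated_by)


def _items(seq) -> list[int]:
    if isinstance(seq, LatchingSequence):
        return seq.items
    return list(seq)


def m_corr(seq, stm_list) -> int:
    """Distinct STM items recalled until the first repeat of a visited item
    or the first extra-list intrusion (the offending event excluded)."""
    stm = set(stm_list)
    visited: set[int] = set()
    for x in _items(seq):
        if x not in stm or x in visited:
            break
        visited.add(x)
    return len(visited)


def m_it(seq, stm_list) -> int:
    """Distinct items until an ordered transition repeats; intrusions are
    removed before counting."""
    items = [x for x in _items(seq) if x in set(stm_list)]
    seen_trans: set[tuple[int, int]] = set()
    visited: set[int] = set()
    prev = None
    for x in items:
        if prev is not None:
            tr = (prev, x)
            if tr in seen_trans:
                break
            seen_trans.add(tr)
        visited.add(x)
        prev = x
    return len(visited)


def m_i1(seq, stm_list) -> int:
    """Distinct items until any item is revisited; intrusions removed."""
    items = [x for x in _items(seq) if x in set(stm_list)]
    visited: set[int] = set()
    for x in items:
        if x in visited:
            break
        visited.add(x)
    return len(visited)


def m_i(seq, stm_list) -> int:
    """Distinct items until some item reaches its third occurrence
    (i.e. is repeated twice); intrusions removed."""
    items = [x for x in _items(seq) if x in set(stm_list)]
    counts: Counter[int] = Counter()
    visited: set[int] = set()
    for x in items:
        if counts[x] >= 2:
            break
        counts[x] += 1
        visited.add(x)
    return len(visited)


def g_log(L: int) -> int:
    """Logarithmic latch budget g(L) = 4 log2(L) - 2."""
    return int(round(4 * math.log2(L) - 2))


def g_linear(L: int) -> int:
    return int(L)


def g_const(L: int | None = None) -> int:
    """Constant budget equal to g_log at L = 64, i.e. 22 latches."""
    return 22


def m_u(seq, stm_list, g: int) -> int:
    """Distinct correct STM items among the first g+1 events (g latches),
    ignoring errors and repetitions."""
    if g < 0:
        raise ValueError("latch budget g must be >= 0")
    stm = set(stm_list)
    items = _items(seq)[: g + 1]
    return len({x for x in items if x in stm})


def _budget_walk(items, stm, L: int, stop_on_violation: bool):
    """Consume events under the dynamic click budget 2L - h.

    ``h`` is the running count of distinct correct recalls; consumption
    stops once ``used >= 2L - h`` (so a perfect run uses exactly L events
    and an all-error run 2L).  Returns (h, events consumed).
    """
    used = 0
    h = 0
    visited: set[int] = set()
    for x in items:
        if used >= 2 * L - h:
            break
        if stop_on_violation and (x not in stm or x in visited):
            break
        used += 1
        if x in stm and x not in visited:
            visited.add(x)
            h += 1
    return h, used


def m_r_budgeted(seq, stm_list, L: int) -> int:
    """Correct novel recalls under the 2L - h budget, ignoring errors and
    repetitions."""
    if L < 1:
        raise ValueError("L must be >= 1")
    h, _ = _budget_walk(_items(seq), set(stm_list), L, stop_on_violation=False)
    return h


def m_corr_budgeted(seq, stm_list, L: int) -> int:
    """Correct novel recalls under the 2L - h budget, additionally stopping
    at the first repeat of a visited STM item or the first intrusion."""
    if L < 1:
        raise ValueError("L must be >= 1")
    h, _ = _budget_walk(_items(seq), set(stm_list), L, stop_on_violation=True)
    return h


def recall_metrics(seq, stm_list, L: int | None = None) -> RecallMetrics:
    """All recall measures of one digitized run."""
    if L is None:
        L = len(tuple(stm_list))
    g = g_log(L) if L >= 2 else 0
    return RecallMetrics(
        m_corr=m_corr(seq, stm_list),
        m_it=m_it(seq, stm_list),
        m_i1=m_i1(seq, stm_list),
        m_i=m_i(seq, stm_list),
        m_u=m_u(seq, stm_list, g),
        m_r=m_r_budgeted(seq, stm_list, L),
        m_corr_budgeted=m_corr_budgeted(seq, stm_list, L),
        g_used=g,
        n_latches=seq.n_latches if isinstance(seq, LatchingSequence) else max(len(seq) - 1, 0),
    )


def quality(traj: OverlapTrajectory, L: int) -> float:
    """Latching quality d12 - Q.

    d12 is the time average of (largest overlap - second largest); Q the
    time average of the mean of the next L-1 overlaps (excluding the
    maximum).  High values mean cleanly separated, well-digitizable
    retrievals.  Requires the full overlap matrix.
    """
    if L < 2:
        raise ValueError("L must be >= 2")
    if traj.m is None:
        raise ValueError("quality requires a fully recorded trajectory")
    if traj.m.shape[1] < L:
        raise ValueError("trajectory has fewer patterns than L")
    # sort each sample's overlaps descending; column 0 = max
    srt = np.sort(traj.m, axis=1)[:, ::-1]
    d12 = float(np.mean(srt[:, 0] - srt[:, 1]))
    q_t = srt[:, 1:L].mean(axis=1)
    return d12 - float(np.mean(q_t))


def transition_stats(seqs, stm_list):
    """Transition counts between STM items and per-item visit frequencies.

    Returns (trans, freq): ``trans[a][b]`` counts a->b steps after removal
    of intrusions; ``freq[a]`` counts visits.  Keys are pattern indices.
    """
    stm = list(stm_list)
    stm_set = set(stm)
    trans: dict[int, Counter] = {x: Counter() for x in stm}
    freq: Counter[int] = Counter()
    for seq in seqs:
        items = [x for x in _items(seq) if x in stm_set]
        for x in items:
            freq[x] += 1
        for a, b in zip(items[:-1], items[1:]):
            trans[a][b] += 1
    return trans, freq


def _pooled_pairs(seqs, z: int):
    pairs = []
    for seq in seqs:
        items = _items(seq)
        for n in range(len(items) - z):
            pairs.append((items[n], items[n + z]))
    return pairs


def mutual_information_profile(seqs, z_max: int) -> np.ndarray:
    """Normalised mutual information I(z)/H for z = 1..z_max.

    Plug-in estimates, base-2 logs, 0 log 0 := 0.  The joint P(mu, nu | z)
    pools all position pairs (n, n+z) that fall inside a single sequence;
    H is the entropy of the marginal item distribution over all positions.
    """
    all_items = [x for seq in seqs for x in _items(seq)]
    if not all_items:
        raise ValueError("empty sequence pool")
    marg = Counter(all_items)
    tot = sum(marg.values())
    H = -sum((c / tot) * math.log2(c / tot) for c in marg.values())
    out = np.zeros(z_max)
    for z in range(1, z_max + 1):
        pairs = _pooled_pairs(seqs, z)
        if not pairs:
            out[z - 1] = np.nan
            continue
        joint = Counter(pairs)
        npairs = len(pairs)
        rows = Counter(a for a, _ in pairs)
        cols = Counter(b for _, b in pairs)
        I = 0.0
        for (aa, bb), c in joint.items():
            pj = c / npairs
            I += pj * math.log2(pj / ((rows[aa] / npairs) * (cols[bb] / npairs)))
        out[z - 1] = I / H if H > 0 else np.nan
    return out


def distance_distribution(seqs, patterns: PatternSet, z: int) -> np.ndarray:
    """Distances d(mu_n, mu_{n+z}) over all in-sequence position pairs."""
    pairs = _pooled_pairs(seqs, z)
    return np.array([distance_d(patterns, a, b) for a, b in pairs])


def classify_phase(seq: LatchingSequence, traj: OverlapTrajectory) -> str:
    """Phase label of one cued run.

    SA   — a single retrieval persists to the step cap;
    noL  — at most one retrieval, then the null attractor;
    L    — two or more retrievals ending in the null attractor;
    infL — two or more retrievals still going at the step cap.
    """
    n = len(seq)
    if traj.terminated_by == "step_cap":
        return "SA" if n <= 1 else "infL"
    return "noL" if n <= 1 else "L"


def serial_score(seq, instruction) -> bool:
    """True iff the first len(instruction) retrieved items equal the
    instruction, in order."""
    instruction = list(instruction)
    if not instruction:
        raise ValueError("instruction must not be empty")
    items = _items(seq)
    return items[: len(instruction)] == instruction


def transition_accuracy(seq, instruction) -> float:
    """Secondary serial score: fraction of instructed adjacent pairs
    reproduced at their position in the retrieval string."""
    instruction = list(instruction)
    if len(instruction) < 2:
        raise ValueError("needs an instruction of length >= 2")
    items = _items(seq)
    hits = 0
    for t in range(len(instruction) - 1):
        if (
            t + 1 < len(items)
            and items[t] == instruction[t]
            and items[t + 1] == instruction[t + 1]
        ):
            hits += 1
    return hits / (len(instruction) - 1)


def serial_capacity(P, L_max: int) -> float:
    """Area-under-the-curve capacity C = sum_{L=1..L_max} P(L) with the
    untested lengths P(1) = P(2) := 1.

    ``P`` maps L (>= 3) to the proportion of correct recalls.
    """
    total = 2.0  # P(1) = P(2) = 1
    for L in range(3, L_max + 1):
        total += float(P.get(L, 0.0)) if hasattr(P, "get") else float(P[L])
    return total
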