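import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pottslatch.dynamics import OverlapTrajectory
from pottslatch.patterns import generate_patterns
from pottslatch.sequence_analysis import (
    LatchingSequence,
    RetrievalEvent,
    classify_phase,
    digitize,
    distance_distribution,
    g_const,
    g_linear,
    g_log,
    m_corr,
    m_corr_budgeted,
    m_i,
    m_i1,
    m_it,
    m_r_budgeted,
    m_u,
    mutual_information_profile,
    recall_metrics,
    serial_capacity,
    serial_score,
    transition_accuracy,
    transition_stats,
)

# ---------------------------------------------------------------- digitize


def _traj(winner, winner_m, sample_dt=0.02, terminated_by="step_cap", p=10):
    winner = np.asarray(winner, dtype=np.int32)
    winner_m = np.asarray(winner_m, dtype=float)
    T = len(winner)
    return OverlapTrajectory(
        times=np.arange(1, T + 1) * sample_dt,
        winner=winner,
        winner_m=winner_m,
        activity=np.full(T, 0.2),
        terminated_by=terminated_by,
        dt=sample_dt,
        p=p,
    )


def test_digitize_threshold_and_dwell():
    # pattern 3 above threshold for 4 samples (0.08 s), pattern 5 for
    # only 1 sample (dropped at min_dwell = 0.04 s = 2 samples)
    winner = [3, 3, 3, 3, 5, 2, 2, 2]
    wm = [0.8, 0.9, 0.85, 0.7, 0.6, 0.75, 0.8, 0.9]
    seq = digitize(_traj(winner, wm), m_star=0.5, min_dwell=0.04)
    assert seq.items == [3, 2]
    assert seq.events[0].peak == pytest.approx(0.9)


def test_digitize_below_threshold_gap_merges_same_pattern():
    # same pattern resumes after a sub-threshold gap: merged into one event
    winner = [4, 4, 4, 4, 4, 4]
    wm = [0.8, 0.8, 0.3, 0.3, 0.8, 0.8]
    seq = digitize(_traj(winner, wm), m_star=0.5, min_dwell=0.04)
    assert seq.items == [4]


def test_digitize_alternation():
    winner = [1, 1, 2, 2, 1, 1]
    wm = [0.9] * 6
    seq = digitize(_traj(winner, wm), m_star=0.5, min_dwell=0.04)
    assert seq.items == [1, 2, 1]
    assert seq.n_latches == 2


def test_digitize_nothing_above_threshold():
    seq = digitize(_traj([1, 2, 3], [0.2, 0.1, 0.3]), m_star=0.5, min_dwell=0.02)
    assert seq.items == []
    assert seq.n_latches == 0


def test_digitize_validates():
    with pytest.raises(ValueError):
        digitize(_traj([1], [0.9]), m_star=1.5)


# ------------------------------------------------- metric oracles (by hand)

LST = [10, 11, 12, 13]


def test_m_corr_hand_cases():
    assert m_corr([10, 11, 12, 13], LST) == 4  # perfect
    assert m_corr([10, 11, 10, 12], LST) == 2  # repeat of 10
    assert m_corr([10, 99, 11], LST) == 1  # intrusion
    assert m_corr([99], LST) == 0
    assert m_corr([], LST) == 0


def test_m_it_repeated_transition():
    # transition 10->11 repeats at the end (its target not counted);
    # intrusion 99 removed first
    assert m_it([10, 11, 99, 12, 10, 11], LST) == 3
    # no transition ever repeats
    assert m_it([10, 11, 12], LST) == 3


def test_m_i1_and_m_i():
    s = [10, 11, 10, 12, 10]
    assert m_i1(s, LST) == 2  # stops at second 10
    assert m_i(s, LST) == 3  # stops at third 10
    assert m_i1([10, 11, 12, 13], LST) == 4


def test_m_u_budget():
    s = [10, 99, 11, 12, 13]
    assert m_u(s, LST, g=2) == 2  # first 3 events: 10, 99, 11
    assert m_u(s, LST, g=10) == 4
    with pytest.raises(ValueError):
        m_u(s, LST, g=-1)


def test_g_functions():
    assert g_log(64) == 22
    assert g_log(2) == 2
    assert g_linear(17) == 17
    assert g_const() == 22


def test_budget_automaton_perfect_and_all_error():
    L = 4
    # perfect recall consumes exactly L events
    assert m_r_budgeted([10, 11, 12, 13, 10, 11], LST, L) == 4
    # all-error run consumes 2L events and recalls nothing
    errs = [99] * 20
    assert m_r_budgeted(errs, LST, L) == 0
    # budgeted m_corr stops at the first violation
    assert m_corr_budgeted([10, 11, 99, 12], LST, L) == 2


def test_budget_interleaved():
    L = 3
    lst = [1, 2, 3]
    # events: err, 1, err, err, 2, err -> budget 2L - h shrinks as h grows;
    # walk: used counts all consumed events
    assert m_r_budgeted([9, 1, 9, 9, 2, 9, 9, 9], lst, L) == 2


# ------------------------------------------- property tests vs brute force


def _brute_m_corr(items, lst):
    seen = set()
    for x in items:
        if x not in lst or x in seen:
            break
        seen.add(x)
    return len(seen)


def _brute_m_i1(items, lst):
    kept = [x for x in items if x in lst]
    seen = set()
    for x in kept:
        if x in seen:
            return len(seen)
        seen.add(x)
    return len(seen)


def _brute_m_i(items, lst):
    kept = [x for x in items if x in lst]
    c = Counter()
    seen = set()
    for x in kept:
        if c[x] == 2:
            return len(seen)
        c[x] += 1
        seen.add(x)
    return len(seen)


def _brute_m_it(items, lst):
    kept = [x for x in items if x in lst]
    trans = set()
    seen = set()
    for i, x in enumerate(kept):
        if i > 0:
            if (kept[i - 1], x) in trans:
                return len(seen)
            trans.add((kept[i - 1], x))
        seen.add(x)
    return len(seen)


def _brute_m_r(items, lst, L):
    used, h, seen = 0, 0, set()
    for x in items:
        if used >= 2 * L - h:
            break
        used += 1
        if x in lst and x not in seen:
            seen.add(x)
            h += 1
    return h


strings = st.lists(st.integers(min_value=0, max_value=9), max_size=40)


@settings(max_examples=250, deadline=None)
@given(strings)
def test_metrics_match_brute_force(items):
    lst = {0, 1, 2, 3}
    L = 4
    assert m_corr(items, lst) == _brute_m_corr(items, lst)
    assert m_i1(items, lst) == _brute_m_i1(items, lst)
    assert m_i(items, lst) == _brute_m_i(items, lst)
    assert m_it(items, lst) == _brute_m_it(items, lst)
    assert m_r_budgeted(items, lst, L) == _brute_m_r(items, lst, L)


@settings(max_examples=250, deadline=None)
@given(strings)
def test_metric_invariants(items):
    lst = {0, 1, 2, 3, 4}
    L = 5
    # revisit stops no later than third occurrence
    assert m_i1(items, lst) <= m_i(items, lst)
    # stopping earlier can only lower the count
    assert m_corr(items, lst) <= m_i1(items, lst)
    assert m_corr_budgeted(items, lst, L) <= m_corr(items, lst)
    assert m_r_budgeted(items, lst, L) <= L
    assert m_u(items, lst, g=3) <= min(4, L)


def test_recall_metrics_bundle():
    seq = LatchingSequence(
        events=[
            RetrievalEvent(pattern=x, onset=i * 0.3, offset=i * 0.3 + 0.2, peak=0.9)
            for i, x in enumerate([10, 11, 12, 10])
        ]
    )
    met = recall_metrics(seq, LST)
    assert met.m_corr == 3
    assert met.n_latches == 3
    assert met.g_used == g_log(4)


# ------------------------------------------------------- MI and distances


def test_mutual_information_oracle():
    # two sequences; at z=1 the pairs are fully determined (1->2, 2->1),
    # computed against a hand-built joint histogram
    seqs = [[1, 2, 1, 2], [2, 1, 2, 1]]
    prof = mutual_information_profile(seqs, z_max=2)
    items = [x for s in seqs for x in s]
    marg = Counter(items)
    tot = len(items)
    H = -sum(c / tot * math.log2(c / tot) for c in marg.values())
    pairs = [(1, 2), (2, 1), (1, 2), (2, 1), (2, 1), (1, 2)]
    joint = Counter(pairs)
    n = len(pairs)
    rows, cols = Counter(a for a, _ in pairs), Counter(b for _, b in pairs)
    I = sum(
        c / n * math.log2((c / n) / ((rows[a] / n) * (cols[b] / n)))
        for (a, b), c in joint.items()
    )
    assert prof[0] == pytest.approx(I / H)
    # at z=2 every pair is (x, x): also perfectly informative
    assert prof[1] == pytest.approx(1.0)


def test_mutual_information_iid_near_zero():
    rng = np.random.default_rng(0)
    seqs = [rng.integers(0, 4, size=200).tolist() for _ in range(10)]
    prof = mutual_information_profile(seqs, z_max=3)
    assert np.all(prof >= 0)  # plug-in MI is nonnegative
    assert np.all(prof < 0.05)  # bias only, for i.i.d. symbols


def test_mutual_information_nan_beyond_length():
    prof = mutual_information_profile([[1, 2]], z_max=3)
    assert not math.isnan(prof[0])
    assert math.isnan(prof[2])


def test_distance_distribution_values():
    ps = generate_patterns(p=6, N=50, S=3, a=0.4, seed=1)
    d = distance_distribution([[0, 1, 2], [3, 4]], ps, z=1)
    assert d.shape == (3,)


# ------------------------------------------------ phase, serial, capacity


def test_classify_phase_four_cases():
    e = [
        RetrievalEvent(pattern=1, onset=0.0, offset=0.2, peak=0.9),
        RetrievalEvent(pattern=2, onset=0.3, offset=0.5, peak=0.9),
    ]
    one = LatchingSequence(events=e[:1])
    two = LatchingSequence(events=e)
    cap = _traj([1], [0.9], terminated_by="step_cap")
    nul = _traj([1], [0.9], terminated_by="null_attractor")
    assert classify_phase(one, cap) == "SA"
    assert classify_phase(two, cap) == "infL"
    assert classify_phase(one, nul) == "noL"
    assert classify_phase(two, nul) == "L"


def test_serial_score_and_transition_accuracy():
    assert serial_score([5, 6, 7, 1], (5, 6, 7))
    assert not serial_score([5, 7, 6], (5, 6, 7))
    assert transition_accuracy([5, 6, 9], (5, 6, 7)) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        serial_score([1], ())


def test_serial_capacity_convention():
    P = {3: 1.0, 4: 0.5, 5: 0.0}
    assert serial_capacity(P, 5) == pytest.approx(2.0 + 1.5)
    # lengths 1 and 2 are always counted as perfect
    assert serial_capacity({}, 2) == pytest.approx(2.0)


def test_transition_stats_counts():
    trans, freq = transition_stats([[1, 2, 9, 1]], [1, 2])
    assert freq[1] == 2 and freq[2] == 1
    assert trans[1][2] == 1 and trans[2][1] == 1
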