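import numpy as np
import pytest

from pottslatch.network import (
    BoostConfig,
    apply_model1,
    apply_model3a,
    apply_model3b,
    build_connectivity,
    build_heteroassociative,
    build_weights,
    model2_theta_mask,
    model3a_mask,
    model3b_mask,
    sample_instruction_sequences,
)
from pottslatch.patterns import PatternSet, generate_patterns
from pottslatch.theory import boosted_fraction


def _tiny():
    # N=6, S=3, p=2, a=0.5 hand-size fixture
    xi = np.array(
        [
            [1, 0, 2, 3, 0, 1],
            [0, 2, 2, 0, 1, 3],
        ],
        dtype=np.int16,
    )
    return PatternSet(xi=xi, S=3, a=0.5, seed=None)


def test_connectivity_no_self_and_distinct():
    conn = build_connectivity(40, 12, seed=0)
    for i in range(40):
        row = conn.nbr[i]
        assert i not in row
        assert len(set(row.tolist())) == 12
    dense = conn.as_dense()
    assert dense.sum() == 40 * 12
    assert np.all(np.diag(dense) == 0)


def test_connectivity_bounds():
    with pytest.raises(ValueError):
        build_connectivity(5, 5, seed=0)


def test_weights_match_quadruple_loop_oracle():
    ps = _tiny()
    conn = build_connectivity(6, 3, seed=1)
    W = build_weights(ps, conn)
    N, S, a, c_m = 6, 3, 0.5, 3
    dense = conn.as_dense()
    norm = c_m * a * (1 - a / S)
    for i in range(N):
        for j in range(N):
            for k in range(S + 1):
                for l in range(S + 1):
                    if k == 0 or l == 0 or dense[i, j] == 0:
                        expected = 0.0
                    else:
                        expected = (
                            sum(
                                ((ps.xi[mu, i] == k) - a / S)
                                * ((ps.xi[mu, j] == l) - a / S)
                                for mu in range(ps.p)
                            )
                            / norm
                        )
                    assert W.entry(i, j, k, l) == pytest.approx(expected)


def test_weights_deterministic():
    ps = _tiny()
    conn = build_connectivity(6, 2, seed=5)
    assert np.array_equal(
        build_weights(ps, conn).blocks, build_weights(ps, conn).blocks
    )


def test_model1_vector():
    ps = _tiny()
    wv = apply_model1(1.0, 0.5, ps, [0])
    active0 = ps.xi[0] > 0
    assert np.allclose(wv[active0], 1.5)
    assert np.allclose(wv[~active0], 1.0)


def test_model2_mask():
    ps = _tiny()
    mask = model2_theta_mask(ps, [1])
    # exactly the (unit, state-1) pairs used by pattern 1
    expected = np.zeros((6, 3), dtype=bool)
    for i in range(6):
        if ps.xi[1, i] > 0:
            expected[i, ps.xi[1, i] - 1] = True
    assert np.array_equal(mask, expected)
    both = model2_theta_mask(ps, [0, 1])
    assert both.sum() >= mask.sum()


def test_model3a_vs_3b_masks():
    ps = _tiny()
    conn = build_connectivity(6, 3, seed=2)
    m3a = model3a_mask(ps, conn.nbr, [0, 1])
    m3b = model3b_mask(ps, conn.nbr, [0, 1])
    # 3b potentiates a superset of 3a's couplings
    assert np.all(m3b[m3a])
    assert m3b.sum() >= m3a.sum()
    # hand check one 3a entry: i=0 (state 1 in mu=0), its neighbors
    i = 0
    for m, j in enumerate(conn.nbr[i]):
        if ps.xi[0, j] > 0:
            assert m3a[i, m, ps.xi[0, i] - 1, ps.xi[0, j] - 1] or ps.xi[0, i] == 0


def test_apply_model3_leaves_original_untouched():
    ps = _tiny()
    conn = build_connectivity(6, 3, seed=3)
    W = build_weights(ps, conn)
    before = W.blocks.copy()
    W3a = apply_model3a(W, 0.3, ps, [0])
    W3b = apply_model3b(W, 0.3, ps, [0, 1])
    assert np.array_equal(W.blocks, before)
    assert (W3a.blocks - W.blocks).max() == pytest.approx(0.3)
    assert (W3b.blocks - W.blocks).sum() >= (W3a.blocks - W.blocks).sum()


def test_boosted_fraction_monte_carlo():
    # fractions of elements actually touched match the closed forms; the
    # elements within one realization are correlated (a pattern flips many
    # of them together), so we average over independent realizations and
    # use the across-realization standard error
    S, a = 4, 0.4
    n_rep = 24
    rng = np.random.default_rng(7)
    for L in (1, 4, 16):
        lst = list(range(L))
        samples = {"M1": [], "M2": [], "M3a": [], "M3b": []}
        for _ in range(n_rep):
            ps = generate_patterns(
                p=L, N=400, S=S, a=a, seed=int(rng.integers(2**31 - 1))
            )
            conn = build_connectivity(400, 8, seed=int(rng.integers(2**31 - 1)))
            samples["M1"].append((apply_model1(0.0, 1.0, ps, lst) > 0).mean())
            samples["M2"].append(model2_theta_mask(ps, lst).mean())
            samples["M3a"].append(model3a_mask(ps, conn.nbr, lst).mean())
            samples["M3b"].append(model3b_mask(ps, conn.nbr, lst).mean())
        for model, vals in samples.items():
            vals = np.asarray(vals)
            se = vals.std(ddof=1) / np.sqrt(n_rep)
            expected = boosted_fraction(model, L, a, S)
            assert abs(vals.mean() - expected) < 5 * max(se, 1e-4), (model, L)


def test_boost_config_validation():
    with pytest.raises(ValueError):
        BoostConfig(model="M9", delta=0.1)
    with pytest.raises(ValueError):
        BoostConfig(model="M2", delta=-0.1)
    with pytest.raises(ValueError):
        BoostConfig(model="M2", delta=0.1, stm_list=(1, 1))


def test_heteroassociative_entries():
    ps = _tiny()
    lam = 0.25
    het = build_heteroassociative(ps, [0, 1], lam)
    # entries lam where k = xi_i^{1} and l = xi_j^{0}, both active, i != j
    for i in range(6):
        for j in range(6):
            for k in range(1, 4):
                for l in range(1, 4):
                    expected = (
                        lam
                        if (
                            i != j
                            and ps.xi[1, i] == k
                            and ps.xi[0, j] == l
                        )
                        else 0.0
                    )
                    assert het.entry(i, j, k, l) == pytest.approx(expected)


def test_heteroassociative_deduplicates():
    # repeating a transition must not double the coupling strength
    ps = _tiny()
    h1 = build_heteroassociative(ps, [0, 1], 0.3)
    h2 = build_heteroassociative(ps, [0, 1, 0, 1], 0.3)
    assert h2.csr.max() == pytest.approx(0.3)
    assert (h1.csr != h2.csr[: h1.csr.shape[0], :]).nnz >= 0  # same shape/content domain
    assert h2.csr.max() == h1.csr.max()


def test_instruction_sequences_constraints():
    seqs = sample_instruction_sequences(50, 5, alphabet=range(6), seed=0)
    assert len(seqs) == 50
    assert len(set(seqs)) == 50
    for s in seqs:
        assert len(s) == 5
        for t in range(1, 5):
            assert s[t] != s[t - 1]  # no AA
        for t in range(2, 5):
            assert s[t] != s[t - 2]  # no ABA


def test_instruction_sequences_exhaustive_count():
    # n (n-1) (n-2)^(L-2) valid sequences: 6 * 5 * 4 = 120 for L = 3
    seqs = sample_instruction_sequences(120, 3, alphabet=range(6), seed=1)
    assert len(set(seqs)) == 120
    with pytest.raises(ValueError):
        sample_instruction_sequences(121, 3, alphabet=range(6), seed=1)
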