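import numpy as np
import pytest

from pottslatch.dynamics import (
    CueSpec,
    SimConfig,
    compute_field,
    cue_field,
    initial_state,
    load_trajectory,
    overlaps,
    run,
    save_trajectory,
    step,
    update_activations,
)
from pottslatch.network import BoostConfig, build_connectivity, build_weights
from pottslatch.patterns import generate_patterns
from pottslatch.sequence_analysis import digitize


def _small_system(p=5, N=60, S=3, a=0.3, c_m=12, seed=1):
    ps = generate_patterns(p=p, N=N, S=S, a=a, seed=seed)
    conn = build_connectivity(N, c_m, seed=seed + 1)
    return ps, build_weights(ps, conn)


def _short_cfg(**kw):
    base = dict(max_updates=320, sample_every=8, cue=CueSpec(pattern=0))
    base.update(kw)
    return SimConfig(**base)


def test_softmax_rows_normalised_every_step():
    ps, W = _small_system()
    cfg = _short_cfg()
    state = initial_state(ps.N, ps.S, cfg)
    cf = cue_field(ps, 0, 1.0)
    for s in range(50):
        step(state, W, cfg, cue=cf if s < 20 else None)
        sums = state.sigma.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert state.sigma.min() >= 0.0


def test_initial_state_softmax_formula():
    cfg = SimConfig()
    st = initial_state(4, 3, cfg)
    # r = theta = 0: sigma_k proportional to 1, background to e^(beta U)
    z0 = np.exp(cfg.beta * cfg.U)
    expected_bg = z0 / (z0 + 3)
    assert np.allclose(st.sigma[:, 0], expected_bg)
    assert np.allclose(st.sigma[:, 1:], 1 / (z0 + 3))


def test_field_oracle_tiny():
    ps, W = _small_system(p=2, N=6, S=3, a=0.5, c_m=2, seed=4)
    cfg = _short_cfg()
    state = initial_state(6, 3, cfg)
    state.sigma = np.random.default_rng(0).dirichlet(np.ones(4), size=6)
    h = compute_field(state, W, w=0.7)
    sig = state.sigma[:, 1:]
    for i in range(6):
        for k in range(1, 4):
            expected = 0.0
            for j in range(6):
                for l in range(1, 4):
                    expected += W.entry(i, j, k, l) * sig[j, l - 1]
            expected += 0.7 * (sig[i, k - 1] - sig[i].mean())
            assert h[i, k - 1] == pytest.approx(expected, abs=1e-12)


def test_cue_field_shape_and_range():
    ps, _ = _small_system()
    cf = cue_field(ps, 2, 1.5)
    assert cf.shape == (60, 3)
    vals = {round(v, 6) for v in np.unique(cf)}
    assert vals <= {round(1.5 * (1 - 0.1), 6), round(1.5 * (-0.1), 6)}
    with pytest.raises(IndexError):
        cue_field(ps, 99, 1.0)


def test_overlap_of_perfect_alignment():
    ps, _ = _small_system()
    ks = np.arange(1, ps.S + 1)
    sig = (ps.xi[3][:, None] == ks[None, :]).astype(float)
    m = overlaps(sig, ps)
    # exactly n_active / (N a): 1 up to the pattern's activity fluctuation
    n_act = np.count_nonzero(ps.xi[3])
    assert m[3] == pytest.approx(n_act / (ps.N * ps.a))
    assert np.all(m[np.arange(ps.p) != 3] < 0.9)
    assert abs(m[3] - 1.0) < 0.3


def test_cue_drives_retrieval():
    ps, W = _small_system()
    traj = run(ps, W, _short_cfg(), backend="numpy")
    # during/after the cue the cued pattern dominates
    assert traj.winner[2] == 0
    assert traj.winner_m[2] > 0.5


def test_backend_equivalence():
    ps, W = _small_system()
    cfg = _short_cfg()
    t_np = run(ps, W, cfg, backend="numpy")
    t_nb = run(ps, W, cfg, backend="numba")
    n = min(len(t_np.times), len(t_nb.times))
    assert n > 10
    assert np.array_equal(t_np.winner[:n], t_nb.winner[:n])
    assert np.abs(t_np.m[:n] - t_nb.m[:n]).max() < 1e-4
    assert t_np.terminated_by == t_nb.terminated_by


def test_identical_seed_bitwise_reproducible():
    ps, W = _small_system()
    cfg = _short_cfg()
    a = run(ps, W, cfg, backend="numba")
    b = run(ps, W, cfg, backend="numba")
    assert np.array_equal(a.winner, b.winner)
    assert np.array_equal(a.winner_m, b.winner_m)
    assert np.array_equal(a.activity, b.activity)


def test_null_attractor_termination():
    # with weak local feedback and strong adaptation the network falls
    # silent shortly after the cue is removed
    ps, W = _small_system()
    cfg = _short_cfg(w=0.0, max_updates=4000)
    traj = run(ps, W, cfg, backend="numpy")
    assert traj.terminated_by == "null_attractor"
    assert len(traj.times) < 4000 / cfg.sample_every


def test_model2_boost_lowers_thresholds():
    ps, W = _small_system()
    cfg = _short_cfg()
    boosted = run(
        ps,
        W,
        cfg,
        boost=BoostConfig(model="M2", delta=0.5, stm_list=(0, 1)),
        backend="numpy",
    )
    plain = run(ps, W, cfg, backend="numpy")
    # the boost must change the trajectory (thresholds enter the dynamics)
    n = min(len(boosted.times), len(plain.times))
    assert not np.allclose(boosted.m[:n], plain.m[:n])


def test_dt_refinement_keeps_first_event():
    ps, W = _small_system()
    c1 = _short_cfg(max_updates=640)
    c2 = SimConfig(
        dt=c1.dt / 2, max_updates=1280, sample_every=16, cue=CueSpec(pattern=0)
    )
    t1 = run(ps, W, c1, backend="numpy")
    t2 = run(ps, W, c2, backend="numpy")
    s1 = digitize(t1, m_star=0.5, min_dwell=0.02)
    s2 = digitize(t2, m_star=0.5, min_dwell=0.02)
    assert s1.items[:1] == s2.items[:1] == [0]


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(gamma_A=1.5)
    with pytest.raises(ValueError):
        SimConfig(dt=1.0)  # larger than tau_A
    with pytest.raises(ValueError):
        CueSpec(duration=0.0)
    with pytest.warns(UserWarning):
        SimConfig(tau1=10.0)  # violates the time-scale ordering


def test_trajectory_save_load_roundtrip(tmp_path):
    ps, W = _small_system()
    traj = run(ps, W, _short_cfg(), backend="numpy")
    path = tmp_path / "traj"
    save_trajectory(traj, path)
    back = load_trajectory(path)
    assert np.array_equal(back.winner, traj.winner)
    assert np.allclose(back.m, traj.m)
    assert back.terminated_by == traj.terminated_by
    assert back.p == traj.p
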