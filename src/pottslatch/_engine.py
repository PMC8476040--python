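"""Batched compiled integrator.

Many runs that share the same couplings (e.g. a Model 2 sweep, where the
boost only touches thresholds) are integrated side by side: state arrays
carry a trailing batch axis, so the expensive tensor-field contraction
streams the coupling blocks once per step for the whole batch.  Columns
whose run has terminated are compacted away between segments.  Arithmetic
is float32; each column's trajectory is independent of which other runs
share its batch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .dynamics import NetworkState, OverlapTrajectory, SimConfig, initial_state
from .network import HeteroWeights, WeightTensor
from .patterns import PatternSet

__all__ = ["simulate_batch"]

_CHUNK = 1000  # steps per kernel call; compaction granularity


@njit(cache=True, fastmath=True)
def _integrate(
    nbr,
    Jt,
    w,
    theta_dec,
    cue,
    cue_on,
    het_on,
    het_indptr,
    het_indices,
    het_data,
    beta,
    U,
    gA,
    dt_t1,
    dt_t2,
    dt_tA,
    dt_tB,
    n_steps,
    sample_every,
    phase,
    sig,
    r,
    theta,
    thA,
    thB,
    act_idx,
    act_state,
    act_ptr,
    aS,
    inv_norm,
    out_winner,
    out_wm,
    out_act,
    out_m,
    record_full,
):
    N, c_m = nbr.shape
    S = Jt.shape[1]
    B = sig.shape[2]
    p = act_ptr.shape[0] - 1
    h = np.empty((N, S, B), dtype=np.float32)
    G = np.empty((c_m * S, B), dtype=np.float32)
    sums = np.empty((N, B), dtype=np.float32)
    acc = np.empty(B, dtype=np.float32)
    tot = np.empty(B, dtype=np.float32)
    n_samp = 0
    for s in range(n_steps):
        # recurrent tensor field: gather presynaptic blocks, one GEMM per unit
        for i in range(N):
            for m_ in range(c_m):
                j = nbr[i, m_]
                base = m_ * S
                for l in range(S):
                    for b in range(B):
                        G[base + l, b] = sig[j, l, b]
            h[i] = np.dot(Jt[i], G)
        # summed activity per unit (pre-step sigma)
        for i in range(N):
            for b in range(B):
                acc_b = np.float32(0.0)
                for l in range(S):
                    acc_b += sig[i, l, b]
                sums[i, b] = acc_b
        # local feedback + cue
        invS = np.float32(1.0 / S)
        for i in range(N):
            for k in range(S):
                for b in range(B):
                    h[i, k, b] += w[i, b] * (sig[i, k, b] - sums[i, b] * invS)
        if cue_on:
            for i in range(N):
                for k in range(S):
                    for b in range(B):
                        h[i, k, b] += cue[i, k, b]
        # heteroassociative drive from the adaptation thresholds
        if het_on:
            for row in range(N * S):
                i = row // S
                k = row % S
                for ptr in range(het_indptr[row], het_indptr[row + 1]):
                    col = het_indices[ptr]
                    v = het_data[ptr]
                    jj = col // S
                    ll = col % S
                    for b in range(B):
                        h[i, k, b] += v * theta[jj, ll, b]
        # Euler updates (all derivatives on the pre-step state)
        for i in range(N):
            for k in range(S):
                for b in range(B):
                    rv = r[i, k, b]
                    r[i, k, b] = rv + dt_t1 * (h[i, k, b] - theta[i, k, b] - rv)
                    tv = theta[i, k, b]
                    theta[i, k, b] = tv + dt_t2 * (sig[i, k, b] - tv - theta_dec[i, k, b])
        for i in range(N):
            for b in range(B):
                thA[i, b] += dt_tA * (gA * sums[i, b] - thA[i, b])
                thB[i, b] += dt_tB * ((np.float32(1.0) - gA) * sums[i, b] - thB[i, b])
        # softmax readout
        for i in range(N):
            for b in range(B):
                z0 = beta * (U + thA[i, b] + thB[i, b])
                mx = z0
                for k in range(S):
                    zk = beta * r[i, k, b]
                    if zk > mx:
                        mx = zk
                Z = np.exp(z0 - mx)
                for k in range(S):
                    e = np.exp(beta * r[i, k, b] - mx)
                    sig[i, k, b] = e
                    Z += e
                inv = np.float32(1.0) / Z
                for k in range(S):
                    sig[i, k, b] *= inv
        # overlap sampling
        if (phase + s + 1) % sample_every == 0:
            for b in range(B):
                tot[b] = 0.0
            for i in range(N):
                for k in range(S):
                    for b in range(B):
                        tot[b] += sig[i, k, b]
            for b in range(B):
                out_act[n_samp, b] = tot[b] / N
                out_wm[n_samp, b] = -np.float32(1e30)
                out_winner[n_samp, b] = -1
            for mu in range(p):
                for b in range(B):
                    acc[b] = 0.0
                for ptr in range(act_ptr[mu], act_ptr[mu + 1]):
                    i = act_idx[ptr]
                    k = act_state[ptr]
                    for b in range(B):
                        acc[b] += sig[i, k, b]
                for b in range(B):
                    mv = inv_norm * (acc[b] - aS * tot[b])
                    if record_full:
                        out_m[n_samp, mu, b] = mv
                    if mv > out_wm[n_samp, b]:
                        out_wm[n_samp, b] = mv
                        out_winner[n_samp, b] = mu
            n_samp += 1
    return n_samp


def _active_index(patterns: PatternSet):
    idx, st, ptr = [], [], [0]
    for mu in range(patterns.p):
        xi = patterns.xi[mu]
        act = np.nonzero(xi > 0)[0]
        idx.append(act)
        st.append(xi[act] - 1)
        ptr.append(ptr[-1] + act.size)
    return (
        np.concatenate(idx).astype(np.int32) if idx else np.zeros(0, np.int32),
        np.concatenate(st).astype(np.int32) if st else np.zeros(0, np.int32),
        np.asarray(ptr, dtype=np.int32),
    )


def simulate_batch(
    patterns: PatternSet,
    weights: WeightTensor,
    config: SimConfig,
    w_vecs: np.ndarray,
    theta_decs: np.ndarray,
    cue_fields: np.ndarray,
    het: HeteroWeights | None = None,
    record: str = "digest",
) -> list[OverlapTrajectory]:
    """Integrate B runs sharing one coupling tensor.

    ``w_vecs``: (B, N) local feedback per run; ``theta_decs``: (B, N, S)
    Model 2 adaptation reductions; ``cue_fields``: (B, N, S) aligned cue
    field per run (each run may cue a different pattern).  Returns one
    trajectory per run, in order.
    """
    N, S, p, a = patterns.N, patterns.S, patterns.p, patterns.a
    B = w_vecs.shape[0]
    if theta_decs.shape != (B, N, S) or cue_fields.shape != (B, N, S):
        raise ValueError("batch input shapes disagree")
    record_full = record == "full"

    ref = initial_state(N, S, config)
    sig = np.repeat(
        ref.sigma[:, 1:, None].astype(np.float32), B, axis=2
    )  # (N, S, B)
    r = np.zeros((N, S, B), dtype=np.float32)
    theta = np.zeros((N, S, B), dtype=np.float32)
    thA = np.zeros((N, B), dtype=np.float32)
    thB = np.zeros((N, B), dtype=np.float32)
    w = np.ascontiguousarray(w_vecs.T, dtype=np.float32)  # (N, B)
    tdec = np.ascontiguousarray(np.moveaxis(theta_decs, 0, 2), dtype=np.float32)
    cue = np.ascontiguousarray(np.moveaxis(cue_fields, 0, 2), dtype=np.float32)

    if het is not None:
        het_on = True
        het_indptr = het.csr.indptr.astype(np.int32)
        het_indices = het.csr.indices.astype(np.int32)
        het_data = het.csr.data.astype(np.float32)
    else:
        het_on = False
        het_indptr = np.zeros(N * S + 1, dtype=np.int32)
        het_indices = np.zeros(0, dtype=np.int32)
        het_data = np.zeros(0, dtype=np.float32)

    act_idx, act_state, act_ptr = _active_index(patterns)
    dt = config.dt
    inv_norm = np.float32(1.0 / (N * a * (1.0 - a / S))) if a > 0 else np.float32(0.0)
    aS = np.float32(a / S)
    act_null = config.activity_null if config.activity_null is not None else np.inf
    cue_steps = max(1, round(config.cue.duration / dt))
    sample_dt = dt * config.sample_every
    n_sustain = max(1, int(np.ceil(config.tau2 / sample_dt)))
    # coupling blocks rearranged to (N, S, c_m*S) so the per-unit field is
    # a single matrix product against the gathered presynaptic activations
    Jt = np.ascontiguousarray(
        weights.blocks.transpose(0, 2, 1, 3), dtype=np.float32
    ).reshape(N, S, weights.nbr.shape[1] * S)
    nbr = np.ascontiguousarray(weights.nbr, dtype=np.int32)

    # per-run accumulators (indexed by original run id)
    winners = [[] for _ in range(B)]
    wms = [[] for _ in range(B)]
    acts = [[] for _ in range(B)]
    ms: list[list[np.ndarray]] = [[] for _ in range(B)]
    terminated = ["step_cap"] * B
    quiet = np.zeros(B, dtype=np.int64)
    alive = np.arange(B)

    global_step = 0
    phase = 0
    while global_step < config.max_updates and alive.size:
        seg = min(_CHUNK, config.max_updates - global_step)
        cue_on = global_step < cue_steps
        if cue_on:
            seg = min(seg, cue_steps - global_step)
        nb = alive.size
        n_samp_max = (phase + seg) // config.sample_every
        out_winner = np.empty((max(n_samp_max, 1), nb), dtype=np.int32)
        out_wm = np.empty((max(n_samp_max, 1), nb), dtype=np.float32)
        out_act = np.empty((max(n_samp_max, 1), nb), dtype=np.float32)
        out_m = (
            np.empty((max(n_samp_max, 1), p, nb), dtype=np.float32)
            if record_full
            else np.empty((1, 1, nb), dtype=np.float32)
        )
        n_samp = _integrate(
            nbr,
            Jt,
            w,
            tdec,
            cue,
            cue_on,
            het_on,
            het_indptr,
            het_indices,
            het_data,
            np.float32(config.beta),
            np.float32(config.U),
            np.float32(config.gamma_A),
            np.float32(dt / config.tau1),
            np.float32(dt / config.tau2),
            np.float32(dt / config.tau_A),
            np.float32(dt / config.tau_B),
            seg,
            config.sample_every,
            phase,
            sig,
            r,
            theta,
            thA,
            thB,
            act_idx,
            act_state,
            act_ptr,
            aS,
            inv_norm,
            out_winner,
            out_wm,
            out_act,
            out_m,
            record_full,
        )
        # distribute samples, update null-attractor counters
        done_local: list[int] = []
        for local, run in enumerate(alive):
            for js in range(n_samp):
                winners[run].append(out_winner[js, local])
                wms[run].append(out_wm[js, local])
                acts[run].append(out_act[js, local])
                if record_full:
                    ms[run].append(out_m[js, :, local].copy())
                step_of_sample = (len(winners[run])) * config.sample_every
                if (
                    step_of_sample > cue_steps
                    and out_wm[js, local] < config.m_null
                    and out_act[js, local] < act_null
                ):
                    quiet[run] += 1
                    if quiet[run] >= n_sustain and run not in [
                        alive[x] for x in done_local
                    ]:
                        terminated[run] = "null_attractor"
                        done_local.append(local)
                else:
                    quiet[run] = 0
        phase = (phase + seg) % config.sample_every
        global_step += seg
        if done_local:
            keep = np.array(
                [x for x in range(alive.size) if x not in set(done_local)],
                dtype=np.int64,
            )
            alive = alive[keep]
            sig = np.ascontiguousarray(sig[:, :, keep])
            r = np.ascontiguousarray(r[:, :, keep])
            theta = np.ascontiguousarray(theta[:, :, keep])
            thA = np.ascontiguousarray(thA[:, keep])
            thB = np.ascontiguousarray(thB[:, keep])
            w = np.ascontiguousarray(w[:, keep])
            tdec = np.ascontiguousarray(tdec[:, :, keep])
            cue = np.ascontiguousarray(cue[:, :, keep])

    out = []
    for run in range(B):
        T = len(winners[run])
        times = (np.arange(1, T + 1)) * sample_dt
        out.append(
            OverlapTrajectory(
                times=times,
                winner=np.asarray(winners[run], dtype=np.int32),
                winner_m=np.asarray(wms[run], dtype=np.float64),
                activity=np.asarray(acts[run], dtype=np.float64),
                terminated_by=terminated[run],
                dt=dt,
                p=p,
                m=np.asarray(ms[run]) if record_full and ms[run] else None,
            )
        )
    return out
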