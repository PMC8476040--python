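"""Time integration of the Potts network and overlap recording.

Each Potts unit carries S active states plus a background state.  Active
states integrate their input field into potentials r_ik (time constant
tau1) and are read out through a softmax at inverse temperature beta; the
background state competes in the softmax with an effective threshold
U + theta_A + theta_B.  Adaptation theta_ik tracks the unit's own
activation per state (tau2), while two inhibitory thresholds track total
unit activity fast (theta_A, tau_A, share gamma_A) and slowly (theta_B,
tau_B, share 1-gamma_A).  Adaptation destabilises a retrieved attractor
and the network "latches" onto a correlated one — the mechanism exploited
for short-term recall.

The continuous equations are integrated by synchronous explicit Euler.
The dynamics are fully deterministic given the initial state and cue; all
run-to-run variability comes from the quenched randomness of patterns,
connectivity and list selection.

A simulation cues one stored pattern with a transient aligned field,
removes the cue and integrates until the network falls into the quiescent
null attractor or a step cap is reached, sampling the overlap of the state
with every stored pattern along the way.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .network import (
    BoostConfig,
    HeteroWeights,
    WeightTensor,
    apply_model1,
    apply_model3a,
    apply_model3b,
    model2_theta_mask,
)
from .patterns import PatternSet

__all__ = [
    "CueSpec",
    "SimConfig",
    "NetworkState",
    "OverlapTrajectory",
    "initial_state",
    "compute_field",
    "update_activations",
    "step",
    "cue_field",
    "overlaps",
    "run",
    "save_trajectory",
    "load_trajectory",
]


@dataclass(frozen=True)
class CueSpec:
    """Transient external field aligned with one stored pattern."""

    pattern: int = 0
    strength: float = 1.0
    duration: float = 0.1  # seconds; default 10 * tau1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("cue duration must be > 0")


@dataclass
class SimConfig:
    """Integration constants and run protocol.

    Time constants are in seconds and must separate scales as
    tau_A < tau1 << tau2 << tau_B (a warning is issued otherwise).
    One "update" is one synchronous Euler step of the whole network.
    """

    tau1: float = 0.01
    tau2: float = 0.2
    tau_A: float = 0.005
    tau_B: float = 100.0
    gamma_A: float = 0.5
    beta: float = 11.0
    U: float = 0.1
    w: float = 1.1
    dt: float | None = None  # defaults to tau_A / 4
    max_updates: int = 100_000
    sample_every: int = 16
    cue: CueSpec = field(default_factory=CueSpec)
    m_null: float = 0.1
    # optional extra condition on summed active-state activation; None
    # disables it (the quiescent softmax keeps substantial background
    # activity, so the overlap criterion alone detects the null attractor)
    activity_null: float | None = None
    seed: int = 0  # provenance only: the integration itself is deterministic

    def __post_init__(self) -> None:
        if self.dt is None:
            self.dt = self.tau_A / 4.0
        if not (0.0 <= self.gamma_A <= 1.0):
            raise ValueError("gamma_A must lie in [0, 1]")
        if self.dt >= self.tau_A:
            raise ValueError("dt must be smaller than tau_A")
        if not (self.tau_A < self.tau1 <= self.tau2 <= self.tau_B):
            warnings.warn(
                "time constants do not satisfy tau_A < tau1 <= tau2 <= tau_B",
                stacklevel=2,
            )

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class NetworkState:
    """Instantaneous state of all units.

    ``sigma`` has S+1 columns: column 0 is the background state, columns
    1..S the active states, and each row sums to 1.  ``r`` and ``theta``
    cover active states only.
    """

    sigma: np.ndarray  # (N, S+1)
    r: np.ndarray  # (N, S)
    theta: np.ndarray  # (N, S)
    thetaA: np.ndarray  # (N,)
    thetaB: np.ndarray  # (N,)
    t: float = 0.0

    @property
    def N(self) -> int:
        return self.r.shape[0]

    @property
    def S(self) -> int:
        return self.r.shape[1]


@dataclass
class OverlapTrajectory:
    """Sampled overlaps of one run.

    ``m`` holds the full (samples, p) overlap matrix when recorded; sweep
    runs keep only the per-sample winning pattern and its overlap, which
    is all digitization needs.
    """

    times: np.ndarray
    winner: np.ndarray  # (T,) argmax-overlap pattern per sample
    winner_m: np.ndarray  # (T,) that maximum overlap
    activity: np.ndarray  # (T,) mean summed active-state activation
    terminated_by: str  # "null_attractor" or "step_cap"
    dt: float
    p: int
    m: np.ndarray | None = None  # (T, p) if recorded in full

    @classmethod
    def from_full(cls, times, m, activity, terminated_by, dt) -> "OverlapTrajectory":
        m = np.asarray(m)
        if m.size:
            winner = m.argmax(axis=1).astype(np.int32)
            winner_m = m.max(axis=1)
        else:
            winner = np.zeros(0, dtype=np.int32)
            winner_m = np.zeros(0)
        return cls(
            times=np.asarray(times),
            winner=winner,
            winner_m=winner_m,
            activity=np.asarray(activity),
            terminated_by=terminated_by,
            dt=dt,
            p=m.shape[1] if m.ndim == 2 else 0,
            m=m,
        )

    @property
    def sample_dt(self) -> float:
        if len(self.times) > 1:
            return float(self.times[1] - self.times[0])
        return self.dt


def initial_state(N: int, S: int, config: SimConfig) -> NetworkState:
    """Equilibrium start: r = theta = theta_A = theta_B = 0 and sigma the
    softmax they imply (so both integration back ends start identically)."""
    state = NetworkState(
        sigma=np.zeros((N, S + 1)),
        r=np.zeros((N, S)),
        theta=np.zeros((N, S)),
        thetaA=np.zeros(N),
        thetaB=np.zeros(N),
    )
    update_activations(state, config)
    return state


def compute_field(
    state: NetworkState,
    weights: WeightTensor,
    w: float | np.ndarray,
    het: HeteroWeights | None = None,
) -> np.ndarray:
    """Input field h_ik (active states only).

    h_ik = sum_{j != i} sum_l J_ijkl sigma_jl
         + w_i (sigma_ik - (1/S) sum_l sigma_il)
         [+ sum_{j != i} sum_l J^het_ijkl theta_jl when serial weights are on].
    """
    sig = state.sigma[:, 1:]  # (N, S)
    h = np.einsum("imkl,iml->ik", weights.blocks, sig[weights.nbr])
    w_arr = np.asarray(w, dtype=float)
    h += (w_arr[:, None] if w_arr.ndim else w_arr) * (
        sig - sig.mean(axis=1, keepdims=True)
    )
    if het is not None:
        h += (het.csr @ state.theta.reshape(-1)).reshape(state.N, state.S)
    return h


def update_activations(state: NetworkState, config: SimConfig) -> NetworkState:
    """Softmax readout over the S active states and the background state.

    sigma_ik = exp(beta r_ik) / Z_i for k > 0 and
    sigma_i0 = exp(beta (U + theta_A + theta_B)) / Z_i, with the maximum
    subtracted inside the exponentials (the result is invariant).
    """
    z = np.concatenate(
        [
            config.beta * (config.U + state.thetaA + state.thetaB)[:, None],
            config.beta * state.r,
        ],
        axis=1,
    )
    z -= z.max(axis=1, keepdims=True)
    e = np.exp(z)
    state.sigma = e / e.sum(axis=1, keepdims=True)
    return state


def step(
    state: NetworkState,
    weights: WeightTensor,
    config: SimConfig,
    w: float | np.ndarray | None = None,
    theta_dec: np.ndarray | None = None,
    cue: np.ndarray | None = None,
    het: HeteroWeights | None = None,
) -> NetworkState:
    """One synchronous explicit-Euler update of the whole network.

    All derivatives are evaluated on the pre-step state; activations are
    then refreshed from the new potentials and thresholds.  ``theta_dec``
    is the per-(unit, state) adaptation reduction of the Model 2 boost;
    ``cue`` an additive external field on the active states.
    """
    dt = config.dt
    h = compute_field(state, weights, config.w if w is None else w, het=het)
    if cue is not None:
        h = h + cue
    sig = state.sigma[:, 1:]
    sumsig = sig.sum(axis=1)
    new_r = state.r + (dt / config.tau1) * (h - state.theta - state.r)
    dec = 0.0 if theta_dec is None else theta_dec
    new_theta = state.theta + (dt / config.tau2) * (sig - state.theta - dec)
    state.thetaA += (dt / config.tau_A) * (config.gamma_A * sumsig - state.thetaA)
    state.thetaB += (dt / config.tau_B) * ((1.0 - config.gamma_A) * sumsig - state.thetaB)
    state.r = new_r
    state.theta = new_theta
    update_activations(state, config)
    if not np.isfinite(state.sigma).all():
        raise FloatingPointError(f"non-finite activations at t={state.t:.4f}s")
    state.t += dt
    return state


def cue_field(patterns: PatternSet, mu: int, strength: float) -> np.ndarray:
    """(N, S) aligned external field g (delta_{xi_i^mu, k} - a/S)."""
    if not (0 <= mu < patterns.p):
        raise IndexError(f"cue pattern {mu} out of range for p={patterns.p}")
    ks = np.arange(1, patterns.S + 1)
    onehot = (patterns.xi[mu][:, None] == ks[None, :]).astype(float)
    return strength * (onehot - patterns.a / patterns.S)


def overlaps(state_sigma_active: np.ndarray, patterns: PatternSet) -> np.ndarray:
    """Overlap m^mu of an (N, S) active-state activation with every pattern.

    m^mu = (1/(N a (1 - a/S))) sum_i sum_k (delta_{xi_i^mu,k} - a/S) sigma_ik;
    at perfect alignment with pattern mu it equals n_active/(N a), i.e. 1
    up to the binomial fluctuation of the pattern's active-unit count.
    """
    sig = state_sigma_active
    a, S, N = patterns.a, patterns.S, patterns.N
    total = sig.sum()
    m = np.empty(patterns.p)
    for mu in range(patterns.p):
        xi = patterns.xi[mu]
        act = xi > 0
        m[mu] = sig[np.nonzero(act)[0], xi[act] - 1].sum() - (a / S) * total
    return m / (N * a * (1.0 - a / S))


def _resolve_boost(
    patterns: PatternSet,
    weights: WeightTensor,
    config: SimConfig,
    boost: BoostConfig | None,
):
    """Translate a boost spec into the quantities the integrator consumes."""
    N, S = patterns.N, patterns.S
    w_vec = np.full(N, config.w, dtype=float)
    theta_dec = np.zeros((N, S))
    if boost is None or boost.model == "none" or boost.delta == 0.0:
        return weights, w_vec, theta_dec
    if boost.model == "M1":
        w_vec = apply_model1(config.w, boost.delta, patterns, boost.stm_list)
    elif boost.model == "M2":
        theta_dec = boost.delta * model2_theta_mask(patterns, boost.stm_list)
    elif boost.model == "M3a":
        weights = apply_model3a(weights, boost.delta, patterns, boost.stm_list)
    elif boost.model == "M3b":
        weights = apply_model3b(weights, boost.delta, patterns, boost.stm_list)
    return weights, w_vec, theta_dec


def run(
    patterns: PatternSet,
    weights: WeightTensor,
    config: SimConfig,
    boost: BoostConfig | None = None,
    het: HeteroWeights | None = None,
    backend: str = "numba",
    record: str = "full",
) -> OverlapTrajectory:
    """Cue, integrate, sample overlaps, and stop on the null attractor or
    the update cap.

    ``backend="numba"`` uses the compiled batched engine (single column);
    ``backend="numpy"`` runs the float64 reference loop, used for oracle
    tests and tiny fixtures.  ``record="digest"`` keeps only per-sample
    winner information instead of the full overlap matrix.
    """
    if backend not in ("numba", "numpy"):
        raise ValueError("backend must be 'numba' or 'numpy'")
    weights, w_vec, theta_dec = _resolve_boost(patterns, weights, config, boost)
    cf = cue_field(patterns, config.cue.pattern, config.cue.strength)
    if backend == "numba":
        from ._engine import simulate_batch

        return simulate_batch(
            patterns,
            weights,
            config,
            w_vecs=w_vec[None, :],
            theta_decs=theta_dec[None, :, :],
            cue_fields=cf[None, :, :],
            het=het,
            record=record,
        )[0]
    return _run_numpy(patterns, weights, config, w_vec, theta_dec, cf, het, record)


def _run_numpy(patterns, weights, config, w_vec, theta_dec, cf, het, record):
    N, S, p = patterns.N, patterns.S, patterns.p
    a = patterns.a
    act_null = config.activity_null if config.activity_null is not None else np.inf
    state = initial_state(N, S, config)
    cue_steps = max(1, round(config.cue.duration / config.dt))
    sample_dt = config.dt * config.sample_every
    n_sustain = max(1, int(np.ceil(config.tau2 / sample_dt)))

    times, ms, acts = [], [], []
    quiet = 0
    terminated = "step_cap"
    for s in range(config.max_updates):
        step(
            state,
            weights,
            config,
            w=w_vec,
            theta_dec=theta_dec,
            cue=cf if s < cue_steps else None,
            het=het,
        )
        if (s + 1) % config.sample_every == 0:
            sig = state.sigma[:, 1:]
            m = overlaps(sig, patterns)
            activity = sig.sum() / N
            times.append(state.t)
            ms.append(m)
            acts.append(activity)
            if s + 1 > cue_steps and m.max() < config.m_null and activity < act_null:
                quiet += 1
                if quiet >= n_sustain:
                    terminated = "null_attractor"
                    break
            else:
                quiet = 0
    m_arr = np.asarray(ms) if ms else np.zeros((0, p))
    traj = OverlapTrajectory.from_full(
        np.asarray(times), m_arr, np.asarray(acts), terminated, config.dt
    )
    if record == "digest":
        traj.m = None
    return traj


def save_trajectory(traj: OverlapTrajectory, path: str | Path) -> None:
    """Binary container (npz) with named arrays plus a JSON sidecar holding
    the termination reason and sampling step."""
    path = Path(path)
    arrays = dict(
        times=traj.times,
        winner=traj.winner,
        winner_m=traj.winner_m,
        activity=traj.activity,
    )
    if traj.m is not None:
        arrays["m"] = traj.m
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = dict(terminated_by=traj.terminated_by, dt=traj.dt, p=traj.p)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_trajectory(path: str | Path) -> OverlapTrajectory:
    path = Path(path)
    data = np.load(path.with_suffix(".npz"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return OverlapTrajectory(
        times=data["times"],
        winner=data["winner"],
        winner_m=data["winner_m"],
        activity=data["activity"],
        terminated_by=meta["terminated_by"],
        dt=meta["dt"],
        p=meta["p"],
        m=data["m"] if "m" in data else None,
    )
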