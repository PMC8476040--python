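# Methods

## Model

### Units and patterns

The network has N = 600 Potts units. Each unit i carries S = 7 active
states plus one background state, summarized by a softmax distribution
σ_ik over k = 0..S. Stored memories are p = 200 random patterns
ξ^μ ∈ {0..S}^N with sparsity a = 0.25: each pattern activates exactly
⌊Na⌋ units, assigning each an active state uniformly. Under this
generator the same-state overlap of two random patterns is a²/S in
expectation, and the pairwise distance d has the closed form
(S−2)a/(2S) + 1/2 ≈ 0.589 at the default (a, S).

### Couplings

Units are connected by a dilute random graph: every unit receives
c_m = 90 distinct presynaptic partners (no self-connections). The
couplings form a Hebbian covariance tensor over active states k, l ≥ 1:

    J_ijkl = (c_ij / (c_m a (1 − a/S))) Σ_μ (δ_{ξ_i^μ,k} − a/S)(δ_{ξ_j^μ,l} − a/S)

Couplings to or from the background state are zero.

### Dynamics

Each unit integrates a field

    h_ik = Σ_j Σ_l J_ijkl σ_jl + w (σ_ik − (1/S) Σ_l σ_il)

where w is a local feedback ("self-reinforcement") term that controls the
latching regime. The state variables are r_ik (input potential) and two
adaptive thresholds θ_ik (state-specific, slow) and a unit-level
θ_i0-type pair of fast/slow inhibition components split by γ_A:

    τ1 dr_ik/dt = h_ik − θ_ik − r_ik              τ1 = 0.01
    τ2 dθ_ik/dt = σ_ik − θ_ik                     τ2 = 0.2
    τ_A, τ_B for the fast/slow inhibition split    τ_A = 0.005, τ_B = 100

Activations are the softmax σ_ik ∝ exp(β r_ik), with the background state
given a constant bias U: σ_i0 ∝ exp(β(U + r_i0)); β = 11, U = 0.1.

Integration is synchronous explicit Euler with all derivatives evaluated
on the pre-step state, dt = τ_A/4 = 1.25 ms, trajectories sampled every 16
steps. The dynamics are deterministic given the cue; all variability is
quenched randomness in patterns and connectivity.

A run starts from the uniform quiescent state, receives a cue field
toward one pattern for 0.1 s, and evolves freely. Retrieval is tracked by
the overlaps

    m^μ = (1/(N a (1 − a/S))) Σ_i Σ_{k≥1} (δ_{ξ_i^μ,k} − a/S) σ_ik.

### Termination: the null attractor

Finite latching sequences end in the globally quiescent state. A run is
labelled `null_attractor` when the largest overlap stays below
m_null = 0.1 for a window of τ2. An additional condition on summed
active-state activity is available (`SimConfig.activity_null`) but
disabled by default: the quiescent softmax retains substantial
active-state mass (the background bias βU is finite), so an activity
threshold tied to the sparsity never fires and the overlap criterion
alone is the meaningful detector. Runs that never meet it stop at the
step cap.

### Phases

Digitized runs are classified by the pair (number of retrieval events,
termination): `noL` — one event then quiescence; `L` — a finite sequence
then quiescence; `infL` — latching alive at the step cap; `SA` — a single
stable attractor at the cap. Along w at γ_A = 0.5 the order is
noL (w ≲ 0.4) → latching (w ≈ 0.8–1.6) → SA (w ≳ 2).

## Short-term memory boosts

Holding a list of L patterns is modelled as a parameter boost confined to
the list:

* **M1** — local feedback w increased by Δw on every unit active in some
  list item. Fraction touched: P_L = 1 − (1−a)^L.
* **M2** — adaptive thresholds θ_ik reduced by Δθ on every (unit, state)
  used by a list item. P_L = 1 − (1−a/S)^L.
* **M3a** — couplings J_ijkl potentiated by ΔJ on connections whose
  (k, l) pair is used by a single list item. P_L = 1 − (1−(a/S)²)^L.
* **M3b** — as 3a but for any pair of boosted unit-states, across items.
  P_L = (1 − (1−a/S)^L)².

The boost loses selectivity as P_L → 1; the critical length L_c solves
P_L = 1 − 1/e, giving 3.5, 27.5, 783.5 and 43.6 items respectively at
(a, S) = (0.25, 7). These inversions are exact and tested to 10⁻⁶.

## Scoring recall

Trajectories are digitized into discrete retrieval events: pattern μ is
retrieved while m^μ is the largest overlap and exceeds m\* = 0.5 for at
least τ2/4; sub-threshold gaps within the same pattern merge. The
digitization is threshold-robust: raising m\* only drops or merges
events, preserving order (asserted at m\* ∈ {0.4, 0.5, 0.6}).

The event sequence is scored against the list with a family of
M-measures differing in the stopping rule:

* `m_corr` — stop at the first repeat **or** intrusion (item outside the
  list); count correct items so far.
* `m_i1` / `m_i` — ignore intrusions; stop at the second / third
  occurrence of an item.
* `m_it` — ignore intrusions; stop when an ordered transition repeats.
* `m_u` — stop after a latch budget of g events; g_log(L) = 4 log2(L) − 2
  (22 events at L = 64).
* `m_r` (budgeted) — a dynamic click budget 2L − h, where h is the number
  of correct recalls so far; intrusions and repeats consume budget.
* `m_corr_budgeted` — `m_corr`'s stopping rule and the budget combined,
  so it never exceeds either.

All scanners are validated against independent brute-force
implementations on random symbol strings (property-based and exhaustive
tests).

## Null baselines

If latching were an equal-probability random walk over the L list items,
the distinct-count before the first revisit would follow the birthday
law: √(πL/2) + 2/3 counts draws including the collision, one fewer counts
distinct items. Simulated walks (10⁴ runs per L over L = 4..512) match
the formula within Monte-Carlo error and fit a log-log slope of ≈ 0.52
(the asymptotic exponent is 0.5; small-L curvature biases the fit
slightly upward). A deterministic greedy baseline that always hops to the
most similar item instead enters a 2–3 item loop almost immediately,
with mean distinct count ≈ 2.7 independent of L — stochastic-like
exploration, not similarity maximization, produces the √L law.

## Serial (instructed) recall

An instruction (I₁, ..., I_L) is imposed by adding weak heteroassociative
couplings from each item's states to its successor's states,

    J^het_ijkl = λ δ_{ξ_i^{I_{t+1}},k} δ_{ξ_j^{I_t},l}   (i ≠ j, summed over t, deduplicated),

driven by the adaptive thresholds so the bias favours the instructed next
item exactly when the current one starts to adapt away. A Model 2
threshold reduction (Δθ = 0.1) holds the whole alphabet in short-term
memory. λ = 0.01 biases without overriding the intrinsic dynamics.
Instructions avoid immediate repeats (AA) and one-back repeats (ABA),
which adaptation forbids; an alphabet of n items admits
n(n−1)(n−2)^(L−2) valid instructions. A run is correct when the first L
digitized items equal the instruction; capacity is the sum over lengths
of the proportion correct, with lengths 1–2 taken as perfect.

## Engine

The reference implementation is plain NumPy, one run at a time, written
directly from the equations. The production engine batches many runs that
share a coupling tensor into a (N, S, B) state array; the field is
computed per unit by gathering the c_m presynaptic activation blocks and
contracting them with a precomputed (S, c_m·S) coupling slab via BLAS.
Per-run quantities (cue pattern, per-unit feedback vector w_i, threshold
reductions) vary across batch columns, so one batch serves mixed
conditions; finished columns (null attractor) are compacted away. The two
backends agree to float32 resolution and identical termination labels,
and identical seeds reproduce trajectories bitwise.

## Parameter choices

Engine constants (β, U, time constants, dt, sampling) are the package
defaults listed above. Experiment sizings — 20 seeds per list length,
8000-step caps for sweeps, 10⁴ walks per L, alphabet size 6 with 6
instructions per length — were fixed from pilot-run variance before the
headline numbers were produced, and are stated alongside each result
(`n` in the acceptance output). Thresholds that the model itself does
not pin down (m\* = 0.5, dwell τ2/4, m_null = 0.1) are config-exposed,
with robustness checks in the test suite.

## Limitations

* Recall saturation results at full network size are qualitative: the
  interior maximum of the boost gain and the magnitude of the budgeted
  recall ceiling are reproduced, but exact peak positions shift with
  seed sets of this size (the gain difference between neighbouring
  lengths is ~1.5 standard errors at 20 seeds).
* The budgeted recall ceiling measured here (≈ 4 items at Δθ = 0.3) is
  of the right order but below the midpoint of its expected magnitude
  band; engine constants not fixed by the model equations (notably the
  inhibition split and cue strength) move it within the band.
* Human-subject comparisons are out of scope: the package reproduces the
  network-side quantities only.
* The greedy baseline uses random similarity matrices, not the stored
  patterns' empirical correlations (the loop-entry behaviour is the same;
  prefactors differ).
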