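"""Free recall of a boosted list: recall counts versus list length.

A list of L patterns is held in short-term memory by lowering the adaptive
thresholds of their unit-states (Model 2, reduction 0.3).  The network is
cued at the first list item and latches freely; every run is scored with
the M-measure family (stop at first repeat or intrusion, budgeted
variants, ...).  Each boosted run is paired with an unboosted baseline from
the same seed, so the boost gain is a within-seed difference.

About two minutes on one CPU (7 list lengths x 8 seeds, paired).
"""

from pottslatch.dynamics import CueSpec, SimConfig
from pottslatch.experiments import boost_gain, build_system, free_recall_sweep

patterns, _, weights = build_system(p=200, N=600, c_m=90, S=7, a=0.25, seed=7)
config = SimConfig(
    w=1.1, gamma_A=0.5, max_updates=8000, sample_every=16, cue=CueSpec(pattern=0)
)

df = free_recall_sweep(
    patterns,
    weights,
    config,
    L_values=[2, 4, 8, 16, 32, 64, 128],
    n_seeds=8,
    delta=0.3,
    boost_model="M2",
    seed=1,
)

print("mean recall metrics per condition and list length:")
cols = ["m_corr", "m_corr_budgeted", "m_r", "m_u"]
print(df.groupby(["condition", "L"])[cols].mean().round(2).to_string())

print("\nboost gain (boosted - baseline m_corr, within seed):")
print(boost_gain(df).round(2).to_string(index=False))

print(
    "\nThe gain rises while the boost still singles the list out, peaks at\n"
    "an intermediate L, and collapses once most unit-states are boosted\n"
    "(the Model 2 critical length is ~27.5 items)."
)
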