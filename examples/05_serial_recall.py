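"""Instructed (serial) recall: biasing the latching order.

A weak heteroassociative coupling (strength lambda) is added from each
instructed item to its successor, while a Model 2 threshold reduction
holds the whole alphabet in short-term memory.  A run counts as correct
when the first L digitized items reproduce the instruction exactly.
Instructions avoid immediate (AA) and one-back (ABA) repeats, which the
adapting network cannot produce.

About five minutes on one CPU (each instruction carries its own
heteroassociative matrix, so the runs cannot share a batch).
"""

import numpy as np

from pottslatch.dynamics import CueSpec, SimConfig
from pottslatch.experiments import (
    build_system,
    serial_capacity_from,
    serial_recall_experiment,
)

patterns, _, weights = build_system(p=200, N=600, c_m=90, S=7, a=0.25, seed=21)
config = SimConfig(
    w=1.0, gamma_A=0.5, max_updates=8000, sample_every=16, cue=CueSpec(pattern=0)
)

rng = np.random.default_rng(21)
alphabet = [int(x) for x in rng.choice(200, size=6, replace=False)]
print(f"alphabet (6 of 200 stored patterns): {alphabet}")

df = serial_recall_experiment(
    patterns,
    weights,
    config,
    alphabet,
    L_values=(3, 4, 5),
    n_seq=6,
    lam=0.01,   # heteroassociative bias strength
    delta=0.1,  # Model 2 threshold reduction holding the alphabet
    seed=3,
)

print("\nproportion of instructions reproduced exactly:")
print(df.groupby("L")["correct"].mean().round(2).to_string())
print(f"\nserial capacity C = {serial_capacity_from(df):.2f} items")
print(
    "\nThe bias only nudges transitions the free dynamics could take, so\n"
    "performance decays with instruction length; lengths 1-2 count as\n"
    "perfect by convention in the capacity sum."
)
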