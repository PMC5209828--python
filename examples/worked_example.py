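"""Walk through every quantity on the tiny shipped instance.

Four subjects (two per class), six genes, five time points. Prints the
per-time F-statistics, the redundancy of the key gene pairs, and the greedy
selection under both redundancy variants. See docs/worked_example.md for the
same numbers derived by hand.
"""

import numpy as np

import tmrmr
from tmrmr.redundancy import pair_distance_matrix, redundancy
from tmrmr.selection import SelectionConfig

ds = tmrmr.worked_example()
per_time, agg = tmrmr.relevance_all(ds)

print("Relevance (one-way F per time point, and the mean across time):")
for j, gid in enumerate(ds.gene_ids):
    row = " ".join(f"{f:6.1f}" for f in per_time[j])
    print(f"  {gid:7s} [{row} ]  mean F = {agg[j]:5.2f}")

print("\nRedundancy of the two key pairs (z-scored trajectories, DTW):")
gid = {g: j for j, g in enumerate(ds.gene_ids)}
for a, b in [("gUP", "gUPs"), ("gUP", "gBUMP")]:
    D = pair_distance_matrix(ds.gene(gid[a]), ds.gene(gid[b]))
    print(
        f"  {a}-{b}: R_c = {redundancy(D, 'C'):.3f} (all subject pairs), "
        f"R_m = {redundancy(D, 'M'):.3f} (matched subjects)"
    )

for variant in ("TMRMR_C", "TMRMR_M"):
    res = tmrmr.select_tmrmr(ds, SelectionConfig(variant=variant, alpha=1.0, m=3))
    steps = ", ".join(
        f"{g} (obj {o:.1f})" for g, o in zip(res.gene_ids, res.objective_trace)
    )
    print(f"\n{variant} greedy selection: {steps}")

print(
    "\ngUPs is gUP lagged by one time step: the matched-subject redundancy"
    "\n(R_m = 0.97) flags the duplicate and TMRMR-M selects gBUMP instead,"
    "\nwhile on this anti-symmetric instance the all-pairs mean dilutes the"
    "\nsignal (R_c = 0.21) and TMRMR-C keeps the duplicate."
)
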