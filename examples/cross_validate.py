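"""Cross-validated accuracy and selection stability on synthetic data.

Feature selection runs strictly inside each training fold (normalization is
refit on training subjects; held-out subjects never influence the gene list).
Reports per-fold and pooled accuracy of a 3-nearest-neighbour classifier on
the selected genes' trajectories, plus the cross-fold stability of the
selected lists.
"""

from sklearn.neighbors import KNeighborsClassifier

import tmrmr
from tmrmr.dataset import minmax_normalize
from tmrmr.evaluation import make_folds, run_cv, stability
from tmrmr.selection import SelectionConfig

ds, _ = tmrmr.generate(tmrmr.SyntheticSpec(seed=1))
plan = make_folds(ds, n_folds=5, seed=1)
cfg = SelectionConfig(variant="TMRMR_C", alpha=0.3, m=8)

table, fold_lists = run_cv(ds, cfg, m_grid=[4, 8], classifier_factory=lambda: KNeighborsClassifier(3), folds=plan)
print("accuracy by m (fold -1 = pooled over all held-out subjects):")
print(table.to_string(index=False))

lists = []
for fold in range(5):
    train = minmax_normalize(ds.subset_subjects(plan.train_indices(fold)))
    lists.append(tmrmr.select_tmrmr(train, SelectionConfig(variant="TMRMR_C", alpha=0.3, m=20)))
rep = stability(lists)
print(
    f"\nstability of the top-{rep.m} lists across folds: "
    f"{rep.n_shared} genes shared by all folds, "
    f"mean Tanimoto {rep.tanimoto:.2f}, mean Spearman rho {rep.spearman_rho:.2f}"
)
print(
    "\nHigh pooled accuracy shows the selected trajectories separate the"
    "\nclasses; the stability numbers say how much of the gene list survives"
    "\nwhen a fifth of the subjects is swapped out."
)
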