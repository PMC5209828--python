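"""Select genes from a synthetic temporal study and compare against truth.

Generates the default synthetic dataset (20 subjects, 2 classes, 200 genes,
10 time points; 8 independent discriminative genes, 3 co-expression clusters
of 4 discriminative-but-redundant genes), then runs TMRMR-C and a pure
relevance ranking and reports how each handles the planted clusters.
"""

import numpy as np

import tmrmr
from tmrmr.dataset import minmax_normalize
from tmrmr.relevance import rank_by_relevance, relevance_all
from tmrmr.selection import SelectionConfig

ds, truth = tmrmr.generate(tmrmr.SyntheticSpec(seed=1))
ds = minmax_normalize(ds)
print(f"dataset: N={ds.n_subjects} subjects, G={ds.n_genes} genes, T={ds.n_times} time points")
print(f"planted: {len(truth.relevant)} independent relevant genes,",
      f"{len(truth.clusters)} clusters of {len(truth.clusters[0])} redundant genes")

m = len(truth.relevant)
res = tmrmr.select_tmrmr(ds, SelectionConfig(variant="TMRMR_C", alpha=0.3, m=m))
_, agg = relevance_all(ds)
f_top = [ds.gene_ids[j] for j in rank_by_relevance(agg)[:m]]


def describe(name, selected):
    planted = set(truth.discriminative)
    hits = sum(g in planted for g in selected)
    per_cluster = [len(set(c) & set(selected)) for c in truth.clusters]
    print(f"\n{name}: {', '.join(selected)}")
    print(f"  planted genes among top {m}: {hits}/{m}")
    print(f"  genes taken per redundancy cluster: {per_cluster}")


describe("TMRMR-C (relevance / DTW-redundancy quotient)", list(res.gene_ids))
describe("pure F-ranking baseline", f_top)

print(
    "\nBoth rankings find only planted signal, but the relevance-only list"
    "\ndraws several interchangeable genes from the same co-expression"
    "\ncluster, while the redundancy term limits each cluster to one"
    "\nrepresentative, freeing slots for independent signal."
)
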