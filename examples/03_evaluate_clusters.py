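"""Score a clustering with ARI, GO annotation ratios, and COR.

Uses tiny hand-built partitions and annotations so every number can be
checked by hand.
"""

from wdcm import (
    AnnotationTable,
    Partition,
    adjusted_rand_index,
    annotation_ratio,
    cluster_overlap_ratio,
)

# Two 2-cluster partitions of the same four genes, maximally disagreeing.
X = Partition({"g1": 0, "g2": 0, "g3": 1, "g4": 1})
C = Partition({"g1": 0, "g3": 0, "g2": 1, "g4": 1})
print(f"ARI(X, X) = {adjusted_rand_index(X, X):.2f}   (identical partitions)")
print(f"ARI(X, C) = {adjusted_rand_index(X, C):.2f}   (worse than chance: negative)")

# Annotation ratio: cluster {g1..g5}; GO term T1 covers 3 of 5 members.
clusters = Partition({f"g{i}": 0 for i in range(1, 6)})
ann = AnnotationTable()
for g in ("g1", "g2", "g3"):
    ann.add(g, "GO:0000001", "BP")
for g in ("g1", "g4"):
    ann.add(g, "GO:0000002", "BP")
res = annotation_ratio(clusters, ann, "BP")
term, ratio = res.per_cluster[0]
print(f"best BP term {term} covers {ratio:.0%} of the cluster; final ratio {res.final:.2f}")

# COR: incomplete-data cluster {g1,g2,g3} overlaps complete cluster {g1,g2}
# in 2/3 of its genes; {g4} nests entirely -> COR = 3/4*2/3 + 1/4*1 = 0.75.
complete = Partition({"g1": 0, "g2": 0, "g3": 1, "g4": 1})
incomplete = Partition({"g1": 0, "g2": 0, "g3": 0, "g4": 1})
print(f"COR = {cluster_overlap_ratio(complete, incomplete):.2f}")
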