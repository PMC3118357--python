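"""Clustering evaluation: ARI, GO annotation ratios, and the Cluster
Overlap Ratio used for missing-data robustness.

All three measures operate on hard :class:`~wdcm.data_io.Partition`
objects. The Adjusted Rand Index is computed in the Hubert–Arabie
pair-count form; note that the adjusted index can be negative for
partitions agreeing less than chance, and this module returns that true
value rather than clipping to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ONTOLOGIES, AnnotationTable, Partition

__all__ = [
    "PairCounts",
    "AnnotationRatioResult",
    "pair_counts",
    "adjusted_rand_index",
    "annotation_ratio",
    "cluster_overlap_ratio",
]


@dataclass(frozen=True)
class PairCounts:
    """Co-assignment counts over all unordered gene pairs.

    a: same cluster in both partitions; b: same in X, different in C;
    c: different in X, same in C; d: different in both.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AnnotationRatioResult:
    """Per-cluster best-term coverage and its mean over clusters."""

    ontology: str
    per_cluster: dict[int, tuple[str | None, float]]  # label -> (term, ratio)
    final: float


def _common_genes(X: Partition, C: Partition) -> list[str]:
    common = [g for g in X.assignments if g in C.assignments]
    if len(common) != len(X.assignments) or len(common) != len(C.assignments):
        warnings.warn(
            f"partitions cover different gene sets; using the "
            f"{len(common)}-gene intersection",
            UserWarning,
        )
    return common


def pair_counts(X: Partition, C: Partition) -> PairCounts:
    """Count gene pairs by co-assignment in two partitions.

    Computed from the contingency table: with n_ij the number of genes in
    cluster i of X and cluster j of C,
    a = Σ C(n_ij, 2), a + b = Σ C(row_i, 2), a + c = Σ C(col_j, 2),
    and d fills up to C(N, 2).
    """
    common = _common_genes(X, C)
    N = len(common)
    if N < 2:
        raise ValueError("pair_counts needs at least 2 common genes")
    x = np.array([X.assignments[g] for g in common])
    c = np.array([C.assignments[g] for g in common])
    cont = pd.crosstab(x, c).to_numpy()

    def comb2(v: np.ndarray) -> int:
        return int((v * (v - 1) // 2).sum())

    a = comb2(cont)
    ab = comb2(cont.sum(axis=1))
    ac = comb2(cont.sum(axis=0))
    total = N * (N - 1) // 2
    b = ab - a
    cc = ac - a
    d = total - a - b - cc
    return PairCounts(a=a, b=b, c=cc, d=d)


def adjusted_rand_index(X: Partition, C: Partition) -> float:
    """Adjusted Rand Index in the pair-count form.

    ARI = 2(ad − bc) / [(a+b)(b+d) + (a+c)(c+d)]. Equals 1 for identical
    partitions, has expectation ~0 for independent partitions, and can be
    negative. When the denominator degenerates to 0 (e.g. both partitions
    all singletons or one single cluster), the index is defined as 1 if the
    partitions agree on every pair and 0 otherwise.
    """
    pc = pair_counts(X, C)
    a, b, c, d = (float(v) for v in (pc.a, pc.b, pc.c, pc.d))
    denom = (a + b) * (b + d) + (a + c) * (c + d)
    if denom == 0.0:
        return 1.0 if (pc.b == 0 and pc.c == 0) else 0.0
    return 2.0 * (a * d - b * c) / denom


def annotation_ratio(
    C: Partition, ann: AnnotationTable, ontology: str
) -> AnnotationRatioResult:
    """Best-single-term GO coverage of each cluster, averaged over clusters.

    For each cluster, every term of the ontology annotating at least one
    member is scanned; the term covering the most members wins (ties go to
    the lexicographically smallest term id) and the cluster's ratio is that
    coverage divided by the cluster size — unannotated genes count in the
    denominator only. The final ratio is the unweighted mean over clusters;
    a cluster with no annotated member scores 0 (with a warning).
    """
    if ontology not in ONTOLOGIES:
        raise ValueError(f"unknown ontology {ontology!r}, expected one of {ONTOLOGIES}")
    per_cluster: dict[int, tuple[str | None, float]] = {}
    for lab, members in C.clusters().items():
        coverage: dict[str, int] = {}
        for g in members:
            for term in ann.lookup(g, ontology):
                coverage[term] = coverage.get(term, 0) + 1
        if not coverage:
            warnings.warn(
                f"cluster {lab}: no gene annotated in {ontology}; ratio 0",
                UserWarning,
            )
            per_cluster[lab] = (None, 0.0)
            continue
        best = min(coverage, key=lambda t: (-coverage[t], t))
        per_cluster[lab] = (best, coverage[best] / len(members))
    final = float(np.mean([r for _, r in per_cluster.values()])) if per_cluster else 0.0
    return AnnotationRatioResult(ontology=ontology, per_cluster=per_cluster, final=final)


def cluster_overlap_ratio(complete: Partition, incomplete: Partition) -> float:
    """Cluster Overlap Ratio between complete- and incomplete-data clusterings.

    For each incomplete cluster I_i, x_i is its best fractional overlap
    with any complete cluster, x_i = max_k |I_i ∩ C_k| / |I_i|, and
    p_i = |I_i| / Σ_j |I_j| its share of the incomplete genes; then
    COR = Σ_i p_i x_i ∈ [0, 1], reaching 1 exactly when every incomplete
    cluster nests inside a single complete cluster.

    Every gene of the incomplete partition must appear in the complete one
    (extras in the complete partition are ignored).
    """
    if not incomplete.assignments:
        raise ValueError("cluster_overlap_ratio: empty incomplete partition")
    unknown = [g for g in incomplete.assignments if g not in complete.assignments]
    if unknown:
        raise ValueError(
            f"{len(unknown)} genes of the incomplete partition are absent from "
            f"the complete partition (e.g. {unknown[0]!r}); restrict first"
        )
    complete_clusters = complete.clusters()
    total = len(incomplete.assignments)
    cor = 0.0
    for members in incomplete.clusters().values():
        mem = set(members)
        best = max(len(mem & set(cm)) for cm in complete_clusters.values())
        x_i = best / len(mem)
        p_i = len(mem) / total
        cor += p_i * x_i
    return float(cor)
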