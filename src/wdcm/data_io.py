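"""Shared data model and tabular I/O.

Expression matrices, cluster partitions, Weibull fit tables and GO annotation
tables are all plain TSV (CSV accepted for matrices), so artifacts stay
diff-able and portable. Missing expression values are carried as ``NaN``
inside :class:`ExpressionMatrix` and never silently treated as numbers:
every consumer must go through :meth:`ExpressionMatrix.gene_values` (which
drops them) or inspect :attr:`ExpressionMatrix.values` explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MISSING_TOKENS",
    "ONTOLOGIES",
    "ExpressionMatrix",
    "Partition",
    "AnnotationTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_partition",
    "write_partition",
    "read_fit_table",
    "write_fit_table",
    "read_annotation_table",
]

#: Cell contents interpreted as a missing value when reading matrices.
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "null"})

#: The three Gene Ontology namespaces.
ONTOLOGIES = ("BP", "CC", "MF")

_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A gene × sample expression matrix with explicit missingness.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (length m).
    sample_ids
        Ordered, unique sample identifiers (length n).
    values
        Float array of shape (m, n); ``NaN`` marks a missing cell. Every
        non-missing cell must be finite.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("matrix must have at least one gene and one sample")
        if np.isinf(self.values).any():
            raise ValueError("non-missing cells must be finite")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    @property
    def n_observed(self) -> int:
        return self.values.size - self.n_missing

    def gene_values(self, gene_id: str) -> np.ndarray:
        """Observed (non-missing) expression values of one gene."""
        row = self.values[self.gene_ids.index(gene_id)]
        return row[~np.isnan(row)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), self.values.copy()
        )


@dataclass
class Partition:
    """A hard clustering: gene identifier → cluster label in 0..k−1.

    Labels are canonical: every label in 0..k−1 is used at least once and
    every gene appears exactly once. ``hubs`` optionally records, per
    cluster label, the gene whose parameter point anchors the cluster.
    """

    assignments: dict[str, int]
    hubs: dict[int, str] | None = None

    def __post_init__(self) -> None:
        labels = set(self.assignments.values())
        if self.assignments:
            k = max(labels) + 1
            if labels != set(range(k)):
                raise ValueError(
                    f"labels must be 0..k-1 with every label used, got {sorted(labels)}"
                )
        if self.hubs is not None:
            for lab, gene in self.hubs.items():
                if lab not in labels:
                    raise ValueError(f"hub for unknown cluster label {lab}")
                if gene not in self.assignments:
                    raise ValueError(f"hub gene {gene!r} not in partition")

    @property
    def k(self) -> int:
        return max(self.assignments.values()) + 1 if self.assignments else 0

    @property
    def genes(self) -> list[str]:
        return list(self.assignments)

    def clusters(self) -> dict[int, list[str]]:
        """Cluster label → member genes, in insertion order."""
        out: dict[int, list[str]] = {lab: [] for lab in range(self.k)}
        for g, lab in self.assignments.items():
            out[lab].append(g)
        return out

    @classmethod
    def from_labels(
        cls,
        gene_ids: Sequence[str],
        labels: Sequence[int],
        hubs: Mapping[int, str] | None = None,
    ) -> "Partition":
        """Build a partition, remapping arbitrary labels to canonical 0..k−1.

        Labels are renumbered by sorted original label, so relative order is
        preserved and the result is deterministic.
        """
        if len(gene_ids) != len(labels):
            raise ValueError("gene_ids and labels length mismatch")
        remap = {old: new for new, old in enumerate(sorted(set(labels)))}
        assignments = {str(g): remap[l] for g, l in zip(gene_ids, labels)}
        new_hubs = (
            {remap[old]: str(gene) for old, gene in hubs.items()} if hubs else None
        )
        return cls(assignments, new_hubs)

    def restrict(self, genes: Iterable[str]) -> "Partition":
        """Sub-partition on ``genes`` (intersection), labels re-canonicalized."""
        keep = [g for g in self.assignments if g in set(genes)]
        hubs = {
            lab: g for lab, g in (self.hubs or {}).items() if g in set(keep)
        } or None
        return Partition.from_labels(keep, [self.assignments[g] for g in keep], hubs)


@dataclass
class AnnotationTable:
    """Gene → GO term sets, per ontology (BP, CC, MF).

    Genes absent from the table look up as empty sets; term sets follow set
    semantics (duplicate annotation rows collapse).
    """

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    def add(self, gene: str, term: str, ontology: str) -> None:
        if ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {ontology!r}, expected one of {ONTOLOGIES}")
        self.entries.setdefault(gene, {}).setdefault(ontology, set()).add(term)

    def lookup(self, gene: str, ontology: str) -> frozenset[str]:
        if ontology not in ONTOLOGIES:
            raise ValueError(f"unknown ontology {ontology!r}, expected one of {ONTOLOGIES}")
        return frozenset(self.entries.get(gene, {}).get(ontology, set()))

    @property
    def genes(self) -> list[str]:
        return list(self.entries)


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    delimiter: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited gene × sample matrix.

    First row is the sample-id header, first column holds gene ids. A cell
    equal to any ``missing_tokens`` entry (after stripping whitespace), or
    empty, becomes missing. Delimiter defaults to tab, or comma for
    ``.csv`` paths.

    Raises
    ------
    ValueError
        On duplicate identifiers, ragged rows, or a non-numeric cell that is
        not a missing token; the message names the offending row/column.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    tokens = set(missing_tokens) | {""}

    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ValueError(f"{path}: empty file")
    header = lines[0].split(sep)
    sample_ids = [c.strip() for c in header[1:]]
    n = len(sample_ids)
    if n == 0:
        raise ValueError(f"{path}: header has no sample columns")

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for ridx, ln in enumerate(lines[1:], start=2):
        cells = ln.split(sep)
        gene = cells[0].strip()
        data = cells[1:]
        if len(data) != n:
            raise ValueError(
                f"{path}: row {ridx} (gene {gene!r}) has {len(data)} values, "
                f"expected {n}"
            )
        vals: list[float] = []
        for cidx, cell in enumerate(data):
            cell = cell.strip()
            if cell in tokens:
                vals.append(math.nan)
                continue
            try:
                vals.append(float(cell))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {ridx}, "
                    f"column {sample_ids[cidx]!r}"
                ) from None
        gene_ids.append(gene)
        rows.append(vals)
    if not gene_ids:
        raise ValueError(f"{path}: no data rows")
    return ExpressionMatrix(gene_ids, sample_ids, np.array(rows, dtype=float))


def write_expression_matrix(
    mat: ExpressionMatrix,
    path: str | Path,
    delimiter: str | None = None,
    missing_token: str = "NA",
) -> None:
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("gene" + sep + sep.join(mat.sample_ids) + "\n")
        for g, row in zip(mat.gene_ids, mat.values):
            cells = [missing_token if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(g + sep + sep.join(cells) + "\n")


def write_partition(p: Partition, path: str | Path) -> None:
    """Write a two-column TSV (gene, cluster); hubs stored as header comments."""
    with open(path, "wt", encoding="utf-8") as fh:
        for lab, gene in sorted((p.hubs or {}).items()):
            fh.write(f"# hub\t{lab}\t{gene}\n")
        fh.write("gene\tcluster\n")
        for g, lab in p.assignments.items():
            fh.write(f"{g}\t{lab}\n")


def read_partition(path: str | Path) -> Partition:
    """Read a two-column TSV partition; inverse of :func:`write_partition`.

    Arbitrary integer labels are accepted and remapped to canonical 0..k−1
    (sorted order preserved).
    """
    genes: list[str] = []
    labels: list[int] = []
    hubs: dict[int, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if ln.startswith("# hub\t"):
                _, lab, gene = ln.split("\t")
                hubs[int(lab)] = gene
                continue
            if ln.startswith("#") or ln.strip() == "":
                continue
            cells = ln.split("\t")
            if cells[0] == "gene":
                continue
            if len(cells) != 2:
                raise ValueError(f"{path}: expected 2 columns, got {len(cells)}: {ln!r}")
            try:
                lab = int(cells[1])
            except ValueError:
                raise ValueError(
                    f"{path}: cluster label {cells[1]!r} for gene {cells[0]!r} "
                    "is not an integer"
                ) from None
            genes.append(cells[0])
            labels.append(lab)
    return Partition.from_labels(genes, labels, hubs or None)


_FIT_COLUMNS = ["gene", "a", "b", "n_obs", "D", "p_value", "accepted", "offset"]


def write_fit_table(fits: Iterable, path: str | Path) -> None:
    """Write per-gene Weibull fits (gene, a, b, n_obs, D, p_value, accepted, offset)."""
    rows = [
        {
            "gene": f.gene_id,
            "a": f.a,
            "b": f.b,
            "n_obs": f.n_obs,
            "D": f.D,
            "p_value": f.p_value,
            "accepted": f.accepted,
            "offset": f.offset,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows, columns=_FIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_fit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in _FIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fit table missing columns {missing}")
    df["accepted"] = df["accepted"].astype(bool)
    return df


def read_annotation_table(path: str | Path, dialect: str = "tsv3col") -> AnnotationTable:
    """Read gene → GO term annotations.

    ``tsv3col`` rows are (gene, term, ontology) with ontology in {BP, CC, MF};
    ``gaf`` follows GAF 2.x column positions, consuming DB-object symbol
    (col 3), GO id (col 5) and aspect (col 9), with aspects P/C/F mapped to
    BP/CC/MF. Comment lines starting with ``!`` or ``#`` are skipped.
    """
    if dialect not in ("tsv3col", "gaf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    table = AnnotationTable()
    with open(path, "rt", encoding="utf-8") as fh:
        for ridx, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if ln.strip() == "" or ln.startswith("!") or ln.startswith("#"):
                continue
            cells = ln.split("\t")
            if dialect == "tsv3col":
                if cells[0].lower() == "gene":  # optional header
                    continue
                if len(cells) < 3:
                    raise ValueError(f"{path}: row {ridx} has fewer than 3 columns")
                gene, term, onto = cells[0], cells[1], cells[2].strip()
                if onto not in ONTOLOGIES:
                    raise ValueError(
                        f"{path}: row {ridx}: unknown ontology {onto!r} "
                        f"(expected BP/CC/MF)"
                    )
            else:
                if len(cells) < 9:
                    raise ValueError(f"{path}: row {ridx} has fewer than 9 GAF columns")
                gene, term, aspect = cells[2], cells[4], cells[8].strip()
                if aspect not in _GAF_ASPECT:
                    raise ValueError(
                        f"{path}: row {ridx}: unknown GAF aspect {aspect!r} "
                        f"(expected P/C/F)"
                    )
                onto = _GAF_ASPECT[aspect]
            table.add(gene, term, onto)
    return table
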