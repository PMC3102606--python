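"""Binary mutation matrices: container, text I/O, call merging, filtering and
per-module descriptive statistics.

The central object is :class:`MutationMatrix`, a samples x genes binary matrix
``X`` with ``x_ij = 1`` when gene *j* carries a somatic aberration (point
mutation or copy-number alteration) in sample *i*.  Everything downstream —
the Winnow exclusivity network, the module search and the algorithmic
significance test — consumes this object.

Two descriptive statistics characterise a candidate module (a gene set):

* **coverage** — fraction of samples with at least one aberration in the set;
* **exclusivity** — fraction of *covered* samples with exactly one aberration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    CallValidationError,
    MatrixFormatError,
    UndefinedStatisticError,
)

__all__ = [
    "MutationMatrix",
    "AberrationCall",
    "ModuleStats",
    "read_matrix",
    "write_matrix",
    "read_point_calls",
    "read_cna_calls",
    "merge_calls",
    "filter_recurrent",
    "coverage",
    "exclusivity",
    "module_stats",
]

AberrationKind = Literal["point_mutation", "amplification", "deletion"]


@dataclass(frozen=True)
class AberrationCall:
    """A single gene-level aberration call in one sample.

    ``synonymous`` is only meaningful for point mutations; non-synonymous,
    validated point mutations and any copy-number call are retained when
    merging into a matrix, everything else is dropped.
    """

    sample_id: str
    gene_id: str
    kind: AberrationKind
    validated: bool = True
    synonymous: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("point_mutation", "amplification", "deletion"):
            raise CallValidationError(f"unknown aberration kind: {self.kind!r}")

    @property
    def retained(self) -> bool:
        """Whether this call contributes a 1 to the merged matrix."""
        if self.kind == "point_mutation":
            return self.validated and not self.synonymous
        return True


@dataclass(frozen=True)
class ModuleStats:
    """Coverage/exclusivity summary for one gene set on one matrix."""

    genes: frozenset[str]
    coverage: float
    exclusivity: float
    covered_samples: int


class MutationMatrix:
    """Binary samples x genes aberration matrix.

    Parameters
    ----------
    samples, genes
        Ordered, unique row and column labels.
    values
        Array of shape ``(len(samples), len(genes))`` containing only 0/1.
    n_universe
        Size of the gene universe the matrix was drawn from, if larger than
        the current column count.  :func:`filter_recurrent` records the
        pre-filter gene count here; the significance test uses it for the
        ``m * log2(n)`` gene-identity penalty.
    """

    def __init__(
        self,
        samples: Sequence[str],
        genes: Sequence[str],
        values: np.ndarray,
        n_universe: int | None = None,
    ) -> None:
        samples = [str(s) for s in samples]
        genes = [str(g) for g in genes]
        values = np.asarray(values)
        if values.ndim != 2 or values.shape != (len(samples), len(genes)):
            raise MatrixFormatError(
                f"value array of shape {values.shape} does not match "
                f"{len(samples)} samples x {len(genes)} genes"
            )
        if values.size and not np.isin(values, (0, 1)).all():
            bad = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise MatrixFormatError(
                f"non-binary entry {values[tuple(bad)]!r} at sample "
                f"{samples[bad[0]]!r}, gene {genes[bad[1]]!r}"
            )
        for kind, labels in (("sample", samples), ("gene", genes)):
            if len(set(labels)) != len(labels):
                seen: set[str] = set()
                dup = next(x for x in labels if x in seen or seen.add(x))
                raise MatrixFormatError(f"duplicate {kind} label: {dup!r}")
        self.samples: list[str] = samples
        self.genes: list[str] = genes
        self.values: np.ndarray = values.astype(np.int8)
        if n_universe is not None and n_universe < len(genes):
            raise MatrixFormatError(
                f"n_universe={n_universe} smaller than gene count {len(genes)}"
            )
        self.n_universe: int = int(n_universe) if n_universe is not None else len(genes)
        self._gene_index = {g: j for j, g in enumerate(genes)}
        self._sample_index = {s: i for i, s in enumerate(samples)}

    # -- basic protocol ----------------------------------------------------
    @property
    def k(self) -> int:
        """Number of samples."""
        return len(self.samples)

    @property
    def n(self) -> int:
        """Number of genes (columns actually present)."""
        return len(self.genes)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MutationMatrix({self.k} samples x {self.n} genes)"

    def equals(self, other: "MutationMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.genes == other.genes
            and np.array_equal(self.values, other.values)
        )

    # -- accessors ---------------------------------------------------------
    def gene_columns(self, genes: Iterable[str]) -> np.ndarray:
        """Column indices for ``genes``, validating membership."""
        idx = []
        for g in genes:
            if g not in self._gene_index:
                raise UndefinedStatisticError(f"unknown gene: {g!r}")
            idx.append(self._gene_index[g])
        return np.asarray(idx, dtype=int)

    def submatrix(self, genes: Sequence[str]) -> np.ndarray:
        """Dense 0/1 array restricted to ``genes`` (all samples)."""
        return self.values[:, self.gene_columns(genes)]

    def column_counts(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        """Per-gene aberration frequency (column sum / k)."""
        return self.column_counts() / float(self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.genes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_universe: int | None = None) -> "MutationMatrix":
        return cls(
            [str(i) for i in frame.index],
            [str(c) for c in frame.columns],
            frame.to_numpy(),
            n_universe=n_universe,
        )


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, sep: str = "\t") -> MutationMatrix:
    """Read a mutation matrix from text.

    Layout: first row is the gene-label header, first column holds sample
    labels, cells are 0/1, tab-separated by default.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").rstrip("\r")
        if not header:
            raise MatrixFormatError(f"{path}: empty header line")
        genes = header.split(sep)[1:]
        samples: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != len(genes) + 1:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {len(genes) + 1} fields, got {len(parts)}"
                )
            samples.append(parts[0])
            row = []
            for g, cell in zip(genes, parts[1:]):
                if cell not in ("0", "1"):
                    raise MatrixFormatError(
                        f"{path}:{lineno}: non-binary value {cell!r} "
                        f"(sample {parts[0]!r}, gene {g!r})"
                    )
                row.append(int(cell))
            rows.append(row)
    values = np.asarray(rows, dtype=np.int8).reshape(len(samples), len(genes))
    return MutationMatrix(samples, genes, values)


def write_matrix(matrix: MutationMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix in the layout accepted by :func:`read_matrix`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(["sample", *matrix.genes]) + "\n")
        for s, row in zip(matrix.samples, matrix.values):
            fh.write(sep.join([s, *("1" if x else "0" for x in row)]) + "\n")


_TRUTHY_VALIDATION = {"valid", "validated", "yes", "true", "1"}
_SYNONYMOUS_CLASSES = {"silent", "synonymous", "synonymous_variant", "syn"}

# MAF-compatible column aliases for point-call files.
_POINT_ALIASES = {
    "sample": ("sample", "tumor_sample_barcode", "sample_id"),
    "gene": ("gene", "hugo_symbol", "gene_id"),
    "validation_status": ("validation_status", "validated"),
    "variant_classification": ("variant_classification", "classification"),
}


def _resolve_column(frame: pd.DataFrame, key: str, aliases: tuple[str, ...]) -> str:
    lower = {c.lower(): c for c in frame.columns}
    for alias in aliases:
        if alias in lower:
            return lower[alias]
    raise MatrixFormatError(f"missing required column {key!r} (accepted: {aliases})")


def read_point_calls(path: str | Path) -> list[AberrationCall]:
    """Read a point-mutation call list (TSV, MAF-compatible column names)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    cols = {k: _resolve_column(frame, k, v) for k, v in _POINT_ALIASES.items()}
    calls = []
    for _, row in frame.iterrows():
        validated = str(row[cols["validation_status"]]).strip().lower() in _TRUTHY_VALIDATION
        synonymous = str(row[cols["variant_classification"]]).strip().lower() in _SYNONYMOUS_CLASSES
        calls.append(
            AberrationCall(
                sample_id=str(row[cols["sample"]]),
                gene_id=str(row[cols["gene"]]),
                kind="point_mutation",
                validated=validated,
                synonymous=synonymous,
            )
        )
    return calls


def read_cna_calls(path: str | Path) -> list[AberrationCall]:
    """Read a gene-level copy-number call list (TSV: sample, gene, direction)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    lower = {c.lower(): c for c in frame.columns}
    for req in ("sample", "gene", "direction"):
        if req not in lower:
            raise MatrixFormatError(f"missing required column {req!r} in CNA call file")
    calls = []
    for _, row in frame.iterrows():
        direction = str(row[lower["direction"]]).strip().lower()
        if direction not in ("amp", "del"):
            raise MatrixFormatError(f"CNA direction must be amp/del, got {direction!r}")
        calls.append(
            AberrationCall(
                sample_id=str(row[lower["sample"]]),
                gene_id=str(row[lower["gene"]]),
                kind="amplification" if direction == "amp" else "deletion",
            )
        )
    return calls


def merge_calls(
    point_calls: Iterable[AberrationCall],
    cna_calls: Iterable[AberrationCall],
    samples: Sequence[str],
    genes: Sequence[str],
) -> MutationMatrix:
    """Merge point-mutation and copy-number calls into one binary matrix.

    ``x_ij = 1`` iff at least one retained call exists for (sample i, gene j):
    a validated non-synonymous point mutation, or any amplification/deletion.
    The direction of copy-number change is deliberately not encoded.  Calls
    referencing samples or genes outside the given universes are a hard error.
    """
    matrix = MutationMatrix(samples, genes, np.zeros((len(samples), len(genes)), np.int8))
    offenders = []
    for call in list(point_calls) + list(cna_calls):
        i = matrix._sample_index.get(call.sample_id)
        j = matrix._gene_index.get(call.gene_id)
        if i is None or j is None:
            offenders.append((call.sample_id, call.gene_id))
            continue
        if call.retained:
            matrix.values[i, j] = 1
    if offenders:
        raise CallValidationError(
            f"{len(offenders)} call(s) reference unknown samples/genes: {offenders[:10]}"
        )
    return matrix


# ---------------------------------------------------------------------------
# Filtering and module statistics
# ---------------------------------------------------------------------------

def filter_recurrent(matrix: MutationMatrix, min_frequency: float) -> MutationMatrix:
    """Restrict to genes altered in at least ``min_frequency`` of samples.

    The comparison is on frequencies and inclusive (``count/k >= f``), so a
    10% threshold over 145 samples keeps genes altered in >= 15 of them.  The
    original gene-universe size is carried along in ``n_universe`` for the
    multiple-testing penalty of the significance test.
    """
    if not 0 < min_frequency <= 1:
        raise ValueError(f"min_frequency must be in (0, 1], got {min_frequency}")
    keep = matrix.frequencies() >= min_frequency
    genes = [g for g, k_ in zip(matrix.genes, keep) if k_]
    return MutationMatrix(
        matrix.samples,
        genes,
        matrix.values[:, keep],
        n_universe=matrix.n_universe,
    )


def coverage(matrix: MutationMatrix, genes: Iterable[str]) -> float:
    """Fraction of samples with >= 1 aberration among ``genes``."""
    genes = list(genes)
    if not genes:
        raise UndefinedStatisticError("coverage of an empty gene set is undefined")
    sub = matrix.submatrix(genes)
    return float((sub.sum(axis=1) >= 1).sum()) / matrix.k


def exclusivity(matrix: MutationMatrix, genes: Iterable[str]) -> float:
    """Fraction of covered samples with exactly one aberration among ``genes``."""
    genes = list(genes)
    if not genes:
        raise UndefinedStatisticError("exclusivity of an empty gene set is undefined")
    per_sample = matrix.submatrix(genes).sum(axis=1)
    covered = int((per_sample >= 1).sum())
    if covered == 0:
        raise UndefinedStatisticError(
            f"exclusivity undefined: no sample covers {sorted(genes)}"
        )
    return float((per_sample == 1).sum()) / covered


def module_stats(matrix: MutationMatrix, genes: Iterable[str]) -> ModuleStats:
    """Coverage and exclusivity of one gene set in one pass."""
    genes = sorted(set(genes))
    per_sample = matrix.submatrix(genes).sum(axis=1)
    covered = int((per_sample >= 1).sum())
    cov = covered / matrix.k
    if covered:
        excl = float((per_sample == 1).sum()) / covered
    else:
        excl = math.nan
    return ModuleStats(frozenset(genes), cov, excl, covered)
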