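"""Algorithmic (compression-based) significance of an RME pattern.

The test compares two prefix codes for a module's k x m binary submatrix:

* **RME coder** — assumes aberrations in the module are unusually frequent and
  mutually exclusive.  It is handed the module gene identities, the per-sample
  and per-gene aberration counts, and then encodes the count-sorted submatrix
  cell by cell.  In a row with no aberration observed yet, the single expected
  aberration (exclusivity assumption) lands on gene *j* with probability
  proportional to *j*'s remaining count; once a row has produced its 1, or a
  row/column count is exhausted, further 1s get only a small probability
  ``epsilon``.
* **Null coder** — aberrations are independent Bernoulli draws at the matrix's
  background frequency ``p_null``.

``d'`` is the total bit saving of the RME coder over the null coder.  From it
we subtract the description cost of the side information:

    d = d' - m*log2(n) - k*log*(m) - m*log*(k) - sort_bits

where ``n`` is the size of the gene universe the module was searched in (an
implicit multiple-testing correction), ``log*`` is the universal-code iterated
logarithm, and ``sort_bits`` prices the count-sorted row/column order.  Since
the counts are transmitted in original sample/gene order, a stable sort is
fully determined by them, so the default sort price is zero bits; the
``tie_groups`` and ``full_permutation`` modes charge for tie-breaking or for
the whole permutation and are available for sensitivity analysis.

By the standard no-free-lunch argument for compression-based testing, the
probability under the null model that *any* encoder saves ``d`` or more bits
is at most ``2^-d``; the reported significance is therefore ``2^-d``
(capped at 1 for non-positive d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .exceptions import DegenerateBackgroundError, ModuleTooSmallError
from .matrix import MutationMatrix

__all__ = [
    "LOG_STAR_CONSTANT",
    "DEFAULT_EPSILON",
    "SignificanceConfig",
    "SignificanceBreakdown",
    "EncodingState",
    "log_star",
    "background_frequency",
    "sort_submatrix",
    "rme_cell_probability",
    "encoding_gain",
    "d_score",
]

#: Universal integer-code normalisation constant (Rissanen's c = 2.865064...),
#: chosen so that sum over positive integers of 2^-log*(x) equals 1.
LOG_STAR_CONSTANT = 2.865064

#: Default probability of a model-violating aberration under the RME coder.
DEFAULT_EPSILON = 2.0**-30

SortPenaltyMode = Literal["none", "tie_groups", "full_permutation"]


@dataclass(frozen=True)
class SignificanceConfig:
    """Tunables of the significance test.

    epsilon
        Probability assigned to a 1 that the exclusivity model considers
        implausible.  Kept very low (default 2^-30): a model-violating
        aberration then costs ~33 bits, an order of magnitude more than a
        null-coded aberration, so a module cannot profitably absorb an
        unrelated recurrent gene; any sufficiently small positive value gives
        identical discovery output, and it must stay positive to avoid
        infinitely large penalties.
    log_star_constant
        Constant c in ``log*(x) = log2(c) + log2(x) + log2(log2(x)) + ...``.
    sort_penalty_mode
        Price of the count-sorted order: "none" (order implied by the
        transmitted counts), "tie_groups" (log2(group!) per tied count group)
        or "full_permutation" (log2(k!) + log2(m!)).
    """

    epsilon: float = DEFAULT_EPSILON
    log_star_constant: float = LOG_STAR_CONSTANT
    sort_penalty_mode: SortPenaltyMode = "none"

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError(f"epsilon must lie in (0, 0.5), got {self.epsilon}")
        if self.log_star_constant <= 1:
            raise ValueError("log_star_constant must exceed 1")
        if self.sort_penalty_mode not in ("none", "tie_groups", "full_permutation"):
            raise ValueError(f"unknown sort_penalty_mode {self.sort_penalty_mode!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "SignificanceConfig":
        """Load from a small key/value (YAML-compatible) text file."""
        import yaml

        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        known = {"epsilon", "log_star_constant", "sort_penalty_mode"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown significance config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class SignificanceBreakdown:
    """Full decomposition of one module's d-score."""

    d_prime: float
    gene_identity_bits: float  # m * log2(n)
    sample_count_bits: float  # k * log*(m)
    gene_count_bits: float  # m * log*(k)
    sort_bits: float
    d: float
    significance: float
    p_null: float


@dataclass
class EncodingState:
    """Running state of the RME coder over a sorted submatrix."""

    per_gene_remaining: np.ndarray  # a_j: unobserved 1s left in each column
    per_sample_remaining: np.ndarray  # b_i: unobserved 1s left in each row
    row_has_one: np.ndarray  # bool per row
    remaining_mutations: int
    remaining_cells: int

    @classmethod
    def for_submatrix(cls, sub: np.ndarray) -> "EncodingState":
        sub = np.asarray(sub)
        return cls(
            per_gene_remaining=sub.sum(axis=0).astype(np.int64),
            per_sample_remaining=sub.sum(axis=1).astype(np.int64),
            row_has_one=np.zeros(sub.shape[0], dtype=bool),
            remaining_mutations=int(sub.sum()),
            remaining_cells=int(sub.size),
        )

    def observe(self, cell: tuple[int, int], value: int) -> None:
        i, j = cell
        self.remaining_cells -= 1
        if value == 1:
            self.per_gene_remaining[j] -= 1
            self.per_sample_remaining[i] -= 1
            self.remaining_mutations -= 1
            self.row_has_one[i] = True


def log_star(x: int | float, config: SignificanceConfig | None = None) -> float:
    """Universal-code length (bits) for a positive integer.

    ``log2(c)`` plus the strictly positive terms of the iterated binary
    logarithm of ``x``.  Arguments below 1 are a domain error.
    """
    if x < 1:
        raise ValueError(f"log_star requires x >= 1, got {x}")
    c = (config or SignificanceConfig()).log_star_constant
    total = math.log2(c)
    term = math.log2(x)
    while term > 0:
        total += term
        term = math.log2(term)
    return total


def background_frequency(matrix: MutationMatrix) -> float:
    """Background per-cell aberration probability: total 1s / (k * n).

    Equivalently the mean number of aberrant genes per sample divided by the
    number of genes.  Estimated on the matrix as given (normally the full,
    unfiltered matrix).
    """
    total = int(matrix.values.sum())
    cells = matrix.values.size
    if cells == 0 or total == 0 or total == cells:
        raise DegenerateBackgroundError(
            "background frequency undefined: matrix is empty, all-zero or all-one"
        )
    return total / cells


# ---------------------------------------------------------------------------
# Canonical sorting
# ---------------------------------------------------------------------------

def _tie_group_bits(counts: Sequence[int]) -> float:
    bits = 0.0
    for count in set(counts):
        g = list(counts).count(count)
        if g > 1:
            bits += math.lgamma(g + 1) / math.log(2)
    return bits


def sort_submatrix(
    sub: np.ndarray,
    config: SignificanceConfig | None = None,
    sample_labels: Sequence[str] | None = None,
    gene_labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, float]:
    """Canonically sort a module submatrix and price the sorted order.

    Columns are ordered by decreasing aberration count (ties by gene label),
    then rows by decreasing count (ties by descending-lexicographic bit
    pattern, then sample label).  The ordering depends only on content and
    labels, never on the input row/column order, which makes the d-score
    invariant under permutations of the input matrix.

    Returns the sorted submatrix and ``sort_bits`` per the configured mode.
    """
    config = config or SignificanceConfig()
    sub = np.asarray(sub)
    k, m = sub.shape
    sample_labels = list(sample_labels) if sample_labels is not None else [str(i) for i in range(k)]
    gene_labels = list(gene_labels) if gene_labels is not None else [str(j) for j in range(m)]

    col_counts = [int(c) for c in sub.sum(axis=0)]
    col_order = sorted(range(m), key=lambda j: (-col_counts[j], gene_labels[j]))
    sub = sub[:, col_order]

    rows = sub.tolist()
    row_counts = [sum(r) for r in rows]
    row_order = sorted(
        range(k),
        key=lambda i: (-row_counts[i], [1 - x for x in rows[i]], sample_labels[i]),
    )
    sub = sub[row_order, :]

    if config.sort_penalty_mode == "none":
        sort_bits = 0.0
    elif config.sort_penalty_mode == "tie_groups":
        sort_bits = _tie_group_bits(list(row_counts)) + _tie_group_bits(list(col_counts))
    else:  # full_permutation
        sort_bits = (math.lgamma(k + 1) + math.lgamma(m + 1)) / math.log(2)
    return sub, sort_bits


# ---------------------------------------------------------------------------
# Cell probabilities and encoding
# ---------------------------------------------------------------------------

def rme_cell_probability(
    state: EncodingState,
    cell: tuple[int, int],
    config: SignificanceConfig | None = None,
    epsilon: float | None = None,
) -> float:
    """RME-model probability that the next (unobserved) cell holds a 1.

    If the cell's row has already produced an aberration, or the gene or
    sample has no unobserved aberrations left, the model considers a 1
    implausible and returns ``epsilon``.  Otherwise the row's single expected
    aberration lands on this gene with probability proportional to its
    remaining count among the row's unobserved cells, clamped into
    ``[epsilon, 1 - epsilon]``.
    """
    i, j = cell
    if epsilon is None:
        epsilon = (config or SignificanceConfig()).epsilon
    a_j = state.per_gene_remaining[j]
    b_i = state.per_sample_remaining[i]
    if state.row_has_one[i] or a_j <= 0 or b_i <= 0:
        return epsilon
    denom = int(state.per_gene_remaining[j:].sum())
    p = a_j / denom
    return min(max(p, epsilon), 1.0 - epsilon)


def encoding_gain(
    sub: np.ndarray,
    p_null: float,
    config: SignificanceConfig | None = None,
) -> float:
    """Bit saving d' of the RME coder over the null coder on a sorted submatrix.

    Cells are visited in row-major (top row first, left to right) order;
    each contributes ``log2(P_RME(x) / P_NULL(x))`` and updates the coder
    state.  ``P_NULL(1) = p_null`` independently per cell.
    """
    if not 0 < p_null < 1:
        raise ValueError(f"p_null must lie in (0, 1), got {p_null}")
    config = config or SignificanceConfig()
    sub = np.asarray(sub)
    if sub.size == 0:
        return 0.0
    k, m = sub.shape
    eps = config.epsilon
    state = EncodingState.for_submatrix(sub)

    log2 = math.log2
    null_one = log2(p_null)
    null_zero = log2(1.0 - p_null)
    one_minus_eps = 1.0 - eps
    log_eps = log2(eps)
    log_one_minus_eps = log2(one_minus_eps)
    d_prime = 0.0
    # plain-Python state mirrors EncodingState; m is tiny so list ops win
    a = [int(x) for x in state.per_gene_remaining]
    b = [int(x) for x in state.per_sample_remaining]
    rows = sub.tolist()
    total_remaining = sum(a)
    for i in range(k):
        row = rows[i]
        b_i = b[i]
        row_open = True
        suffix = total_remaining  # sum of a[j:] while the row is still open
        for j in range(m):
            a_j = a[j]
            if not row_open or b_i <= 0 or a_j <= 0:
                if row[j] == 1:
                    d_prime += log_eps - null_one
                    a[j] = a_j - 1
                    b_i -= 1
                    total_remaining -= 1
                    row_open = False
                else:
                    d_prime += log_one_minus_eps - null_zero
                suffix -= a[j]
                continue
            p = a_j / suffix
            if p < eps:
                p = eps
            elif p > one_minus_eps:
                p = one_minus_eps
            if row[j] == 1:
                d_prime += log2(p) - null_one
                a[j] = a_j - 1
                b_i -= 1
                total_remaining -= 1
                row_open = False
                suffix -= a[j]
            else:
                d_prime += log2(1.0 - p) - null_zero
                suffix -= a_j
        b[i] = b_i
        state.row_has_one[i] = not row_open
        state.remaining_cells -= m
    state.per_gene_remaining[:] = a
    state.per_sample_remaining[:] = b
    state.remaining_mutations = total_remaining
    return d_prime


def d_score(
    matrix: MutationMatrix,
    genes: Iterable[str],
    n_total: int | None = None,
    config: SignificanceConfig | None = None,
    p_null: float | None = None,
) -> SignificanceBreakdown:
    """Score a module: d-score and significance ``2^-d`` with full breakdown.

    ``n_total`` is the size of the gene universe searched (defaults to the
    matrix's recorded universe); ``p_null`` defaults to the background
    frequency of the given matrix, which should be the full pre-filter matrix
    so that the null model reflects the genome-wide passenger rate.
    """
    config = config or SignificanceConfig()
    genes = sorted(set(genes))
    m = len(genes)
    if m < 2:
        raise ModuleTooSmallError(
            f"module must contain at least 2 genes, got {m}: {genes}"
        )
    if n_total is None:
        n_total = matrix.n_universe
    if n_total < matrix.n:
        raise ValueError(f"n_total={n_total} smaller than matrix gene count {matrix.n}")
    if p_null is None:
        p_null = background_frequency(matrix)

    sub = matrix.submatrix(genes)
    k = matrix.k
    sub_sorted, sort_bits = sort_submatrix(
        sub, config, sample_labels=matrix.samples, gene_labels=genes
    )
    d_prime = encoding_gain(sub_sorted, p_null, config)

    gene_identity_bits = m * math.log2(n_total)
    sample_count_bits = k * log_star(m, config)
    gene_count_bits = m * log_star(k, config)
    d = d_prime - gene_identity_bits - sample_count_bits - gene_count_bits - sort_bits
    significance = 2.0 ** (-d) if d > 0 else 1.0
    return SignificanceBreakdown(
        d_prime=d_prime,
        gene_identity_bits=gene_identity_bits,
        sample_count_bits=sample_count_bits,
        gene_count_bits=gene_count_bits,
        sort_bits=sort_bits,
        d=d,
        significance=significance,
        p_null=p_null,
    )
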