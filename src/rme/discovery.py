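"""Module search on the pruned exclusivity graph and the end-to-end pipeline.

Every gene in the graph seeds a greedy local search that enumerates *all*
connected gene sets up to a size limit; candidates are scored with the
algorithmic significance test against the full-matrix background, thresholded
at ``d >= d_threshold`` and reduced to a disjoint final list: repeatedly take
the largest-size bin, emit its highest-d member, and drop every remaining
candidate sharing a gene with it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .exceptions import UndefinedStatisticError
from .matrix import ModuleStats, MutationMatrix, filter_recurrent, module_stats
from .significance import (
    SignificanceBreakdown,
    SignificanceConfig,
    background_frequency,
    d_score,
)
from .winnow import ExclusivityGraph, WinnowConfig, prune_to_graph, score_edges

__all__ = [
    "CandidateModule",
    "DiscoveryConfig",
    "enumerate_connected",
    "score_candidates",
    "select_disjoint",
    "run_discovery",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateModule:
    """A scored candidate module (connected gene set)."""

    genes: frozenset[str]
    seed: str
    stats: ModuleStats
    breakdown: SignificanceBreakdown

    @property
    def d(self) -> float:
        return self.breakdown.d

    @property
    def significance(self) -> float:
        return self.breakdown.significance

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.genes))


@dataclass(frozen=True)
class DiscoveryConfig:
    """End-to-end pipeline configuration.

    Defaults mirror the glioblastoma analysis: 10% recurrence, modules of up
    to five genes, significance cutoff 2^-50 (d_threshold = 50 bits).
    ``d_threshold`` should generally grow with the size of the input data.
    """

    min_recurrence: float = 0.10
    max_module_size: int = 5
    d_threshold: float = 50.0
    winnow: WinnowConfig = field(default_factory=WinnowConfig)
    significance: SignificanceConfig = field(default_factory=SignificanceConfig)
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.d_threshold <= 0:
            raise ValueError("d_threshold must be positive")
        if self.max_module_size < 2:
            raise ValueError("max_module_size must be >= 2")


def enumerate_connected(
    graph: ExclusivityGraph,
    seed: str,
    max_size: int,
) -> list[frozenset[str]]:
    """All connected gene sets of size 2..max_size containing ``seed``.

    Uses the standard fixed-enumeration trick for connected induced subgraphs:
    grow the set one neighbour at a time, only ever adding nodes not yet
    "forbidden", so each set is produced exactly once.  Output is
    deterministic: sorted by size, then by the sorted gene tuple.
    """
    g = graph.graph
    if seed not in g:
        raise UndefinedStatisticError(f"seed gene {seed!r} not in graph")
    results: set[frozenset[str]] = set()

    def grow(current: set[str], frontier: set[str], forbidden: set[str]) -> None:
        if len(current) >= 2:
            results.add(frozenset(current))
        if len(current) == max_size:
            return
        candidates = sorted(frontier)
        local_forbidden = set(forbidden)
        for node in candidates:
            new_frontier = (frontier | set(g.neighbors(node))) - current - local_forbidden - {node}
            grow(current | {node}, new_frontier, set(local_forbidden))
            local_forbidden.add(node)

    grow({seed}, set(g.neighbors(seed)), {seed})
    return sorted(results, key=lambda s: (len(s), tuple(sorted(s))))


def score_candidates(
    matrix: MutationMatrix,
    candidates: Iterable[tuple[str, frozenset[str]]] | Iterable[frozenset[str]],
    n_total: int | None = None,
    config: DiscoveryConfig | None = None,
    p_null: float | None = None,
) -> list[CandidateModule]:
    """Score candidate gene sets and keep those with ``d >= d_threshold``.

    Candidates may be bare gene sets or (seed, gene set) pairs; duplicate
    sets reached from different seeds are collapsed to a single record.
    ``matrix`` should be the full (pre-filter) matrix so the null model uses
    the genome-wide background frequency.
    """
    config = config or DiscoveryConfig()
    if p_null is None:
        p_null = background_frequency(matrix)
    seen: dict[frozenset[str], str] = {}
    for item in candidates:
        if isinstance(item, tuple):
            seed, genes = item
        else:
            seed, genes = min(item), item
        genes = frozenset(genes)
        if genes not in seen:
            seen[genes] = seed
    scored: list[CandidateModule] = []
    for genes in sorted(seen, key=lambda s: (len(s), tuple(sorted(s)))):
        breakdown = d_score(matrix, genes, n_total=n_total, config=config.significance, p_null=p_null)
        if breakdown.d >= config.d_threshold:
            scored.append(
                CandidateModule(
                    genes=genes,
                    seed=seen[genes],
                    stats=module_stats(matrix, genes),
                    breakdown=breakdown,
                )
            )
    scored.sort(key=lambda c: (-c.d, c.sorted_genes()))
    return scored


def select_disjoint(scored: Sequence[CandidateModule]) -> list[CandidateModule]:
    """Reduce scored candidates to a gene-disjoint list.

    Candidates are binned by size; repeatedly the largest occupied bin is
    consulted, its highest-d member (ties by lexicographically smallest gene
    list) is emitted, and every remaining candidate sharing a gene with it is
    discarded.  Output in emission order.
    """
    remaining = list(scored)
    selected: list[CandidateModule] = []
    used: set[str] = set()
    while remaining:
        top_size = max(c.size for c in remaining)
        bin_top = [c for c in remaining if c.size == top_size]
        winner = min(bin_top, key=lambda c: (-c.d, c.sorted_genes()))
        selected.append(winner)
        used |= winner.genes
        remaining = [c for c in remaining if not (c.genes & used)]
    return selected


def run_discovery(
    matrix: MutationMatrix,
    n_total: int | None = None,
    config: DiscoveryConfig | None = None,
) -> list[CandidateModule]:
    """Full pipeline: filter, build the Winnow graph, search, score, select.

    The recurrence filter and Winnow network see only recurrent genes; the
    significance test is evaluated against the background frequency and gene
    universe of the matrix as given (pre-filter), so the multiple-testing
    penalty reflects the whole search space.  Deterministic given config.
    """
    config = config or DiscoveryConfig()
    if n_total is None:
        n_total = matrix.n_universe
    filtered = filter_recurrent(matrix, config.min_recurrence)
    if filtered.n < 2:
        logger.warning(
            "only %d gene(s) pass the %.0f%% recurrence filter; no modules can be formed",
            filtered.n,
            100 * config.min_recurrence,
        )
        return []
    weights = score_edges(filtered, config.winnow)
    graph = prune_to_graph(weights)
    candidates: list[tuple[str, frozenset[str]]] = []
    for seed in graph.genes:
        for genes in enumerate_connected(graph, seed, config.max_module_size):
            candidates.append((seed, genes))
    p_null = background_frequency(matrix)
    scored = score_candidates(matrix, candidates, n_total=n_total, config=config, p_null=p_null)
    return select_disjoint(scored)
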