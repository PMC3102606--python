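"""Exclusivity network construction with the Winnow online learner.

A dense all-pairs exclusivity network is too large and too densely connected
to search directly, so each gene is instead used as the target of two
complementary Winnow runs against the rest of the matrix:

* run 1 — features are the *complemented* bits of every other gene, label is
  the classifier gene's status: an aberration in the classifier should predict
  non-aberration elsewhere;
* run 2 — features are the original bits, label is the complement of the
  classifier's status: non-aberration in the classifier should predict
  aberration in exclusive partners.

Winnow's multiplicative, mistake-driven updates make it robust to the many
irrelevant passenger genes, so the learned weights separate genuine exclusive
partners from background.  The directed weight w(g -> j) is the mean of the
two runs' final weights for feature j; per classifier, only edges scoring at
least the second-highest outgoing weight survive (an adaptive rather than
absolute cutoff, since weight scales differ between classifiers), and the
directed survivors are merged into an undirected exclusivity graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import UndefinedStatisticError
from .matrix import MutationMatrix

__all__ = [
    "WinnowConfig",
    "ExclusivityGraph",
    "pairwise_exclusivity",
    "winnow_fit",
    "score_edges",
    "prune_to_graph",
]


@dataclass(frozen=True)
class WinnowConfig:
    """Winnow2 hyper-parameters.

    promotion_factor
        Multiplicative update alpha (> 1); demotion divides by the same factor.
    threshold_fraction
        The firing threshold is this fraction of the feature count.
    epochs
        Full passes over the samples, visited in input order (deterministic).
    """

    promotion_factor: float = 2.0
    threshold_fraction: float = 0.5
    epochs: int = 10

    def __post_init__(self) -> None:
        if self.promotion_factor <= 1:
            raise ValueError("promotion_factor must exceed 1")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ExclusivityGraph:
    """Undirected gene graph with exclusivity weights.

    ``graph`` is a networkx Graph whose edges carry ``weight`` (max of the
    retained directed weights) and the raw per-direction weights
    ``w_forward``/``w_backward`` keyed by the lexicographic orientation.
    """

    graph: nx.Graph

    @property
    def genes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_weight(self, a: str, b: str) -> float:
        return float(self.graph.edges[a, b]["weight"])

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def write_edge_list(self, path: str | Path) -> None:
        """Tab-separated gene_a, gene_b, weight (lexicographic pairs)."""
        with Path(path).open("w") as fh:
            fh.write("gene_a\tgene_b\tweight\n")
            for a, b in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{a}\t{b}\t{self.graph.edges[a, b]['weight']:.6g}\n")


def pairwise_exclusivity(matrix: MutationMatrix, pair: Sequence[str]) -> float:
    """Exclusivity of one gene pair.

    Number of samples where exactly one of the pair is mutated divided by the
    number of samples where at least one is.  Diagnostic only — the pipeline
    scores edges with Winnow instead of building this dense network.
    """
    a, b = pair
    sub = matrix.submatrix([a, b]).sum(axis=1)
    union = int((sub >= 1).sum())
    if union == 0:
        raise UndefinedStatisticError(f"no sample covers pair ({a!r}, {b!r})")
    return float((sub == 1).sum()) / union


def winnow_fit(
    features: np.ndarray,
    labels: np.ndarray,
    config: WinnowConfig | None = None,
) -> np.ndarray:
    """Train Winnow2 and return the final per-feature weights.

    ``features`` is a (samples x features) 0/1 array, ``labels`` a 0/1 vector.
    Weights start at 1; the learner predicts 1 when the summed weight of
    active features reaches ``threshold_fraction * n_features``, promotes
    active weights by ``alpha`` on a false negative and demotes them by
    ``1/alpha`` on a false positive.  Weights stay strictly positive.
    """
    config = config or WinnowConfig()
    features = np.asarray(features)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on the number of samples")
    k, n_feat = features.shape
    if k < 1:
        raise ValueError("need at least one sample")
    theta = config.threshold_fraction * n_feat
    alpha = config.promotion_factor
    w = np.ones(n_feat, dtype=float)
    active_rows = [np.flatnonzero(features[i]) for i in range(k)]
    for _ in range(config.epochs):
        for i in range(k):
            active = active_rows[i]
            prediction = w[active].sum() >= theta
            y = labels[i] == 1
            if y and not prediction:
                w[active] *= alpha
            elif prediction and not y:
                w[active] /= alpha
    return w


def score_edges(
    matrix: MutationMatrix,
    config: WinnowConfig | None = None,
) -> pd.DataFrame:
    """Directed Winnow weight table over all ordered gene pairs.

    Row = classifier gene, column = feature gene; ``w(g -> j)`` is the mean of
    the complemented-array run and the complemented-classifier run.  The
    diagonal is NaN.  Deterministic given matrix and config.
    """
    config = config or WinnowConfig()
    if matrix.n < 2:
        raise ValueError("need at least two genes to score edges")
    X = matrix.values.astype(np.int8)
    genes = matrix.genes
    table = pd.DataFrame(np.nan, index=genes, columns=genes, dtype=float)
    for g_idx, g in enumerate(genes):
        others = [j for j in range(matrix.n) if j != g_idx]
        feats = X[:, others]
        label = X[:, g_idx]
        # run 1: aberration in g predicts non-aberration elsewhere
        w1 = winnow_fit(1 - feats, label, config)
        # run 2: non-aberration in g predicts aberration elsewhere
        w2 = winnow_fit(feats, 1 - label, config)
        table.iloc[g_idx, others] = (w1 + w2) / 2.0
    return table


def prune_to_graph(weights: pd.DataFrame) -> ExclusivityGraph:
    """Prune a directed weight table to a sparse undirected exclusivity graph.

    For each classifier gene, outgoing edges scoring at least its
    second-highest outgoing weight are retained (ties included; classifiers
    with fewer than two outgoing weights keep everything).  An undirected edge
    exists when either side retained it; its weight is the maximum retained
    directed weight, and both raw directions are stored on the edge.
    """
    graph = nx.Graph()
    genes = list(weights.index)
    graph.add_nodes_from(genes)
    values = weights.to_numpy()
    for gi, g in enumerate(genes):
        row = values[gi]
        finite = np.flatnonzero(~np.isnan(row))
        if finite.size == 0:
            continue
        if finite.size < 2:
            cutoff = -np.inf
        else:
            cutoff = np.sort(row[finite])[-2]
        for j in finite:
            w = row[j]
            if w >= cutoff:
                other = genes[j]
                a, b = sorted((g, other))
                prev = graph.edges[a, b]["weight"] if graph.has_edge(a, b) else -np.inf
                graph.add_edge(a, b, weight=max(prev, float(w)))
                key = "w_forward" if g == a else "w_backward"
                graph.edges[a, b][key] = float(w)
    return ExclusivityGraph(graph)
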