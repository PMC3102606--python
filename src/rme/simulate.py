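"""Synthetic mutation matrices, planted RME modules, and detector benchmarks.

The generator reproduces the frequency structure of real tumor panels: a
handful of highly recurrent driver genes on top of a long tail of rarely hit
passengers.  Two frequency models are available:

* ``binned_empirical`` — re-draw gene frequencies from a binned version of a
  source frequency distribution (1%-wide bins up to 10% frequency, 5%-wide
  above, proportions taken from the source, uniform draws within a bin).  The
  packaged :func:`gbm_like_frequencies` list is a synthetic stand-in shaped
  like a 145-sample glioblastoma panel: ~1% of genes above 10% frequency and
  a mean of ~13.4 aberrant genes per sample over 1290 genes.
* ``large_panel`` — three-tier model for bigger gene panels: 0.1% of genes
  above 0.2 frequency, 0.9% between 0.1 and 0.2, and 99% below 0.1, uniform
  within each tier's range.

A planted module replaces ``size`` randomly chosen columns with a perfectly
exclusive pattern: ``ceil(coverage * k)`` samples each get exactly one module
aberration, with per-gene counts drawn uniformly among the splits that keep
every module gene above the recurrence threshold.

:func:`run_benchmark` replays a detector over independently seeded data sets
and reports *sensitivity* (the planted gene set is among the reported
modules) and *precision* (the planted set strictly outranks every other
reported module).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from .baselines import BaselineMethod, PermutationCorrection, permutation_correction
from .discovery import CandidateModule, DiscoveryConfig, run_discovery
from .exceptions import SimulationConfigError
from .matrix import MutationMatrix

__all__ = [
    "FrequencySpec",
    "SeededTruth",
    "SimulationParams",
    "BenchmarkRecord",
    "BenchmarkResult",
    "gbm_like_frequencies",
    "exclusive_pattern_matrix",
    "sample_background",
    "plant_module",
    "simulate_dataset",
    "run_benchmark",
    "rme_detector",
    "baseline_detector",
    "ModuleDetectionReport",
    "PairDetectionReport",
]


# ---------------------------------------------------------------------------
# Frequency models
# ---------------------------------------------------------------------------

def gbm_like_frequencies(n: int = 1290, k: int = 145, mean_per_sample: float = 13.38) -> np.ndarray:
    """Synthetic per-gene aberration frequencies shaped like a GBM panel.

    A deterministic stand-in (no real tumor data is bundled) with the
    qualitative features of an empirical driver-biased panel: one gene above
    20% frequency, ~0.9% of genes between 10% and 20%, and a heavily
    low-frequency tail starting at 1/k, scaled so the expected number of
    aberrant genes per sample is ``mean_per_sample``.
    """
    n_high = max(1, round(0.001 * n))
    n_mid = max(1, round(0.009 * n))
    n_low = n - n_high - n_mid
    if n_low <= 0:
        raise SimulationConfigError(f"n={n} too small for the three-tier shape")
    high = np.full(n_high, 0.25)
    mid = np.linspace(0.105, 0.195, n_mid)
    floor, ceil_ = 1.0 / k, 0.0995
    target_low = mean_per_sample - high.sum() - mid.sum()
    if not n_low * floor < target_low < n_low * ceil_:
        raise SimulationConfigError("mean_per_sample infeasible for the tail shape")
    t = np.linspace(0.0, 1.0, n_low)

    def tail_sum(power: float) -> float:
        return float((floor + (ceil_ - floor) * t**power).sum())

    lo, hi = 1.0, 1024.0
    while tail_sum(hi) > target_low:
        hi *= 2
    for _ in range(200):
        mid_p = 0.5 * (lo + hi)
        if tail_sum(mid_p) > target_low:
            lo = mid_p
        else:
            hi = mid_p
    low = floor + (ceil_ - floor) * t ** (0.5 * (lo + hi))
    return np.concatenate([high, mid, low[::-1]])


@dataclass(frozen=True)
class FrequencySpec:
    """How to assign a target aberration frequency to each simulated gene."""

    mode: str = "binned_empirical"
    source_frequencies: tuple[float, ...] | None = None
    tier_proportions: tuple[float, float, float] = (0.001, 0.009, 0.99)

    def __post_init__(self) -> None:
        if self.mode not in ("binned_empirical", "large_panel"):
            raise SimulationConfigError(f"unknown frequency mode {self.mode!r}")
        if self.mode == "binned_empirical" and self.source_frequencies is None:
            object.__setattr__(
                self, "source_frequencies", tuple(gbm_like_frequencies())
            )
        if self.source_frequencies is not None:
            freqs = np.asarray(self.source_frequencies)
            if freqs.size and ((freqs < 0).any() or (freqs > 1).any()):
                raise SimulationConfigError("source frequencies must lie in [0, 1]")
        if abs(sum(self.tier_proportions) - 1.0) > 1e-9:
            raise SimulationConfigError("tier proportions must sum to 1")

    @staticmethod
    def bin_edges(max_frequency: float) -> np.ndarray:
        """1%-wide bins up to 10% frequency, 5%-wide above."""
        fine = np.arange(0.0, 0.10, 0.01)
        coarse = np.arange(0.10, max(max_frequency, 0.10) + 0.05, 0.05)
        return np.concatenate([fine, coarse])

    def draw_frequencies(self, n: int, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "large_panel":
            tiers = rng.choice(3, size=n, p=list(self.tier_proportions))
            lows = np.array([0.2, 0.1, 1.0 / k])
            highs = np.array([0.3, 0.2, 0.1])
            u = rng.random(n)
            return lows[tiers] + u * (highs[tiers] - lows[tiers])
        source = np.asarray(self.source_frequencies, dtype=float)
        edges = self.bin_edges(float(source.max()))
        which = np.digitize(source, edges) - 1  # bin index per source gene
        counts = np.bincount(which, minlength=edges.size)
        props = counts[: edges.size - 1].astype(float)
        tail = counts[edges.size - 1 :].sum()  # values at/above the last edge
        props[-1] += tail
        props /= props.sum()
        bins = rng.choice(props.size, size=n, p=props)
        lo = edges[bins]
        hi = np.append(edges[1:], edges[-1] + 0.05)[bins]
        return lo + rng.random(n) * (hi - lo)


@dataclass(frozen=True)
class SeededTruth:
    """The planted module and the pattern it was given."""

    module_genes: frozenset[str]
    coverage: float
    per_gene_counts: dict[str, int] = field(hash=False, compare=False, default_factory=dict)


@dataclass(frozen=True)
class SimulationParams:
    """One benchmark condition: panel size and planted-module shape."""

    k: int = 145
    n: int = 1290
    spec: FrequencySpec = field(default_factory=FrequencySpec)
    module_size: int = 3
    coverage: float = 1.0
    min_recurrence: float = 0.10


def exclusive_pattern_matrix(
    k: int,
    size: int,
    coverage: float,
    exclusivity: float = 1.0,
) -> MutationMatrix:
    """Deterministic module pattern for score-surface sweeps.

    ``round(coverage * k)`` covered samples; of those, a fraction
    ``exclusivity`` carry exactly one module aberration (assigned round-robin
    across the genes) and the rest carry exactly two (round-robin gene
    pairs), so aberrations are equally distributed and the realised coverage
    and exclusivity match the requested values as closely as rounding allows.
    """
    if not 0 < coverage <= 1 or not 0 <= exclusivity <= 1:
        raise SimulationConfigError("coverage in (0,1] and exclusivity in [0,1] required")
    covered = round(coverage * k)
    singles = round(exclusivity * covered)
    values = np.zeros((k, size), dtype=np.int8)
    for i in range(singles):
        values[i, i % size] = 1
    for i in range(singles, covered):
        values[i, i % size] = 1
        values[i, (i + 1) % size] = 1
    samples = [f"s{i:04d}" for i in range(k)]
    genes = [f"g{j:02d}" for j in range(size)]
    return MutationMatrix(samples, genes, values)


def sample_background(
    k: int,
    n: int,
    spec: FrequencySpec | None = None,
    random_seed: int | Sequence[int] = 0,
) -> MutationMatrix:
    """Independent-gene background matrix with realistic frequency structure."""
    if k < 1 or n < 1:
        raise SimulationConfigError("k and n must be >= 1")
    spec = spec or FrequencySpec()
    rng = np.random.default_rng(random_seed)
    freqs = spec.draw_frequencies(n, k, rng)
    values = (rng.random((k, n)) < freqs[None, :]).astype(np.int8)
    samples = [f"s{i:04d}" for i in range(k)]
    genes = [f"g{j:05d}" for j in range(n)]
    return MutationMatrix(samples, genes, values)


def plant_module(
    matrix: MutationMatrix,
    size: int,
    coverage: float,
    min_recurrence: float,
    random_seed: int | Sequence[int] = 0,
) -> tuple[MutationMatrix, SeededTruth]:
    """Replace ``size`` columns with a perfectly exclusive planted module.

    ``ceil(coverage * k)`` samples get exactly one module aberration each;
    per-gene counts are uniform over the compositions that keep every module
    gene at or above the recurrence count.  The chosen columns carry no
    background noise, so the planted exclusivity is exactly 1.
    """
    if not 0.5 <= coverage <= 1.0:
        raise SimulationConfigError(f"coverage must lie in [0.5, 1.0], got {coverage}")
    if not 2 <= size <= 5:
        raise SimulationConfigError(f"module size must lie in 2..5, got {size}")
    k = matrix.k
    covered = int(np.ceil(coverage * k))
    min_count = int(np.ceil(min_recurrence * k))
    if size * min_count > covered:
        raise SimulationConfigError(
            f"cannot give {size} genes >= {min_count} aberrations within {covered} covered samples"
        )
    rng = np.random.default_rng(random_seed)
    gene_idx = np.sort(rng.choice(matrix.n, size=size, replace=False))
    sample_idx = rng.choice(k, size=covered, replace=False)
    # uniform composition of the surplus over the module genes (stars and bars)
    surplus = covered - size * min_count
    if surplus == 0 or size == 1:
        extra = np.zeros(size, dtype=int)
    else:
        bars = np.sort(rng.choice(surplus + size - 1, size=size - 1, replace=False))
        cuts = np.concatenate([[-1], bars, [surplus + size - 1]])
        extra = np.diff(cuts) - 1
    counts = min_count + extra
    values = matrix.values.copy()
    values[:, gene_idx] = 0
    offset = 0
    for g, c in zip(gene_idx, counts):
        values[sample_idx[offset : offset + c], g] = 1
        offset += c
    genes = [matrix.genes[g] for g in gene_idx]
    truth = SeededTruth(
        module_genes=frozenset(genes),
        coverage=covered / k,
        per_gene_counts={g: int(c) for g, c in zip(genes, counts)},
    )
    planted = MutationMatrix(matrix.samples, matrix.genes, values, n_universe=matrix.n_universe)
    return planted, truth


def simulate_dataset(
    params: SimulationParams,
    random_seed: int = 0,
) -> tuple[MutationMatrix, SeededTruth]:
    """Background plus planted module, bit-for-bit reproducible per seed."""
    background = sample_background(params.k, params.n, params.spec, [random_seed, 0])
    return plant_module(
        background,
        params.module_size,
        params.coverage,
        params.min_recurrence,
        random_seed=[random_seed, 1],
    )


# ---------------------------------------------------------------------------
# Detector adapters
# ---------------------------------------------------------------------------

class DetectionReport(Protocol):
    """What a detector must report for the benchmark to grade a run."""

    def is_detected(self, genes: frozenset[str]) -> bool: ...

    def is_unique_best(self, genes: frozenset[str]) -> bool: ...

    def n_reported(self) -> int: ...


class ModuleDetectionReport:
    """Report backed by a list of scored modules (the RME pipeline output)."""

    def __init__(self, modules: Sequence[CandidateModule]) -> None:
        self.modules = list(modules)

    def is_detected(self, genes: frozenset[str]) -> bool:
        return any(m.genes == genes for m in self.modules)

    def is_unique_best(self, genes: frozenset[str]) -> bool:
        target = next((m for m in self.modules if m.genes == genes), None)
        if target is None:
            return False
        return all(m.d < target.d for m in self.modules if m.genes != genes)

    def n_reported(self) -> int:
        return len(self.modules)


class PairDetectionReport:
    """Report backed by permutation-corrected pair statistics.

    A pair is *reported* when its corrected significance is at or below
    ``alpha``; ranking is by (corrected significance, raw statistic), and a
    tie with any other reported pair forfeits uniqueness.
    """

    def __init__(self, correction: PermutationCorrection, alpha: float = 0.05) -> None:
        self.correction = correction
        self.alpha = alpha
        self._mask = correction.reported_mask(alpha)

    def _locate(self, genes: frozenset[str]) -> int | None:
        if len(genes) != 2:
            return None
        a, b = sorted(genes)
        c = self.correction
        try:
            gi, gj = c.genes.index(a), c.genes.index(b)
        except ValueError:
            return None
        pos = np.flatnonzero((c.idx_i == gi) & (c.idx_j == gj))
        return int(pos[0]) if pos.size else None

    def is_detected(self, genes: frozenset[str]) -> bool:
        pos = self._locate(genes)
        return pos is not None and bool(self._mask[pos])

    def is_unique_best(self, genes: frozenset[str]) -> bool:
        pos = self._locate(genes)
        if pos is None or not self._mask[pos]:
            return False
        c = self.correction
        corr, stat = c.corrected[pos], c.statistic[pos]
        others = self._mask.copy()
        others[pos] = False
        rival = (c.corrected[others] < corr) | (
            (c.corrected[others] == corr) & (c.statistic[others] <= stat)
        )
        return not bool(rival.any())

    def n_reported(self) -> int:
        return int(self._mask.sum())


Detector = Callable[[MutationMatrix, int], DetectionReport]


def rme_detector(config: DiscoveryConfig | None = None) -> Detector:
    """Wrap the RME discovery pipeline as a benchmark detector."""
    config = config or DiscoveryConfig()

    def detect(matrix: MutationMatrix, random_seed: int) -> ModuleDetectionReport:
        return ModuleDetectionReport(run_discovery(matrix, config=config))

    return detect


def baseline_detector(
    method: BaselineMethod,
    n_permutations: int = 1000,
    alpha: float = 0.05,
) -> Detector:
    """Wrap a pairwise baseline (with permutation correction) as a detector.

    The baseline sees the full, unfiltered matrix: these statistics have no
    recurrence requirement, which is exactly the failure mode the benchmark
    probes (a pair mutated once each, never together, already attains the
    most exclusive likelihood ratio possible).
    """

    def detect(matrix: MutationMatrix, random_seed: int) -> PairDetectionReport:
        correction = permutation_correction(
            matrix, method=method, n_permutations=n_permutations, random_seed=random_seed
        )
        return PairDetectionReport(correction, alpha=alpha)

    return detect


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkRecord:
    seed: int
    detected: bool
    top_ranked: bool
    runtime_s: float
    n_reported: int
    error: str | None = None


@dataclass(frozen=True)
class BenchmarkResult:
    """Sensitivity/precision of one detector over seeded simulations."""

    n_runs: int
    sensitivity: float
    precision: float
    records: tuple[BenchmarkRecord, ...]

    @property
    def mean_runtime_s(self) -> float:
        return float(np.mean([r.runtime_s for r in self.records]))


def run_benchmark(
    detector: Detector,
    params: SimulationParams,
    n_runs: int,
    base_seed: int = 0,
) -> BenchmarkResult:
    """Run a detector over ``n_runs`` seeded data sets and grade each run.

    Seeds ``base_seed .. base_seed + n_runs - 1`` generate the data sets; a
    detector failure counts as a non-detection and is recorded on the run.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    records: list[BenchmarkRecord] = []
    for i in range(n_runs):
        seed = base_seed + i
        matrix, truth = simulate_dataset(params, random_seed=seed)
        start = time.perf_counter()
        try:
            report = detector(matrix, seed)
            detected = report.is_detected(truth.module_genes)
            top = report.is_unique_best(truth.module_genes)
            n_rep = report.n_reported()
            error = None
        except Exception as exc:  # noqa: BLE001 - recorded, not swallowed silently
            detected = top = False
            n_rep = 0
            error = f"{type(exc).__name__}: {exc}"
        records.append(
            BenchmarkRecord(
                seed=seed,
                detected=detected,
                top_ranked=top,
                runtime_s=time.perf_counter() - start,
                n_reported=n_rep,
                error=error,
            )
        )
    sens = float(np.mean([r.detected for r in records]))
    prec = float(np.mean([r.top_ranked for r in records]))
    return BenchmarkResult(
        n_runs=n_runs,
        sensitivity=sens,
        precision=prec,
        records=tuple(records),
    )
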