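# Methods

## The problem

Tumor characterization panels produce, per patient, a catalogue of somatic
aberrations — validated non-synonymous point mutations and gene-level
copy-number changes. Genes belonging to one functional module are often hit
*recurrently* across a cohort but almost never twice in the same tumor: once
any member is disabled, selective pressure on the others disappears. `rme`
detects such **recurrent, mutually exclusive (RME)** gene modules directly
from the binary tumor-by-gene matrix, with no pathway priors.

Two descriptive statistics characterize a candidate module `M` on a matrix of
`k` samples:

- **coverage** = fraction of samples with ≥ 1 aberration in `M`;
- **exclusivity** = fraction of *covered* samples with exactly 1 aberration.

## Pipeline

1. **Recurrence filter.** Genes altered in fewer than `min_recurrence` of
   samples (default 10%, inclusive on frequencies) carry too little signal
   for exclusivity estimates and are removed from the network stage. The
   pre-filter gene count `n` is retained: it prices the later search.
2. **Winnow network.** For each remaining gene `g`, two Winnow2 runs are
   trained with `g` as the target: one on the complemented matrix (aberration
   in `g` should predict non-aberration elsewhere), one with complemented
   labels (non-aberration in `g` should predict aberration in exclusive
   partners). The directed edge weight `w(g→j)` is the mean of the two final
   weights for feature `j`. Winnow's multiplicative, mistake-driven updates
   tolerate the many irrelevant passenger genes. Because weight scales differ
   per classifier, pruning is adaptive: each classifier keeps outgoing edges
   scoring at least its second-highest weight (ties included); the undirected
   union of survivors, weighted by the larger retained direction, is the
   exclusivity graph.
3. **Search.** Every node seeds an exhaustive enumeration of connected gene
   sets up to `max_module_size` (default 5, inclusive). Duplicates reached
   from different seeds are collapsed.
4. **Scoring** with the algorithmic significance test (below); candidates
   with `d ≥ d_threshold` (default 50 bits, i.e. significance `2^-50`) are
   kept.
5. **Selection.** Candidates are binned by size; repeatedly the largest bin's
   highest-`d` member is emitted and every remaining candidate sharing a gene
   with it is discarded. Output modules are therefore pairwise gene-disjoint.
   Ties on `d` break toward the lexicographically smallest gene list, making
   the whole pipeline deterministic.

## The algorithmic significance test

Whether a `k × m` module submatrix `X` contains a real RME pattern is decided
by a compression (minimum-description-length) argument: compare the bits
needed to encode `X` by a coder that *assumes* the pattern against a null
coder that assumes independent aberrations at the matrix-wide background
rate `p_null` (total 1s over `k·n`, taken from the **unfiltered** matrix, so
the null reflects the genome-wide passenger rate).

The RME coder receives side information — the module's gene identities, the
per-sample aberration counts `a_{i,0}` and per-gene counts `b_{0,j}` — and
visits the count-sorted matrix row by row, left to right. At each cell it
assigns a probability to observing a 1:

- if the row has not yet produced an aberration and both the gene's and the
  sample's remaining counts are positive, the row's single expected
  aberration lands on gene `j` with probability proportional to `j`'s
  remaining count among the row's unobserved cells (a Bayes-posterior under
  the exclusivity assumption), clamped to `[ε, 1−ε]`;
- otherwise a 1 would violate the model and receives only `ε`.

Each cell contributes `log2(P_RME(x) / P_NULL(x))` to the raw gain `d′`.
The description cost of the side information is then subtracted:

    d = d′ − m·log2(n) − k·log*(m) − m·log*(k) − sort_bits

`m·log2(n)` names the module's genes inside the searched universe and acts as
an implicit multiple-testing correction; the count vectors are priced with
the universal integer code `log*(x) = log2(c) + log2 x + log2 log2 x + …`
(positive terms only, `c = 2.865064`). Because the counts are transmitted in
the original sample/gene order, a stable sort is fully determined by them and
the default sort price is zero bits; `tie_groups` (log2 of each tied group's
factorial) and `full_permutation` (`log2 k! + log2 m!`) modes are available
for sensitivity analysis.

Reported significance is `2^-d`, capped at 1 for `d ≤ 0`. The cap and the
penalties make the test conservative by construction: for any prefix code,
the probability under the null that the coder saves `d0` or more bits is at
most `2^-d0` (verified empirically in the calibration test).

### Numerical choices

- **ε (model-violation probability), default `2^-30`.** A 1 that the
  exclusivity model cannot explain costs ~33 bits — far more than the ~6.5
  bits the null coder pays at GBM-like background rates. This matters for
  model selection: adding an unrelated recurrent gene to a true module
  relieves the size penalties by roughly `log2 n + k·Δlog*(m) + log*(k)`
  bits, and if violations were cheap the enlarged module would still clear
  the threshold and displace the true one in the size-binned selection. With
  a genuinely small ε the method reports exactly the exclusive core. Any
  sufficiently small positive value yields the same discovery output
  (perfectly exclusive patterns never pay ε on a 1); zero is excluded to
  avoid infinite penalties.
- **Canonical sort.** Columns order by (count desc, gene label), rows by
  (count desc, pattern desc-lexicographic, sample label). The order depends
  only on content and labels, so `d` is invariant under any permutation of
  the input matrix; ties are broken deterministically.
- **p_null** comes from the matrix handed to discovery, before recurrence
  filtering (a post-filter estimate would conflate driver enrichment with
  background). `d_score` accepts an explicit override for sweeps or for
  externally estimated backgrounds.
- **Degenerate inputs.** All-zero/all-one matrices have no defined
  background; modules of fewer than two genes are rejected; an all-zero
  module encodes to `d ≤ 0` and reports significance 1.

## Baselines

Two classical pairwise exclusivity statistics are included for comparison:
`LR = f12/(f1·f2)` (empirical co-mutation over the product of marginals;
0 for disjoint pairs regardless of recurrence) and the hypergeometric
left-tail `P(overlap ≤ observed)` for random placement of the two sample
sets. Both are corrected empirically: each gene column is permuted
independently (preserving marginals, destroying dependence), the most
exclusive pair statistic per permuted matrix is recorded, and a pair's
corrected significance is the fraction of permutations whose best statistic
was *strictly* more extreme. The strict comparison matters for the
likelihood ratio, whose value 0 is attained by any disjoint pair: with a
non-strict rule the statistic's own ubiquitous ties would mask even a
perfect planted pair. Baselines are evaluated on the unfiltered matrix —
having no recurrence requirement is precisely their documented failure mode.

## Synthetic data

The generator emulates a driver-biased tumor panel. Per-gene frequencies are
drawn either from a binned empirical distribution (1%-wide bins below 10%
frequency, 5%-wide above; proportions from a source list; uniform within the
chosen bin) or from a three-tier large-panel model (0.1% of genes above 0.2,
0.9% in (0.1, 0.2], 99% below 0.1). Since no tumor data is bundled, the
default source list `gbm_like_frequencies()` is a deterministic synthetic
stand-in shaped like a 145-sample glioblastoma panel: 1290 genes, one above
20% frequency, ~1% above 10%, a heavy low-frequency tail starting at `1/k`,
and ~13.4 expected aberrant genes per sample. (Re-binning the tail shifts
realized matrices to ~11–12 aberrant genes per sample; the discovery results
are insensitive to this difference.)

A planted module replaces `size` randomly chosen columns: `⌈coverage·k⌉`
samples get exactly one module aberration each (exclusivity exactly 1), with
per-gene counts uniform over the compositions that keep every gene at or
above the recurrence floor — sampled directly by stars-and-bars rather than
rejection. Planted columns carry no residual background noise.

What the generator does **not** model: co-occurring (non-exclusive) modules,
imperfect planted exclusivity, subclonal structure, sample-specific mutation
rates, and correlated passengers. Passing benchmarks therefore demonstrate
recovery of clean exclusive signals over independent noise, not robustness
to these real-data complications.

## Benchmark design and problem sizes

`run_benchmark` replays a detector over independently seeded data sets and
scores **sensitivity** (the exact planted gene set appears among reported
modules) and **precision** (it strictly outranks every other reported
module; any tie forfeits). The packaged configurations use the panel scale
of 145 samples × 1290 genes with full-coverage planted modules; we run 100
replicates for the three-gene recovery experiment and 50 replicates with 200
permutations per baseline for the method comparison, which keeps the whole
suite within a desktop-scale compute budget while leaving binomial noise on
a 90% rate at about ±3–6 points.

## Known limitations

- The per-cell probability model is one concrete Bayes-posterior consistent
  with the exclusivity assumption; other allocations of the row's expected
  aberration are conceivable and can be swapped behind
  `rme_cell_probability`.
- At 100 samples or fewer, a three-gene module needs near-full coverage to
  clear `d = 50` (the `k·log*(m)` penalty is proportionally heavier), so the
  default threshold is conservative for small cohorts; `d_threshold` should
  scale with the input.
- In our benchmark the hypergeometric baseline does *not* reproduce the low
  precision sometimes attributed to exclusivity p-values: a full-coverage
  planted pair's left-tail p (~1e-40) is smaller than any background pair's
  under every tie-handling rule we could justify, so its precision stays
  near 1 while the likelihood ratio's collapses to ~0. The compression
  test's precision advantage over the likelihood ratio is dramatic; over the
  hypergeometric test, at these conditions, it is not.
- Selection prefers larger modules at equal significance; a submodule of a
  reported module is never reported separately, by design.
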