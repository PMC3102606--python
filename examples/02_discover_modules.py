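"""End-to-end module discovery on a synthetic tumor panel.

Simulates a 145-sample x 1290-gene panel with one planted, perfectly
exclusive 3-gene module, runs the full pipeline (recurrence filter, Winnow
exclusivity network, connected-set search, significance test, disjoint
selection) and prints the report.
"""

from rme import SimulationParams, run_discovery, simulate_dataset

params = SimulationParams(k=145, n=1290, module_size=3, coverage=1.0)
matrix, truth = simulate_dataset(params, random_seed=7)
print(f"panel: {matrix.k} samples x {matrix.n} genes; "
      f"planted module {sorted(truth.module_genes)} "
      f"(per-gene counts {truth.per_gene_counts})\n")

modules = run_discovery(matrix)
print(f"{len(modules)} module(s) with d >= 50:\n")
print("rank  genes                          size  coverage  exclusivity        d  significance")
for rank, mod in enumerate(modules, 1):
    print(f"{rank:>4}  {','.join(mod.sorted_genes()):30s} {mod.size:>4}  "
          f"{mod.stats.coverage:8.2f}  {mod.stats.exclusivity:11.2f}  "
          f"{mod.d:7.1f}  {mod.significance:.3g}")
print()
print("The planted gene set should be reported first: its aberrations cover")
print("every sample exactly once, the strongest possible exclusivity signal.")
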