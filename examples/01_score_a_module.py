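"""Score one candidate module with the algorithmic significance test.

Builds a deterministic 100-sample, 3-gene mutually exclusive pattern at full
coverage, scores it against a glioblastoma-like background rate, and prints
the bit-level breakdown.
"""

from rme import d_score, exclusive_pattern_matrix

PANEL_GENES = 1290          # size of the gene universe the module was found in
BACKGROUND = 13.38 / 1290   # mean aberrant genes per sample / panel size

matrix = exclusive_pattern_matrix(k=100, size=3, coverage=1.0, exclusivity=1.0)
result = d_score(matrix, matrix.genes, n_total=PANEL_GENES, p_null=BACKGROUND)

print(f"raw compression gain d' = {result.d_prime:8.1f} bits")
print(f"gene identities  m*log2(n) = {result.gene_identity_bits:8.1f} bits")
print(f"sample counts    k*log*(m) = {result.sample_count_bits:8.1f} bits")
print(f"gene counts      m*log*(k) = {result.gene_count_bits:8.1f} bits")
print(f"sort order                 = {result.sort_bits:8.1f} bits")
print(f"d = {result.d:.1f} bits  ->  significance 2^-d = {result.significance:.3g}")
print()
print("d is the encoding saving of the exclusivity-aware coder over the")
print("independent-background coder after paying for every piece of side")
print("information; above 50 bits the module clears the 2^-50 cutoff.")
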