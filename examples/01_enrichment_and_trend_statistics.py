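"""Overlap enrichment and the chi-square test for trend.

Reproduces two self-contained statistics of the override analysis: the
hypergeometric enrichment of predicted miRNA targets among downregulated
genes, and a Cochran-Armitage trend test over degree-stratified
percent-PC bins.
"""

from tomnet import chi_square_trend, pearson_directional_p, test_enrichment

# Of 5910 differentially expressed genes, 3678 were down in cancer; 4829
# were predicted miRNA targets, 3206 of which were down.  Is the overlap
# larger than chance?
enr = test_enrichment(N=5910, K=3678, n=4829, k=3206)
print(f"miRNA-target / downregulated overlap: log10 p = {enr.log10_p_upper:.2f}")
print("  -> targets of upregulated miRNAs are strongly enriched for downregulation")

# A decreasing fraction of upregulated (PC) targets across increasing
# miRNA-count bins: proportions 30/60, 18/60, 9/60, 4/60.
x2, p = chi_square_trend([30, 18, 9, 4], [60, 60, 60, 60])
print(f"trend across miRNA-count bins: X2 = {x2:.2f}, p = {p:.2e}")
print("  -> percent-PC falls as more upregulated miRNAs target a gene")

# The one-sided significance of a strong anti-correlation over ten normal
# samples, the criterion used to call co-expression repressor targets.
p_dir = pearson_directional_p(-0.8, 10)
print(f"directional p for r = -0.8, n = 10: {p_dir:.4f}")
print("  -> a pair at the r < -0.8 threshold is significant at p < 0.003")
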