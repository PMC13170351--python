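"""Editing-level comparisons: z-scored matrix, Welch t per site with
BH-FDR across sites, TPM expression, and the tRNA-Arg2 codon-usage test.
"""

import numpy as np
import pandas as pd

from editscan.stats import (
    arg2_codon_enrichment,
    bh_fdr,
    group_test,
    tpm,
    zscore_rows,
)

# a small sites x samples editing matrix: 3 replicates per condition;
# site_a responds to the condition, site_b does not
matrix = pd.DataFrame(
    {
        "rich_1": [32.0, 6.0], "rich_2": [35.0, 5.2], "rich_3": [30.5, 6.7],
        "min_1": [12.0, 5.5], "min_2": [14.5, 6.2], "min_3": [11.0, 5.9],
    },
    index=["site_a", "site_b"],
)
z, flagged = zscore_rows(matrix)
print("z-scored editing levels (rows standardized for heatmap display):")
print(z.round(2).to_string())

pvals = []
for site, row in matrix.iterrows():
    res = group_test(
        {"rich": row[:3].to_numpy(), "minimal": row[3:].to_numpy()},
        method="welch_t",
    )
    pvals.append(res.pvalue)
    print(f"\n{site}: Welch t = {res.statistic:.2f}, p = {res.pvalue:.4f}, "
          f"means {res.group_means}")
q = bh_fdr(pvals)
print(f"\nBH-adjusted q-values: {np.round(q, 4)}")

counts, lengths = [900, 450, 90], [1500, 800, 300]
print(f"\nTPM for counts {counts}, lengths {lengths}:")
print(" ", np.round(tpm(counts, lengths), 1), "(sums to 1e6)")

rich_up = ["CGTCGACGCAAA" * 10]   # arginine-rich coding sequences
minimal_up = ["AAAGGGTTTCCC" * 10]
res = arg2_codon_enrichment(rich_up, minimal_up)
print(
    f"\ntRNA-Arg2-dependent codon usage (CGU/CGA/CGC): "
    f"{res.extra['freq_a']:.1%} vs {res.extra['freq_b']:.1%}, "
    f"odds ratio {res.statistic:.1f}, Fisher two-sided p = {res.pvalue:.2e}"
)
print(
    "\nsite_a's low q-value marks a condition-dependent editing change; "
    "site_b is\nflat.  The codon test asks whether one gene set leans "
    "more on the codons\ndecoded through the edited tRNA wobble position."
)
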