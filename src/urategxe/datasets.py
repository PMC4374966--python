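"""Published serum-urate GWAS summary statistics used as worked examples.

Small frozen tables of meta-analysis summary statistics for well-known
urate loci (SLC2A9, ABCG2, RBFOX3, ...), taken from published
BMI-stratified and SNP-by-BMI interaction genome-wide meta-analyses of
European-ancestry cohorts. They serve as inputs to worked examples: the
package recombines them (inverse-variance pooling, strata-difference
testing, +/-2SE intervals) rather than quoting derived quantities.
"""

from __future__ import annotations

import pandas as pd

#: SNP-by-BMI interaction estimates for the RBFOX3 index SNP rs898534
#: (effect per allele per kg/m^2 on the z-scored urate trait), from the
#: discovery and replication waves of a published interaction GWAMA.
RBFOX3_INTERACTION = pd.DataFrame(
    {
        "analysis": ["discovery", "replication"],
        "snp": ["rs898534", "rs898534"],
        "beta": [-0.016, -0.009],
        "se": [0.003, 0.005],
        "n": [28610, 13959],
    }
)

#: BMI-stratified meta-analysed main effects for the ABCG2 index SNP
#: rs2199936 in men (z-scored urate per A1 allele).
ABCG2_MEN_STRATA = pd.DataFrame(
    {
        "stratum": ["lean", "overweight", "obese"],
        "beta": [-0.323, -0.243, -0.141],
        "se": [0.033, 0.025, 0.036],
    }
).set_index("stratum")

#: ABCG2 rs2231142 lean-stratum effect magnitude in women.
ABCG2_LEAN_WOMEN = {"beta": 0.173, "se": 0.024}

#: counts used in published multiple-testing corrections
N_CANDIDATE_SNPS = 14          # genome-wide significant index SNPs screened
N_STRATA_COMPARISONS = 3       # lean-overweight, lean-obese, overweight-obese
N_KEGG_PATHWAYS = 229
N_PATHWAY_ANALYSES = 9         # 3 BMI strata x 3 sex subsets
N_GENES_GENOME = 17787         # genes in the gene-based association screen
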