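"""Fisher's-method meta-analysis of two cohorts' p-values.

The worked example combines the discovery and replication p-values of the
two loci that replicated across a Chinese discovery cohort and a US
Caucasian replication cohort (HK2: 7.58e-6 and 0.024; UMOD: 2.93e-6 and
0.047)."""

from pleioscan import fisher_combine

for label, pvals in [("HK2 locus (ALM-W)", [7.58e-6, 0.024]),
                     ("UMOD locus (ALM-BR)", [2.93e-6, 0.047])]:
    res = fisher_combine(pvals)
    print(f"{label}: p = {pvals[0]:.3g} and {pvals[1]:.3g} "
          f"-> X = {res.statistic:.3f} on {res.df} df, "
          f"combined p = {res.p_combined:.3e}")

print("\nX = -2*sum(ln p) is chi-square with 2k df under the joint null; a "
      "combined p below each input reflects concordant evidence across "
      "cohorts.")
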