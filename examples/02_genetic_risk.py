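"""Hardy-Weinberg checks and genetic risk grouping.

The chi-square compares observed genotype counts with the p^2 / 2pq /
q^2 proportions implied by the observed allele frequencies (df = 1);
the AD-GRS counts risk-allele-carrying genotypes at CLU, CR1 and
PICALM (0-3, split low 0-1 / high 2-3).
"""

from riskscape import (GeneticProfile, GenotypeCounts, classify_apoe,
                       compute_adgrs, hardy_weinberg_chisq)

for snp, counts in [("CR1", GenotypeCounts(213, 332, 85)),
                    ("PICALM", GenotypeCounts(151, 233, 245))]:
    chi2, df, p = hardy_weinberg_chisq(counts)
    print(f"{snp}: chi2 = {chi2:.3f} (df={df}), p = {p:.4f}")
print("Both SNPs deviate from Hardy-Weinberg equilibrium at these "
      "counts — an excess of one homozygote class relative to 2pq.")

profile = GeneticProfile(apoe="e3/e4", clu="C/T", cr1="G/G", picalm="T/C")
score, group = compute_adgrs(profile)
print(f"\nAPOE e3/e4 -> {classify_apoe(profile).value} "
      "(epsilon-4 carrier: elevated AD genetic risk)")
print(f"CLU C/T + CR1 G/G + PICALM T/C -> AD-GRS {score} ({group.value}): "
      "carriers at two of three loci put this person in the high group")
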