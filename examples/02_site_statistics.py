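"""Per-site validation statistics for the 17 genotyped high-impact SNPs.

Loads the bundled validation-cohort genotype counts (337 fertile stallions,
19 breeds), computes allele frequencies, observed heterozygosity, the
Hardy-Weinberg chi-square and the expected number of mutant-homozygous
stallions, and prints the cohort summary.
"""

from lofscreen.datasets import load_validation_counts, validation_site_stats, validation_verdicts

genes = dict(zip(load_validation_counts().site_id, load_validation_counts().gene))
stats = validation_site_stats()  # e_hom referenced to the full 337 stallions

print(f"{'site':>14} {'gene':<10} {'maf':>7} {'het':>6} {'chi2':>8} {'p_hwe':>9} {'E(hom)':>7} grp")
for s in stats:
    p_txt = "-" if s.p_hwe is None else f"{s.p_hwe:.2g}"
    print(
        f"{s.site_id:>14} {genes[s.site_id]:<10} {s.maf:7.4f} {s.het_obs:6.3f}"
        f" {s.chi2:8.3f} {p_txt:>9} {s.e_hom:7.2f} {s.maf_group:>3}"
    )

_, _, summary = validation_verdicts()
print()
print(f"mean MAF over {summary.n_sites} sites: {summary.mean_maf:.2f}")
print(f"variants with mutant allele but no mutant homozygote: {summary.n_missing_hom_mutant}")
print(f"variants with all three genotypes: {summary.n_all_three_genotypes} "
      f"(mean mutant-homozygote frequency {summary.mean_hom_mutant_freq:.2f})")
print(f"sites deviating from HWE at 0.05: {summary.n_hwe_deviating}")
print()
print("A low E(hom) with zero observed mutant homozygotes is what the screen")
print("predicts for a recessive allele that impairs fertility: carriers are")
print("common enough, homozygotes are missing from the fertile cohort.")
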