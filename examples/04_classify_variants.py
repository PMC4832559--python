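"""Class I / II / III verdicts for the 17 validated high-impact SNPs.

Class I: significantly associated with the fertility breeding value after
Bonferroni correction. Class II: mutant homozygote missing, allele shared
by several breeds - a candidate (in)fertility locus. Class III: private
variants and variants with all three genotypes but no association.
"""

from lofscreen.classification import partition_sizes
from lofscreen.datasets import validation_verdicts

_, verdicts, _ = validation_verdicts()

for cls in ("I", "II", "III"):
    members = [v for v in verdicts if v.variant_class == cls]
    print(f"class {cls} ({len(members)}):")
    for v in members:
        flags = []
        if v.assoc_significant:
            flags.append("assoc")
        if v.missing_hom_mutant:
            flags.append("no hom-mutant")
        if v.private:
            flags.append("private")
        print(f"  {v.site_id:>14} {v.gene:<20} breeds={v.n_breeds:>2} "
              f"maf-group {v.maf_group:<3} {' / '.join(flags)}")
print()
print("partition:", partition_sizes(verdicts))
print("One associated fertility locus, nine candidate loci whose mutant")
print("homozygotes are absent from fertile stallions, and seven variants with")
print("no obvious reproductive relevance.")
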