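"""Verify a suspected deletion through allelic imbalance at intronic SNPs.

A heterozygous SNP in the comparator sample should show ~50/50 allele
reads; if the tumour has lost one copy of the locus, reads from one allele
drop.  With two independent informative SNPs imbalanced the locus is
deletion-consistent; with only one the evidence stays suggestive.
"""

from amlpanel import allelic_imbalance, generate_snp_counts

for case, title in [("two-informative", "matched remission comparator"),
                    ("one-informative", "unmatched reference comparator")]:
    verdicts, locus = allelic_imbalance(generate_snp_counts(case))
    print(f"{title} ({case}):")
    for v in verdicts:
        if not v.informative:
            print(f"  {v.snp_id}: homozygous in comparator - uninformative")
        else:
            state = (f"imbalanced (allele {v.direction} reduced, "
                     f"p={v.p_value:.2e})" if v.imbalanced else "balanced")
            print(f"  {v.snp_id}: heterozygous, {state}")
    print(f"  locus verdict: {locus}\n")
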