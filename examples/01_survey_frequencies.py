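"""Allele frequencies, CIs and Hardy-Weinberg screening of the bundled survey.

Loads the packaged table of genotype/allele frequencies for 39 pharmacogene
SNVs observed in 357 Cuban volunteers, inverts the 2-decimal rounding back to
integer genotype counts, and re-derives the published quantities.
"""

from pgxfreq import (
    CUBAN_SURVEY_N,
    allele_freq,
    heterozygosity_summary,
    hwe_chisq,
    load_cuban_snv_table,
    reconstruct_counts,
)

records = load_cuban_snv_table()
print(f"{len(records)} SNVs, cohort n = {CUBAN_SURVEY_N}\n")

print("rsid        gene     counts (ref/het/alt)   p_alt  (95% CI, Wilson)   HWE p")
for rec in records[:6]:
    c = reconstruct_counts(rec, CUBAN_SURVEY_N)
    est = allele_freq(c)
    hwe = hwe_chisq(c)
    print(
        f"{rec.variant.rsid:<11} {rec.variant.gene:<8} "
        f"({c.n_ref_hom}/{c.n_het}/{c.n_alt_hom})".ljust(45)
        + f"{est.p_alt:.3f}  ({est.ci_low:.3f}-{est.ci_high:.3f})     {hwe.p_value:.3f}"
    )

het = heterozygosity_summary(records)
print(
    f"\nObserved heterozygosity ranges {het.min_het:.0%} ({het.min_locus}) "
    f"to {het.max_het:.0%} ({het.max_locus})."
)

deviating = [
    r.variant.rsid
    for r in records
    if hwe_chisq(reconstruct_counts(r, CUBAN_SURVEY_N)).p_value < 0.05
]
print(
    f"Loci deviating from Hardy-Weinberg equilibrium at p < 0.05: "
    f"{', '.join(deviating)}.\nIn an admixed cohort such deviations usually "
    "reflect population stratification (Wahlund effect), not genotyping error."
)
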