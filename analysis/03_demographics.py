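"""Demographics and vascular risk factors per group, clinical-table style:
mean (SD) with a pooled t test for continuous covariates, count (%) with a
Pearson chi-square for binary ones."""

from _paths import RESULTS, load_atlas_and_cohort

from plp.pipeline import demographic_table

_, cohort = load_atlas_and_cohort()
table = demographic_table(cohort)
table.to_csv(RESULTS / "demographics.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"\nwrote {RESULTS / 'demographics.tsv'}")
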