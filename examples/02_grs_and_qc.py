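"""Build genetic risk scores and run per-SNP quality control.

Each mother's unweighted GRS counts her 25(OH)D-lowering alleles over
the six-SNP panel; the synthesis (2 SNPs) and metabolism (4 SNPs)
sub-scores partition the total, so total = synthesis + metabolism for
every complete profile.  QC reports minor-allele frequency and the
1-df chi-square Hardy-Weinberg test per SNP.
"""

from vdgrs import GeneratorConfig, generate, grs_frame, snp_qc
from vdgrs.genetics import qc_report

dataset = generate(GeneratorConfig(seed=42))

qc = qc_report(snp_qc(dataset.participants, dataset.manifest))
print(qc.to_string(index=False))
# hwe_p > 0.05 for all SNPs indicates genotype frequencies consistent with HWE

scores = grs_frame(dataset.participants, dataset.manifest)
print("\nGRS distribution (total score):")
print(scores["vitd_grs"].value_counts().sort_index().to_string())
print("\ndichotomized groups:", scores["vitd_group"].value_counts().to_dict())
assert (scores["vitd_grs"] == scores["synthesis_grs"] + scores["metabolism_grs"]).all()
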