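"""Simulate a case-control genotyping study and run quality control.

Generates the built-in QC fixture: 515 cases + 770 controls typed at 33
candidate SNPs, in which 56 cases and 19 controls have a genotype missing
rate above 20%, one SNP failed genotyping entirely and two are too rare to
analyze.  Subject-level then SNP-level QC should therefore retain exactly
1210 subjects and 30 SNPs.
"""

from polyrisk import QCThresholds, filter_snps, filter_subjects, make_qc_fixture

ds = make_qc_fixture(seed=1)
print(f"raw cohort: {ds.n_subjects} subjects x {ds.n_variants} SNPs")

kept, subj_report = filter_subjects(ds, QCThresholds())
n_cases = int(kept.status_mask("case").sum())
print(
    f"after subject QC (missing rate > 20% removed): {kept.n_subjects} subjects "
    f"({n_cases} cases / {kept.n_subjects - n_cases} controls), "
    f"{len(subj_report.removed_subjects)} removed"
)

clean, snp_report = filter_snps(kept, QCThresholds())
print(f"after SNP QC: {clean.n_variants} SNPs retained")
for snp, reason in snp_report.removed_snps:
    print(f"  removed {snp}: {reason}")
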