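"""Linkage disequilibrium between chromosome-19 SNPs and the APOE locus.

APOE is recoded biallelically (e2/e3 vs e4) and two-locus haplotype
frequencies are estimated from unphased genotypes by EM.  A SNP with
r-squared >= 0.2 against APOE is a tag of the APOE signal rather than an
independent risk factor; in the default simulation rs2075650 is built to
tag the e4 allele at r-squared ~0.48.
"""

from polyrisk import apoe_as_biallelic, ld_screen, make_qc_fixture, run_qc

clean, _ = run_qc(make_qc_fixture(seed=1))
chr19 = [v.snp_id for v in clean.variants if v.chromosome == "19"]
target = apoe_as_biallelic(clean.subjects)

frame = ld_screen(clean, target, chr19, r2_threshold=0.2)
print("LD of chromosome-19 SNPs with APOE (e2/e3 vs e4):")
print(frame.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
flagged = frame[frame.flagged].snp_id.tolist()
print(f"\nflagged as APOE tags (r2 >= 0.2): {', '.join(flagged) or 'none'}")
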