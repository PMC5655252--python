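"""Load the packaged PSP study table and summarise what the studies report.

Prints the cohort totals and, per covariate, how many of the 18 studies
report it and over what range — the numbers that decide which covariates
are even eligible for meta-regression (at least 10 reporting studies).
"""

import coordmeta as cm

studies = cm.load_psp_studies()
print(f"studies: {len(studies)}")
print(f"patients: {sum(s.n_patients for s in studies)}")
print(f"controls: {sum(s.n_controls for s in studies)}")
print(f"1.5 T scanners: {sum(1 for s in studies if s.scanner_tesla == 1.5)}")
print(f"corrected thresholds: {sum(1 for s in studies if s.threshold_corrected)}")
print()
print(cm.summarize_availability(studies))
print()
print(
    "Each row: number of studies reporting the covariate and the range of\n"
    "reported study means. Covariates with fewer than 10 reporting studies\n"
    "(here H&Y stage and FAB) are skipped by the meta-regression stage."
)
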