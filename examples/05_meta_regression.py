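"""Voxel-wise meta-regression with a planted covariate effect.

Links the planted atrophy amplitude to patient age (slope +0.1 per year
on Hedges g), simulates 18 studies, and asks the meta-regression stage
whether voxels exist where the study-level effect depends on age — using
the conservative threshold (p < 0.0005, extent > 10) that guards the
many-voxels-times-many-covariates search.
"""

import numpy as np

import coordmeta as cm

truth = cm.TruthSpec(seed=5, covariate_links={"age": 0.1})
dataset = cm.simulate_dataset(truth)
grid = truth.build_grid()
study_maps = [
    cm.StudyMaps(rec.study_id, *cm.reconstruct_study_maps(peaks, rec, grid))
    for rec, peaks in zip(dataset.studies, dataset.peak_tables)
]

ages = [s.age_patient_mean for s in dataset.studies]
maps, k_used = cm.meta_regress_maps(study_maps, ages)
spec = cm.ThresholdSpec(p_voxel=0.0005, min_peak_abs_z=1.0, min_extent_voxels=10)
clusters = cm.extract_clusters(maps["z"], maps["p"], spec)

print(f"meta-regression on age over {k_used} studies")
center = np.array(truth.clusters[0].center_mni)
for c in clusters:
    d = np.linalg.norm(np.array(c.peak_mni) - center)
    print(
        f"  {c.sign:9s} slope cluster, {c.extent:4d} voxels, "
        f"peak {c.peak_mni} (|peak - planted center| = {d:.1f} mm)"
    )
print()
print(
    "A positive-slope ('increase') cluster overlapping the planted sphere\n"
    "recovers the age link: older cohorts show weaker planted reductions.\n"
    "Any distant cluster illustrates why the conservative threshold and\n"
    "replication across covariates matter when maps are reconstructed\n"
    "from thresholded peak reports."
)
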