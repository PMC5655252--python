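"""Full coordinate-based meta-analysis on a synthetic dataset.

Uses the generator's default study conditions: 18 studies, per-arm sizes
12-30, one planted gray-matter-reduction cluster (Hedges g = -0.8, 10 mm
sphere at (-6, 4, 2)), studies reporting peaks at their modal p < 0.05
threshold. Each study's signed effect-size map is reconstructed with the
20 mm proximity kernel, pooled voxel-wise with DerSimonian-Laird random
effects, and thresholded at the default operating point (p < 0.005,
|Z| >= 1, extent >= 10).
"""

import coordmeta as cm

truth = cm.TruthSpec(seed=42)
dataset = cm.simulate_dataset(truth)
print(f"simulated {truth.k_studies} studies; peaks per study:",
      [len(t) for t in dataset.peak_tables])

grid = truth.build_grid()
study_maps = [
    cm.StudyMaps(rec.study_id, *cm.reconstruct_study_maps(peaks, rec, grid))
    for rec, peaks in zip(dataset.studies, dataset.peak_tables)
]
maps = cm.pooled_maps(study_maps)
clusters = cm.extract_clusters(maps["z"], maps["p"])

print()
print(cm.cluster_table(clusters).to_string(index=False))
print()
for c in clusters:
    mm, val = cm.cluster_effect_peak(maps["effect"], c)
    print(f"cluster {c.sign:9s} extent {c.extent:5d}: pooled-effect peak {val:+.3f} at {mm}")
print()
print(
    "The largest reduction cluster sits on the planted center with a\n"
    "pooled-effect peak near the planted g = -0.8. The smaller clusters\n"
    "are false positives from the lenient per-study reporting threshold;\n"
    "the jackknife example shows how they are told apart."
)
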