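import numpy as np
import pytest

import coordmeta as cm

#: compact grid for unit tests (half-extent 24 mm, spherical 22 mm mask)
SMALL_GRID_SPEC = {
    "kind": "box",
    "half_extent_mm": 24.0,
    "voxel_mm": 2.0,
    "mask_radius_mm": 22.0,
    "center_mm": (0.0, 0.0, 0.0),
}

PLANTED_CENTER = (-6.0, 4.0, 2.0)


@pytest.fixture(scope="session")
def psp_studies():
    return cm.load_psp_studies()


@pytest.fixture(scope="session")
def small_grid():
    return cm.BrainGrid.from_box(half_extent_mm=24.0, voxel_mm=2.0, mask_radius_mm=22.0)


def strong_truth(seed: int, **overrides) -> cm.TruthSpec:
    """High-SNR regime: strong planted atrophy, strict per-study threshold.

    Mirrors studies reporting at the conventional p < 0.001 level with
    per-study peak effects of the size VBM studies of PSP actually report;
    every study detects the planted cluster and spurious reports are rare.
    """
    kw = dict(
        clusters=(cm.ClusterTruth(PLANTED_CENTER, 10.0, -1.5),),
        study_threshold_p=0.001,
        report_min_extent=10,
        seed=seed,
    )
    kw.update(overrides)
    return cm.TruthSpec(**kw)


def build_study_maps(dataset: cm.SyntheticDataset):
    grid = dataset.truth.build_grid()
    return [
        cm.StudyMaps(rec.study_id, *cm.reconstruct_study_maps(peaks, rec, grid))
        for rec, peaks in zip(dataset.studies, dataset.peak_tables)
    ]
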