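"""Thresholding, cluster extraction, jackknife sensitivity, and bias tests.

Statistical maps are thresholded at an uncorrected voxel p (default 0.005)
with a minimum peak |Z| (default 1) and a minimum cluster extent (default
10 voxels) — the conventional operating point of coordinate-based
meta-analysis, chosen to balance false positives and negatives.  Negative
(gray-matter reduction) and positive (increase) effects are processed
separately.  Robustness is probed by a leave-one-out jackknife (does each
cluster survive every study's omission?) and small-study/publication bias
by Egger's regression on the study effects extracted at each meta-analytic
peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .effects import StudyMaps
from .grid import VolumeMap
from .meta import pooled_maps

__all__ = [
    "ThresholdSpec",
    "ClusterResult",
    "EggerResult",
    "JackknifeResult",
    "extract_clusters",
    "cluster_effect_peak",
    "cluster_table",
    "jackknife",
    "egger_at_peaks",
]

#: 26-neighbourhood connectivity for cluster forming.
_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class ThresholdSpec:
    """Voxel p, minimum peak |Z|, and minimum cluster extent."""

    p_voxel: float = 0.005
    min_peak_abs_z: float = 1.0
    min_extent_voxels: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.p_voxel < 1:
            raise ValueError("p_voxel must lie in (0, 1)")
        if self.min_peak_abs_z <= 0 or self.min_extent_voxels <= 0:
            raise ValueError("threshold components must be positive")


@dataclass(frozen=True)
class ClusterResult:
    """A suprathreshold connected component of the statistical map."""

    voxel_indices: frozenset  # linear (C-order) indices into the full grid
    extent: int
    peak_mni: Tuple[float, float, float]
    peak_z: float
    peak_p: float
    sign: str  # "reduction" | "increase"

    def __post_init__(self) -> None:
        if self.extent != len(self.voxel_indices):
            raise ValueError("extent must equal the number of member voxels")


@dataclass(frozen=True)
class EggerResult:
    """Egger regression of standardised effects on precision at one peak."""

    intercept: float
    intercept_se: float
    t: float
    p: float
    n_studies: int
    peak_mni: Tuple[float, float, float]
    computable: bool = True
    funnel: pd.DataFrame = field(default_factory=pd.DataFrame, compare=False)


@dataclass
class JackknifeResult:
    """Leave-one-out replication table: rows = omitted study, cols = cluster."""

    table: pd.DataFrame
    totals: pd.Series  # "k out of N" count per main cluster

    @property
    def n_iterations(self) -> int:
        return len(self.table)


def extract_clusters(
    z_map: VolumeMap,
    p_map: VolumeMap,
    spec: ThresholdSpec = ThresholdSpec(),
) -> List[ClusterResult]:
    """Partition suprathreshold voxels into 26-connected clusters.

    Voxels with p < ``p_voxel`` are kept, split by the sign of Z, and
    labelled; components are discarded when their extent is below
    ``min_extent_voxels`` or their peak |Z| is below ``min_peak_abs_z``.
    The peak is the member voxel of maximum |Z| (ties: smallest linear
    index).  Clusters are returned sorted by extent, descending.
    """
    if z_map.grid != p_map.grid:
        raise ValueError("z and p maps must share one grid")
    grid = z_map.grid
    z3 = z_map.to_3d(0.0)
    p3 = p_map.to_3d(1.0)
    supra = (p3 < spec.p_voxel) & grid.mask

    clusters: List[ClusterResult] = []
    for sign_name, sign_sel in (("reduction", z3 < 0), ("increase", z3 > 0)):
        labels, n = ndimage.label(supra & sign_sel, structure=_STRUCTURE)
        for lab in range(1, n + 1):
            lin = np.flatnonzero(labels.ravel(order="C") == lab)
            extent = lin.size
            if extent < spec.min_extent_voxels:
                continue
            zvals = z3.ravel(order="C")[lin]
            peak_pos = int(np.argmax(np.abs(zvals)))  # first max = smallest index
            peak_lin = int(lin[peak_pos])
            peak_z = float(zvals[peak_pos])
            if abs(peak_z) < spec.min_peak_abs_z:
                continue
            ijk = np.unravel_index(peak_lin, grid.shape, order="C")
            peak_mm = tuple(float(v) for v in grid.ijk_to_mm(np.array(ijk))[0])
            clusters.append(
                ClusterResult(
                    voxel_indices=frozenset(int(i) for i in lin),
                    extent=int(extent),
                    peak_mni=peak_mm,
                    peak_z=peak_z,
                    peak_p=float(p3.ravel(order="C")[peak_lin]),
                    sign=sign_name,
                )
            )
    clusters.sort(key=lambda c: (-c.extent, c.sign, c.peak_mni))
    return clusters


def cluster_effect_peak(effect_map: VolumeMap, cluster: ClusterResult):
    """Location and value of the pooled-effect extremum inside a cluster.

    The cluster's |Z| peak is what the report tables carry; the pooled-effect
    extremum is the natural point estimate of *where* and *how large* the
    underlying effect is, and is what parameter-recovery checks score.
    """
    grid = effect_map.grid
    eff3 = effect_map.to_3d(0.0).ravel(order="C")
    lin = np.array(sorted(cluster.voxel_indices))
    vals = eff3[lin]
    pos = int(np.argmax(vals)) if cluster.sign == "increase" else int(np.argmin(vals))
    peak_lin = int(lin[pos])
    ijk = np.unravel_index(peak_lin, grid.shape, order="C")
    mm = tuple(float(v) for v in grid.ijk_to_mm(np.array(ijk))[0])
    return mm, float(vals[pos])


def cluster_table(clusters: Sequence[ClusterResult]) -> pd.DataFrame:
    """Tabulate clusters (peak MNI, extent, Z, p) for reporting."""
    rows = []
    for label, c in zip(_labels(), clusters):
        rows.append(
            {
                "cluster": label,
                "sign": c.sign,
                "peak_x": c.peak_mni[0],
                "peak_y": c.peak_mni[1],
                "peak_z_mm": c.peak_mni[2],
                "n_voxels": c.extent,
                "peak_z": c.peak_z,
                "peak_p": c.peak_p,
            }
        )
    cols = ["cluster", "sign", "peak_x", "peak_y", "peak_z_mm", "n_voxels", "peak_z", "peak_p"]
    return pd.DataFrame(rows, columns=cols)


def _labels():
    import itertools
    import string

    for size in range(1, 3):
        for combo in itertools.product(string.ascii_uppercase, repeat=size):
            yield "".join(combo)


def jackknife(
    study_maps: Sequence[StudyMaps],
    spec: ThresholdSpec = ThresholdSpec(),
    main_clusters: Optional[Sequence[ClusterResult]] = None,
) -> JackknifeResult:
    """Leave-one-out replication of the main-analysis clusters.

    Each of the N repeats omits one study, re-pools, re-thresholds, and
    checks for every main cluster whether any same-sign suprathreshold
    cluster shares at least one voxel with it.
    """
    if len(study_maps) < 3:
        raise ValueError("jackknife requires >= 3 studies")
    if main_clusters is None:
        full = pooled_maps(study_maps)
        main_clusters = extract_clusters(full["z"], full["p"], spec)
    labels = [lab for lab, _ in zip(_labels(), main_clusters)]
    rows = {}
    for i, omitted in enumerate(study_maps):
        subset = [sm for j, sm in enumerate(study_maps) if j != i]
        sub = pooled_maps(subset)
        sub_clusters = extract_clusters(sub["z"], sub["p"], spec)
        row = {}
        for lab, main in zip(labels, main_clusters):
            row[lab] = any(
                c.sign == main.sign and not main.voxel_indices.isdisjoint(c.voxel_indices)
                for c in sub_clusters
            )
        rows[omitted.study_id] = row
    table = pd.DataFrame(
        [[rows[sm.study_id][lab] for lab in labels] for sm in study_maps],
        index=pd.Index([sm.study_id for sm in study_maps], name="omitted_study"),
        columns=labels,
        dtype=bool if labels else object,
    )
    totals = table.sum(axis=0).astype(int)
    totals.name = f"replications_of_{len(study_maps)}"
    return JackknifeResult(table=table, totals=totals)


def _egger_fit(g: np.ndarray, s: np.ndarray) -> Tuple[float, float, float, float]:
    """Egger regression g/s = intercept + slope·(1/s); intercept t-test.

    Degenerate no-spread precision (all s equal) leaves the intercept
    undefined by least squares; it is taken as exactly 0 (all signal
    attributed to the slope through the origin), with p = 1.
    """
    y = g / s
    x = 1.0 / s
    n = y.size
    if np.ptp(x) < 1e-12 * max(1.0, float(np.abs(x).max())):
        return 0.0, float("nan"), float("nan"), 1.0
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - 2
    sigma2 = float(resid @ resid) / dof if dof > 0 else float("nan")
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = float(np.sqrt(cov[0, 0]))
    if se == 0.0:
        return float(beta[0]), 0.0, float("nan"), 1.0
    t = float(beta[0] / se)
    p = float(np.clip(2.0 * stats.t.sf(abs(t), dof), 1e-300, 1.0))
    return float(beta[0]), se, t, p


def egger_at_peaks(
    study_maps: Sequence[StudyMaps],
    clusters: Sequence[ClusterResult],
) -> List[EggerResult]:
    """Egger's test at each cluster's peak voxel.

    At the peak, each study contributes its reconstructed effect gᵢ and
    standard error sᵢ = √vᵢ; the standardised effects gᵢ/sᵢ are regressed
    on the precisions 1/sᵢ and the intercept is t-tested two-tailed.  The
    funnel-plot coordinates (gᵢ, 1/sᵢ) are attached for plotting.
    """
    if len(study_maps) < 3:
        raise ValueError("Egger's test requires >= 3 studies")
    if not clusters:
        raise ValueError("no clusters supplied")
    grid = study_maps[0].effect.grid
    mask_lin = grid.mask_indices()
    lin_to_pos = {int(l): i for i, l in enumerate(mask_lin)}
    results = []
    for c in clusters:
        # peak voxel position within the mask ordering
        ijk = np.rint(grid.mm_to_ijk(np.array(c.peak_mni))[0]).astype(int)
        peak_lin = int(np.ravel_multi_index(tuple(ijk), grid.shape, order="C"))
        pos = lin_to_pos[peak_lin]
        g = np.array([sm.effect.values[pos] for sm in study_maps])
        s = np.sqrt(np.array([sm.variance.values[pos] for sm in study_maps]))
        ok = s > 0
        funnel = pd.DataFrame(
            {
                "study_id": [sm.study_id for sm in study_maps],
                "effect": g,
                "precision": np.where(ok, 1.0 / np.where(ok, s, 1.0), np.nan),
            }
        )
        if ok.sum() < 3:
            results.append(
                EggerResult(
                    intercept=float("nan"),
                    intercept_se=float("nan"),
                    t=float("nan"),
                    p=float("nan"),
                    n_studies=int(ok.sum()),
                    peak_mni=c.peak_mni,
                    computable=False,
                    funnel=funnel,
                )
            )
            continue
        b0, se, t, p = _egger_fit(g[ok], s[ok])
        results.append(
            EggerResult(
                intercept=b0,
                intercept_se=se,
                t=t,
                p=p,
                n_studies=int(ok.sum()),
                peak_mni=c.peak_mni,
                computable=True,
                funnel=funnel,
            )
        )
    return results


def plot_funnel(result: EggerResult, ax=None):
    """Thin funnel-plot rendering of one peak's study effects."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(result.funnel["effect"], result.funnel["precision"])
    ax.set_xlabel("effect size (Hedges g)")
    ax.set_ylabel("precision (1/SE)")
    ax.set_title(f"peak {result.peak_mni}, Egger p = {result.p:.3g}")
    return ax
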