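"""End-to-end orchestration of the meta-analysis from a config file.

``run_main`` executes the full chain — study/peak loading, per-study map
reconstruction, random-effects pooling, cluster extraction — and writes
maps (NIfTI), cluster tables (TSV, reduction and increase reported
separately even when empty), and a JSON summary with full provenance
(config, seed, input hashes, versions).  The companion runners re-use the
same machinery for the subgroup analysis, the leave-one-out jackknife,
the heterogeneity map, Egger bias tests at the main peaks, and voxel-wise
meta-regressions.  Meta-regression enforces the availability rule: a
covariate reported by fewer than ``min_covariate_studies`` studies
(default 10) is skipped with a logged reason.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import yaml

from . import __version__
from .effects import KernelSpec, StudyMaps, reconstruct_study_maps
from .grid import BrainGrid, VolumeMap
from .inference import (
    ClusterResult,
    EggerResult,
    JackknifeResult,
    ThresholdSpec,
    cluster_table,
    egger_at_peaks,
    extract_clusters,
    jackknife,
)
from .meta import meta_regress_maps, pooled_maps, q_heterogeneity_map
from .study_io import (
    AVAILABILITY_FIELDS,
    StudyRecord,
    load_peak_tables,
    load_study_table,
)
from scipy import stats

__all__ = [
    "RunConfig",
    "RunResult",
    "run_main",
    "run_subgroup",
    "run_jackknife",
    "run_heterogeneity",
    "run_bias",
    "run_meta_regressions",
    "covariate_vector",
]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["age", "male_ratio", "updrs3", "mmse", "duration", "scanner_tesla"]


@dataclass
class RunConfig:
    study_table: str
    peak_tables: str
    output_dir: str = "coordmeta_out"
    mask: Optional[str] = None  # NIfTI mask path; overrides grid
    grid: Dict = field(default_factory=lambda: {"kind": "mni152", "voxel_mm": 2.0})
    kernel: KernelSpec = field(default_factory=KernelSpec)
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    metareg_threshold: ThresholdSpec = field(
        default_factory=lambda: ThresholdSpec(p_voxel=0.0005, min_peak_abs_z=1.0, min_extent_voxels=10)
    )
    covariates: List[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    min_covariate_studies: int = 10
    subgroup_tag: str = "PSP-RS-criteria"
    egger_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        for key, typ in (("kernel", KernelSpec), ("threshold", ThresholdSpec), ("metareg_threshold", ThresholdSpec)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    def build_grid(self) -> BrainGrid:
        if self.mask:
            return BrainGrid.from_mask_nifti(self.mask)
        spec = dict(self.grid)
        kind = spec.pop("kind", "mni152")
        if kind == "mni152":
            return BrainGrid.mni152(**spec)
        if kind == "box":
            return BrainGrid.from_box(**spec)
        raise ValueError(f"unknown grid kind {kind!r}")


@dataclass
class RunResult:
    studies: List[StudyRecord]
    study_maps: List[StudyMaps]
    maps: Dict[str, VolumeMap]
    clusters: List[ClusterResult]
    reduction_table: "object"
    increase_table: "object"
    output_dir: Optional[Path] = None


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig):
    studies = load_study_table(config.study_table)
    if len(studies) < 2:
        raise ValueError("at least 2 studies are required")
    peaks = load_peak_tables(config.peak_tables, studies)
    grid = config.build_grid()
    log.info(
        "inputs: %d studies (table sha256=%s), peaks sha256=%s, grid %s @ %.1f mm",
        len(studies),
        _sha256(config.study_table)[:12],
        _sha256(config.peak_tables)[:12] if Path(config.peak_tables).is_file() else "dir",
        "x".join(map(str, grid.shape)),
        grid.voxel_size_mm,
    )
    return studies, peaks, grid


def build_study_maps(studies, peak_tables, grid, kernel: KernelSpec = KernelSpec()) -> List[StudyMaps]:
    out = []
    for rec, peaks in zip(studies, peak_tables):
        eff, var = reconstruct_study_maps(peaks, rec, grid, kernel)
        out.append(StudyMaps(rec.study_id, eff, var))
    return out


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", na_rep="NA")


def _write_maps(maps: Dict[str, VolumeMap], out: Path, prefix: str) -> None:
    for name, vmap in maps.items():
        vmap.to_nifti().to_filename(str(out / f"{prefix}_{name}.nii.gz"))


def _provenance(config: RunConfig, extra: Optional[Dict] = None) -> Dict:
    prov = {
        "coordmeta_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "input_sha256": {
            "study_table": _sha256(config.study_table),
            "peak_tables": _sha256(config.peak_tables)
            if Path(config.peak_tables).is_file()
            else sorted(_sha256(p) for p in Path(config.peak_tables).glob("*.tsv")),
        },
    }
    if extra:
        prov.update(extra)
    return prov


def _run_on(studies, peaks, grid, config: RunConfig, out_sub: Optional[str]) -> RunResult:
    study_maps = build_study_maps(studies, peaks, grid, config.kernel)
    log.info("reconstructed %d study maps", len(study_maps))
    maps = pooled_maps(study_maps)
    clusters = extract_clusters(maps["z"], maps["p"], config.threshold)
    reduction = cluster_table([c for c in clusters if c.sign == "reduction"])
    increase = cluster_table([c for c in clusters if c.sign == "increase"])
    log.info(
        "pooled: %d reduction / %d increase clusters",
        len(reduction),
        len(increase),
    )
    out_dir = None
    if config.output_dir:
        out_dir = Path(config.output_dir) if out_sub is None else Path(config.output_dir) / out_sub
        out_dir.mkdir(parents=True, exist_ok=True)
        _write_maps(maps, out_dir, "pooled")
        _write_tsv(reduction, out_dir / "clusters_reduction.tsv")
        _write_tsv(increase, out_dir / "clusters_increase.tsv")
        summary = _provenance(
            config,
            {
                "n_studies": len(studies),
                "n_reduction_clusters": int(len(reduction)),
                "n_increase_clusters": int(len(increase)),
            },
        )
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8")
    return RunResult(studies, study_maps, maps, clusters, reduction, increase, out_dir)


def run_main(config: RunConfig) -> RunResult:
    """Full main meta-analysis: load → reconstruct → pool → threshold → report."""
    studies, peaks, grid = _load_inputs(config)
    return _run_on(studies, peaks, grid, config, out_sub=None)


def run_subgroup(config: RunConfig, tag: Optional[str] = None) -> RunResult:
    """Identical pipeline restricted to studies carrying a subgroup tag."""
    tag = tag if tag is not None else config.subgroup_tag
    studies, peaks, grid = _load_inputs(config)
    keep = [i for i, s in enumerate(studies) if tag in s.subgroup_tags]
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 studies carry tag {tag!r}")
    log.info("subgroup %r: %d of %d studies", tag, len(keep), len(studies))
    sub_studies = [studies[i] for i in keep]
    sub_peaks = [peaks[i] for i in keep]
    return _run_on(sub_studies, sub_peaks, grid, config, out_sub=f"subgroup_{tag}")


def run_jackknife(config: RunConfig) -> JackknifeResult:
    """Leave-one-out sensitivity analysis of the main clusters."""
    studies, peaks, grid = _load_inputs(config)
    study_maps = build_study_maps(studies, peaks, grid, config.kernel)
    result = jackknife(study_maps, config.threshold)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.table.to_csv(out / "jackknife.tsv", sep="\t")
    return result


def run_heterogeneity(config: RunConfig):
    """Between-study heterogeneity map (Cochran Q) with its own clusters."""
    studies, peaks, grid = _load_inputs(config)
    study_maps = build_study_maps(studies, peaks, grid, config.kernel)
    q_map, p_map = q_heterogeneity_map(study_maps)
    # express excess heterogeneity as an equivalent one-sided normal deviate
    z_equiv = VolumeMap(grid, stats.norm.isf(np.clip(p_map.values, 1e-300, 1.0)), "z")
    clusters = extract_clusters(z_equiv, p_map, config.threshold)
    table = cluster_table(clusters)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_maps({"q": q_map, "q_p": p_map}, out, "heterogeneity")
        _write_tsv(table, out / "heterogeneity_clusters.tsv")
    return q_map, p_map, clusters, table


def run_bias(config: RunConfig) -> List[EggerResult]:
    """Egger's test (and funnel data) at the main-analysis peaks."""
    studies, peaks, grid = _load_inputs(config)
    study_maps = build_study_maps(studies, peaks, grid, config.kernel)
    maps = pooled_maps(study_maps)
    clusters = extract_clusters(maps["z"], maps["p"], config.threshold)
    if not clusters:
        log.info("no clusters; Egger's test not applicable")
        return []
    results = egger_at_peaks(study_maps, clusters)
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        rows = [
            {
                "peak_x": r.peak_mni[0],
                "peak_y": r.peak_mni[1],
                "peak_z_mm": r.peak_mni[2],
                "intercept": r.intercept,
                "intercept_se": r.intercept_se,
                "t": r.t,
                "p": r.p,
                "n_studies": r.n_studies,
                "significant": bool(r.computable and r.p < config.egger_alpha),
            }
            for r in results
        ]
        _write_tsv(pd.DataFrame(rows), out / "egger.tsv")
    return results


def covariate_vector(studies: Sequence[StudyRecord], name: str) -> List[Optional[float]]:
    """Study-level values for a named covariate (None where unreported)."""
    if name not in AVAILABILITY_FIELDS:
        raise ValueError(f"unknown covariate {name!r}; known: {sorted(AVAILABILITY_FIELDS)}")
    attr = AVAILABILITY_FIELDS[name]
    return [getattr(s, attr) for s in studies]


def run_meta_regressions(config: RunConfig) -> Dict[str, Dict]:
    """Voxel-wise meta-regression for each configured covariate.

    Covariates reported by fewer than ``min_covariate_studies`` studies are
    skipped with a logged reason; the rest are analysed at the conservative
    meta-regression threshold.
    """
    studies, peaks, grid = _load_inputs(config)
    study_maps = build_study_maps(studies, peaks, grid, config.kernel)
    results: Dict[str, Dict] = {}
    for name in config.covariates:
        values = covariate_vector(studies, name)
        n_avail = sum(v is not None for v in values)
        if n_avail < config.min_covariate_studies:
            reason = (
                f"covariate {name!r} available in {n_avail} studies, "
                f"fewer than the required {config.min_covariate_studies}"
            )
            log.info("skipping meta-regression: %s", reason)
            results[name] = {"skipped": True, "reason": reason, "n_available": n_avail}
            continue
        maps, n_used = meta_regress_maps(study_maps, values)
        clusters = extract_clusters(maps["z"], maps["p"], config.metareg_threshold)
        results[name] = {
            "skipped": False,
            "n_available": n_avail,
            "n_used": n_used,
            "maps": maps,
            "clusters": clusters,
            "table": cluster_table(clusters),
        }
        if config.output_dir:
            out = Path(config.output_dir) / "metareg"
            out.mkdir(parents=True, exist_ok=True)
            _write_maps(maps, out, name)
            _write_tsv(results[name]["table"], out / f"{name}_clusters.tsv")
    return results
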