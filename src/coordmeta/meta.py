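"""Voxel-wise random-effects pooling, heterogeneity, and meta-regression.

The pooled map is the DerSimonian–Laird random-effects mean of the study
effect-size maps, computed independently at every in-mask voxel.  Weights
are 1/(vᵢ + τ²): sample size enters through the Hedges-g sampling variance
vᵢ, and between-study heterogeneity through the moment estimator τ².
Cochran's Q (with its χ² p-value on k−1 df) maps where studies disagree
more than their sampling variances allow.  Meta-regression fits a weighted
least-squares line of study effects on a study-level covariate with
random-effects weights, voxel-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .effects import StudyMaps
from .grid import BrainGrid, VolumeMap

__all__ = [
    "PooledVoxelResult",
    "MetaRegressionResult",
    "dl_tau2",
    "pool_voxel",
    "pooled_maps",
    "q_heterogeneity_map",
    "meta_regress_voxel",
    "meta_regress_maps",
]

_P_FLOOR = 1e-300  # keep p maps inside (0, 1]


@dataclass(frozen=True)
class PooledVoxelResult:
    pooled_effect: float
    pooled_se: float
    tau2: float
    Q: float
    z: float
    p_two_tailed: float


@dataclass(frozen=True)
class MetaRegressionResult:
    slope: float
    slope_se: float
    z: float
    p: float
    n_studies_used: int
    intercept: float = 0.0


# ---------------------------------------------------------------------------
# array kernels: effects/variances arrays of shape (k, ...) pooled along axis 0

def _dl_arrays(G: np.ndarray, V: np.ndarray):
    k = G.shape[0]
    w = 1.0 / V
    sw = w.sum(axis=0)
    g_fe = (w * G).sum(axis=0) / sw
    Q = (w * (G - g_fe) ** 2).sum(axis=0)
    C = sw - (w**2).sum(axis=0) / sw
    tau2 = np.maximum(0.0, (Q - (k - 1)) / C)
    return Q, C, tau2


def _pool_arrays(G: np.ndarray, V: np.ndarray, tau2: Optional[np.ndarray] = None):
    Q, _, tau2_hat = _dl_arrays(G, V)
    if tau2 is None:
        tau2 = tau2_hat
    ws = 1.0 / (V + tau2)
    sws = ws.sum(axis=0)
    mu = (ws * G).sum(axis=0) / sws
    se = np.sqrt(1.0 / sws)
    z = mu / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    return mu, se, tau2, Q, z, p


def _validate_kv(effects, variances) -> Tuple[np.ndarray, np.ndarray]:
    G = np.asarray(effects, dtype=float)
    V = np.asarray(variances, dtype=float)
    if G.shape != V.shape:
        raise ValueError("effects and variances must have equal shapes")
    if G.shape[0] < 2:
        raise ValueError("pooling requires at least 2 studies")
    if np.any(V <= 0):
        raise ValueError("variances must be strictly positive")
    return G, V


# ---------------------------------------------------------------------------
# scalar interface

def dl_tau2(effects: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian–Laird between-study variance.

    τ² = max(0, (Q − (k−1)) / C) with fixed-effect weights w = 1/v,
    Q = Σw(g − ḡ_FE)² and C = Σw − Σw²/Σw.
    """
    G, V = _validate_kv(effects, variances)
    return float(_dl_arrays(G, V)[2])


def pool_voxel(
    effects: Sequence[float],
    variances: Sequence[float],
    sample_sizes: Optional[Sequence[float]] = None,
    tau2: Optional[float] = None,
) -> PooledVoxelResult:
    """Random-effects pooled estimate at one voxel.

    ``sample_sizes`` is accepted for interface completeness; the sample
    sizes act through the Hedges-g variances, which is how the pooled mean
    is "weighted by the sample size".  Passing ``tau2=0.0`` forces the
    fixed-effect inverse-variance estimator.
    """
    G, V = _validate_kv(effects, variances)
    mu, se, tau2_used, Q, z, p = _pool_arrays(G, V, None if tau2 is None else np.asarray(tau2, dtype=float))
    return PooledVoxelResult(
        pooled_effect=float(mu),
        pooled_se=float(se),
        tau2=float(tau2_used),
        Q=float(Q),
        z=float(z),
        p_two_tailed=float(p),
    )


# ---------------------------------------------------------------------------
# map interface

def _stack(study_maps: Sequence[StudyMaps]) -> Tuple[BrainGrid, np.ndarray, np.ndarray]:
    if len(study_maps) < 2:
        raise ValueError("pooling requires at least 2 studies")
    grid = study_maps[0].effect.grid
    for sm in study_maps:
        if sm.effect.grid != grid or sm.variance.grid != grid:
            raise ValueError("all study maps must share one grid")
    G = np.stack([sm.effect.values for sm in study_maps])
    V = np.stack([sm.variance.values for sm in study_maps])
    return grid, G, V


def pooled_maps(study_maps: Sequence[StudyMaps]) -> Dict[str, VolumeMap]:
    """Voxel-wise random-effects pooling of study maps.

    Returns maps keyed ``effect``, ``se``, ``z``, ``p``, ``q``, ``tau2``,
    all sharing the input grid.
    """
    grid, G, V = _stack(study_maps)
    mu, se, tau2, Q, z, p = _pool_arrays(G, V)
    return {
        "effect": VolumeMap(grid, mu, "effect_size"),
        "se": VolumeMap(grid, se, "effect_size"),
        "z": VolumeMap(grid, z, "z"),
        "p": VolumeMap(grid, p, "p"),
        "q": VolumeMap(grid, Q, "q"),
        "tau2": VolumeMap(grid, tau2, "q"),
    }


def q_heterogeneity_map(study_maps: Sequence[StudyMaps]) -> Tuple[VolumeMap, VolumeMap]:
    """Voxel-wise Cochran Q with χ² p-values on k−1 degrees of freedom."""
    grid, G, V = _stack(study_maps)
    k = G.shape[0]
    Q, _, _ = _dl_arrays(G, V)
    p = np.clip(stats.chi2.sf(Q, k - 1), _P_FLOOR, 1.0)
    return VolumeMap(grid, Q, "q"), VolumeMap(grid, p, "p")


# ---------------------------------------------------------------------------
# meta-regression

def _metareg_arrays(G: np.ndarray, V: np.ndarray, x: np.ndarray):
    """WLS of study effects on (1, x), random-effects weights.

    τ² is the method-of-moments estimate from the residual Q of the
    fixed-effect-weighted fit (k−2 df); final weights are 1/(v + τ²).
    G, V may have trailing voxel axes; x is per-study.
    """
    k = G.shape[0]
    xs = x.reshape((k,) + (1,) * (G.ndim - 1))

    def wls(w):
        S0 = w.sum(axis=0)
        S1 = (w * xs).sum(axis=0)
        S2 = (w * xs**2).sum(axis=0)
        Sy = (w * G).sum(axis=0)
        Sxy = (w * xs * G).sum(axis=0)
        D = S0 * S2 - S1**2
        slope = (S0 * Sxy - S1 * Sy) / D
        intercept = (S2 * Sy - S1 * Sxy) / D
        return slope, intercept, S0, S1, S2, D

    w0 = 1.0 / V
    slope0, inter0, S0, S1, S2, D0 = wls(w0)
    resid = G - inter0 - slope0 * xs
    Qres = (w0 * resid**2).sum(axis=0)
    # tr(A^-1 B) with A = X'WX, B = X'W^2X, closed form for the 2x2 design
    T0 = (w0**2).sum(axis=0)
    T1 = (w0**2 * xs).sum(axis=0)
    T2 = (w0**2 * xs**2).sum(axis=0)
    C = S0 - (S2 * T0 - 2.0 * S1 * T1 + S0 * T2) / D0
    tau2 = np.maximum(0.0, (Qres - (k - 2)) / C)

    w = 1.0 / (V + tau2)
    slope, intercept, S0, S1, S2, D = wls(w)
    slope_se = np.sqrt(S0 / D)
    z = slope / slope_se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR, 1.0)
    return slope, slope_se, z, p, intercept


def meta_regress_voxel(
    effects: Sequence[float],
    variances: Sequence[float],
    covariate: Sequence[float],
) -> MetaRegressionResult:
    """Random-effects meta-regression of effects on one covariate.

    Studies with a missing (None/NaN) covariate are dropped and counted;
    at least 3 usable studies are required and the covariate must vary.
    """
    G = np.asarray(effects, dtype=float)
    V = np.asarray(variances, dtype=float)
    x = np.asarray([np.nan if c is None else c for c in covariate], dtype=float)
    if not (G.shape == V.shape == x.shape):
        raise ValueError("effects, variances and covariate must have equal length")
    keep = np.isfinite(x)
    G, V, x = G[keep], V[keep], x[keep]
    if G.shape[0] < 3:
        raise ValueError("meta-regression requires >= 3 studies with the covariate")
    if np.any(V <= 0):
        raise ValueError("variances must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: singular design")
    slope, se, z, p, intercept = _metareg_arrays(G, V, x)
    return MetaRegressionResult(
        slope=float(slope),
        slope_se=float(se),
        z=float(z),
        p=float(p),
        n_studies_used=int(G.shape[0]),
        intercept=float(intercept),
    )


def meta_regress_maps(
    study_maps: Sequence[StudyMaps],
    covariate: Sequence[float],
) -> Tuple[Dict[str, VolumeMap], int]:
    """Voxel-wise meta-regression; returns maps (slope, z, p) and k used."""
    grid, G, V = _stack(study_maps)
    x = np.asarray([np.nan if c is None else c for c in covariate], dtype=float)
    if x.shape[0] != G.shape[0]:
        raise ValueError("one covariate value per study is required")
    keep = np.isfinite(x)
    if keep.sum() < 3:
        raise ValueError("meta-regression requires >= 3 studies with the covariate")
    G, V, x = G[keep], V[keep], x[keep]
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant: singular design")
    slope, se, z, p, _ = _metareg_arrays(G, V, x)
    maps = {
        "slope": VolumeMap(grid, slope, "effect_size"),
        "z": VolumeMap(grid, z, "z"),
        "p": VolumeMap(grid, p, "p"),
    }
    return maps, int(keep.sum())
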