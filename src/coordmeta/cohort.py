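"""Study-level meta-analysis of group comparability.

Before pooling brain maps, one checks that the patient and control cohorts
are demographically comparable across studies: the standardized mean
difference (Hedges g) of age, and the ratio of male proportions.  Both are
pooled with DerSimonian–Laird random effects over the studies reporting the
required fields.

Orientation conventions (documented, since the source literature often
leaves them implicit): age SMD is patients minus controls; the sex ratio
compares the male proportion of patients to that of controls, so values
above 1 mean the patient groups contain relatively more men.  The ratio is
available as a true relative risk (default) or as an odds ratio
(``measure="or"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .effects import hedges_j
from .meta import dl_tau2
from .study_io import StudyRecord

__all__ = [
    "PooledScalarResult",
    "smd_hedges",
    "log_risk_ratio",
    "log_odds_ratio",
    "pool_scalar",
    "pooled_age_smd",
    "pooled_sex_rr",
    "pooled_sex_ratio",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PooledScalarResult:
    estimate: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    k_studies: int
    model: str = "random"
    tau2: float = 0.0


def smd_hedges(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> Tuple[float, float]:
    """Hedges-g standardized mean difference (group1 − group2) and variance."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    sp = math.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    if sp == 0:
        raise ValueError("pooled SD is zero")
    g = hedges_j(n1, n2) * (m1 - m2) / sp
    v = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return g, v


def _continuity(a: int, n1: int, c: int, n2: int) -> Tuple[float, float, float, float]:
    """0.5 continuity correction applied to all cells when any count is 0."""
    if a == 0 or c == 0 or a == n1 or c == n2:
        log.info("zero cell in 2x2 table; applying 0.5 continuity correction")
        return a + 0.5, n1 + 1.0, c + 0.5, n2 + 1.0
    return float(a), float(n1), float(c), float(n2)


def log_risk_ratio(a: int, n1: int, c: int, n2: int) -> Tuple[float, float]:
    """log RR of event proportion a/n1 vs c/n2 with delta-method variance."""
    a_, n1_, c_, n2_ = _continuity(a, n1, c, n2)
    lrr = math.log((a_ / n1_) / (c_ / n2_))
    v = 1.0 / a_ - 1.0 / n1_ + 1.0 / c_ - 1.0 / n2_
    return lrr, v


def log_odds_ratio(a: int, n1: int, c: int, n2: int) -> Tuple[float, float]:
    """log OR of the same 2x2 table with the Woolf variance."""
    a_, n1_, c_, n2_ = _continuity(a, n1, c, n2)
    b_, d_ = n1_ - a_, n2_ - c_
    lor = math.log((a_ * d_) / (b_ * c_))
    v = 1.0 / a_ + 1.0 / b_ + 1.0 / c_ + 1.0 / d_
    return lor, v


def pool_scalar(
    effects: Sequence[float],
    variances: Sequence[float],
    model: str = "random",
) -> PooledScalarResult:
    """Inverse-variance pooling (DL random effects by default) of scalars."""
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("pooling requires >= 2 studies")
    tau2 = dl_tau2(y, v) if model == "random" else 0.0
    w = 1.0 / (v + tau2)
    est = float((w * y).sum() / w.sum())
    se = float(math.sqrt(1.0 / w.sum()))
    zcrit = stats.norm.ppf(0.975)
    z = est / se
    p = float(np.clip(2.0 * stats.norm.sf(abs(z)), 1e-300, 1.0))
    return PooledScalarResult(
        estimate=est,
        ci_low=est - zcrit * se,
        ci_high=est + zcrit * se,
        z=float(z),
        p=p,
        k_studies=int(y.shape[0]),
        model=model,
        tau2=tau2,
    )


def pooled_age_smd(studies: Sequence[StudyRecord], model: str = "random") -> PooledScalarResult:
    """Pooled age SMD (patients − controls) over studies with complete data."""
    ys, vs = [], []
    for s in studies:
        if None in (s.age_patient_mean, s.age_patient_sd, s.age_control_mean, s.age_control_sd):
            continue
        g, v = smd_hedges(
            s.age_patient_mean, s.age_patient_sd, s.n_patients,
            s.age_control_mean, s.age_control_sd, s.n_controls,
        )
        ys.append(g)
        vs.append(v)
    if len(ys) < 2:
        raise ValueError("fewer than 2 studies with complete age mean/SD")
    return pool_scalar(ys, vs, model=model)


def pooled_sex_ratio(
    studies: Sequence[StudyRecord],
    measure: str = "rr",
    model: str = "random",
) -> PooledScalarResult:
    """Pooled male-proportion ratio, patients vs controls.

    ``measure="rr"`` pools the log relative risk of male sex (delta-method
    variance); ``measure="or"`` pools the log odds ratio (Woolf variance).
    The returned estimate and CI are exponentiated back to the ratio scale;
    z and p refer to the log-scale test of ratio = 1.
    """
    if measure not in ("rr", "or"):
        raise ValueError("measure must be 'rr' or 'or'")
    fn = log_risk_ratio if measure == "rr" else log_odds_ratio
    ys, vs = [], []
    for s in studies:
        if s.male_patients is None or s.male_controls is None:
            continue
        lr, v = fn(s.male_patients, s.n_patients, s.male_controls, s.n_controls)
        ys.append(lr)
        vs.append(v)
    if len(ys) < 2:
        raise ValueError("fewer than 2 studies with male counts for both groups")
    pooled = pool_scalar(ys, vs, model=model)
    return PooledScalarResult(
        estimate=math.exp(pooled.estimate),
        ci_low=math.exp(pooled.ci_low),
        ci_high=math.exp(pooled.ci_high),
        z=pooled.z,
        p=pooled.p,
        k_studies=pooled.k_studies,
        model=pooled.model,
        tau2=pooled.tau2,
    )


def pooled_sex_rr(studies: Sequence[StudyRecord], model: str = "random") -> PooledScalarResult:
    """Pooled relative risk of male sex, patients vs controls."""
    return pooled_sex_ratio(studies, measure="rr", model=model)
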