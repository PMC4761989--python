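"""Volumetric segmentation evaluation and method-agreement statistics.

Overlap metrics follow the Udupa volume-fraction convention, computed on
voxel counts against a reference mask and the retina slab (ILM to BM):

* TPVF = |auto & truth| / |truth|
* FPVF = |auto \\ truth| / (|retina| - |truth|)
* DSC  = 2 |auto & truth| / (|auto| + |truth|)
* PPV  = |auto & truth| / |auto|

Agreement between two volume series is summarized by ordinary least
squares (slope, intercept, R^2), the paired t-test, and Bland-Altman 95%
limits of agreement ``mean(diff) +/- 1.96 * sd(diff)`` (sample sd).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import ContractError, RegionMask

__all__ = [
    "SegmentationMetrics",
    "AgreementStats",
    "compute_metrics",
    "agreement_stats",
    "paired_t_test",
]


@dataclass
class SegmentationMetrics:
    tpvf: float
    fpvf: float
    dsc: float
    ppv: float
    tpvf_defined: bool = True   # False when the truth mask is empty
    ppv_defined: bool = True    # False when the automatic mask is empty

    def as_percent(self) -> dict[str, float]:
        return {
            "tpvf_pct": 100.0 * self.tpvf,
            "fpvf_pct": 100.0 * self.fpvf,
            "dsc_pct": 100.0 * self.dsc,
            "ppv_pct": 100.0 * self.ppv,
        }


def _as_mask(m) -> np.ndarray:
    return m.mask if isinstance(m, RegionMask) else np.asarray(m, bool)


def compute_metrics(auto, truth, retina) -> SegmentationMetrics:
    """Overlap metrics of an automatic mask against truth, on one grid."""
    a, g, r = _as_mask(auto), _as_mask(truth), _as_mask(retina)
    if not (a.shape == g.shape == r.shape):
        raise ContractError("metric masks must share one grid")
    if np.any(g & ~r):
        raise ContractError("truth mask must lie inside the retina mask")
    tp = float((a & g).sum())
    na, ng, nr = float(a.sum()), float(g.sum()), float(r.sum())

    tpvf_defined = ng > 0
    tpvf = tp / ng if tpvf_defined else 0.0
    neg = nr - ng
    fpvf = float((a & ~g).sum()) / neg if neg > 0 else 0.0
    dsc = 2.0 * tp / (na + ng) if (na + ng) > 0 else 1.0
    ppv_defined = na > 0
    ppv = tp / na if ppv_defined else 0.0
    return SegmentationMetrics(tpvf, fpvf, dsc, ppv, tpvf_defined, ppv_defined)


@dataclass
class AgreementStats:
    slope: float
    intercept: float
    r_squared: float
    mean_difference: float      # mean(a - b)
    loa_low: float              # 95% limits of agreement
    loa_high: float


def agreement_stats(volumes_a, volumes_b) -> AgreementStats:
    """OLS regression of b on a plus Bland-Altman limits of agreement."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    if a.shape != b.shape:
        raise ContractError("series must have equal length")
    if a.size < 3:
        raise ContractError("agreement statistics need at least 3 pairs")
    if np.allclose(a, a[0]):
        slope, intercept, r2 = 0.0, float(b.mean()), 1.0 if np.allclose(b, b[0]) else 0.0
    else:
        res = stats.linregress(a, b)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    diff = a - b
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(slope, intercept, r2, md, md - 1.96 * sd, md + 1.96 * sd)


def paired_t_test(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on the differences (df = n - 1).

    Identical series give (0, 1); a zero-variance non-zero difference is
    degenerate and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ContractError("paired t-test needs two equal series of length >= 2")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0
    if diff.std(ddof=1) == 0:
        raise ContractError("degenerate input: constant non-zero difference")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
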