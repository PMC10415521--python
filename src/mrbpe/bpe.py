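"""Voxelwise background parenchymal enhancement (BPE) mapping.

The parenchyma is segmented on the *pre-contrast* fat-suppressed frame of
the DCE series (so no enhancement is presumed), the maximum-enhancement
time point (MTP) is the post-contrast frame with the highest median
parenchymal intensity, and the map is

    BPE (%) = 100 * (I_MTP - I_FTP) / I_FTP

over parenchyma voxels, where FTP is the first (pre-contrast) frame.  The
per-breast BPE distribution is summarised by its median, quartiles,
moment skewness g1 and non-excess kurtosis b2 (normal -> 3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import DceSeries
from .masking import BreastMask
from .fcm import TissueSegmentation, segment_fgt


class ExclusionError(ValueError):
    """Nothing left to analyse after exclusions/guards."""


@dataclass
class DistributionSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    skewness: float
    kurtosis: float
    n: int
    moments_defined: bool = True


@dataclass
class BpeResult:
    """Voxelwise % enhancement over one breast's parenchyma."""

    bpe_map_pct: np.ndarray            # NaN outside the parenchyma
    mtp_index: int
    ftp_index: int
    median_pct: float
    q1_pct: float
    q3_pct: float
    iqr_pct: float
    skewness: float
    kurtosis: float
    n_voxels: int
    laterality: str
    n_dropped_low_denominator: int = 0

    @property
    def values(self) -> np.ndarray:
        return self.bpe_map_pct[np.isfinite(self.bpe_map_pct)]


def summarise_distribution(values) -> DistributionSummary:
    """Quantiles (linear interpolation between order statistics), sample
    skewness g1 = m3 / m2^(3/2) and non-excess kurtosis b2 = m4 / m2^2.

    With zero variance the moments are undefined: they are returned as NaN
    with ``moments_defined`` False, while the quantiles are still valid.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation
    if np.ptp(x) == 0 or np.var(x) == 0:
        warnings.warn("zero variance: skewness/kurtosis undefined",
                      RuntimeWarning, stacklevel=2)
        skew = kurt = float("nan")
        defined = False
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        defined = True
    return DistributionSummary(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(q3 - q1),
        skewness=skew, kurtosis=kurt, n=int(x.size), moments_defined=defined,
    )


def segment_parenchyma_precontrast(
    dce: DceSeries,
    breast_on_dce: BreastMask,
    exclusion: np.ndarray | None = None,
    n_clusters: int = 7,
    assignment="highest:3",
    **fcm_kwargs,
) -> TissueSegmentation:
    """Segment parenchyma on the pre-contrast frame within the breast mask.

    On fat-suppressed pre-contrast T1w images the parenchyma is bright, so
    the default labelling takes the highest-centroid clusters; regions of
    poor fat suppression are removed through ``exclusion`` before fitting.
    """
    mask = np.asarray(breast_on_dce.values, dtype=bool)
    if exclusion is not None:
        excl = np.asarray(exclusion, dtype=bool)
        if excl.shape != mask.shape:
            raise ValueError("exclusion mask geometry differs from the DCE grid")
        mask = mask & ~excl
    if not mask.any():
        raise ExclusionError("breast mask is empty after exclusions")
    pre = dce.frame(dce.pre_contrast_index)
    working = BreastMask(mask, breast_on_dce.affine.copy(),
                         breast_on_dce.laterality,
                         breast_on_dce.erosion_radius_vox)
    return segment_fgt(pre, working, n_clusters=n_clusters,
                       assignment=assignment, **fcm_kwargs)


def select_mtp(dce: DceSeries, parenchyma: TissueSegmentation) -> int:
    """Maximum-enhancement time point: the post-contrast frame with the
    highest median intensity over the parenchyma; ties take the earliest."""
    mask = np.asarray(parenchyma.fgt_mask, dtype=bool)
    if not mask.any():
        raise ExclusionError("parenchyma segmentation is empty")
    if dce.n_post < 1:
        raise ValueError("need at least one post-contrast frame")
    medians = [float(np.median(dce.data[..., t][mask]))
               for t in range(1, dce.n_frames)]
    return 1 + int(np.argmax(medians))  # argmax returns the first maximum


def compute_bpe_map(
    dce: DceSeries,
    parenchyma: TissueSegmentation,
    mtp_index: int,
    denominator_floor_fraction: float = 0.01,
) -> BpeResult:
    """Voxelwise BPE (%) over the parenchyma and its distribution summary.

    Parenchyma voxels whose pre-contrast intensity falls below
    ``denominator_floor_fraction`` times the parenchymal pre-contrast
    median are dropped (the ratio is undefined there) and counted in
    ``n_dropped_low_denominator``.
    """
    if not (dce.pre_contrast_index < mtp_index < dce.n_frames):
        raise ValueError(f"mtp_index {mtp_index} outside the post-contrast range")
    mask = np.asarray(parenchyma.fgt_mask, dtype=bool)
    if not mask.any():
        raise ExclusionError("parenchyma segmentation is empty")
    ftp = dce.pre_contrast_index
    i_ftp = dce.data[..., ftp][mask]
    i_mtp = dce.data[..., mtp_index][mask]
    floor = denominator_floor_fraction * float(np.median(i_ftp))
    keep = i_ftp > floor
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ExclusionError(
            "all parenchyma voxels dropped by the low-denominator guard")
    vals = 100.0 * (i_mtp[keep] - i_ftp[keep]) / i_ftp[keep]
    bpe_map = np.full(mask.shape, np.nan)
    idx = np.zeros(mask.shape, dtype=bool)
    idx[mask] = keep
    bpe_map[idx] = vals
    summ = summarise_distribution(vals)
    return BpeResult(
        bpe_map_pct=bpe_map,
        mtp_index=int(mtp_index),
        ftp_index=int(ftp),
        median_pct=summ.median,
        q1_pct=summ.q1,
        q3_pct=summ.q3,
        iqr_pct=summ.iqr,
        skewness=summ.skewness,
        kurtosis=summ.kurtosis,
        n_voxels=summ.n,
        laterality=parenchyma.laterality,
        n_dropped_low_denominator=n_dropped,
    )
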