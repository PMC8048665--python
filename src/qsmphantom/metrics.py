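"""The seven challenge evaluation metrics for QSM reconstructions.

All RMSE-type scores are multiplied by 100.  The normaliser of every
RMSE-type metric is the L2 norm of the demeaned ground truth over the same
mask, so a reconstruction equal to the truth scores 0 and an all-zero
reconstruction scores 100.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "nrmse",
    "rmse_detrended",
    "deviation_from_linear_slope",
    "calc_streak",
    "calc_moment",
    "evaluate_all",
]


def _demean(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return x[mask] - x[mask].mean()


def nrmse(recon: np.ndarray, truth: np.ndarray, mask: np.ndarray) -> float:
    """Whole-brain RMSE after demeaning within the mask, x100."""
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    if recon.shape != truth.shape:
        raise ValueError("recon and truth are on different grids")
    t = _demean(truth, mask)
    norm = np.linalg.norm(t)
    if norm == 0:
        raise ValueError("ground truth is constant over the mask; nRMSE undefined")
    return 100.0 * float(np.linalg.norm(_demean(recon, mask) - t) / norm)


def rmse_detrended(
    recon: np.ndarray,
    truth: np.ndarray,
    roi_mask: np.ndarray,
    fit_intercept: bool = True,
) -> tuple[float, bool]:
    """Slope-compensated, demeaned, normalised RMSE over an ROI, x100.

    A linear fit of recon against truth over the ROI estimates the
    proportionality slope; the reconstruction is divided by that slope before
    scoring, so scale errors are measured by the linearity metric instead.
    Returns (score, detrended_flag); a non-positive fitted slope is flagged
    and the score computed without detrending.
    """
    roi = roi_mask.astype(bool)
    t = truth[roi]
    r = recon[roi]
    if np.unique(t).size < 2:
        raise ValueError("ROI needs at least two distinct truth values")
    if fit_intercept:
        A = np.stack([t, np.ones_like(t)], axis=1)
        slope = np.linalg.lstsq(A, r, rcond=None)[0][0]
    else:
        slope = float(t @ r / (t @ t))
    detrended = slope > 0
    scaled = recon / slope if detrended else recon
    return nrmse(scaled, truth, roi), bool(detrended)


def deviation_from_linear_slope(
    recon: np.ndarray,
    dgm_masks: Mapping[str, np.ndarray],
    prescribed_means: Mapping[str, float],
    through_origin: bool = True,
) -> float:
    """|slope - 1| of region-mean recon vs prescribed chi over the DGM nuclei."""
    names = sorted(dgm_masks)
    if len(names) < 2:
        raise ValueError("need at least two deep-gray regions")
    y = np.array([recon[dgm_masks[n].astype(bool)].mean() for n in names])
    x = np.array([prescribed_means[n] for n in names])
    if through_origin:
        slope = float(x @ y / (x @ x))
    else:
        slope = float(np.polyfit(x, y, 1)[0])
    return abs(slope - 1.0)


def _box_mask(shape, lo, hi) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    sl = tuple(slice(max(0, a), min(n, b + 1)) for a, b, n in zip(lo, hi, shape))
    m[sl] = True
    return m


def calc_streak(
    recon: np.ndarray,
    truth: np.ndarray,
    calc_mask: np.ndarray,
    brain_mask: np.ndarray | None = None,
    inner_margin: int = 2,
    shell_width: int = 6,
) -> float:
    """SD of (recon - truth) in a hollow box around the calcification.

    The inner boundary is the calcification bounding box expanded by
    ``inner_margin`` voxels; the outer boundary lies ``shell_width`` voxels
    beyond it.  The shell is intersected with the brain mask.
    """
    calc = calc_mask.astype(bool)
    if not calc.any():
        raise ValueError("empty calcification mask")
    _, n_comp = ndimage.label(calc)
    if n_comp != 1:
        raise ValueError(f"calcification mask has {n_comp} connected components, expected 1")
    coords = np.argwhere(calc)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    inner = _box_mask(calc.shape, lo - inner_margin, hi + inner_margin)
    outer = _box_mask(calc.shape, lo - inner_margin - shell_width, hi + inner_margin + shell_width)
    roi = outer & ~inner
    if brain_mask is not None:
        roi &= brain_mask.astype(bool)
    if not roi.any():
        raise ValueError(
            f"empty streak shell: calcification bbox {lo}..{hi} too close to the mask edge"
        )
    return float(np.std(recon[roi] - truth[roi]))


def calc_moment(
    recon: np.ndarray,
    calc_region: np.ndarray,
    voxel_volume: float = 1.0,
) -> float:
    """Volumetric susceptibility moment sum(chi) * voxel volume [ppm*mm^3].

    ``calc_region`` should include the calcification plus a small (2-voxel)
    dilation, making the moment robust to redistribution of the reconstructed
    susceptibility in the no-signal region.
    """
    return float(recon[calc_region.astype(bool)].sum() * voxel_volume)


@dataclass
class MetricReport:
    """The seven challenge scores (RMSE-type values are x100)."""

    nrmse: float
    rmse_detrend_tissue: float
    rmse_detrend_blood: float
    rmse_detrend_dgm: float
    deviation_from_linear_slope: float
    calc_streak: float
    calc_moment: float
    calc_moment_truth: float
    calc_moment_deviation: float
    detrend_flags: dict

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate_all(
    recon: np.ndarray,
    truth: np.ndarray,
    masks: Mapping[str, np.ndarray],
    prescribed_means: Mapping[str, float],
    voxel_volume: float = 1.0,
) -> MetricReport:
    """Compute the full challenge metric suite.

    ``masks`` requires: 'brain', 'tissue' (GM+WM), 'blood' (vein mask,
    dilated by one voxel here), 'calc', and 'dgm_regions' (mapping of the six
    deep-gray nuclei).
    """
    blood_roi = ndimage.binary_dilation(masks["blood"].astype(bool))
    dgm_regions = masks["dgm_regions"]
    dgm_mask = np.zeros(truth.shape, dtype=bool)
    for m in dgm_regions.values():
        dgm_mask |= m.astype(bool)
    calc_region = ndimage.binary_dilation(masks["calc"].astype(bool), iterations=2)
    s_tissue, f_tissue = rmse_detrended(recon, truth, masks["tissue"])
    s_blood, f_blood = rmse_detrended(recon, truth, blood_roi)
    s_dgm, f_dgm = rmse_detrended(recon, truth, dgm_mask)
    m_rec = calc_moment(recon, calc_region, voxel_volume)
    m_tru = calc_moment(truth, calc_region, voxel_volume)
    return MetricReport(
        nrmse=nrmse(recon, truth, masks["brain"]),
        rmse_detrend_tissue=s_tissue,
        rmse_detrend_blood=s_blood,
        rmse_detrend_dgm=s_dgm,
        deviation_from_linear_slope=deviation_from_linear_slope(
            recon, dgm_regions, prescribed_means
        ),
        calc_streak=calc_streak(recon, truth, masks["calc"], masks["brain"]),
        calc_moment=m_rec,
        calc_moment_truth=m_tru,
        calc_moment_deviation=m_rec - m_tru,
        detrend_flags={"tissue": f_tissue, "blood": f_blood, "dgm": f_dgm},
    )
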