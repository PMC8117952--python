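"""Myocardial segmentation refinement on the quantitative MBF map.

The perfusion-image segmentation is the prior: the endocardium is re-grown
from the LV, which on the map is singled out by the blood pool's extremely
high flow; the epicardium is re-detected with the same polar Canny +
harmonic extension + active contour machinery, but with the edge search
constrained to a band around the prior's radius profile (the map background
is patchy, so the prior keeps the search honest).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage import measure
from skimage.morphology import convex_hull_image

from . import geometry
from .core import Contour, MBFMap, MyoSegmentation, VentricleMasks
from .errors import DegenerateContour, EmptyBloodPool, NoEdgeFound
from .perfseg import (PerfSegParams, _repair_endo_inside_epi,
                      detect_epicardial_edge, polar_transform,
                      refine_active_contour)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MapSegParams:
    blood_q: float = 0.5               # threshold = q * median prior-LV flow
    blood_min_flow: float = 3.0        # absolute floor, ml/g/min
    min_pool_px: int = 10
    band_fraction: float = 0.20        # Canny search band around the prior
    clamp_fraction: float = 0.25       # epi radius clamp around the prior
    map_smooth_sigma: float = 1.0
    bright_rim_percentile: float = 97.5
    perf: PerfSegParams = field(default_factory=PerfSegParams)


def grow_endocardium_on_map(mbf_map: MBFMap, lv_prior_mask: np.ndarray,
                            params: MapSegParams = MapSegParams()
                            ) -> tuple[Contour, np.ndarray]:
    """Region-grow the blood pool on the map and trace the endocardium.

    The pool is the connected set of pixels reaching the prior LV with
    flow >= max(blood_min_flow, blood_q * median prior-LV flow); its convex
    hull is the cavity (papillary muscles included) and its boundary the
    endocardial contour.  Returns (contour, grown pool mask).
    """
    lv_prior_mask = np.asarray(lv_prior_mask, dtype=bool)
    if not lv_prior_mask.any():
        raise EmptyBloodPool("empty LV prior")
    v = mbf_map.values
    threshold = max(params.blood_min_flow,
                    params.blood_q * float(np.median(v[lv_prior_mask])))
    above = v >= threshold
    lab = measure.label(above, connectivity=1)
    pool_labels = np.unique(lab[lv_prior_mask & above])
    pool_labels = pool_labels[pool_labels > 0]
    pool = np.isin(lab, pool_labels)
    if pool.sum() < params.min_pool_px:
        raise EmptyBloodPool(
            f"grown blood pool has {int(pool.sum())} px (< "
            f"{params.min_pool_px})")
    hull = convex_hull_image(pool)
    contour = Contour(geometry.resample_closed(
        geometry.mask_boundary_contour(hull),
        n_points=params.perf.snake.n_points))
    return contour, pool


def refine_epicardium_on_map(mbf_map: MBFMap, epi_prior: Contour,
                             lv_center,
                             params: MapSegParams = MapSegParams(),
                             pool_mask: np.ndarray | None = None) -> Contour:
    """Band-restricted polar edge detection + snake on the smoothed map.

    The already-grown blood pool (``pool_mask``) is filled with the median
    myocardial-band flow first, so the overwhelming pool/myocardium edge
    cannot capture the epicardial contour across a thin wall.  Falls back
    to the prior contour with a warning when no edge chain with sufficient
    angular coverage exists inside the band; the final radius profile is
    clamped to +-clamp_fraction of the prior's profile.
    """
    values = mbf_map.values
    if pool_mask is not None and pool_mask.any():
        filled = binary_dilation(pool_mask)
        band_px = _myo_band_mask(values.shape, lv_center, epi_prior,
                                 params.clamp_fraction) & ~filled
        fill_value = (float(np.median(values[band_px])) if band_px.any()
                      else float(np.median(values[~filled])))
        values = np.where(filled, fill_value, values)
    smoothed = gaussian_filter(values, params.map_smooth_sigma)
    nr, nc = smoothed.shape
    prior_pts = epi_prior.points
    prior_theta = geometry.pixel_angles_deg(prior_pts[:, 0], prior_pts[:, 1],
                                            lv_center)
    prior_r = np.hypot(prior_pts[:, 0] - lv_center[0],
                       prior_pts[:, 1] - lv_center[1])
    order = np.argsort(prior_theta)
    prior_theta, prior_r = prior_theta[order], prior_r[order]

    pp = params.perf
    max_radius = max(min(lv_center[0], lv_center[1], nr - 1 - lv_center[0],
                         nc - 1 - lv_center[1]) - 1.0, prior_r.max() + 2.0)
    polar = polar_transform(smoothed, lv_center, pp.n_angles,
                            int(round(pp.radius_bins_per_px * max_radius)),
                            max_radius)
    angles = polar.bin_angles_deg()
    prior_profile = np.interp(angles, prior_theta, prior_r,
                              period=360.0)

    # restrict the edge search to a radial band around the prior: outside
    # the band each angle row is clamp-filled with its band-edge value,
    # which flattens all gradients there without creating artificial ones
    radii = polar.bin_radii_px()
    lo = (1 - params.band_fraction) * prior_profile
    hi = (1 + params.band_fraction) * prior_profile
    idx = np.arange(polar.n_radii)[None, :].repeat(polar.n_angles, axis=0)
    lo_idx = np.searchsorted(radii, lo)[:, None]
    hi_idx = (np.searchsorted(radii, hi) - 1)[:, None]
    idx = np.clip(idx, lo_idx, np.maximum(hi_idx, lo_idx))
    banded = polar
    banded.values = np.take_along_axis(polar.values, idx, axis=1)

    lv_radius_guess = prior_profile.min() / (pp.min_radius_factor * 2.0)
    try:
        edge = detect_epicardial_edge(banded, lv_radius_guess, pp)
    except NoEdgeFound as e:
        log.warning("map epicardial edge not found (%s); keeping prior", e)
        return epi_prior
    init = edge.to_contour(lv_center, pp.snake.n_points)
    refined = refine_active_contour(init, smoothed, pp.snake)

    # clamp the refined radius profile to the prior's neighbourhood
    pts = refined.points
    theta = geometry.pixel_angles_deg(pts[:, 0], pts[:, 1], lv_center)
    r = np.hypot(pts[:, 0] - lv_center[0], pts[:, 1] - lv_center[1])
    ref = np.interp(theta, prior_theta, prior_r, period=360.0)
    r_clamped = np.clip(r, (1 - params.clamp_fraction) * ref,
                        (1 + params.clamp_fraction) * ref)
    rows, cols = geometry.polar_to_cartesian(theta, r_clamped, lv_center)
    return Contour(np.column_stack([rows, cols]))


def _myo_band_mask(shape, lv_center, epi_prior: Contour,
                   clamp_fraction: float) -> np.ndarray:
    """Pixels within the prior epicardial radius (stretched by the clamp)."""
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    pts = epi_prior.points
    mean_r = float(np.hypot(pts[:, 0] - lv_center[0],
                            pts[:, 1] - lv_center[1]).mean())
    rr = np.hypot(rows - lv_center[0], cols - lv_center[1])
    return rr <= (1 + clamp_fraction) * mean_r


def segment_mbf_map(mbf_map: MBFMap, perf_seg: MyoSegmentation,
                    vents: VentricleMasks,
                    params: MapSegParams = MapSegParams()
                    ) -> MyoSegmentation:
    """Final map segmentation from the perfusion-image prior.

    Map-only segmentation (no prior) is unsupported by contract: the prior
    is what makes the patchy map background tractable.
    """
    if perf_seg is None:
        raise ValueError("perfusion-image prior segmentation is required")
    endo, pool = grow_endocardium_on_map(mbf_map, vents.lv_mask, params)
    r, c = np.nonzero(pool)
    lv_center = (float(r.mean()), float(c.mean()))
    epi = refine_epicardium_on_map(mbf_map, perf_seg.epi, lv_center, params,
                                   pool_mask=pool)
    epi = _repair_endo_inside_epi(endo, epi, lv_center)

    shape = mbf_map.values.shape
    myo = epi.mask(shape) & ~pool & ~endo.mask(shape)
    myo = _erode_bright_rim(mbf_map.values, myo, params)
    if not myo.any():
        raise DegenerateContour("map myocardial annulus is empty")
    return MyoSegmentation(endo=endo, epi=epi, myo_mask=myo)


def _erode_bright_rim(values: np.ndarray, myo: np.ndarray,
                      params: MapSegParams) -> np.ndarray:
    """Drop anomalously bright myo pixels touching the epicardial rim.

    Emulates the manual convention of excluding bright epicardial-border
    pixels (RV blood, fat, coronaries): pixels above the 97.5th percentile
    of myocardial flow that lie on the outer rim are eroded (1 px only).
    """
    if not myo.any():
        return myo
    cutoff = np.percentile(values[myo], params.bright_rim_percentile)
    rim = myo & binary_dilation(~myo)  # myo pixels adjacent to non-myo
    drop = rim & (values > cutoff)
    if drop.any():
        log.info("eroded %d anomalously bright rim pixels", int(drop.sum()))
    return myo & ~drop
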