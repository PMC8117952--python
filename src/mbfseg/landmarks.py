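"""Ventricle detection and RV insertion-angle landmark.

The LV and RV blood pools are found on the basal slice from the temporal
standard-deviation image: it is thresholded at several quantile levels, the
levels vote with increasing weight, and the surviving high-vote blobs are
classified by the time-to-peak of their mean enhancement curve — the
earliest-enhancing pool is the RV, the later, central, roughly convex pool
is the LV.  The anterior RV insertion angle is then the RV boundary pixel
with the smallest counterclockwise angle after rotating the RV to the
canonical "left of the LV" pose.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.segmentation import find_boundaries

from . import geometry
from .core import InsertionLandmark, PerfusionSeries, VentricleMasks
from .errors import LVNotFound, MissingRV, RVNotFound


@dataclass(frozen=True)
class LandmarkParams:
    n_levels: int = 5
    base_quantile: float = 0.75         # lowest SD threshold quantile
    top_quantile: float = 0.95          # highest SD threshold quantile
    vote_quantile_cut: float = 0.90     # candidate pixels: SD above this
    min_blob_px: int = 15
    min_lv_solidity: float = 0.80
    sd_floor_fraction: float = 0.02     # of frame dynamic range; kills SD==0


def detect_ventricles(series: PerfusionSeries,
                      params: LandmarkParams = LandmarkParams()
                      ) -> VentricleMasks:
    """Locate LV (and RV when visible) blood pools on a dynamic series.

    Raises :class:`LVNotFound` (fatal, study-abort contract) if no candidate
    blob satisfies the LV criteria; a missing RV raises nothing — the
    returned masks simply have ``rv_mask=None``.
    """
    frames = series.frames
    sd = frames.std(axis=0)
    drange = float(frames.max() - frames.min())
    if sd.max() <= params.sd_floor_fraction * max(drange, 1e-12) or drange == 0:
        raise LVNotFound("no temporal enhancement in the series")

    # multi-level quantile thresholding with weighted voting
    qs = np.linspace(params.base_quantile, params.top_quantile,
                     params.n_levels)
    levels = np.quantile(sd, qs)
    votes = np.zeros_like(sd)
    for w, lev in enumerate(levels, start=1):
        votes += w * (sd >= lev)
    cut = np.quantile(sd, params.vote_quantile_cut)
    candidate = (sd >= cut) & (votes > 0)

    lab = measure.label(candidate, connectivity=2)
    props = measure.regionprops(lab)
    blobs = []
    nr, nc = sd.shape
    img_center = np.array([(nr - 1) / 2.0, (nc - 1) / 2.0])
    for p in props:
        if p.area < params.min_blob_px:
            continue
        mask = lab == p.label
        curve = frames[:, mask].mean(axis=1)
        blobs.append({
            "mask": mask,
            "ttp": int(np.argmax(curve)),
            "curve": curve,
            "solidity": p.solidity,
            "centrality": float(np.linalg.norm(
                np.array(p.centroid) - img_center)),
        })
    if not blobs:
        raise LVNotFound("no candidate blood-pool blob survived voting")

    convex = [b for b in blobs if b["solidity"] >= params.min_lv_solidity]
    if not convex:
        raise LVNotFound("no roughly convex blood-pool candidate")
    # LV: the latest-enhancing convex blob, ties broken by centrality.
    lv = sorted(convex, key=lambda b: (-b["ttp"], b["centrality"]))[0]
    earlier = [b for b in blobs
               if b["ttp"] < lv["ttp"] and b["mask"] is not lv["mask"]]
    rv = min(earlier, key=lambda b: b["ttp"]) if earlier else None

    lv_mask = lv["mask"]
    r, c = np.nonzero(lv_mask)
    return VentricleMasks(
        lv_mask=lv_mask,
        rv_mask=rv["mask"] if rv is not None else None,
        lv_center=(float(r.mean()), float(c.mean())),
        peak_lv_frame=lv["ttp"],
    )


def detect_rv_insertion(vents: VentricleMasks) -> InsertionLandmark:
    """Anterior RV insertion angle from the RV boundary about the LV centre.

    The RV boundary angles are rotated so their circular mean maps to 180
    deg (RV to the left of the LV); the boundary pixel with the smallest
    rotated counterclockwise angle from 0 deg is the anterior junction, and
    its angle is reported in the original frame.  Boundary pixels within
    0.5 deg of the minimum are tie-broken by smallest radius (the junction
    touches the LV wall).
    """
    if vents.rv_mask is None:
        raise MissingRV("RV mask required for insertion detection")
    boundary = find_boundaries(vents.rv_mask, mode="inner")
    rows, cols = np.nonzero(boundary)
    if len(rows) == 0:
        raise RVNotFound("RV boundary is empty")
    theta = geometry.pixel_angles_deg(rows, cols, vents.lv_center)
    radius = np.hypot(rows - vents.lv_center[0], cols - vents.lv_center[1])

    rad = np.radians(theta)
    mass_center = np.degrees(np.arctan2(np.sin(rad).mean(),
                                        np.cos(rad).mean())) % 360.0
    rotation = 180.0 - mass_center
    rotated = np.mod(theta + rotation, 360.0)
    best = rotated.min()
    tie = rotated <= best + 0.5
    idx = np.nonzero(tie)[0][np.argmin(radius[tie])]
    angle = geometry.normalize_angle_deg(rotated[idx] - rotation)
    return InsertionLandmark(lv_center=vents.lv_center,
                             rv_insertion_angle_deg=angle)


def angle_difference(a_deg: float, b_deg: float) -> float:
    """Absolute angular difference on the circle, in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)
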