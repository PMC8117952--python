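"""End-to-end study processing: landmarks -> perfusion segmentation ->
MBF-map segmentation -> sectorization -> sector-wise MBF / MPR.

The basal rest series anchors landmark detection; the same insertion angle
is reused on every slice with the origin re-centred on each slice's LV.
Slices run base -> mid -> apex, ventricles propagated by temporal
cross-correlation.  A study fails if and only if the LV cannot be located
on some slice (or the basal RV needed for the insertion landmark is
missing); any other per-slice abort is recorded in the status and the
remaining slices continue.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .core import (Condition, InsertionLandmark, MBFMap, MyoSegmentation,
                   PerfusionSeries, SectorReport, SliceLocation)
from .errors import LVNotFound, MissingRV, PipelineAbort
from .landmarks import detect_rv_insertion, detect_ventricles
from .mapseg import segment_mbf_map
from .perfseg import propagate_slice, segment_perfusion_slice
from .sectors import (assign_sectors, build_sector_model, compute_mpr,
                      sector_means)

log = logging.getLogger(__name__)

SLICE_ORDER = (SliceLocation.BASE, SliceLocation.MID, SliceLocation.APEX)


@dataclass
class StudyResult:
    success: bool
    failure_cause: Optional[str] = None
    landmark: Optional[InsertionLandmark] = None
    perf_segmentations: dict = field(default_factory=dict)
    map_segmentations: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)     # (loc, cond) -> SectorReport
    mpr: dict = field(default_factory=dict)         # loc -> per-sector array
    status: dict = field(default_factory=dict)      # (loc, cond) -> str


def process_study(rest_series: dict, stress_series: dict,
                  rest_maps: dict, stress_maps: dict,
                  config: PipelineConfig = PipelineConfig()) -> StudyResult:
    """Run the full pipeline on one study.

    ``rest_series``/``stress_series`` map SliceLocation -> PerfusionSeries
    (base required); the map dicts likewise to MBFMap.
    """
    result = StudyResult(success=True)
    series_by_cond = {Condition.REST: rest_series,
                      Condition.STRESS: stress_series}
    maps_by_cond = {Condition.REST: rest_maps,
                    Condition.STRESS: stress_maps}

    # landmark from the basal rest series
    try:
        base_vents_rest = detect_ventricles(rest_series[SliceLocation.BASE],
                                            config.landmarks)
        landmark = detect_rv_insertion(base_vents_rest)
    except (LVNotFound, MissingRV) as e:
        result.success = False
        result.failure_cause = f"{type(e).__name__}(base): {e}"
        result.status[(SliceLocation.BASE, Condition.REST)] = str(e)
        return result
    result.landmark = landmark

    for cond in (Condition.REST, Condition.STRESS):
        series = series_by_cond[cond]
        maps = maps_by_cond[cond]
        if cond == Condition.REST:
            vents = base_vents_rest
        else:
            try:
                vents = detect_ventricles(series[SliceLocation.BASE],
                                          config.landmarks)
            except LVNotFound as e:
                result.success = False
                result.failure_cause = f"LVNotFound(base/{cond.value}): {e}"
                result.status[(SliceLocation.BASE, cond)] = str(e)
                return result

        prev_vents, prev_series = None, None
        for loc in SLICE_ORDER:
            if loc not in series:
                result.status[(loc, cond)] = "slice absent"
                continue
            s = series[loc]
            try:
                if prev_vents is not None:
                    epi_r = _epi_radius(result.perf_segmentations.get(
                        (prev_series.slice_location, cond)))
                    vents = propagate_slice(prev_vents, prev_series, s,
                                            config.perfseg,
                                            prev_epi_radius_px=epi_r)
                note = "" if vents.rv_mask is not None else "; RV absent"
                perf_seg = segment_perfusion_slice(s, vents, config.perfseg)
                result.perf_segmentations[(loc, cond)] = perf_seg
                map_seg = segment_mbf_map(maps[loc], perf_seg, vents,
                                          config.mapseg)
                result.map_segmentations[(loc, cond)] = map_seg
                result.status[(loc, cond)] = "ok" + note
            except LVNotFound as e:
                result.success = False
                result.failure_cause = (
                    f"LVNotFound({loc.value}/{cond.value}): {e}")
                result.status[(loc, cond)] = f"LVNotFound: {e}"
                return result
            except PipelineAbort as e:
                result.status[(loc, cond)] = f"{type(e).__name__}: {e}"
                log.warning("slice %s/%s aborted: %s", loc.value, cond.value,
                            e)
                prev_vents, prev_series = vents, s
                continue
            prev_vents, prev_series = vents, s

            # sectorize on the final map segmentation
            seg = result.map_segmentations[(loc, cond)]
            center = _mask_centroid(seg.endo.mask(maps[loc].values.shape))
            model = build_sector_model(center,
                                       landmark.rv_insertion_angle_deg,
                                       config.sectors.n_sectors,
                                       config.sectors.direction)
            labels = assign_sectors(seg.myo_mask, model)
            result.reports[(loc, cond)] = sector_means(
                maps[loc], labels, config.sectors.n_sectors)

    for loc in SLICE_ORDER:
        stress_rep = result.reports.get((loc, Condition.STRESS))
        rest_rep = result.reports.get((loc, Condition.REST))
        if stress_rep is not None and rest_rep is not None:
            result.mpr[loc] = compute_mpr(stress_rep, rest_rep)
    return result


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    r, c = np.nonzero(mask)
    return (float(r.mean()), float(c.mean()))


def _epi_radius(seg: Optional[MyoSegmentation]) -> Optional[float]:
    if seg is None:
        return None
    pts = seg.epi.points
    center = pts.mean(axis=0)
    return float(np.hypot(pts[:, 0] - center[0],
                          pts[:, 1] - center[1]).mean())
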