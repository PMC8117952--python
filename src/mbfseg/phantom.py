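"""Synthetic first-pass perfusion phantom with full ground truth.

The phantom emulates a motion-free short-axis perfusion study at three slice
locations: a circular LV blood pool inside an annular myocardium, a
crescent-shaped RV pool hugging the epicardium, gamma-variate contrast
enhancement (RV enhances first, then LV, then myocardium; blood pools
enhance much more strongly than muscle), and matching MBF pixel maps that
are piecewise constant per tissue before noise.  Background tissue gets a
slow, early, low-amplitude enhancement so that after per-pixel temporal
normalization the pre-contrast baseline image shows dark myocardium against
brighter background — the contrast the epicardial edge detector exploits.

Optional regional perfusion defects scale the flow of selected sectors; the
defect lives in the maps (flow), not in the dynamic series.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (Condition, Contour, MBFMap, PerfusionSeries, SliceLocation)
from .errors import DomainError, GeometryError
from . import geometry

SLICES = (SliceLocation.BASE, SliceLocation.MID, SliceLocation.APEX)
CONDITIONS = (Condition.REST, Condition.STRESS)


def gamma_variate(t, t0: float, alpha: float, beta: float,
                  amplitude: float) -> np.ndarray:
    """Normalized gamma-variate bolus curve.

    Zero for t <= t0; peaks at exactly ``amplitude`` at t = t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0 or amplitude <= 0:
        raise DomainError("gamma-variate shape parameters must be positive")
    t = np.asarray(t, dtype=float)
    tp = alpha * beta
    x = np.clip((t - t0) / tp, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = amplitude * np.power(x, alpha) * np.exp(alpha * (1.0 - x))
    return np.where(t <= t0, 0.0, y)


@dataclass(frozen=True)
class EnhancementCurve:
    t0_s: float
    alpha: float
    beta: float
    amplitude: float

    def __call__(self, t):
        return gamma_variate(t, self.t0_s, self.alpha, self.beta,
                             self.amplitude)

    @property
    def peak_time_s(self) -> float:
        return self.t0_s + self.alpha * self.beta


@dataclass(frozen=True)
class SliceGeometry:
    lv_center: tuple[float, float]
    lv_radius_px: float
    myo_outer_radius_px: float
    rv_present: bool = True


@dataclass(frozen=True)
class DefectSpec:
    """Flow reduction in selected sectors of a 6-sector model anchored at
    the true insertion angle (ccw)."""
    sectors: tuple[int, ...]            # 1-based sector indices
    fraction: float                     # flow scaled by (1 - fraction)
    conditions: tuple[Condition, ...] = CONDITIONS
    n_sectors: int = 6


@dataclass(frozen=True)
class PhantomConfig:
    image_size: tuple[int, int] = (64, 64)
    geometry: dict = field(default_factory=lambda: {
        SliceLocation.BASE: SliceGeometry((32.0, 32.0), 10.0, 16.0, True),
        SliceLocation.MID: SliceGeometry((32.0, 32.0), 9.0, 14.5, True),
        SliceLocation.APEX: SliceGeometry((32.0, 32.0), 7.0, 11.5, False),
    })
    rv_crescent_width_deg: float = 80.0
    rv_crescent_thickness_px: float = 6.0
    true_insertion_angle_deg: float = 120.0
    # enhancement curves (seconds; amplitudes in signal units over baseline)
    rv_curve: EnhancementCurve = EnhancementCurve(3.0, 3.0, 1.2, 3.0)
    lv_curve: EnhancementCurve = EnhancementCurve(6.0, 3.0, 1.4, 3.0)
    myo_curve: EnhancementCurve = EnhancementCurve(10.0, 3.0, 2.5, 1.0)
    background_curve: EnhancementCurve = EnhancementCurve(1.0, 1.2, 25.0, 0.15)
    baseline_intensity: float = 1.0
    n_frames: int = 60
    frame_interval_s: float = 1.0
    noise_sd: float = 0.1               # series noise (SNR 10 vs myo peak)
    # maps (ml/g/min)
    rest_mbf: float = 1.0
    stress_mbf: float = 3.0
    pool_flow_factor: float = 6.0       # pool flow = factor x myocardial flow
    background_flow: float = 0.3
    background_patchiness: float = 0.15
    mbf_noise_sd: float = 0.125         # map noise (SNR 8 vs rest MBF)
    defect: Optional[DefectSpec] = None
    # slices whose LV blood pool does not enhance (renders as background):
    # models the "extremely small/invisible LV blood pool" failure mode
    suppress_lv_slices: tuple = ()
    pixel_spacing_mm: tuple[float, float] = (2.0, 2.0)
    rng_seed: int = 0

    def validate(self) -> None:
        nr, nc = self.image_size
        for loc, g in self.geometry.items():
            if g.lv_radius_px >= g.myo_outer_radius_px:
                raise GeometryError(f"{loc}: LV radius must be < outer radius")
            outer = g.myo_outer_radius_px + (
                self.rv_crescent_thickness_px if g.rv_present else 0.0)
            r, c = g.lv_center
            if (r - outer < 0 or c - outer < 0
                    or r + outer > nr - 1 or c + outer > nc - 1):
                raise GeometryError(f"{loc}: geometry does not fit the image")
        if self.defect is not None and not 0 <= self.defect.fraction < 1:
            raise GeometryError("defect fraction must lie in [0, 1)")
        peaks = [self.rv_curve.peak_time_s, self.lv_curve.peak_time_s,
                 self.myo_curve.peak_time_s]
        if not peaks[0] < peaks[1] < peaks[2]:
            raise GeometryError("enhancement must peak RV < LV < myocardium")


@dataclass
class SliceTruth:
    lv_mask: np.ndarray
    rv_mask: Optional[np.ndarray]
    myo_mask: np.ndarray
    endo: Contour
    epi: Contour
    lv_center: tuple[float, float]


@dataclass
class PhantomStudy:
    config: PhantomConfig
    series: dict                        # (SliceLocation, Condition) -> PerfusionSeries
    maps: dict                          # (SliceLocation, Condition) -> MBFMap
    truth: dict                         # SliceLocation -> SliceTruth
    noiseless_maps: dict                # (SliceLocation, Condition) -> 2D array
    true_insertion_angle_deg: float = 0.0


def _slice_masks(config: PhantomConfig, loc: SliceLocation):
    nr, nc = config.image_size
    g = config.geometry[loc]
    rows, cols = np.mgrid[0:nr, 0:nc]
    rr = np.hypot(rows - g.lv_center[0], cols - g.lv_center[1])
    lv = rr <= g.lv_radius_px
    myo = (rr > g.lv_radius_px) & (rr <= g.myo_outer_radius_px)
    rv = None
    if g.rv_present:
        theta = geometry.pixel_angles_deg(rows, cols, g.lv_center)
        rel = np.mod(theta - config.true_insertion_angle_deg, 360.0)
        band = ((rr > g.myo_outer_radius_px)
                & (rr <= g.myo_outer_radius_px
                   + config.rv_crescent_thickness_px))
        rv = band & (rel < config.rv_crescent_width_deg)
        if not rv.any():
            raise GeometryError(f"{loc}: RV crescent rendered empty")
    return lv, myo, rv, rr


def _defect_mask(config: PhantomConfig, loc: SliceLocation,
                 myo_mask: np.ndarray, condition: Condition):
    d = config.defect
    if d is None or condition not in d.conditions:
        return np.zeros_like(myo_mask)
    nr, nc = config.image_size
    rows, cols = np.nonzero(myo_mask)
    theta = geometry.pixel_angles_deg(rows, cols,
                                      config.geometry[loc].lv_center)
    rel = np.mod(theta - config.true_insertion_angle_deg, 360.0)
    sector = np.floor(rel / (360.0 / d.n_sectors)).astype(int) + 1
    hit = np.isin(sector, d.sectors)
    mask = np.zeros_like(myo_mask)
    mask[rows[hit], cols[hit]] = True
    return mask


def generate_phantom(config: Optional[PhantomConfig] = None) -> PhantomStudy:
    """Render the full study: 6 dynamic series, 6 MBF maps, and ground truth.

    Same config (including seed) gives a bit-identical study.
    """
    config = config or PhantomConfig()
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    t = np.arange(config.n_frames) * config.frame_interval_s

    truth, series, maps, noiseless = {}, {}, {}, {}
    for loc in SLICES:
        g = config.geometry[loc]
        lv, myo, rv, _ = _slice_masks(config, loc)
        endo = geometry.disk_contour(g.lv_center, g.lv_radius_px, 180)
        epi = geometry.disk_contour(g.lv_center, g.myo_outer_radius_px, 180)
        truth[loc] = SliceTruth(lv, rv, myo, Contour(endo), Contour(epi),
                                g.lv_center)

        # dynamic series: tissue-wise gamma-variate on a flat baseline
        clean = np.full((config.n_frames,) + config.image_size,
                        config.baseline_intensity)
        clean += config.background_curve(t)[:, None, None]
        tissues = [(myo, config.myo_curve), (rv, config.rv_curve)]
        if loc not in config.suppress_lv_slices:
            tissues.append((lv, config.lv_curve))
        for mask, curve in tissues:
            if mask is not None:
                delta = (curve(t) - config.background_curve(t))[:, None, None]
                clean = np.where(mask[None], clean + delta, clean)

        # maps: per-region flow constants + patchy background
        patch = gaussian_filter(
            rng.standard_normal(config.image_size), 3.0)
        patch = (patch / max(np.abs(patch).max(), 1e-12)
                 * config.background_patchiness)
        for cond in CONDITIONS:
            noise = (rng.standard_normal(clean.shape) * config.noise_sd
                     if config.noise_sd > 0 else 0.0)
            series[(loc, cond)] = PerfusionSeries(
                loc, clean + noise, config.pixel_spacing_mm, t, cond)

            myo_flow = (config.rest_mbf if cond == Condition.REST
                        else config.stress_mbf)
            pool_flow = config.pool_flow_factor * myo_flow
            flow = np.clip(config.background_flow + patch, 0.0, None)
            flow = np.where(myo, myo_flow, flow)
            dmask = _defect_mask(config, loc, myo, cond)
            if dmask.any():
                flow = np.where(dmask, myo_flow * (1 - config.defect.fraction),
                                flow)
            flow = np.where(lv, pool_flow, flow)
            if rv is not None:
                flow = np.where(rv, pool_flow, flow)
            noiseless[(loc, cond)] = flow
            mnoise = (rng.standard_normal(flow.shape) * config.mbf_noise_sd
                      if config.mbf_noise_sd > 0 else 0.0)
            maps[(loc, cond)] = MBFMap(np.clip(flow + mnoise, 0.0, None),
                                       config.pixel_spacing_mm, loc, cond)

    study = PhantomStudy(config, series, maps, truth, noiseless,
                         config.true_insertion_angle_deg)
    _assert_temporal_ordering(study)
    return study


def _assert_temporal_ordering(study: PhantomStudy) -> None:
    """RV mean curve peaks strictly before LV, which peaks before myo."""
    loc = SliceLocation.BASE
    if loc in study.config.suppress_lv_slices:
        return
    s = study.series[(loc, Condition.REST)]
    tr = study.truth[loc]
    lv_peak = int(np.argmax(s.frames[:, tr.lv_mask].mean(axis=1)))
    myo_peak = int(np.argmax(s.frames[:, tr.myo_mask].mean(axis=1)))
    if tr.rv_mask is not None:
        rv_peak = int(np.argmax(s.frames[:, tr.rv_mask].mean(axis=1)))
        if not rv_peak < lv_peak:
            raise GeometryError("RV curve must peak before LV curve")
    if not lv_peak < myo_peak:
        raise GeometryError("LV curve must peak before myocardial curve")


def true_sector_means(study: PhantomStudy, n_sectors: int = 6) -> dict:
    """Ground-truth sector means from the truth masks and noiseless maps.

    Returns {(slice_location, condition): array of n_sectors means}.
    """
    from .sectors import assign_sectors, build_sector_model

    out = {}
    for loc in SLICES:
        tr = study.truth[loc]
        model = build_sector_model(tr.lv_center,
                                   study.true_insertion_angle_deg, n_sectors)
        labels = assign_sectors(tr.myo_mask, model)
        for cond in CONDITIONS:
            flow = study.noiseless_maps[(loc, cond)]
            means = np.full(n_sectors, np.nan)
            for s in range(1, n_sectors + 1):
                sel = labels == s
                if sel.any():
                    means[s - 1] = flow[sel].mean()
            out[(loc, cond)] = means
    return out
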