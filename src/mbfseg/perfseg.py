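"""Myocardial segmentation from the dynamic perfusion image series.

Per slice the chain is: region-grow the LV blood pool at its peak-intensity
frame and take the convex hull (papillary muscles end up inside, so the
enhanced LV boundary is the endocardium); temporally normalize every pixel
to its own intensity range; average the pre-contrast frames into a baseline
image (myocardium/LV dark, background bright); transform it to the polar
domain about the LV, run Canny, keep the longest edge chain and extend it
around the full circle with a periodic harmonic fit; refine that epicardial
estimate with an active contour on the first principal component of the
washout frames; subsequent slices re-locate the ventricles by temporal
cross-correlation against the previous slice's blood-pool curves.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage import measure
from skimage.feature import canny
from skimage.morphology import convex_hull_image

from . import geometry
from .core import Contour, MyoSegmentation, PerfusionSeries, VentricleMasks
from .errors import (ArrivalNotFound, DegenerateContour, GrowthOverflow,
                     InsufficientFrames, LVNotFound, NoEdgeFound, RVNotFound)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SnakeParams:
    n_points: int = 120
    alpha: float = 0.05        # elasticity weight
    beta: float = 2.0          # bending weight
    w_edge: float = 1.0        # image (edge energy) weight
    step: float = 0.5          # implicit Euler time step
    sigma: float = 2.0         # Gaussian pre-smoothing of the image
    max_iter: int = 250
    tol: float = 0.05          # mean point displacement convergence (px)
    min_area_fraction: float = 0.25


@dataclass(frozen=True)
class PerfSegParams:
    # region growing
    grow_k: float = 3.0
    grow_sd_floor_fraction: float = 0.02
    grow_max_area_fraction: float = 0.40
    # polar / Canny edge detection
    n_angles: int = 360
    radius_bins_per_px: float = 2.0
    canny_sigma: float = 2.0
    canny_high_fraction: float = 0.7
    canny_low_fraction: float = 0.3
    gradient_percentile: float = 95.0
    angular_smooth_bins: float = 8.0   # pre-smoothing along the angle axis
    min_chain_deg: float = 60.0
    min_chain_contrast: float = 3.0    # chain mean gradient vs image median
    min_radius_factor: float = 1.2     # discard chains inside 1.2 x LV radius
    max_chain_radius_iqr_px: float = 6.0  # radially incoherent chains are noise
    chain_score_fraction: float = 0.5  # near-top chains compete; innermost wins
    fit_harmonics: int = 6
    outlier_px: float = 3.0            # detected radii this far from the fit
    #                                    are treated as extended
    # baseline image
    n_baseline_frames: int = 3
    arrival_n_sd: float = 3.0
    # slice propagation
    min_seed_correlation: float = 0.7
    search_radius_factor: float = 2.5
    snake: SnakeParams = field(default_factory=SnakeParams)


# --------------------------------------------------------------------------
# temporal normalization and the baseline image
# --------------------------------------------------------------------------

def temporal_normalize(series: PerfusionSeries) -> PerfusionSeries:
    """Scale every pixel's time curve to [0, 1] over its own range.

    This highlights relative enhancement timing instead of absolute signal,
    amplifying the small enhancement of hypoperfused tissue to the same
    level as healthy myocardium.  Constant pixels map to 0.
    """
    frames = series.frames
    vmin = frames.min(axis=0, keepdims=True)
    vmax = frames.max(axis=0, keepdims=True)
    eps = 1e-6 * max(float(frames.max() - frames.min()), 1e-30)
    norm = (frames - vmin) / (vmax - vmin + eps)
    return PerfusionSeries(series.slice_location, norm,
                           series.pixel_spacing_mm, series.frame_times_s,
                           series.condition)


def baseline_image(normalized: PerfusionSeries, lv_curve: np.ndarray,
                   params: PerfSegParams = PerfSegParams()) -> np.ndarray:
    """Mean of the normalized frames acquired before contrast arrival.

    Arrival is the first frame whose LV mean exceeds the pre-contrast mean
    by ``arrival_n_sd`` baseline standard deviations.
    """
    lv_curve = np.asarray(lv_curve, dtype=float)
    nb = params.n_baseline_frames
    base_mean = lv_curve[:nb].mean()
    base_sd = lv_curve[:nb].std()
    threshold = base_mean + params.arrival_n_sd * base_sd
    above = np.nonzero(lv_curve > threshold)[0]
    above = above[above >= 1]
    if len(above) == 0:
        raise ArrivalNotFound("LV curve never exceeds the baseline threshold")
    arrival = int(above[0])
    return normalized.frames[:arrival].mean(axis=0)


# --------------------------------------------------------------------------
# polar domain
# --------------------------------------------------------------------------

@dataclass
class PolarImage:
    """Image resampled on an (angle_bin, radius_bin) grid about a centre.

    Angle bin i covers [i*360/n_angles, (i+1)*360/n_angles) in the package
    angle convention; samples are taken at bin centres.
    """
    values: np.ndarray
    center: tuple[float, float]
    n_angles: int
    n_radii: int
    max_radius_px: float

    @property
    def angle_bin_deg(self) -> float:
        return 360.0 / self.n_angles

    @property
    def radius_bin_px(self) -> float:
        return self.max_radius_px / self.n_radii

    def bin_angles_deg(self) -> np.ndarray:
        return (np.arange(self.n_angles) + 0.5) * self.angle_bin_deg

    def bin_radii_px(self) -> np.ndarray:
        return (np.arange(self.n_radii) + 0.5) * self.radius_bin_px


def polar_transform(image: np.ndarray, center, n_angles: int = 360,
                    n_radii: int | None = None,
                    max_radius: float | None = None) -> PolarImage:
    """Bilinear resampling of a Cartesian image onto a polar grid."""
    nr, nc = image.shape
    if max_radius is None:
        max_radius = min(center[0], center[1],
                         nr - 1 - center[0], nc - 1 - center[1])
    if n_radii is None:
        n_radii = max(int(round(2 * max_radius)), 8)
    theta = (np.arange(n_angles) + 0.5) * (360.0 / n_angles)
    radii = (np.arange(n_radii) + 0.5) * (max_radius / n_radii)
    tt, rr = np.meshgrid(theta, radii, indexing="ij")
    rows, cols = geometry.polar_to_cartesian(tt, rr, center)
    values = map_coordinates(image.astype(float), [rows, cols],
                             order=1, mode="nearest")
    return PolarImage(values, tuple(center), n_angles, n_radii,
                      float(max_radius))


def polar_inverse(polar: PolarImage, shape=None) -> np.ndarray:
    """Resample a polar image back onto the Cartesian grid (0 outside)."""
    if shape is None:
        n = int(np.ceil(2 * polar.max_radius_px)) + 1
        shape = (n, n)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    o_r, o_c = polar.center
    r = np.hypot(rows - o_r, cols - o_c)
    theta = geometry.pixel_angles_deg(rows, cols, (o_r, o_c))

    ai = theta / polar.angle_bin_deg - 0.5
    ri = r / polar.radius_bin_px - 0.5
    a0 = np.floor(ai).astype(int)
    fa = ai - a0
    a0 = np.mod(a0, polar.n_angles)
    a1 = np.mod(a0 + 1, polar.n_angles)
    r0 = np.clip(np.floor(ri).astype(int), 0, polar.n_radii - 1)
    fr = np.clip(ri - np.floor(ri), 0.0, 1.0)
    r1 = np.clip(r0 + 1, 0, polar.n_radii - 1)
    v = polar.values
    out = ((1 - fa) * (1 - fr) * v[a0, r0] + fa * (1 - fr) * v[a1, r0]
           + (1 - fa) * fr * v[a0, r1] + fa * fr * v[a1, r1])
    out[r > polar.max_radius_px] = 0.0
    return out


# --------------------------------------------------------------------------
# LV region growing
# --------------------------------------------------------------------------

def grow_lv(series: PerfusionSeries, seed_mask: np.ndarray, frame_idx: int,
            params: PerfSegParams = PerfSegParams(),
            apply_hull: bool = True) -> np.ndarray:
    """Region-grow the LV cavity on one frame and convex-hull the result.

    4-connected growth; a pixel joins when |v - mean| <= k * sd with the
    region mean/SD updated incrementally (SD floored at a small fraction of
    the frame's dynamic range so a uniform seed is well-defined).  The hull
    folds papillary muscles into the cavity.
    """
    from skimage.restoration import estimate_sigma

    img = series.frames[frame_idx]
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if not seed_mask.any():
        raise LVNotFound("empty LV seed mask")
    nr, nc = img.shape
    # SD floor: a fraction of the dynamic range (uniform seeds) or the
    # frame's estimated noise level (tiny seeds anchor on one noisy draw)
    noise_sd = float(estimate_sigma(img))
    floor = max(params.grow_sd_floor_fraction * float(img.max() - img.min()),
                noise_sd if np.isfinite(noise_sd) else 0.0)
    max_px = int(params.grow_max_area_fraction * img.size)

    region = seed_mask.copy()
    n = int(region.sum())
    vals = img[region]
    s1, s2 = float(vals.sum()), float((vals ** 2).sum())

    frontier = deque()
    queued = region.copy()
    rows, cols = np.nonzero(region)
    for r, c in zip(rows, cols):
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not queued[rr, cc]:
                queued[rr, cc] = True
                frontier.append((rr, cc))

    while frontier:
        r, c = frontier.popleft()
        mean = s1 / n
        var = max(s2 / n - mean * mean, 0.0)
        sd = max(np.sqrt(var), floor)
        v = img[r, c]
        if abs(v - mean) <= params.grow_k * sd:
            region[r, c] = True
            n += 1
            s1 += v
            s2 += v * v
            if n > max_px:
                raise GrowthOverflow(
                    f"LV growth exceeded {params.grow_max_area_fraction:.0%}"
                    " of the image")
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not queued[rr, cc]:
                    queued[rr, cc] = True
                    frontier.append((rr, cc))
    return convex_hull_image(region) if apply_hull else region


# --------------------------------------------------------------------------
# polar Canny epicardial edge
# --------------------------------------------------------------------------

@dataclass
class RadialEdge:
    """Full-circle epicardial radius profile in the polar domain."""
    radius_px: np.ndarray              # length n_angles
    detected: np.ndarray               # bool; False where harmonics filled in
    angles_deg: np.ndarray

    def to_contour(self, center, n_points: int = 120) -> Contour:
        rows, cols = geometry.polar_to_cartesian(self.angles_deg,
                                                 self.radius_px, center)
        pts = np.column_stack([rows, cols])
        return Contour(geometry.resample_closed(pts, n_points=n_points))


def _harmonic_fit(angles_deg, radii, harmonics: int, ridge: float = 1e-6):
    """Periodic least-squares radius model r(theta) = a0 + sum_k (ak cos +
    bk sin); returns a callable."""
    t = np.radians(np.asarray(angles_deg, dtype=float))
    cols = [np.ones_like(t)]
    for k in range(1, harmonics + 1):
        cols += [np.cos(k * t), np.sin(k * t)]
    X = np.column_stack(cols)
    A = X.T @ X + ridge * np.eye(X.shape[1])
    coef = np.linalg.solve(A, X.T @ np.asarray(radii, dtype=float))

    def model(theta_deg):
        tt = np.radians(np.asarray(theta_deg, dtype=float))
        out = np.full_like(tt, coef[0])
        for k in range(1, harmonics + 1):
            out = out + coef[2 * k - 1] * np.cos(k * tt) \
                      + coef[2 * k] * np.sin(k * tt)
        return out

    return model


def detect_epicardial_edge(polar: PolarImage, lv_radius_px: float,
                           params: PerfSegParams = PerfSegParams()
                           ) -> RadialEdge:
    """Canny edges in the polar domain, longest chain, harmonic extension.

    Chains are 8-connected edge components; those lying inside
    ``min_radius_factor * lv_radius`` are discarded (LV cavity edges), and
    the chain covering the most angle bins seeds the profile.  Bins without
    a detection — and detected bins far from the periodic fit (the RV wall
    pulls the chain outward where it abuts the myocardium) — are filled
    from the harmonic fit and flagged as extended.
    """
    # angular pre-smoothing: the polar grid oversamples small arcs, so
    # Cartesian pixel noise becomes angularly elongated streaks; averaging
    # along the (periodic) angle axis suppresses them while reinforcing the
    # angularly coherent myocardial edge
    img = gaussian_filter(polar.values,
                          (params.angular_smooth_bins, 0.0),
                          mode=("wrap", "nearest"))
    pad = max(int(3 * params.angular_smooth_bins), 24)
    padded = np.vstack([img[-pad:], img, img[:pad]])

    smoothed = gaussian_filter(padded, params.canny_sigma)
    gr, gc = np.gradient(smoothed)
    gmag = np.hypot(gr, gc)
    ref = np.percentile(gmag, params.gradient_percentile)
    edges = canny(padded, sigma=params.canny_sigma,
                  low_threshold=params.canny_low_fraction * ref,
                  high_threshold=params.canny_high_fraction * ref)
    edges = edges[pad:pad + polar.n_angles]

    g = gmag[pad:pad + polar.n_angles]
    g_median = max(float(np.median(g)), 1e-30)
    lab = measure.label(edges, connectivity=2)
    radii_px = polar.bin_radii_px()
    chains = []
    for lid in range(1, lab.max() + 1):
        a_idx, r_idx = np.nonzero(lab == lid)
        mean_radius = radii_px[r_idx].mean()
        if mean_radius < params.min_radius_factor * lv_radius_px:
            continue
        q75, q25 = np.percentile(radii_px[r_idx], [75, 25])
        if q75 - q25 > params.max_chain_radius_iqr_px:
            continue                    # radially incoherent: noise streak
        if g[a_idx, r_idx].mean() < params.min_chain_contrast * g_median:
            continue                    # no real contrast: noise ridge
        coverage = len(np.unique(a_idx))
        score = coverage * g[a_idx, r_idx].mean()
        chains.append((score, mean_radius, coverage, a_idx, r_idx))
    min_bins = params.min_chain_deg / polar.angle_bin_deg
    if not chains:
        raise NoEdgeFound("no radially coherent edge chain beyond the LV")
    # the longest (coverage x gradient-strength) chain seeds the edge; when
    # several chains are comparably strong, the epicardium is the innermost
    # one (the RV outer wall produces an equally strong edge further out)
    top = max(c[0] for c in chains)
    viable = [c for c in chains
              if c[0] >= params.chain_score_fraction * top]
    best = min(viable, key=lambda c: c[1])
    if best[2] < min_bins:
        raise NoEdgeFound("longest polar edge chain covers < "
                          f"{params.min_chain_deg:.0f} degrees")
    # fold in fragments of the same edge: chains whose radius agrees with
    # the seed chain's (noise breaks the edge into pieces under hysteresis)
    seed_median = np.median(radii_px[best[4]])
    a_idx = [best[3]]
    r_idx = [best[4]]
    for c in chains:
        if c is best:
            continue
        if abs(np.median(radii_px[c[4]]) - seed_median) <= params.outlier_px:
            a_idx.append(c[3])
            r_idx.append(c[4])
    a_idx = np.concatenate(a_idx)
    r_idx = np.concatenate(r_idx)
    n = polar.n_angles
    profile = np.full(n, np.nan)
    for a in np.unique(a_idx):
        profile[a] = radii_px[r_idx[a_idx == a]].mean()
    detected = np.isfinite(profile)
    angles = polar.bin_angles_deg()

    # robust fit: bins far from the circular-median radius are outliers
    # (e.g. the chain jumping to the RV outer wall where it abuts the
    # myocardium); the harmonic fit then uses inliers only and fills the
    # remaining bins
    med = np.median(profile[detected])
    resid = np.abs(profile[detected] - med)
    inlier_bins = np.nonzero(detected)[0][resid <= params.outlier_px]
    if len(inlier_bins) >= 2 * params.fit_harmonics + 1:
        inliers = np.zeros(n, dtype=bool)
        inliers[inlier_bins] = True
        detected = inliers
    # cap the harmonic order by angular coverage so extrapolation over wide
    # undetected arcs stays tame
    coverage_frac = detected.sum() / n
    order = int(min(params.fit_harmonics,
                    max(1, round(params.fit_harmonics * coverage_frac))))
    fit = _harmonic_fit(angles[detected], profile[detected], order)
    full = np.where(detected, profile, fit(angles))
    lo = params.min_radius_factor * lv_radius_px
    full = np.clip(full, max(polar.radius_bin_px, lo),
                   polar.max_radius_px - polar.radius_bin_px)
    return RadialEdge(full, detected, angles)


# --------------------------------------------------------------------------
# PCA washout image
# --------------------------------------------------------------------------

def pca_washout_image(series: PerfusionSeries, peak_lv_frame: int
                      ) -> np.ndarray:
    """First principal-component image of the post-peak (washout) frames.

    Frames strictly after the LV peak are treated as observations over
    pixel variables and mean-centred per pixel; the leading principal axis,
    rendered as an image, concentrates the coherent contrast kinetics and
    suppresses noise.  Sign is chosen so enhancing (bright-on-average)
    tissue is positive.
    """
    washout = series.frames[peak_lv_frame + 1:]
    if washout.shape[0] < 3:
        raise InsufficientFrames("need >= 3 frames after the LV peak")
    flat = washout.reshape(washout.shape[0], -1)
    centered = flat - flat.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    pc = vt[0]
    mean_img = flat.mean(axis=0)
    if np.dot(pc, mean_img - mean_img.mean()) < 0:
        pc = -pc
    return pc.reshape(series.shape)


# --------------------------------------------------------------------------
# active contour
# --------------------------------------------------------------------------

def _internal_matrix(n: int, alpha: float, beta: float,
                     step: float) -> np.ndarray:
    """Inverse of (I + step*K), K the cyclic elasticity/bending operator."""
    d2 = np.zeros(n)
    d2[[0, 1, -1]] = [-2.0, 1.0, 1.0]
    d4 = np.zeros(n)
    d4[[0, 1, 2, -2, -1]] = [6.0, -4.0, 1.0, 1.0, -4.0]
    first_row = -alpha * d2 + beta * d4
    K = np.empty((n, n))
    for i in range(n):
        K[i] = np.roll(first_row, i)
    return np.linalg.inv(np.eye(n) + step * K)


def refine_active_contour(init: Contour, image: np.ndarray,
                          params: SnakeParams = SnakeParams()) -> Contour:
    """Classic closed snake driven by the edge energy |grad(G_sigma * I)|^2.

    Internal (elasticity + bending) terms are integrated implicitly; the
    loop stops on mean displacement < tol or at max_iter.  A step that
    makes the contour self-intersect is rolled back and iteration stops; a
    collapse below ``min_area_fraction`` of the initial area raises
    :class:`DegenerateContour`.
    """
    pts = geometry.resample_closed(init.points, n_points=params.n_points)
    init_area = geometry.polygon_area(pts)
    if init_area <= 0:
        raise DegenerateContour("zero-area initial contour")

    smoothed = gaussian_filter(np.asarray(image, dtype=float), params.sigma)
    gr, gc = np.gradient(smoothed)
    edge = gr ** 2 + gc ** 2
    emax = edge.max()
    if emax > 0:
        edge = edge / emax
    f_r, f_c = np.gradient(edge)

    inv = _internal_matrix(params.n_points, params.alpha, params.beta,
                           params.step)
    nr, nc = image.shape
    last_simple = pts.copy()
    for _ in range(params.max_iter):
        fr = map_coordinates(f_r, [pts[:, 0], pts[:, 1]], order=1,
                             mode="nearest")
        fc = map_coordinates(f_c, [pts[:, 0], pts[:, 1]], order=1,
                             mode="nearest")
        force = params.w_edge * np.column_stack([fr, fc])
        new = inv @ (pts + params.step * force)
        new[:, 0] = np.clip(new[:, 0], 0, nr - 1)
        new[:, 1] = np.clip(new[:, 1], 0, nc - 1)
        displacement = np.linalg.norm(new - pts, axis=1).mean()
        pts = new
        if geometry.polygon_area(pts) < params.min_area_fraction * init_area:
            raise DegenerateContour("active contour collapsed")
        if not geometry.is_simple(pts):
            pts = last_simple
            log.warning("snake self-intersected; rolled back")
            break
        last_simple = pts.copy()
        if displacement < params.tol:
            break
    return Contour(pts)


# --------------------------------------------------------------------------
# slice-to-slice propagation
# --------------------------------------------------------------------------

def propagate_slice(prev_vents: VentricleMasks,
                    prev_series: PerfusionSeries,
                    next_series: PerfusionSeries,
                    params: PerfSegParams = PerfSegParams(),
                    prev_epi_radius_px: float | None = None
                    ) -> VentricleMasks:
    """Re-locate the ventricles on the next slice by temporal correlation.

    The previous slice's LV/RV mean curves are correlated against every
    pixel curve inside a window around the previous LV centre; the
    best-correlated pixel seeds region growing at the basal peak frame.
    An unfindable LV aborts; a missing RV is tolerated.
    """
    if prev_epi_radius_px is None:
        prev_epi_radius_px = 1.8 * np.sqrt(prev_vents.lv_mask.sum() / np.pi)
    search_radius = params.search_radius_factor * prev_epi_radius_px

    nr, nc = next_series.shape
    rows, cols = np.mgrid[0:nr, 0:nc]
    window = (np.hypot(rows - prev_vents.lv_center[0],
                       cols - prev_vents.lv_center[1]) <= search_radius)

    def best_pixel(ref_curve):
        curves = next_series.frames[:, window]
        rc = ref_curve - ref_curve.mean()
        cc = curves - curves.mean(axis=0, keepdims=True)
        denom = (np.linalg.norm(rc) * np.linalg.norm(cc, axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (rc @ cc) / denom
        corr = np.nan_to_num(corr, nan=-1.0)
        k = int(np.argmax(corr))
        wr, wc = np.nonzero(window)
        return float(corr[k]), (int(wr[k]), int(wc[k]))

    lv_ref = prev_series.frames[:, prev_vents.lv_mask].mean(axis=1)
    corr, seed = best_pixel(lv_ref)
    if corr < params.min_seed_correlation:
        raise LVNotFound(
            f"best LV correlation {corr:.2f} below threshold on "
            f"{next_series.slice_location.value} slice")
    seed_mask = np.zeros((nr, nc), dtype=bool)
    seed_mask[seed] = True
    lv_mask = grow_lv(next_series, seed_mask, prev_vents.peak_lv_frame,
                      params)

    rv_mask = None
    if prev_vents.rv_mask is not None:
        rv_ref = prev_series.frames[:, prev_vents.rv_mask].mean(axis=1)
        try:
            corr, seed = best_pixel(rv_ref)
            if corr < params.min_seed_correlation:
                raise RVNotFound("RV correlation too low")
            if lv_mask[seed]:
                raise RVNotFound("RV seed fell inside the LV")
            seed_mask = np.zeros((nr, nc), dtype=bool)
            seed_mask[seed] = True
            rv_mask = grow_lv(next_series, seed_mask,
                              prev_vents.peak_lv_frame, params,
                              apply_hull=False)
            rv_mask &= ~lv_mask
            if not rv_mask.any():
                rv_mask = None
        except (RVNotFound, GrowthOverflow) as e:
            log.info("RV not propagated to %s: %s",
                     next_series.slice_location.value, e)
            rv_mask = None

    r, c = np.nonzero(lv_mask)
    return VentricleMasks(lv_mask, rv_mask,
                          (float(r.mean()), float(c.mean())),
                          prev_vents.peak_lv_frame)


# --------------------------------------------------------------------------
# slice orchestrator
# --------------------------------------------------------------------------

def segment_perfusion_slice(series: PerfusionSeries, vents: VentricleMasks,
                            params: PerfSegParams = PerfSegParams()
                            ) -> MyoSegmentation:
    """Full perfusion-image myocardial segmentation for one slice."""
    lv_grown = grow_lv(series, vents.lv_mask, vents.peak_lv_frame, params)
    r, c = np.nonzero(lv_grown)
    lv_center = (float(r.mean()), float(c.mean()))
    lv_radius = float(np.sqrt(lv_grown.sum() / np.pi))
    endo = Contour(geometry.resample_closed(
        geometry.mask_boundary_contour(lv_grown),
        n_points=params.snake.n_points))

    normalized = temporal_normalize(series)
    lv_curve = series.frames[:, vents.lv_mask].mean(axis=1)
    base_img = baseline_image(normalized, lv_curve, params)

    nr, nc = series.shape
    max_radius = max(min(lv_center[0], lv_center[1],
                         nr - 1 - lv_center[0], nc - 1 - lv_center[1]) - 1.0,
                     2.0 * lv_radius)
    polar = polar_transform(base_img, lv_center, params.n_angles,
                            int(round(params.radius_bins_per_px
                                      * max_radius)), max_radius)
    edge = detect_epicardial_edge(polar, lv_radius, params)
    epi_init = edge.to_contour(lv_center, params.snake.n_points)

    washout = pca_washout_image(series, vents.peak_lv_frame)
    epi = refine_active_contour(epi_init, washout, params.snake)
    epi = _repair_endo_inside_epi(endo, epi, lv_center)

    myo_mask = epi.mask(series.shape) & ~lv_grown & ~endo.mask(series.shape)
    if not myo_mask.any():
        raise DegenerateContour("myocardial annulus is empty")
    return MyoSegmentation(endo=endo, epi=epi, myo_mask=myo_mask)


def _repair_endo_inside_epi(endo: Contour, epi: Contour, center,
                            max_steps: int = 3) -> Contour:
    """Radially dilate epi (1 px steps, max 3) until endo fits inside."""
    from shapely.geometry import Point, Polygon

    pts = epi.points.copy()
    for _ in range(max_steps + 1):
        poly = Polygon(pts)
        if poly.is_valid and all(
                poly.covers(Point(p)) for p in endo.points):
            return Contour(pts)
        direction = pts - np.asarray(center)
        norm = np.linalg.norm(direction, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        pts = pts + direction / norm
    raise DegenerateContour("endocardium not containable inside epicardium")
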