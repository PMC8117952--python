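"""Segmentation and measurement agreement statistics.

Area agreement comes from the 2x2 pixel confusion table (Dice, Cohen kappa,
accuracy, sensitivity, specificity, PPV, volume overlap error, relative
volume difference); border agreement from contour point-set distances (a
directed RMS nearest-neighbour distance, Hausdorff, average symmetric
surface distance, and a pooled-covariance Mahalanobis distance between the
point clouds); paired measurements via Bland-Altman, Pearson, ICC(2,1) and
the Mann-Whitney U test.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .core import Contour
from .errors import EmptyReference, SingularCovariance, ZeroVariance
from .geometry import resample_closed

RESAMPLE_SPACING_PX = 0.5


@dataclass(frozen=True)
class AreaAgreement:
    dice: float
    kappa: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    volume_overlap_error: float
    relative_volume_difference: float


@dataclass(frozen=True)
class BorderDistances:
    rms_nn_mm: float
    hausdorff_mm: float
    assd_mm: float
    mahalanobis: float


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd: float
    loa_low: float
    loa_high: float


def confusion_counts(auto_mask, ref_mask):
    a = np.asarray(auto_mask, dtype=bool)
    r = np.asarray(ref_mask, dtype=bool)
    if a.shape != r.shape:
        raise ValueError("mask shapes differ")
    tp = int((a & r).sum())
    fp = int((a & ~r).sum())
    fn = int((~a & r).sum())
    tn = int((~a & ~r).sum())
    return tp, fp, fn, tn


def area_agreement(auto_mask, ref_mask) -> AreaAgreement:
    """All pixel-overlap statistics from one confusion table.

    Kappa uses the full image as background (no bounding-box restriction).
    Raises :class:`EmptyReference` when the reference mask is empty.
    """
    tp, fp, fn, tn = confusion_counts(auto_mask, ref_mask)
    n = tp + fp + fn + tn
    n_ref = tp + fn
    n_auto = tp + fp
    if n_ref == 0:
        raise EmptyReference("reference mask is empty")
    dice = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0
    po = (tp + tn) / n
    pe = ((n_auto * n_ref) + (fp + tn) * (fn + tn)) / (n * n)
    kappa = (po - pe) / (1 - pe) if pe != 1 else 1.0
    return AreaAgreement(
        dice=dice,
        kappa=kappa,
        accuracy=po,
        sensitivity=tp / n_ref,
        specificity=tn / (tn + fp) if (tn + fp) else np.nan,
        ppv=tp / n_auto if n_auto else np.nan,
        volume_overlap_error=1 - tp / (tp + fp + fn) if (tp + fp + fn) else 0.0,
        relative_volume_difference=(n_auto - n_ref) / n_ref,
    )


def _points_mm(contour: Contour, spacing) -> np.ndarray:
    pts = resample_closed(contour.points, spacing=RESAMPLE_SPACING_PX)
    return pts * np.asarray(spacing, dtype=float)[None, :]


def rms_nn_border_distance(auto: Contour, ref: Contour,
                           spacing=(1.0, 1.0)) -> float:
    """Directed auto->ref root-mean-square nearest-neighbour distance (mm).

    Each automated boundary point contributes its distance to the nearest
    reference point; the result is the RMS over automated points.
    """
    a = _points_mm(auto, spacing)
    r = _points_mm(ref, spacing)
    d = cdist(a, r).min(axis=1)
    return float(np.sqrt(np.mean(d ** 2)))


def hausdorff(auto: Contour, ref: Contour, spacing=(1.0, 1.0)) -> float:
    """Symmetric Hausdorff distance between the borders, in mm."""
    a = _points_mm(auto, spacing)
    r = _points_mm(ref, spacing)
    d = cdist(a, r)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def assd(auto: Contour, ref: Contour, spacing=(1.0, 1.0)) -> float:
    """Average symmetric surface distance between the borders, in mm."""
    a = _points_mm(auto, spacing)
    r = _points_mm(ref, spacing)
    d = cdist(a, r)
    all_d = np.concatenate([d.min(axis=1), d.min(axis=0)])
    return float(all_d.mean())


def mahalanobis(auto: Contour, ref: Contour) -> float:
    """Centroid separation under the pooled covariance of the point clouds.

    Dimensionless; raises :class:`SingularCovariance` for degenerate
    (e.g. collinear) point sets.
    """
    a = resample_closed(auto.points, spacing=RESAMPLE_SPACING_PX)
    r = resample_closed(ref.points, spacing=RESAMPLE_SPACING_PX)
    mu_a, mu_r = a.mean(axis=0), r.mean(axis=0)
    na, nr = len(a), len(r)
    cov_a = np.cov(a, rowvar=False)
    cov_r = np.cov(r, rowvar=False)
    pooled = ((na - 1) * cov_a + (nr - 1) * cov_r) / (na + nr - 2)
    try:
        inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError as e:
        raise SingularCovariance("pooled covariance is singular") from e
    if np.linalg.cond(pooled) > 1e12:
        raise SingularCovariance("pooled covariance is near-singular")
    diff = mu_a - mu_r
    return float(np.sqrt(diff @ inv @ diff))


# --- paired-measurement statistics ----------------------------------------

def bland_altman(auto_values, ref_values) -> BlandAltman:
    """Bias (auto - ref) and 1.96-SD limits of agreement."""
    a = np.asarray(auto_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if a.shape != r.shape or len(a) < 3:
        raise ValueError("need equal-length paired sequences, n >= 3")
    d = a - r
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def pearson(auto_values, ref_values) -> float:
    a = np.asarray(auto_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if a.std() == 0 or r.std() == 0:
        raise ZeroVariance("correlation undefined for constant sequence")
    return float(stats.pearsonr(a, r).statistic)


def icc(auto_values, ref_values) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, for the two raters (automated, manual)."""
    a = np.asarray(auto_values, dtype=float)
    r = np.asarray(ref_values, dtype=float)
    if a.shape != r.shape or len(a) < 3:
        raise ValueError("need equal-length paired sequences, n >= 3")
    data = np.column_stack([a, r])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = (ms_rows + (k - 1) * ms_err
             + k * (ms_cols - ms_err) / n)
    if denom == 0:
        raise ZeroVariance("ICC undefined: no variance")
    return float((ms_rows - ms_err) / denom)


def mann_whitney(auto_values, ref_values) -> float:
    """Two-sided Mann-Whitney U p-value (scipy)."""
    res = stats.mannwhitneyu(auto_values, ref_values,
                             alternative="two-sided")
    return float(res.pvalue)


def mann_whitney_u(auto_values, ref_values) -> float:
    """The U statistic itself (for the first sample)."""
    res = stats.mannwhitneyu(auto_values, ref_values,
                             alternative="two-sided")
    return float(res.statistic)
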