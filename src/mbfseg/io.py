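"""Readers and writers for the standard formats the pipeline touches.

Formats: classic single-frame DICOM series (read-only), NIfTI-1 (4D dynamic
series, 2D MBF maps or delimited text grids), a versioned JSON segmentation
schema, and tidy CSV sector reports.
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (Condition, Contour, InsertionLandmark, MBFMap,
                   MyoSegmentation, PerfusionSeries, SectorReport,
                   SliceLocation)
from .errors import MalformedSeries, MissingMetadata, NegativeFlow, SchemaError

log = logging.getLogger(__name__)

SEGMENTATION_SCHEMA_VERSION = 1


def read_perfusion(path, format: str = "nifti4d",
                   slice_location: SliceLocation = SliceLocation.BASE,
                   condition: Condition = Condition.REST) -> PerfusionSeries:
    """Read a dynamic perfusion series from a NIfTI 4D file or a DICOM dir.

    Frames are ordered by acquisition/trigger time for DICOM input.  Missing
    spacing or timing metadata is replaced by 1.0 mm / 1.0 s defaults with a
    warning (the pipeline only uses frame ordering, never absolute times).
    """
    path = Path(path)
    if format == "nifti4d":
        return _read_nifti4d(path, slice_location, condition)
    if format == "dicom_dir":
        return _read_dicom_dir(path, slice_location, condition)
    raise ValueError(f"unknown format {format!r}")


def _read_nifti4d(path, slice_location, condition) -> PerfusionSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise MalformedSeries(f"expected 4D NIfTI, got {data.ndim}D")
    if data.shape[2] != 1:
        raise MalformedSeries("expected a single spatial slice (x, y, 1, t)")
    # NIfTI (x, y, 1, t) -> (t, row, col); x is column-fastest in our layout
    frames = np.transpose(data[:, :, 0, :], (2, 0, 1)).astype(float)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else None
    if not spacing or any(s <= 0 for s in spacing):
        warnings.warn("NIfTI spacing missing; defaulting to 1.0 mm",
                      MissingMetadata)
        spacing = (1.0, 1.0)
    dt = float(zooms[3]) if len(zooms) >= 4 and zooms[3] > 0 else None
    if dt is None:
        warnings.warn("NIfTI frame timing missing; defaulting to 1.0 s",
                      MissingMetadata)
        dt = 1.0
    times = np.arange(frames.shape[0]) * dt
    return PerfusionSeries(slice_location, frames, spacing, times, condition)


def _read_dicom_dir(path, slice_location, condition) -> PerfusionSeries:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise MalformedSeries(f"no DICOM instances under {path}")
    uids = {getattr(d, "SeriesInstanceUID", None) for d in datasets}
    if len(uids) > 1:
        raise MalformedSeries("directory mixes multiple SeriesInstanceUIDs")

    def sort_key(d):
        for attr in ("TriggerTime", "AcquisitionTime", "InstanceNumber"):
            v = getattr(d, attr, None)
            if v is not None:
                try:
                    return float(v)
                except (TypeError, ValueError):
                    continue
        return 0.0

    datasets.sort(key=sort_key)
    arrays = [d.pixel_array.astype(float) for d in datasets]
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise MalformedSeries(f"inconsistent frame shapes: {shapes}")
    frames = np.stack(arrays)
    spacing = getattr(datasets[0], "PixelSpacing", None)
    if spacing is None:
        warnings.warn("DICOM PixelSpacing missing; defaulting to 1.0 mm",
                      MissingMetadata)
        spacing = (1.0, 1.0)
    else:
        spacing = (float(spacing[0]), float(spacing[1]))
    keys = [sort_key(d) for d in datasets]
    if len(set(keys)) == len(keys) and all(np.diff(keys) > 0):
        times = np.asarray(keys, dtype=float)
        times = (times - times[0])
        if getattr(datasets[0], "TriggerTime", None) is not None:
            times = times / 1000.0  # TriggerTime is in ms
        if np.any(np.diff(times) <= 0):
            times = np.arange(len(datasets), dtype=float)
    else:
        warnings.warn("DICOM timing missing; defaulting to 1.0 s spacing",
                      MissingMetadata)
        times = np.arange(len(datasets), dtype=float)
    return PerfusionSeries(slice_location, frames, spacing, times, condition)


# --- MBF maps --------------------------------------------------------------

def read_mbf_map(path, pixel_spacing_mm=(1.0, 1.0),
                 slice_location: SliceLocation = SliceLocation.BASE,
                 condition: Condition = Condition.REST,
                 negative_tolerance: float = 0.01) -> MBFMap:
    """Read a 2D MBF map from NIfTI or a delimited text grid.

    Small negative values (>= -negative_tolerance, deconvolution ringing)
    are clipped to 0 with a log message; larger negatives raise
    :class:`NegativeFlow`.
    """
    path = Path(path)
    if path.suffix in (".nii", ".gz") or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        values = np.asanyarray(img.dataobj).astype(float)
        values = np.squeeze(values)
        zooms = img.header.get_zooms()
        if len(zooms) >= 2 and all(z > 0 for z in zooms[:2]):
            pixel_spacing_mm = (float(zooms[0]), float(zooms[1]))
    else:
        values = np.loadtxt(str(path), delimiter=None)
    if values.ndim != 2:
        raise MalformedSeries("MBF map must be 2D")
    vmin = values.min()
    if vmin < -negative_tolerance:
        raise NegativeFlow(f"map contains flow {vmin:.3f} ml/g/min")
    if vmin < 0:
        log.info("clipping %d slightly negative map pixels to 0",
                 int((values < 0).sum()))
        values = np.clip(values, 0.0, None)
    return MBFMap(values, pixel_spacing_mm, slice_location, condition)


def write_mbf_map(mbf_map: MBFMap, path) -> None:
    """Write a map as 2D NIfTI (.nii) or whitespace-delimited text."""
    path = Path(path)
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag([mbf_map.pixel_spacing_mm[0],
                          mbf_map.pixel_spacing_mm[1], 1.0, 1.0])
        img = nib.Nifti1Image(mbf_map.values.astype(np.float32), affine)
        img.header.set_zooms(mbf_map.pixel_spacing_mm)
        nib.save(img, str(path))
    else:
        np.savetxt(str(path), mbf_map.values, fmt="%.6g")


# --- segmentation JSON -----------------------------------------------------

def write_segmentation(seg: MyoSegmentation, landmark: InsertionLandmark,
                       path, pixel_spacing_mm=(1.0, 1.0)) -> None:
    doc = {
        "schema_version": SEGMENTATION_SCHEMA_VERSION,
        "endo": np.asarray(seg.endo.points).tolist(),
        "epi": np.asarray(seg.epi.points).tolist(),
        "lv_center": list(landmark.lv_center),
        "rv_insertion_angle_deg": landmark.rv_insertion_angle_deg,
        "image_shape": list(seg.myo_mask.shape),
        "pixel_spacing_mm": list(pixel_spacing_mm),
    }
    Path(path).write_text(json.dumps(doc))


def read_segmentation(path) -> tuple[MyoSegmentation, InsertionLandmark]:
    try:
        doc = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as e:
        raise SchemaError(f"cannot parse segmentation file: {e}") from e
    for key in ("endo", "epi", "lv_center", "rv_insertion_angle_deg",
                "image_shape"):
        if key not in doc:
            raise SchemaError(f"segmentation file missing {key!r}")
    try:
        seg = MyoSegmentation(endo=Contour(np.asarray(doc["endo"], float)),
                              epi=Contour(np.asarray(doc["epi"], float)),
                              image_shape=tuple(doc["image_shape"]))
        landmark = InsertionLandmark(tuple(doc["lv_center"]),
                                     float(doc["rv_insertion_angle_deg"]))
    except Exception as e:
        raise SchemaError(f"invalid segmentation content: {e}") from e
    return seg, landmark


# --- sector reports --------------------------------------------------------

def write_sector_report(reports: Sequence[SectorReport], path_csv,
                        study_id: str = "study",
                        mpr: Optional[dict] = None) -> None:
    """Write tidy CSV: study_id, slice, condition, sector, mean_mbf,
    pixel_count, mpr.

    ``mpr`` maps slice location -> per-sector MPR array (nan = missing);
    the mpr column is blank for stress rows' rest-missing studies.
    """
    import pandas as pd

    rows = []
    for rep in reports:
        for s in range(rep.n_sectors):
            m = rep.mean_mbf[s]
            mpr_val = ""
            if (mpr is not None and rep.condition == Condition.STRESS
                    and rep.slice_location in mpr):
                v = mpr[rep.slice_location][s]
                mpr_val = "" if not np.isfinite(v) else round(float(v), 6)
            rows.append({
                "study_id": study_id,
                "slice": rep.slice_location.value,
                "condition": rep.condition.value,
                "sector": s + 1,
                "mean_mbf": ("NA" if rep.pixel_count[s] == 0
                             else round(float(m), 6)),
                "pixel_count": int(rep.pixel_count[s]),
                "mpr": mpr_val,
            })
    pd.DataFrame(rows).to_csv(path_csv, index=False)
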