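"""Axial CT ingestion (DICOM) and result reports (CSV/JSON).

A series is read into :class:`CTSlice` objects carrying the rescaled HU
grid, the physical pixel spacing (needed to express the ROI area in
cm^2) and, when the scanner recorded it, the per-slice CTDIvol
(tag 0018,9345).  Slices are ordered along the scan axis by
ImagePositionPatient z, falling back to InstanceNumber.

Writing is the inverse path: rendered synthetic slices can be serialized
to single-frame CT Image Storage files so the full DICOM pipeline is
exercisable without clinical data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

from .dosimetry import DwResult, SSDEReport, size_conversion_factor, ssde

log = logging.getLogger(__name__)

__all__ = [
    "CTSlice",
    "EmptySeriesError",
    "load_series",
    "to_hu",
    "read_ctdi_vol",
    "write_series",
    "write_slice_dicom",
    "write_report",
]

#: lower clamp for HU; CT padding values below this are physically meaningless
HU_FLOOR = -1024.0
CTDI_VOL_TAG = pydicom.tag.Tag(0x0018, 0x9345)


class EmptySeriesError(ValueError):
    """No readable DICOM image found at the given location."""


@dataclass
class CTSlice:
    """One axial CT image in Hounsfield Units plus physical metadata."""

    hu: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    ctdi_vol_mGy: float | None = None
    slice_index: int = 0
    source_id: str = "synthetic"

    def __post_init__(self):
        hu = np.asarray(self.hu, dtype=float)
        if hu.ndim != 2:
            raise ValueError(f"HU grid must be 2-D, got shape {hu.shape}")
        if min(hu.shape) < 16:
            raise ValueError(f"image too small: {hu.shape}")
        if not np.all(np.isfinite(hu)):
            raise ValueError("HU grid contains non-finite values")
        self.hu = np.maximum(hu, HU_FLOOR)
        sr, sc = self.pixel_spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing_mm}")
        if self.ctdi_vol_mGy is not None and self.ctdi_vol_mGy < 0:
            raise ValueError(f"CTDIvol must be non-negative, got {self.ctdi_vol_mGy}")

    @property
    def n_rows(self) -> int:
        return self.hu.shape[0]

    @property
    def n_cols(self) -> int:
        return self.hu.shape[1]

    @property
    def pixel_area_cm2(self) -> float:
        sr, sc = self.pixel_spacing_mm
        return (sr * sc) / 100.0


def to_hu(stored_values: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Rescale stored pixel values to HU: ``slope * stored + intercept``.

    Output is clipped below at -1024 HU to suppress out-of-field padding.
    """
    if slope == 0:
        raise ValueError("RescaleSlope must be non-zero")
    hu = np.asarray(stored_values, dtype=float) * slope + intercept
    return np.maximum(hu, HU_FLOOR)


def read_ctdi_vol(ds: Dataset, override: float | None = None) -> float | None:
    """CTDIvol in mGy from tag (0018,9345), or ``None`` when unavailable.

    An explicit ``override`` (user configuration) always wins.  Negative
    tag values are treated as absent with a logged warning.
    """
    if override is not None:
        return float(override)
    if CTDI_VOL_TAG in ds:
        value = ds[CTDI_VOL_TAG].value
        if value is None:
            return None
        value = float(value)
        if value < 0:
            log.warning("ignoring negative CTDIvol tag value %.3f in %s",
                        value, getattr(ds, "filename", "<dataset>"))
            return None
        return value
    return None


def _dicom_files(path: Path | str | Iterable[Path | str]) -> list[Path]:
    if isinstance(path, (str, Path)):
        p = Path(path)
        if p.is_dir():
            return sorted(q for q in p.iterdir() if q.is_file())
        return [p]
    return [Path(p) for p in path]


def load_series(
    path: Path | str | Iterable[Path | str],
    ctdi_vol_override: float | None = None,
) -> list[CTSlice]:
    """Read a directory (or explicit file list) into an ordered slice list.

    Ordering is by ImagePositionPatient z when every file carries it,
    otherwise by InstanceNumber; ties fall back to file name, so the
    result is deterministic for a fixed input.

    Raises
    ------
    EmptySeriesError
        If no file yields a readable DICOM image.
    ValueError
        If PixelSpacing is missing (physical area is required) or matrix
        sizes are inconsistent across the series.
    """
    datasets = []
    for f in _dicom_files(path):
        try:
            ds = pydicom.dcmread(f)
        except Exception:  # not a DICOM file; skip
            continue
        if "PixelData" not in ds:
            continue
        datasets.append((f, ds))
    if not datasets:
        raise EmptySeriesError(f"empty series: no readable DICOM image under {path!r}")

    def sort_key(item):
        f, ds = item
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None and len(ipp) == 3:
            return (0, float(ipp[2]), str(f))
        return (1, float(getattr(ds, "InstanceNumber", 0) or 0), str(f))

    datasets.sort(key=sort_key)

    slices = []
    shape = None
    for index, (f, ds) in enumerate(datasets):
        if "PixelSpacing" not in ds:
            raise ValueError(f"missing PixelSpacing in {f}; cannot compute area in cm^2")
        arr = ds.pixel_array
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise ValueError(
                f"inconsistent matrix sizes in series: {arr.shape} vs {shape} ({f})"
            )
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = to_hu(arr, slope, intercept)
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        slices.append(
            CTSlice(
                hu=hu,
                pixel_spacing_mm=spacing,
                ctdi_vol_mGy=read_ctdi_vol(ds, override=ctdi_vol_override),
                slice_index=index,
                source_id=str(f),
            )
        )
    return slices


def write_slice_dicom(
    ct: CTSlice,
    path: Path | str,
    *,
    series_uid: str | None = None,
    instance_number: int = 1,
    z_mm: float = 0.0,
) -> Path:
    """Serialize one slice as a single-frame CT Image Storage file.

    HU are stored as unsigned 16-bit with RescaleIntercept -1024 and
    RescaleSlope 1, so the round trip is exact to integer HU.
    """
    path = Path(path)
    stored = np.round(ct.hu - HU_FLOOR).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.Modality = "CT"
    ds.Rows, ds.Columns = ct.hu.shape
    ds.PixelSpacing = [ct.pixel_spacing_mm[0], ct.pixel_spacing_mm[1]]
    ds.InstanceNumber = instance_number
    ds.ImagePositionPatient = [0.0, 0.0, float(z_mm)]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1
    ds.RescaleIntercept = int(HU_FLOOR)
    if ct.ctdi_vol_mGy is not None:
        ds.add_new(CTDI_VOL_TAG, "FD", float(ct.ctdi_vol_mGy))
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    return path


def write_series(slices: Sequence[CTSlice], out_dir: Path | str,
                 slice_thickness_mm: float = 5.0) -> list[Path]:
    """Write each slice of a series into ``out_dir`` as slice_###.dcm."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    paths = []
    for i, ct in enumerate(slices):
        p = out_dir / f"slice_{i:03d}.dcm"
        write_slice_dicom(ct, p, series_uid=series_uid, instance_number=i + 1,
                          z_mm=i * slice_thickness_mm)
        paths.append(p)
    return paths


def write_report(
    results: Sequence[DwResult],
    summary: SSDEReport,
    out_prefix: Path | str,
    per_slice_ctdi: Sequence[float | None] | None = None,
) -> tuple[Path, Path]:
    """Write the per-slice CSV and the series-summary JSON.

    The CSV has one row per slice (index, A_ROI, mean HU, D_w, and the
    per-slice SSDE whenever a CTDIvol is known — per-slice values first,
    else the series value from the summary).  Returns (csv_path,
    json_path).
    """
    if len(results) == 0:
        raise ValueError("no per-slice results to report")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, r in enumerate(results):
        ctdi = None
        if per_slice_ctdi is not None and per_slice_ctdi[i] is not None:
            ctdi = per_slice_ctdi[i]
        elif summary.ctdi_vol_mGy is not None:
            ctdi = summary.ctdi_vol_mGy
        slice_ssde = None
        if ctdi is not None:
            f_slice = size_conversion_factor(r.dw_cm, summary.phantom_ref)
            slice_ssde = ssde(ctdi, f_slice)
        rows.append(
            {
                "slice_index": r.slice_index,
                "area_cm2": r.area_cm2,
                "mean_hu": r.mean_hu,
                "dw_cm": r.dw_cm,
                "ssde_mGy": slice_ssde,
            }
        )
    csv_path = out_prefix.with_suffix(".csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)

    json_path = out_prefix.with_suffix(".json")
    payload = {
        "algorithm": summary.algorithm,
        "n_slices": len(results),
        "mean_dw_cm": summary.mean_dw_cm,
        "f_size": summary.f_size,
        "ctdi_vol_mGy": summary.ctdi_vol_mGy,
        "ssde_mGy": summary.ssde_mGy,
        "phantom_ref": summary.phantom_ref,
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return csv_path, json_path
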