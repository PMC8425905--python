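"""Water-equivalent diameter (D_w) and size-specific dose estimate (SSDE).

D_w is the diameter of a water cylinder with the same total x-ray
attenuation as the patient cross-section.  For a body mask (ROI) on an
axial HU slice it is

    D_w = 2 * sqrt( (mean_HU/1000 + 1) * A_ROI / pi )

with A_ROI the physical ROI area in cm^2.  Internally the computation is
carried out as a per-pixel sum of water-equivalent areas,
``sum_i (HU_i/1000 + 1) * a_px``, which is algebraically identical but
makes air pixels (HU = -1000) contribute exactly zero.

SSDE rescales the scanner output dose CTDIvol by a size conversion
factor f(D_w) taken from the AAPM Report 204 exponential fits
(body 32-cm or head 16-cm reference phantom).
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "DwResult",
    "SSDEReport",
    "water_equivalent_diameter",
    "mean_dw",
    "size_conversion_factor",
    "load_conversion_curves",
    "ssde",
    "percent_diff_dw",
    "percent_diff_ssde",
]


@dataclass(frozen=True)
class DwResult:
    """Per-slice D_w outcome.

    Attributes
    ----------
    slice_index : int
        Ordinal of the slice within its series.
    area_cm2 : float
        Physical ROI area A_ROI in cm^2.
    mean_hu : float
        Arithmetic mean HU over the ROI (dimensionless).
    dw_cm : float
        Water-equivalent diameter in cm.
    """

    slice_index: int
    area_cm2: float
    mean_hu: float
    dw_cm: float


@dataclass(frozen=True)
class SSDEReport:
    """Series-level summary: mean D_w, conversion factor and SSDE.

    ``ssde_mGy`` is ``ctdi_vol_mGy * f_size`` and is ``None`` whenever no
    CTDIvol is available (D_w itself does not depend on scanner output).
    """

    mean_dw_cm: float
    f_size: float
    ctdi_vol_mGy: float | None
    ssde_mGy: float | None
    phantom_ref: str
    algorithm: str


def _as_bool_mask(mask) -> np.ndarray:
    """Accept a plain boolean grid or any object with a ``mask`` attribute."""
    m = getattr(mask, "mask", mask)
    return np.asarray(m, dtype=bool)


def water_equivalent_diameter(
    hu: np.ndarray,
    mask,
    pixel_spacing_mm: tuple[float, float],
    slice_index: int = 0,
) -> DwResult:
    """Compute D_w of ``hu`` restricted to the body ``mask``.

    Parameters
    ----------
    hu : ndarray
        2-D grid of Hounsfield Units.
    mask : ndarray of bool or BodyMask
        ROI; must contain at least one pixel.
    pixel_spacing_mm : (row, col)
        Physical pixel spacing in mm.

    Raises
    ------
    ValueError
        If the mask is empty or the total water-equivalent area is
        negative (mean HU below -1000, which the HU floor should prevent).
    """
    hu = np.asarray(hu, dtype=float)
    m = _as_bool_mask(mask)
    if m.shape != hu.shape:
        raise ValueError(f"mask shape {m.shape} != image shape {hu.shape}")
    cells = hu[m]
    if cells.size == 0:
        raise ValueError("empty mask: cannot compute water-equivalent diameter")
    sr, sc = pixel_spacing_mm
    px_area_cm2 = (sr * sc) / 100.0
    area_cm2 = cells.size * px_area_cm2
    mean_hu = float(cells.mean())
    # per-pixel water-equivalent area; HU = -1000 yields an exact 0.0 term,
    # dropped before summing so air pixels cannot perturb the sum even at
    # the last-ulp level (summation order is otherwise preserved)
    terms = cells / 1000.0 + 1.0
    aw_cm2 = float(np.sum(terms[terms != 0.0])) * px_area_cm2
    if aw_cm2 < 0.0:
        raise ValueError(
            f"negative water-equivalent area ({aw_cm2:.3g} cm^2): mean HU below -1000"
        )
    dw_cm = 2.0 * math.sqrt(aw_cm2 / math.pi)
    return DwResult(slice_index=slice_index, area_cm2=area_cm2, mean_hu=mean_hu, dw_cm=dw_cm)


def mean_dw(results: Sequence[DwResult]) -> float:
    """Unweighted series mean of per-slice D_w values (cm)."""
    if len(results) == 0:
        raise ValueError("mean_dw requires at least one per-slice result")
    return float(np.mean([r.dw_cm for r in results]))


def load_conversion_curves() -> dict:
    """Load the packaged size-conversion-factor coefficient table."""
    with resources.files("ctsize.data").joinpath("size_conversion.json").open() as fh:
        return json.load(fh)


def size_conversion_factor(
    dw_cm: float,
    phantom_ref: str = "body-32cm",
    coefficients: Mapping[str, Mapping[str, float]] | None = None,
) -> float:
    """Size conversion factor f = a * exp(-b * D_w).

    Coefficients default to the packaged AAPM Report 204 exponential fits
    (``body-32cm`` and ``head-16cm``).  Outside the tabulated size range
    (6-55 cm) the fit is extrapolated with a warning.
    """
    if dw_cm <= 0:
        raise ValueError(f"non-positive water-equivalent diameter: {dw_cm}")
    table = load_conversion_curves()
    curves = coefficients if coefficients is not None else table["curves"]
    if phantom_ref not in curves:
        raise KeyError(
            f"unknown reference phantom {phantom_ref!r}; available: {sorted(curves)}"
        )
    lo, hi = table["valid_range_cm"]
    if not lo <= dw_cm <= hi:
        warnings.warn(
            f"D_w = {dw_cm:.1f} cm outside the fitted size range "
            f"[{lo:.0f}, {hi:.0f}] cm; extrapolating the conversion factor",
            stacklevel=2,
        )
    c = curves[phantom_ref]
    return float(c["a"] * math.exp(-c["b"] * dw_cm))


def ssde(ctdi_vol_mGy: float, f_size: float) -> float:
    """SSDE = CTDIvol * f_size (mGy)."""
    if ctdi_vol_mGy <= 0:
        raise ValueError(f"CTDIvol must be positive, got {ctdi_vol_mGy}")
    if f_size <= 0:
        raise ValueError(f"conversion factor must be positive, got {f_size}")
    return ctdi_vol_mGy * f_size


def percent_diff_dw(dw_new: float, dw_old: float) -> float:
    """Relative difference (new - old) / old in percent."""
    if dw_old <= 0:
        raise ValueError(f"reference D_w must be positive, got {dw_old}")
    return (dw_new - dw_old) / dw_old * 100.0


def percent_diff_ssde(ssde_new: float, ssde_old: float) -> float:
    """Relative SSDE difference (new - old) / old in percent."""
    if ssde_old <= 0:
        raise ValueError(f"reference SSDE must be positive, got {ssde_old}")
    return (ssde_new - ssde_old) / ssde_old * 100.0
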