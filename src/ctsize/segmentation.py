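"""Patient body contouring on axial HU slices.

Two automated contouring algorithms are provided:

* :func:`contour_body_new` — threshold at -200 HU, label connected
  components, fill each component's outer contour, keep the six largest
  objects, drop objects whose centroid lies below the CT-table line
  (400 rows from the top on a 512-row matrix), and take the union of the
  survivors.  Separated body parts (a lowered arm, two legs) are all
  retained.
* :func:`contour_body_old` — the legacy variant that keeps only the
  single largest object after table removal, which under-segments
  multi-part cross-sections.

Components are 8-connected.  Hole filling makes interior cavities (lungs)
part of the body mask, as they must be for attenuation-weighted size
metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

log = logging.getLogger(__name__)

__all__ = [
    "ComponentInfo",
    "BodyMask",
    "ContourParams",
    "NoPatientFoundError",
    "threshold_image",
    "label_components",
    "select_largest",
    "remove_table",
    "contour_body_new",
    "contour_body_old",
]

DEFAULT_THRESHOLD_HU = -200.0
DEFAULT_K_OBJECTS = 6
DEFAULT_TABLE_Y_LIMIT_PX = 400
#: matrix size the table line is defined on; other sizes scale proportionally
REFERENCE_N_ROWS = 512


class NoPatientFoundError(ValueError):
    """Raised when every candidate object lies below the table line."""


@dataclass(frozen=True)
class ComponentInfo:
    """One labeled object with its outer contour filled.

    ``area_px`` and ``centroid_rc`` refer to the filled region, so a
    chest contour's area includes the lung cavities.
    """

    label: int
    area_px: int
    centroid_rc: tuple[float, float]
    filled_mask: np.ndarray

    def __post_init__(self):
        if self.area_px < 1:
            raise ValueError("component must contain at least one pixel")
        if self.area_px != int(self.filled_mask.sum()):
            raise ValueError("area_px inconsistent with filled_mask")


@dataclass(frozen=True)
class ContourParams:
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    k_objects: int = DEFAULT_K_OBJECTS
    table_y_limit_px: int = DEFAULT_TABLE_Y_LIMIT_PX


@dataclass
class BodyMask:
    """Final patient ROI with provenance of kept/discarded objects."""

    mask: np.ndarray
    retained: list[ComponentInfo] = field(default_factory=list)
    removed_as_table: list[ComponentInfo] = field(default_factory=list)
    params: ContourParams | None = None


def threshold_image(hu: np.ndarray, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """Binary foreground: HU >= threshold (inclusive, default -200)."""
    hu = np.asarray(hu)
    if hu.size == 0:
        raise ValueError("empty image")
    return hu >= threshold_hu


def label_components(binary: np.ndarray) -> list[ComponentInfo]:
    """Label 8-connected components and fill each outer contour.

    Interior holes (background fully enclosed by a component) are
    absorbed into that component's ``filled_mask``; area and centroid
    are those of the filled region.  Returns an empty list for an
    all-background grid.
    """
    binary = np.asarray(binary, dtype=bool)
    labels = measure.label(binary, connectivity=2)
    out: list[ComponentInfo] = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        filled_bbox = ndimage.binary_fill_holes(region.image)
        filled = np.zeros(binary.shape, dtype=bool)
        filled[r0:r1, c0:c1] = filled_bbox
        rows, cols = np.nonzero(filled_bbox)
        centroid = (float(rows.mean()) + r0, float(cols.mean()) + c0)
        out.append(
            ComponentInfo(
                label=int(region.label),
                area_px=int(filled_bbox.sum()),
                centroid_rc=centroid,
                filled_mask=filled,
            )
        )
    return out


def select_largest(components: list[ComponentInfo], k: int = DEFAULT_K_OBJECTS) -> list[ComponentInfo]:
    """The ``min(k, len)`` largest components by filled area.

    Descending area; ties broken by ascending label for determinism.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ranked = sorted(components, key=lambda c: (-c.area_px, c.label))
    return ranked[:k]


def effective_table_limit(table_y_limit_px: int, n_rows: int) -> int:
    """Table line scaled from the 512-row reference to ``n_rows``."""
    return round(table_y_limit_px * n_rows / REFERENCE_N_ROWS)


def remove_table(
    components: list[ComponentInfo],
    n_rows: int,
    table_y_limit_px: int = DEFAULT_TABLE_Y_LIMIT_PX,
) -> tuple[list[ComponentInfo], list[ComponentInfo]]:
    """Split components into (retained, removed-as-table).

    An object whose centroid row exceeds the (scaled) table line is
    treated as the CT couch and removed.  A retained component may still
    extend below the line — e.g. a large torso touching the couch pad —
    which is logged but kept, since the centroid rule decides.
    """
    limit = effective_table_limit(table_y_limit_px, n_rows)
    retained, removed = [], []
    for c in components:
        if c.centroid_rc[0] > limit:
            removed.append(c)
            log.info(
                "removed table-like object: label=%d area=%d px centroid_row=%.1f (> %d)",
                c.label, c.area_px, c.centroid_rc[0], limit,
            )
        else:
            retained.append(c)
            rows = np.nonzero(c.filled_mask.any(axis=1))[0]
            if rows.size and rows[-1] > limit:
                log.warning(
                    "retained object label=%d extends below the table line "
                    "(max row %d > %d); centroid rule keeps it",
                    c.label, rows[-1], limit,
                )
    if not retained:
        raise NoPatientFoundError("no patient found above table line")
    return retained, removed


def _contour(hu: np.ndarray, params: ContourParams, keep_all: bool) -> BodyMask:
    binary = threshold_image(hu, params.threshold_hu)
    components = label_components(binary)
    candidates = select_largest(components, params.k_objects)
    retained, removed = remove_table(
        candidates, n_rows=binary.shape[0], table_y_limit_px=params.table_y_limit_px
    )
    if not keep_all:
        retained = select_largest(retained, 1)
    mask = np.zeros(binary.shape, dtype=bool)
    for c in retained:
        mask |= c.filled_mask
    return BodyMask(mask=mask, retained=retained, removed_as_table=removed, params=params)


def contour_body_new(hu: np.ndarray, params: ContourParams | None = None) -> BodyMask:
    """Multi-object body contour: union of the six largest non-table objects."""
    return _contour(hu, params or ContourParams(), keep_all=True)


def contour_body_old(hu: np.ndarray, params: ContourParams | None = None) -> BodyMask:
    """Legacy body contour: the single largest non-table object only."""
    return _contour(hu, params or ContourParams(), keep_all=False)
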