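"""Synthetic axial CT phantoms with closed-form ground truth.

Scenes are built from elliptical "body parts" on an air background
(-1000 HU): a soft-tissue torso, optional lung cavities nested inside
it, optional separated arms or legs, and an optional dense table strip
near the image bottom.  Because every region is an ellipse, the exact
area and area-weighted mean HU — and therefore the exact
water-equivalent diameter — follow in closed form, giving an analytic
oracle against which the raster pipeline can be validated.

Five library scenes mirror the cross-sections that matter for
multi-object contouring: a pelvis (one object), a chest with both arms
raised (one object, two lung holes), a chest with one or two arms
lowered (two / three objects) and two separated legs (two comparable
objects).

Rasterization is pixel-center point-in-ellipse with no anti-aliasing,
so the discrete mask is unambiguous and deterministic for a fixed spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_dicom import CTSlice
from .segmentation import BodyMask, effective_table_limit

__all__ = [
    "Ellipse",
    "BodyPart",
    "TableStrip",
    "PhantomSpec",
    "render",
    "analytic_dw",
    "analytic_area_cm2",
    "scene_library",
    "water_ellipse_spec",
    "SCENE_NAMES",
]

SCENE_NAMES = (
    "pelvis",
    "chest_arms_up",
    "chest_one_arm_down",
    "chest_two_arms_down",
    "two_legs",
)

SOFT_TISSUE_HU = 40.0
LUNG_HU = -800.0
TABLE_HU = 200.0
AIR_HU = -1000.0


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in physical (cm) image coordinates.

    ``center_rc_cm`` is (row, col) measured from the image top-left;
    ``semi_axes_cm`` is (row semi-axis, col semi-axis).
    """

    center_rc_cm: tuple[float, float]
    semi_axes_cm: tuple[float, float]
    hu: float

    @property
    def area_cm2(self) -> float:
        return math.pi * self.semi_axes_cm[0] * self.semi_axes_cm[1]

    def contains(self, r_cm, c_cm) -> np.ndarray:
        dr = (np.asarray(r_cm) - self.center_rc_cm[0]) / self.semi_axes_cm[0]
        dc = (np.asarray(c_cm) - self.center_rc_cm[1]) / self.semi_axes_cm[1]
        return dr * dr + dc * dc <= 1.0

    def boundary_points(self, n: int = 64) -> np.ndarray:
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return np.stack(
            [
                self.center_rc_cm[0] + self.semi_axes_cm[0] * np.sin(t),
                self.center_rc_cm[1] + self.semi_axes_cm[1] * np.cos(t),
            ],
            axis=1,
        )


@dataclass(frozen=True)
class BodyPart:
    """A body ellipse with optional nested cavities (e.g. lungs)."""

    outline: Ellipse
    cavities: tuple[Ellipse, ...] = ()


@dataclass(frozen=True)
class TableStrip:
    """Horizontal dense strip emulating the CT couch near the image bottom."""

    top_row_cm: float
    thickness_cm: float = 1.2
    width_cm: float = 30.0
    hu: float = TABLE_HU

    @property
    def centroid_row_cm(self) -> float:
        return self.top_row_cm + self.thickness_cm / 2.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full scene description; the analytic oracle operates on this."""

    bodies: tuple[BodyPart, ...]
    table: TableStrip | None = None
    n_rows: int = 512
    n_cols: int = 512
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8)
    background_hu: float = AIR_HU
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 16 or self.n_cols < 16:
            raise ValueError("matrix must be at least 16x16")
        height = self.n_rows * self.pixel_spacing_mm[0] / 10.0
        width = self.n_cols * self.pixel_spacing_mm[1] / 10.0
        for body in self.bodies:
            e = body.outline
            if e.hu < -200.0:
                raise ValueError(
                    f"body HU {e.hu} below the -200 detection threshold"
                )
            r, c = e.center_rc_cm
            ar, ac = e.semi_axes_cm
            if not (0 < r - ar and r + ar < height and 0 < c - ac and c + ac < width):
                raise ValueError(f"body ellipse {e} not fully inside the grid")
            for cav in body.cavities:
                pts = cav.boundary_points()
                if not np.all(e.contains(pts[:, 0], pts[:, 1])):
                    raise ValueError(f"cavity {cav} not inside its body outline")
        if self.table is not None:
            limit_px = effective_table_limit(400, self.n_rows)
            centroid_px = self.table.centroid_row_cm / (self.pixel_spacing_mm[0] / 10.0)
            if centroid_px <= limit_px:
                raise ValueError(
                    f"table centroid at row {centroid_px:.0f} px is not below the "
                    f"table line ({limit_px} px)"
                )

    @property
    def field_cm(self) -> tuple[float, float]:
        return (
            self.n_rows * self.pixel_spacing_mm[0] / 10.0,
            self.n_cols * self.pixel_spacing_mm[1] / 10.0,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def render(spec: PhantomSpec, ctdi_vol_mGy: float | None = None) -> tuple[CTSlice, BodyMask]:
    """Rasterize a spec into an HU slice plus its ground-truth body mask.

    The mask is the union of the filled body outlines; cavities keep
    their own HU in the image but belong to the mask (lungs are part of
    the patient cross-section).  Raises if a body overlaps the table.
    """
    sr_cm = spec.pixel_spacing_mm[0] / 10.0
    sc_cm = spec.pixel_spacing_mm[1] / 10.0
    r_cm = (np.arange(spec.n_rows) + 0.5) * sr_cm
    c_cm = (np.arange(spec.n_cols) + 0.5) * sc_cm
    rr, cc = np.meshgrid(r_cm, c_cm, indexing="ij")

    hu = np.full((spec.n_rows, spec.n_cols), spec.background_hu, dtype=float)
    truth = np.zeros_like(hu, dtype=bool)
    for body in spec.bodies:
        outline = body.outline.contains(rr, cc)
        hu[outline] = body.outline.hu
        for cav in body.cavities:
            inside = cav.contains(rr, cc)
            hu[inside] = cav.hu
        truth |= outline

    if spec.table is not None:
        t = spec.table
        _, width = spec.field_cm
        c0 = (width - t.width_cm) / 2.0
        table_mask = (
            (rr >= t.top_row_cm)
            & (rr < t.top_row_cm + t.thickness_cm)
            & (cc >= c0)
            & (cc < c0 + t.width_cm)
        )
        if np.any(table_mask & truth):
            raise ValueError("table strip overlaps a body part")
        hu[table_mask] = t.hu

    ct = CTSlice(
        hu=hu,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        ctdi_vol_mGy=ctdi_vol_mGy,
        slice_index=0,
        source_id="synthetic",
    )
    return ct, BodyMask(mask=truth)


def analytic_area_cm2(spec: PhantomSpec) -> float:
    """Exact patient area: sum of filled body-outline areas (cavities included)."""
    return sum(b.outline.area_cm2 for b in spec.bodies)


def analytic_dw(spec: PhantomSpec) -> float:
    """Exact water-equivalent diameter from the continuous geometry.

    Bodies are assumed pairwise disjoint and cavities disjoint within
    their body, which every library scene satisfies.  Each region
    contributes water-equivalent area (HU/1000 + 1) * area, so

        D_w = 2 * sqrt( sum_regions (HU/1000 + 1) * A / pi ).
    """
    aw = 0.0
    for body in spec.bodies:
        cavity_area = sum(c.area_cm2 for c in body.cavities)
        aw += (body.outline.hu / 1000.0 + 1.0) * (body.outline.area_cm2 - cavity_area)
        for cav in body.cavities:
            aw += (cav.hu / 1000.0 + 1.0) * cav.area_cm2
    return 2.0 * math.sqrt(aw / math.pi)


def water_ellipse_spec(
    axes_cm: tuple[float, float],
    hu: float = 0.0,
    n_rows: int = 512,
    n_cols: int = 512,
    pixel_spacing_mm: tuple[float, float] = (0.8, 0.8),
) -> PhantomSpec:
    """A single uniform ellipse (full axis lengths in cm) centred in the grid."""
    height = n_rows * pixel_spacing_mm[0] / 10.0
    width = n_cols * pixel_spacing_mm[1] / 10.0
    body = BodyPart(
        Ellipse(
            center_rc_cm=(height / 2.0, width / 2.0),
            semi_axes_cm=(axes_cm[0] / 2.0, axes_cm[1] / 2.0),
            hu=hu,
        )
    )
    return PhantomSpec(bodies=(body,), n_rows=n_rows, n_cols=n_cols,
                       pixel_spacing_mm=pixel_spacing_mm)


# --- scene library ---------------------------------------------------------

# base geometry in cm; vertical (row) semi-axis first, then lateral (col)
_SCENE_CENTER_RC = (17.0, 20.48)
_TABLE = TableStrip(top_row_cm=34.6, thickness_cm=1.2, width_cm=30.0)

_TORSO_CHEST_UP = ((10.0, 11.5), SOFT_TISSUE_HU)
_LUNG = (5.5, 4.0)          # semi-axes of each lung cavity
_LUNG_OFFSET = (-0.5, 5.3)  # (dv, |dh|) from torso centre
_TORSO_ARMS_DOWN = ((7.5, 8.0), SOFT_TISSUE_HU)
_LUNG_SMALL = (4.0, 3.0)
_LUNG_SMALL_OFFSET = (-0.3, 3.7)
_ARM = (2.8, 2.2)
_ARM_OFFSET = (1.0, 10.9)   # lateral gap torso<->arm: 10.9 - 2.2 - 8.0 = 0.7 cm
_PELVIS = ((9.0, 12.0), SOFT_TISSUE_HU)
_LEG = (5.5, 4.5)
_LEG_OFFSET = (0.0, 5.7)


def _jitter(rng: np.random.Generator, semi: tuple[float, float]) -> tuple[float, float]:
    f = rng.uniform(0.97, 1.03, size=2)
    return (semi[0] * f[0], semi[1] * f[1])


def scene_library(name: str, size_scale: float = 1.0, seed: int = 0) -> PhantomSpec:
    """Parameterized spec for one of the five library scenes.

    ``size_scale`` scales every body dimension and position about the
    scene centre (0.5-1.5 supported); ``seed`` drives a small (<= 3%)
    deterministic jitter of axes and a sub-centimetre jitter of the
    scene centre, so cohorts of distinct but plausible subjects can be
    generated.  The CT table strip is part of every scene and is not
    scaled (the couch does not grow with the patient).
    """
    if name not in SCENE_NAMES:
        raise ValueError(f"unknown scene {name!r}; choose from {SCENE_NAMES}")
    if not 0.5 <= size_scale <= 1.5:
        raise ValueError(f"size_scale must be in [0.5, 1.5], got {size_scale}")
    rng = np.random.default_rng(seed)
    s = size_scale
    cy = _SCENE_CENTER_RC[0] + rng.uniform(-0.4, 0.4)
    cx = _SCENE_CENTER_RC[1] + rng.uniform(-0.4, 0.4)

    def ellipse(offset_vh, semi, hu):
        dv, dh = offset_vh
        return Ellipse(
            center_rc_cm=(cy + s * dv, cx + s * dh),
            semi_axes_cm=(s * semi[0], s * semi[1]),
            hu=hu,
        )

    bodies: list[BodyPart] = []
    if name == "pelvis":
        semi, hu = _PELVIS
        bodies.append(BodyPart(ellipse((0.0, 0.0), _jitter(rng, semi), hu)))
    elif name == "chest_arms_up":
        semi, hu = _TORSO_CHEST_UP
        lungs = tuple(
            ellipse((_LUNG_OFFSET[0], side * _LUNG_OFFSET[1]), _jitter(rng, _LUNG), LUNG_HU)
            for side in (-1, +1)
        )
        bodies.append(BodyPart(ellipse((0.0, 0.0), _jitter(rng, semi), hu), lungs))
    elif name in ("chest_one_arm_down", "chest_two_arms_down"):
        semi, hu = _TORSO_ARMS_DOWN
        lungs = tuple(
            ellipse(
                (_LUNG_SMALL_OFFSET[0], side * _LUNG_SMALL_OFFSET[1]),
                _jitter(rng, _LUNG_SMALL),
                LUNG_HU,
            )
            for side in (-1, +1)
        )
        bodies.append(BodyPart(ellipse((0.0, 0.0), _jitter(rng, semi), hu), lungs))
        sides = (+1,) if name == "chest_one_arm_down" else (-1, +1)
        for side in sides:
            bodies.append(
                BodyPart(
                    ellipse(
                        (_ARM_OFFSET[0], side * _ARM_OFFSET[1]),
                        _jitter(rng, _ARM),
                        SOFT_TISSUE_HU,
                    )
                )
            )
    elif name == "two_legs":
        for side in (-1, +1):
            bodies.append(
                BodyPart(
                    ellipse(
                        (_LEG_OFFSET[0], side * _LEG_OFFSET[1]),
                        _jitter(rng, _LEG),
                        SOFT_TISSUE_HU,
                    )
                )
            )
    return PhantomSpec(bodies=tuple(bodies), table=_TABLE, seed=seed)
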