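"""Lesion quantification: typed polygon annotations -> nine grading features.

A fundus image annotated with typed lesion polygons (hemorrhage HE, hard
exudate EX, soft exudate SE, aneurysm AN, new vessels NV) is summarised by
nine attributes: four area ratios ``R_HE, R_EX, R_SE, R_NV`` (total polygon
area of the type divided by the retinal area) and five counts
``N_HE, N_EX, N_SE, N_AN, N_NV``.  Aneurysms contribute a count only — their
areas are too small for a meaningful ratio.

The retina is modelled as a perfect disk whose radius is half the width of
the cropped image, so vertically clipped photographs (common in screening
sets) still yield a well-defined retinal area, and ratios are comparable
across source resolutions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("drgrade")

LESION_TYPES = ("HE", "EX", "SE", "AN", "NV")
#: lesion types for which an area ratio is part of the feature vector
RATIO_TYPES = ("HE", "EX", "SE", "NV")

FEATURE_NAMES = ("R_HE", "R_EX", "R_SE", "R_NV",
                 "N_HE", "N_EX", "N_SE", "N_AN", "N_NV")

LESION_LONG_NAMES = {
    "HE": "hemorrhage",
    "EX": "hard exudate",
    "SE": "soft exudate",
    "AN": "aneurysm",
    "NV": "new vessel",
}


class InvalidPolygonError(ValueError):
    """Raised for polygons with < 3 vertices or non-finite coordinates."""


@dataclass(frozen=True)
class Polygon:
    """Simple polygon in pixel coordinates (0-based, x right, y down).

    Closure is implicit: the last vertex connects back to the first.
    Coordinates are continuous floats; no pixel-grid rounding is applied.
    """

    vertices: tuple[tuple[float, float], ...]

    def __init__(self, vertices: Sequence[Sequence[float]]):
        verts = tuple((float(x), float(y)) for x, y in vertices)
        if len(verts) < 3:
            raise InvalidPolygonError(
                f"polygon needs at least 3 vertices, got {len(verts)}")
        for x, y in verts:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise InvalidPolygonError(f"non-finite vertex ({x}, {y})")
            if x < 0 or y < 0:
                logger.warning("polygon vertex (%g, %g) has negative "
                               "coordinate", x, y)
        object.__setattr__(self, "vertices", verts)

    @classmethod
    def from_flat(cls, flat: Sequence[float]) -> "Polygon":
        """Build from a flat COCO-style [x1, y1, x2, y2, ...] list."""
        if len(flat) % 2 != 0:
            raise InvalidPolygonError(
                f"flat coordinate list has odd length {len(flat)}")
        return cls(list(zip(flat[0::2], flat[1::2])))

    def to_flat(self) -> list[float]:
        return [c for xy in self.vertices for c in xy]


@dataclass(frozen=True)
class LesionInstance:
    """One annotated lesion: its type and outline polygon."""

    lesion_type: str
    polygon: Polygon

    def __post_init__(self):
        if self.lesion_type not in LESION_TYPES:
            raise ValueError(
                f"unknown lesion type {self.lesion_type!r}; "
                f"expected one of {LESION_TYPES}")


@dataclass
class ImageAnnotation:
    """All lesion instances of one fundus image, plus its pixel dimensions.

    Width/height refer to the image *after* cropping to the retina; the
    retinal disk radius is width/2.
    """

    image_id: str
    width: float
    height: float
    instances: list[LesionInstance] = field(default_factory=list)

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"image {self.image_id!r}: non-positive dimensions "
                f"{self.width}x{self.height}")
        for inst in self.instances:
            for x, y in inst.polygon.vertices:
                if not (0 <= x <= self.width and 0 <= y <= self.height):
                    logger.warning(
                        "image %s: %s vertex (%g, %g) outside %gx%g frame",
                        self.image_id, inst.lesion_type, x, y,
                        self.width, self.height)
                    break


@dataclass(frozen=True)
class RetinaGeometry:
    """Retina-as-disk model: radius in pixels, area = radius^2 * pi."""

    radius: float
    area: float


@dataclass(frozen=True)
class FeatureVector:
    """The nine grading attributes.

    Ratios are dimensionless fractions of the retinal disk area; counts are
    non-negative integers.  A zero count for a type implies its ratio is
    exactly zero (no lesion, no area).
    """

    R_HE: float = 0.0
    R_EX: float = 0.0
    R_SE: float = 0.0
    R_NV: float = 0.0
    N_HE: int = 0
    N_EX: int = 0
    N_SE: int = 0
    N_AN: int = 0
    N_NV: int = 0

    def __post_init__(self):
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for t in RATIO_TYPES:
            if getattr(self, f"N_{t}") == 0 and getattr(self, f"R_{t}") != 0:
                # vectors quantified from annotations always satisfy this;
                # hand-built probe vectors may not, so warn rather than fail
                logger.warning("N_%s is 0 but R_%s = %g", t, t,
                               getattr(self, f"R_{t}"))

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES],
                        dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "FeatureVector":
        kw = dict(zip(FEATURE_NAMES, values))
        for n in ("N_HE", "N_EX", "N_SE", "N_AN", "N_NV"):
            kw[n] = int(round(kw[n]))
        return cls(**kw)


# ---------------------------------------------------------------------------
# area computations


def polygon_area(poly: Polygon) -> float:
    """Shoelace area of a polygon, |sum(x_j*y_{j+1} - y_j*x_{j+1})| / 2.

    The last vertex wraps around to the first.  The formula is applied
    unconditionally; for a self-intersecting outline it returns the absolute
    signed area (loops of opposite orientation cancel) and a warning is
    logged, since annotation polygons are expected to be simple.
    """
    pts = np.asarray(poly.vertices, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    signed = float(np.sum(x * yn - y * xn)) / 2.0
    return abs(signed)


def retina_area(cropped_width: float) -> RetinaGeometry:
    """Disk model of the retina from the cropped image width.

    The radius is half the cropped width; this stays correct for images whose
    top/bottom retinal caps are cut off, because clipping is vertical only.
    """
    if cropped_width <= 0:
        raise ValueError(f"cropped width must be positive, got {cropped_width}")
    radius = cropped_width / 2.0
    return RetinaGeometry(radius=radius, area=radius * radius * math.pi)


def lesion_ratio(instances: Iterable[LesionInstance],
                 retina: RetinaGeometry) -> float:
    """Total area of same-typed lesions divided by the retinal area.

    Overlapping polygons of one type are summed naively (each polygon's area
    counts in full); an empty list gives 0.
    """
    instances = list(instances)
    if not instances:
        return 0.0
    types = {inst.lesion_type for inst in instances}
    if len(types) > 1:
        raise ValueError(f"mixed lesion types in ratio input: {sorted(types)}")
    total = sum(polygon_area(inst.polygon) for inst in instances)
    ratio = total / retina.area
    if ratio > 1.0:
        logger.warning("lesion ratio %.4f exceeds 1: total %s area larger "
                       "than the retinal disk model", ratio, types.pop())
    return ratio


def build_features(annotation: ImageAnnotation,
                   retina: RetinaGeometry) -> FeatureVector:
    """Assemble the nine-feature vector of one annotated image.

    Counts are per-type instance counts; ratios cover HE, EX, SE and NV.
    AN contributes only a count.
    """
    by_type: dict[str, list[LesionInstance]] = {t: [] for t in LESION_TYPES}
    for inst in annotation.instances:
        if inst.lesion_type not in by_type:
            raise ValueError(
                f"unknown lesion type {inst.lesion_type!r} in image "
                f"{annotation.image_id!r}")
        by_type[inst.lesion_type].append(inst)

    kw: dict[str, float] = {}
    for t in LESION_TYPES:
        kw[f"N_{t}"] = len(by_type[t])
    for t in RATIO_TYPES:
        kw[f"R_{t}"] = lesion_ratio(by_type[t], retina)
    return FeatureVector(**kw)
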