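"""Planar contour arithmetic and slice-stack volumetry.

Short-axis cardiac measurements start from manually traced closed contours
on each image slice.  The volume of a structure (a ventricular cavity, the
myocardium, or the epicardial fat layer) is obtained by the stacked-slab
form of Simpson's rule: the net traced area of every slice is multiplied by
the effective slice spacing (slice thickness plus inter-slice gap) and the
slabs are summed from base to apex.  Mass follows by multiplying the volume
with a tissue density (0.92 g/ml for adipose tissue, 1.05 g/ml for
myocardium).

Coordinates are millimetres in the image plane; areas are mm², volumes ml
(= cm³ = 1000 mm³) and masses grams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "PHASES",
    "STRUCTURES",
    "ROLES",
    "FAT_DENSITY_G_PER_ML",
    "MYOCARDIAL_DENSITY_G_PER_ML",
    "MM3_PER_ML",
    "ContourValidationError",
    "EmptyMeasurementError",
    "Contour",
    "ContourStack",
    "VolumetricResult",
    "polygon_area",
    "slice_area",
    "stack_volume",
    "volume_to_mass",
]

PHASES = ("end_diastole", "end_systole")
STRUCTURES = ("lv_endo", "lv_epi", "rv_endo", "eat", "lge")
ROLES = ("outer", "hole")

#: density of adipose tissue used to convert fat volume to mass
FAT_DENSITY_G_PER_ML = 0.92
#: density of myocardium used to convert wall volume to mass
MYOCARDIAL_DENSITY_G_PER_ML = 1.05
MM3_PER_ML = 1000.0


class ContourValidationError(ValueError):
    """A contour or stack violates a geometric or structural invariant."""


class EmptyMeasurementError(ValueError):
    """No contour of the requested structure/phase exists anywhere in the stack."""


def _dedup_points(points: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate vertices and a closing vertex equal to the first."""
    if len(points) == 0:
        return points
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(points[1:] != points[:-1], axis=1)
    points = points[keep]
    if len(points) > 1 and np.array_equal(points[0], points[-1]):
        points = points[:-1]
    return points


@dataclass(frozen=True)
class Contour:
    """One closed planar tracing on one slice.

    Parameters
    ----------
    points
        Ordered (x, y) vertices in millimetres.  The polygon is implicitly
        closed; a repeated closing vertex and consecutive duplicates are
        removed before validation.
    slice_index
        Zero-based slice position, 0 = most basal slice.
    phase
        ``end_diastole`` or ``end_systole``.
    structure
        Which anatomical structure the tracing outlines.
    role
        ``outer`` for an enclosing boundary, ``hole`` for an excluded
        inner region (e.g. the epicardial border inside a fat ring).
    """

    points: np.ndarray
    slice_index: int
    phase: str
    structure: str
    role: str = "outer"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourValidationError(
                f"{self._where()}: points must be an (n, 2) array, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ContourValidationError(f"{self._where()}: non-finite coordinates")
        pts = _dedup_points(pts)
        object.__setattr__(self, "points", pts)
        if self.slice_index < 0:
            raise ContourValidationError(f"{self._where()}: negative slice index")
        if self.phase not in PHASES:
            raise ContourValidationError(f"{self._where()}: unknown phase {self.phase!r}")
        if self.structure not in STRUCTURES:
            raise ContourValidationError(
                f"{self._where()}: unknown structure {self.structure!r}"
            )
        if self.role not in ROLES:
            raise ContourValidationError(f"{self._where()}: unknown role {self.role!r}")
        if len(pts) < 3:
            raise ContourValidationError(
                f"{self._where()}: contour needs at least 3 distinct points, got {len(pts)}"
            )
        poly = Polygon(pts)
        if not poly.is_valid:
            raise ContourValidationError(f"{self._where()}: self-intersecting contour")
        if poly.area <= 0.0:
            raise ContourValidationError(f"{self._where()}: degenerate (zero-area) contour")

    def _where(self) -> str:
        return (
            f"contour(slice={self.slice_index}, structure={self.structure}, "
            f"phase={self.phase}, role={self.role})"
        )

    def as_polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass
class ContourStack:
    """All tracings of one subject plus the acquisition geometry."""

    contours: list[Contour]
    slice_thickness_mm: float
    inter_slice_gap_mm: float
    n_slices: int
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.slice_thickness_mm <= 0:
            raise ContourValidationError("slice_thickness_mm must be positive")
        if self.inter_slice_gap_mm < 0:
            raise ContourValidationError("inter_slice_gap_mm must be non-negative")
        if self.n_slices < 1:
            raise ContourValidationError("n_slices must be >= 1")
        for c in self.contours:
            if c.slice_index >= self.n_slices:
                raise ContourValidationError(
                    f"{c._where()}: slice index outside 0..{self.n_slices - 1}"
                )
        self._validate_holes()

    @property
    def slice_spacing_mm(self) -> float:
        """Effective slab height: thickness + gap, so gapped stacks tile the heart."""
        return self.slice_thickness_mm + self.inter_slice_gap_mm

    def _validate_holes(self) -> None:
        for c in self.contours:
            if c.role != "hole":
                continue
            outers = [
                o
                for o in self.contours
                if o.role == "outer"
                and o.slice_index == c.slice_index
                and o.structure == c.structure
                and o.phase == c.phase
            ]
            hole_poly = c.as_polygon()
            if not any(o.as_polygon().contains(hole_poly.representative_point()) for o in outers):
                raise ContourValidationError(
                    f"{c._where()}: hole not inside any outer contour of the same "
                    "slice/structure/phase"
                )

    def select(self, structure: str, phase: str) -> list[Contour]:
        return [c for c in self.contours if c.structure == structure and c.phase == phase]


@dataclass
class VolumetricResult:
    """Volume (and optionally mass) of one structure measured on a stack."""

    structure: str
    volume_ml: float
    density_g_per_ml: float | None = None
    mass_g: float | None = None
    per_slice_areas_mm2: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def with_mass(self, density_g_per_ml: float) -> "VolumetricResult":
        """Return a copy carrying ``mass_g = density × volume``."""
        return VolumetricResult(
            structure=self.structure,
            volume_ml=self.volume_ml,
            density_g_per_ml=density_g_per_ml,
            mass_g=volume_to_mass(self.volume_ml, density_g_per_ml),
            per_slice_areas_mm2=self.per_slice_areas_mm2,
        )


def polygon_area(contour: Contour) -> float:
    """Enclosed area of one contour in mm² (shoelace magnitude).

    Orientation-independent and strictly positive for a valid contour.
    """
    return float(contour.as_polygon().area)


def slice_area(contours_of_one_slice: Sequence[Contour]) -> float:
    """Net traced area of one slice: outer areas minus hole areas, in mm².

    An empty sequence is a legitimate empty slice and contributes zero.
    All contours must refer to the same slice, phase and structure.
    """
    contours = list(contours_of_one_slice)
    if not contours:
        return 0.0
    keys = {(c.slice_index, c.phase, c.structure) for c in contours}
    if len(keys) > 1:
        raise ContourValidationError(
            f"slice_area received contours from multiple slices/phases/structures: {sorted(keys)}"
        )
    outer = sum(polygon_area(c) for c in contours if c.role == "outer")
    holes = sum(polygon_area(c) for c in contours if c.role == "hole")
    net = outer - holes
    if net < 0:
        c = contours[0]
        raise ContourValidationError(
            f"slice {c.slice_index} ({c.structure}, {c.phase}): hole area {holes:.3f} mm² "
            f"exceeds outer area {outer:.3f} mm²"
        )
    return net


def stack_volume(stack: ContourStack, structure: str, phase: str) -> VolumetricResult:
    """Stacked-slab (modified Simpson's rule) volume of a structure in ml.

    Every slice contributes its net traced area times the slice spacing;
    slices without a tracing contribute zero.  Raises
    :class:`EmptyMeasurementError` when the structure/phase is absent from
    the whole stack, so a missing measurement never reads as a silent zero.
    """
    selected = stack.select(structure, phase)
    if not selected:
        raise EmptyMeasurementError(
            f"no {structure!r} contour at phase {phase!r} anywhere in stack "
            f"{stack.subject_id!r}"
        )
    areas = np.zeros(stack.n_slices)
    for idx in range(stack.n_slices):
        at_slice = [c for c in selected if c.slice_index == idx]
        areas[idx] = slice_area(at_slice)
    volume_ml = float(np.sum(areas) * stack.slice_spacing_mm / MM3_PER_ML)
    return VolumetricResult(
        structure=structure,
        volume_ml=volume_ml,
        per_slice_areas_mm2=areas,
    )


def volume_to_mass(volume_ml: float, density_g_per_ml: float) -> float:
    """Convert a volume to mass, ``mass = density × volume`` (g)."""
    if volume_ml < 0:
        raise ContourValidationError(f"negative volume: {volume_ml}")
    if density_g_per_ml <= 0:
        raise ContourValidationError(f"non-positive density: {density_g_per_ml}")
    return density_g_per_ml * volume_ml
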