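"""Synthetic short-axis contour phantoms with closed-form ground truth.

The phantom is a nested family of ellipsoids sharing a common centre and
long (z) axis: an endocardial cavity, an epicardial surface obtained by
adding a uniform wall thickness to each semi-axis, and an epicardial fat
shell obtained by adding a further fat thickness.  The base can be
truncated by a plane perpendicular to the long axis, mimicking the open
ventricular base.  At end-systole the cavity is a uniformly scaled copy of
the end-diastolic cavity, so the ground-truth ejection fraction is
``100·(1 − es_scale³)`` when the cavity is untruncated.

All ground-truth volumes come from the closed-form truncated-ellipsoid
integral, making the phantom an analytic oracle for the stacked-slab
volumetry.  An optional angular wedge restricts the fat shell to a range of
the ellipse's parametric angle, producing partial (crescent-shaped) fat
contours with hole-free geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    FAT_DENSITY_G_PER_ML,
    MYOCARDIAL_DENSITY_G_PER_ML,
    MM3_PER_ML,
    Contour,
    ContourStack,
)

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomError",
    "truncated_ellipsoid_volume_ml",
    "generate_phantom",
    "perturb_contours",
]


class PhantomError(ValueError):
    """The phantom specification cannot produce a valid contour stack."""


def truncated_ellipsoid_volume_ml(
    semi_axes_mm: tuple[float, float, float], z_cut_mm: float | None = None
) -> float:
    """Volume (ml) of the ellipsoid portion with z ≤ z_cut.

    For semi-axes (a, b, c) the cross-section at height z is an ellipse of
    area π·a·b·(1 − z²/c²); integrating from −c to min(c, z_cut) gives

        V = π·a·b·( z − z³/(3c²) + 2c/3 )  evaluated at z = min(c, z_cut).

    ``z_cut=None`` (or z_cut ≥ c) yields the full 4/3·π·a·b·c.
    """
    a, b, c = semi_axes_mm
    if min(a, b, c) <= 0:
        raise PhantomError(f"semi-axes must be positive, got {semi_axes_mm}")
    zh = c if z_cut_mm is None else min(c, z_cut_mm)
    if zh <= -c:
        return 0.0
    vol_mm3 = math.pi * a * b * (zh - zh**3 / (3 * c**2) + 2 * c / 3)
    return vol_mm3 / MM3_PER_ML


@dataclass
class PhantomSpec:
    """Parametric description of the ventricular phantom.

    fat_azimuth_range restricts the fat shell to a parametric-angle wedge
    (t0, t1) with 0 ≤ t0 < t1 ≤ 2π; ``None`` means a full circumferential
    shell.
    """

    endo_semi_axes_mm: tuple[float, float, float] = (30.0, 25.0, 20.0)
    wall_thickness_mm: float = 10.0
    fat_thickness_mm: float = 4.0
    basal_truncation_fraction: float = 0.0
    es_scale: float = 0.7
    slice_thickness_mm: float = 4.0
    inter_slice_gap_mm: float = 2.0
    vertices_per_contour: int = 128
    fat_azimuth_range: tuple[float, float] | None = None
    subject_id: str = "phantom"
    seed: int = 0

    def __post_init__(self) -> None:
        a, b, c = self.endo_semi_axes_mm
        if min(a, b, c) <= 0:
            raise PhantomError("endocardial semi-axes must be positive")
        if self.wall_thickness_mm <= 0:
            raise PhantomError("wall thickness must be positive")
        if self.fat_thickness_mm < 0:
            raise PhantomError("fat thickness must be non-negative")
        if not 0.0 <= self.basal_truncation_fraction < 1.0:
            raise PhantomError("basal truncation fraction must lie in [0, 1)")
        if not 0.0 < self.es_scale <= 1.0:
            raise PhantomError("es_scale must lie in (0, 1]")
        if self.slice_thickness_mm <= 0 or self.inter_slice_gap_mm < 0:
            raise PhantomError("invalid slice thickness/gap")
        if self.vertices_per_contour < 16:
            raise PhantomError("need at least 16 vertices per contour")
        if self.fat_azimuth_range is not None:
            t0, t1 = self.fat_azimuth_range
            if not (0.0 <= t0 < t1 <= 2 * math.pi):
                raise PhantomError("fat azimuth range must satisfy 0 <= t0 < t1 <= 2*pi")

    # nested surfaces -----------------------------------------------------
    @property
    def epi_semi_axes_mm(self) -> tuple[float, float, float]:
        a, b, c = self.endo_semi_axes_mm
        w = self.wall_thickness_mm
        return (a + w, b + w, c + w)

    @property
    def fat_outer_semi_axes_mm(self) -> tuple[float, float, float]:
        a, b, c = self.epi_semi_axes_mm
        f = self.fat_thickness_mm
        return (a + f, b + f, c + f)

    @property
    def z_cut_mm(self) -> float:
        """Basal truncation plane: a fraction of the outermost long extent removed."""
        c_out = self.fat_outer_semi_axes_mm[2]
        return c_out * (1.0 - 2.0 * self.basal_truncation_fraction)


@dataclass
class PhantomTruth:
    """Closed-form reference values for a phantom."""

    volumes_ml: dict = field(default_factory=dict)  # keyed (structure, phase)
    lv_mass_g: float = 0.0
    eat_mass_g: float = 0.0
    eat_volume_ml: float = 0.0
    lv_ef_pct: float = 0.0


def _cross_section(semi_axes: tuple[float, float, float], z: float) -> tuple[float, float] | None:
    """In-plane semi-axes of an ellipsoid cut at height z, or None outside."""
    a, b, c = semi_axes
    if abs(z) >= c:
        return None
    shrink = math.sqrt(1.0 - (z / c) ** 2)
    return a * shrink, b * shrink

def _ellipse_points(ax: float, ay: float, n: int) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return np.column_stack([ax * np.cos(t), ay * np.sin(t)])


def _wedge_points(
    outer: tuple[float, float], inner: tuple[float, float] | None, t_range: tuple[float, float], n: int
) -> np.ndarray:
    """Annular (or solid) sector between two concentric ellipse arcs."""
    t0, t1 = t_range
    t = np.linspace(t0, t1, n)
    arc_out = np.column_stack([outer[0] * np.cos(t), outer[1] * np.sin(t)])
    if inner is None:
        return np.vstack([arc_out, [[0.0, 0.0]]])
    arc_in = np.column_stack([inner[0] * np.cos(t[::-1]), inner[1] * np.sin(t[::-1])])
    return np.vstack([arc_out, arc_in])


def generate_phantom(spec: PhantomSpec) -> tuple[ContourStack, PhantomTruth]:
    """Slice the phantom into a contour stack and compute its analytic truth.

    Slices are sampled at mid-slab planes from the basal truncation plane
    down past the apex; slice index 0 is the most basal slice.  The
    returned truth holds closed-form volumes for every (structure, phase)
    that receives contours, plus fat/myocardial masses and the cavity
    ejection fraction.
    """
    spacing = spec.slice_thickness_mm + spec.inter_slice_gap_mm
    endo, epi, fat_out = (
        spec.endo_semi_axes_mm,
        spec.epi_semi_axes_mm,
        spec.fat_outer_semi_axes_mm,
    )
    z_top = spec.z_cut_mm
    z_bottom = -fat_out[2]
    extent = z_top - z_bottom
    if extent <= 0:
        raise PhantomError("truncation removes the entire phantom")
    n_slices = max(1, math.ceil(extent / spacing))
    s = spec.es_scale
    endo_es = (s * endo[0], s * endo[1], s * endo[2])
    n = spec.vertices_per_contour

    wedge = spec.fat_azimuth_range
    wedge_fraction = 1.0 if wedge is None else (wedge[1] - wedge[0]) / (2 * math.pi)

    contours: list[Contour] = []
    for idx in range(n_slices):
        z = z_top - (idx + 0.5) * spacing
        # end-diastolic cavity and epicardium, clipped at the basal plane
        if z <= spec.z_cut_mm:
            cs = _cross_section(endo, z)
            if cs:
                contours.append(Contour(_ellipse_points(*cs, n), idx, "end_diastole", "lv_endo"))
            cs_epi = _cross_section(epi, z)
            if cs_epi:
                contours.append(
                    Contour(_ellipse_points(*cs_epi, n), idx, "end_diastole", "lv_epi")
                )
            cs_fat = _cross_section(fat_out, z)
            if cs_fat:
                if wedge is None:
                    contours.append(
                        Contour(_ellipse_points(*cs_fat, n), idx, "end_diastole", "eat", "outer")
                    )
                    if cs_epi:
                        contours.append(
                            Contour(
                                _ellipse_points(*cs_epi, n), idx, "end_diastole", "eat", "hole"
                            )
                        )
                else:
                    contours.append(
                        Contour(
                            _wedge_points(cs_fat, cs_epi, wedge, n),
                            idx,
                            "end_diastole",
                            "eat",
                            "outer",
                        )
                    )
        # end-systolic cavity: uniformly scaled copy, basal plane scales too
        if z <= s * spec.z_cut_mm:
            cs_es = _cross_section(endo_es, z)
            if cs_es:
                contours.append(
                    Contour(_ellipse_points(*cs_es, n), idx, "end_systole", "lv_endo")
                )

    if not contours:
        raise PhantomError("slicing misses the phantom geometry entirely")

    stack = ContourStack(
        contours=contours,
        slice_thickness_mm=spec.slice_thickness_mm,
        inter_slice_gap_mm=spec.inter_slice_gap_mm,
        n_slices=n_slices,
        subject_id=spec.subject_id,
    )

    zc = spec.z_cut_mm
    v_endo_ed = truncated_ellipsoid_volume_ml(endo, zc)
    v_epi_ed = truncated_ellipsoid_volume_ml(epi, zc)
    v_fat_out = truncated_ellipsoid_volume_ml(fat_out, zc)
    v_endo_es = truncated_ellipsoid_volume_ml(endo_es, s * zc)
    v_eat = wedge_fraction * (v_fat_out - v_epi_ed)
    truth = PhantomTruth(
        volumes_ml={
            ("lv_endo", "end_diastole"): v_endo_ed,
            ("lv_endo", "end_systole"): v_endo_es,
            ("lv_epi", "end_diastole"): v_epi_ed,
            ("eat", "end_diastole"): v_eat,
        },
        lv_mass_g=MYOCARDIAL_DENSITY_G_PER_ML * (v_epi_ed - v_endo_ed),
        eat_mass_g=FAT_DENSITY_G_PER_ML * v_eat,
        eat_volume_ml=v_eat,
        lv_ef_pct=100.0 * (1.0 - v_endo_es / v_endo_ed),
    )
    return stack, truth


def perturb_contours(stack: ContourStack, observer_noise_sd_mm: float, seed: int) -> ContourStack:
    """Simulate observer tracing variability by radial vertex jitter.

    Each vertex is displaced along the ray from its contour's centroid by a
    zero-mean Gaussian offset (mm).  With sd = 0 the stack is copied
    unchanged.  Deterministic for a fixed seed.
    """
    if observer_noise_sd_mm < 0:
        raise PhantomError("noise sd must be non-negative")
    if observer_noise_sd_mm == 0.0:
        return ContourStack(
            contours=list(stack.contours),
            slice_thickness_mm=stack.slice_thickness_mm,
            inter_slice_gap_mm=stack.inter_slice_gap_mm,
            n_slices=stack.n_slices,
            subject_id=stack.subject_id,
        )
    rng = np.random.default_rng(seed)
    new_contours = []
    for c in stack.contours:
        pts = c.points
        centroid = pts.mean(axis=0)
        rel = pts - centroid
        radii = np.linalg.norm(rel, axis=1)
        radii = np.where(radii == 0, 1.0, radii)
        unit = rel / radii[:, None]
        offsets = rng.normal(0.0, observer_noise_sd_mm, size=len(pts))
        new_pts = centroid + rel + unit * offsets[:, None]
        new_contours.append(
            Contour(new_pts, c.slice_index, c.phase, c.structure, c.role)
        )
    return ContourStack(
        contours=new_contours,
        slice_thickness_mm=stack.slice_thickness_mm,
        inter_slice_gap_mm=stack.inter_slice_gap_mm,
        n_slices=stack.n_slices,
        subject_id=stack.subject_id,
    )
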