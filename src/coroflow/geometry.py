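"""Parametric stenosed-vessel geometry.

A vessel is described by a straight (optionally curved) centerline, a
smoothly varying lumen radius with a cosine-squared stenotic narrowing,
and a uniform-thickness wall.  The surface model is a stack of
cross-section rings (centerline point + lumen contour + outer wall
contour), the synthetic stand-in for a lumen/wall reconstruction from
intravascular imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


class VesselSpecError(ValueError):
    """Raised when a vessel specification violates its bounds."""


@dataclass
class VesselSpec:
    """Parametric description of a stenosed tubular vessel (mm units).

    Attributes
    ----------
    length : float
        Vessel length along the centerline, mm.
    base_radius : float
        Lumen radius of the healthy segment, mm.
    stenosis_severity : float
        Fractional diameter reduction at the throat, in [0, 1).
    stenosis_center : float
        Arclength position of the throat, mm.
    stenosis_length : float
        Axial extent of the narrowing, mm.
    wall_thickness : float
        Radial wall thickness, mm.
    taper : float
        Linear radius change per unit length (mm/mm), default 0.
    centerline_curvature : float, optional
        Radius of curvature of a circular-arc centerline, mm.  None
        means straight.
    n_rings : int
        Number of cross-section rings in the surface model.
    """

    length: float = 30.0
    base_radius: float = 1.5
    stenosis_severity: float = 0.4
    stenosis_center: float = 15.0
    stenosis_length: float = 10.0
    wall_thickness: float = 0.5
    taper: float = 0.0
    centerline_curvature: Optional[float] = None
    n_rings: int = 61

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.length <= 0:
            raise VesselSpecError(f"length must be > 0, got {self.length}")
        if self.base_radius <= 0:
            raise VesselSpecError(
                f"base_radius must be > 0, got {self.base_radius}"
            )
        if not (0.0 <= self.stenosis_severity < 1.0):
            raise VesselSpecError(
                "stenosis_severity must lie in [0, 1), got "
                f"{self.stenosis_severity}"
            )
        if self.wall_thickness <= 0:
            raise VesselSpecError(
                f"wall_thickness must be > 0, got {self.wall_thickness}"
            )
        if self.stenosis_severity > 0:
            lo = self.stenosis_center - self.stenosis_length / 2.0
            hi = self.stenosis_center + self.stenosis_length / 2.0
            if lo < 0.0 or hi > self.length:
                raise VesselSpecError(
                    "stenosis extent [{:.3g}, {:.3g}] mm must lie within "
                    "[0, {:.3g}] mm".format(lo, hi, self.length)
                )
        if self.n_rings < 2:
            raise VesselSpecError(f"n_rings must be >= 2, got {self.n_rings}")
        # radius must stay positive along the whole vessel
        r_ends = min(self.lumen_radius(0.0), self.lumen_radius(self.length))
        if r_ends <= 0:
            raise VesselSpecError("taper drives the lumen radius to <= 0")

    def lumen_radius(self, s) -> np.ndarray:
        """Lumen radius at arclength ``s`` (mm).

        The healthy radius is ``base_radius + taper*s``; the stenosis is a
        cosine-squared dip reaching a fractional diameter reduction of
        ``stenosis_severity`` at ``stenosis_center``.  The profile is C1
        along arclength, which hex meshing requires.
        """
        s = np.asarray(s, dtype=float)
        r = self.base_radius + self.taper * s
        if self.stenosis_severity > 0:
            half = self.stenosis_length / 2.0
            x = (s - self.stenosis_center) / self.stenosis_length
            inside = np.abs(s - self.stenosis_center) <= half
            dip = np.where(inside, np.cos(np.pi * x) ** 2, 0.0)
            r = r * (1.0 - self.stenosis_severity * dip)
        return r


@dataclass
class Ring:
    """One cross-section: centerline point plus lumen and wall contours."""

    center: np.ndarray          # (3,)
    lumen: np.ndarray           # (n, 3) ordered contour points
    wall: np.ndarray            # (n, 3) outer contour, same ordering
    arclength: float            # mm along the centerline
    lumen_radius: float         # mm
    normal: np.ndarray = field(default=None)  # centerline tangent


@dataclass
class SurfaceModel:
    """Ordered stack of cross-section rings describing lumen + wall."""

    rings: list
    spec: VesselSpec

    @property
    def arclengths(self) -> np.ndarray:
        return np.array([r.arclength for r in self.rings])

    @property
    def lumen_radii(self) -> np.ndarray:
        return np.array([r.lumen_radius for r in self.rings])

    def min_lumen_radius(self) -> float:
        return float(self.lumen_radii.min())


def _frame(spec: VesselSpec, s: np.ndarray):
    """Centerline points and tangents at arclengths ``s``.

    Straight vessels run along +z.  A curved centerline is a circular
    arc of the given radius of curvature in the x-z plane.
    """
    s = np.asarray(s, dtype=float)
    if spec.centerline_curvature is None:
        centers = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        tangents = np.tile([0.0, 0.0, 1.0], (len(s), 1))
    else:
        rc = float(spec.centerline_curvature)
        if rc <= 0:
            raise VesselSpecError("centerline_curvature must be > 0")
        phi = s / rc
        centers = np.column_stack(
            [rc * (1.0 - np.cos(phi)), np.zeros_like(s), rc * np.sin(phi)]
        )
        tangents = np.column_stack(
            [np.sin(phi), np.zeros_like(s), np.cos(phi)]
        )
    return centers, tangents


def build_vessel(spec: VesselSpec, n_contour: int = 64) -> SurfaceModel:
    """Build the lumen + wall surface model from a vessel spec.

    The lumen contour of each ring is a circle of the local lumen radius
    in the plane normal to the centerline; the wall contour is the same
    circle offset outward by ``wall_thickness``.
    """
    spec.validate()
    s = np.linspace(0.0, spec.length, spec.n_rings)
    radii = spec.lumen_radius(s)
    centers, tangents = _frame(spec, s)
    theta = np.linspace(0.0, 2.0 * np.pi, n_contour, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rings = []
    for k in range(spec.n_rings):
        t = tangents[k]
        # in-plane orthonormal basis (e1, e2, t); vessels bend in x-z so
        # e2 = +y is always valid
        e2 = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(e2, t)
        e1 /= np.linalg.norm(e1)
        ring_dirs = np.outer(cos_t, e1) + np.outer(sin_t, e2)
        lum = centers[k] + radii[k] * ring_dirs
        wal = centers[k] + (radii[k] + spec.wall_thickness) * ring_dirs
        rings.append(
            Ring(
                center=centers[k],
                lumen=lum,
                wall=wal,
                arclength=float(s[k]),
                lumen_radius=float(radii[k]),
                normal=t,
            )
        )
    return SurfaceModel(rings=rings, spec=spec)
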