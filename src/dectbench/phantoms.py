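"""Analytic digital phantoms.

Phantoms are compositions of analytic shapes (disks, axis-aligned ellipses)
with materials attached. Shapes may be nested: a shape's material occupies
its area minus the area of the shapes directly contained in it (replacement,
not superposition), so ray path lengths per material follow from simple
chord arithmetic.

Provided builders:

* ``make_acr_module_a`` -- the water cylinder QA phantom (200 mm diameter)
  with bone, polyethylene, acrylic, air (25 mm) and water (50 mm) inserts.
* ``make_calibration_phantom`` -- the two-configuration multi-energy
  calibration phantom (20 cm water cylinder, 2.86 cm calcium insert placed
  centrally or at the 9 o'clock position).
* ``make_water_cylinder`` -- plain water disks for vendor-style calibration.
* ``make_abdomen_surrogate`` -- elliptical water body with a fat ring and
  two bone disks, for position-consistency experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .physics import Material


class GeometryError(ValueError):
    """Phantom/ROI geometry is invalid or outside the field of view."""


# ---------------------------------------------------------------------------
# Shapes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Disk:
    """Circular cylinder cross-section. Coordinates in mm, isocenter origin."""

    center: tuple[float, float]
    radius: float
    material: Material

    def __post_init__(self):
        if self.radius <= 0:
            raise GeometryError("disk radius must be positive")

    @property
    def extent(self) -> float:
        """Largest distance from isocenter to any point of the shape (mm)."""
        return math.hypot(*self.center) + self.radius

    def shifted(self, dx: float, dy: float) -> "Disk":
        return replace(self, center=(self.center[0] + dx, self.center[1] + dy))

    def contains_shape(self, other) -> bool:
        d = math.hypot(other.center[0] - self.center[0],
                       other.center[1] - self.center[1])
        r = other.radius if isinstance(other, Disk) else max(other.semi_axes)
        return d + r < self.radius

    def chord_lengths(self, ox, oy, ux, uy):
        """Chord length (mm) of rays (origin, unit direction) through the disk."""
        cx = self.center[0] - ox
        cy = self.center[1] - oy
        proj = cx * ux + cy * uy
        d2 = cx * cx + cy * cy - proj * proj
        h2 = self.radius**2 - d2
        return 2.0 * np.sqrt(np.clip(h2, 0.0, None))


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned elliptical cross-section (semi-axes in mm)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # (a along x, b along y)

    material: Material = None

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise GeometryError("ellipse semi-axes must be positive")

    @property
    def extent(self) -> float:
        return math.hypot(*self.center) + max(self.semi_axes)

    def shifted(self, dx: float, dy: float) -> "Ellipse":
        return replace(self, center=(self.center[0] + dx, self.center[1] + dy))

    def contains_shape(self, other) -> bool:
        # conservative test in coordinates scaled by the outer semi-axes,
        # where this ellipse becomes the unit circle
        a, b = self.semi_axes
        dx = (other.center[0] - self.center[0]) / a
        dy = (other.center[1] - self.center[1]) / b
        if isinstance(other, Ellipse):
            oa, ob = other.semi_axes
        else:
            oa = ob = other.radius
        return math.hypot(dx, dy) + max(oa / a, ob / b) < 1.0

    def chord_lengths(self, ox, oy, ux, uy):
        a, b = self.semi_axes
        px = (ox - self.center[0]) / a
        py = (oy - self.center[1]) / b
        vx = ux / a
        vy = uy / b
        qa = vx * vx + vy * vy
        qb = px * vx + py * vy
        qc = px * px + py * py - 1.0
        disc = qb * qb - qa * qc
        # |t2 - t1| with t along the (unit) original ray direction
        return 2.0 * np.sqrt(np.clip(disc, 0.0, None)) / qa


# ---------------------------------------------------------------------------
# Phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Phantom:
    """Background shape plus non-overlapping (possibly nested) inserts."""

    background: Disk | Ellipse
    inserts: tuple = ()
    offset: tuple[float, float] = (0.0, 0.0)
    name: str = "phantom"

    def __post_init__(self):
        object.__setattr__(self, "inserts", tuple(self.inserts))
        for ins in self.inserts:
            if not self.background.contains_shape(ins) and not any(
                    o is not ins and o.contains_shape(ins) for o in self.inserts):
                raise GeometryError(
                    f"insert at {ins.center} not strictly inside its container")
        self._check_overlap()

    def _check_overlap(self):
        disks = [s for s in self.inserts if isinstance(s, Disk)]
        for i, a in enumerate(disks):
            for b in disks[i + 1:]:
                if a.contains_shape(b) or b.contains_shape(a):
                    continue  # nesting is allowed
                d = math.hypot(a.center[0] - b.center[0],
                               a.center[1] - b.center[1])
                if d < a.radius + b.radius:
                    raise GeometryError("inserts overlap")

    def shapes(self) -> list:
        """All shapes with the phantom offset applied, background first."""
        dx, dy = self.offset
        return [s.shifted(dx, dy) for s in (self.background, *self.inserts)]

    @property
    def extent(self) -> float:
        dx, dy = self.offset
        return max(s.shifted(dx, dy).extent for s in (self.background, *self.inserts))

    def with_offset(self, dx: float, dy: float) -> "Phantom":
        return replace(self, offset=(dx, dy))

    def materials(self) -> dict[str, Material]:
        out = {}
        for s in (self.background, *self.inserts):
            out[s.material.name] = s.material
        return out


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

# Default ACR module A layout: four 25 mm inserts at 60 mm radial offset on
# the diagonals, 50 mm water insert at the center. Only relative placement
# matters for the physics; positions are configurable via `insert_radius_mm`.
_ACR_ANGLES_DEG = {"bone": 45.0, "polyethylene": 135.0,
                   "acrylic": 225.0, "air": 315.0}


def make_acr_module_a(materials: dict[str, Material],
                      offset: tuple[float, float] = (0.0, 0.0),
                      insert_radius_mm: float = 60.0,
                      with_beads: bool = False) -> Phantom:
    """ACR CT accreditation phantom, module A (single slice)."""
    water = materials["water"]
    inserts = []
    for name, ang in _ACR_ANGLES_DEG.items():
        a = math.radians(ang)
        c = (insert_radius_mm * math.cos(a), insert_radius_mm * math.sin(a))
        inserts.append(Disk(center=c, radius=12.5, material=materials[name]))
    inserts.append(Disk(center=(0.0, 0.0), radius=25.0, material=water))
    if with_beads:
        for a in (0.0, 90.0, 180.0, 270.0):
            r = math.radians(a)
            inserts.append(Disk(center=(97.0 * math.cos(r), 97.0 * math.sin(r)),
                                radius=0.5, material=materials["steel"]))
    return Phantom(background=Disk((0.0, 0.0), 100.0, water),
                   inserts=inserts, offset=offset, name="acr_module_a")


def make_calibration_phantom(materials: dict[str, Material],
                             config: str = "all-water",
                             hole_radius_mm: float = 60.0) -> Phantom:
    """Multi-energy calibration phantom: 20 cm water cylinder, one optional
    calcium insert (diameter 2.86 cm) at the center or the 9 o'clock hole."""
    water = materials["water"]
    calcium = materials["calcium"]
    bg = Disk((0.0, 0.0), 100.0, water)
    if config == "all-water":
        inserts = ()
    elif config == "central-calcium":
        inserts = (Disk((0.0, 0.0), 14.3, calcium),)
    elif config == "offset-calcium":
        inserts = (Disk((-hole_radius_mm, 0.0), 14.3, calcium),)
    else:
        raise ValueError(f"unknown calibration configuration {config!r}")
    return Phantom(background=bg, inserts=inserts,
                   name=f"calibration_{config}")


def make_water_cylinder(materials: dict[str, Material],
                        diameter_mm: float) -> Phantom:
    """Plain centered water disk of the given diameter."""
    return Phantom(background=Disk((0.0, 0.0), diameter_mm / 2.0,
                                   materials["water"]),
                   name=f"water_{diameter_mm:.0f}mm")


def make_abdomen_surrogate(materials: dict[str, Material],
                           offset: tuple[float, float] = (0.0, 0.0)) -> Phantom:
    """Elliptical abdomen-like phantom: 400 x 300 mm fat-ringed water body
    with two bone disks (vertebra-like and rib-like)."""
    fat = materials["adipose"]
    water = materials["water"]
    bone = materials["bone"]
    outer = Ellipse((0.0, 0.0), (200.0, 150.0), material=fat)
    body = Ellipse((0.0, 0.0), (175.0, 125.0), material=water)
    spine = Disk((0.0, -75.0), 15.0, material=bone)
    rib = Disk((120.0, 40.0), 8.0, material=bone)
    return Phantom(background=outer, inserts=(body, spine, rib),
                   offset=offset, name="abdomen_surrogate")
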