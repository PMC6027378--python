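"""Parametric scaffold-unit geometry and its voxelization.

The simulated volume is the cubic pore ("unit") of edge 2r enclosed by four
fibers of an orthogonal fibrous scaffold.  Each fiber presents a circular
cap that bulges into the unit from one of the four lateral faces; the cap
is parameterised by its sagitta: the displacement ``delta`` of an indicator
point from the mid-point of the nearest cube edge.  With the chord pinned
to the full cube edge ``2r``, the sagitta fixes the fiber diameter through
the sagitta relation

    D = (r**2 + delta**2) / delta,

which attains its minimum D = 2r at delta = r (fiber inscribed in the
unit) and diverges as delta -> 0 (flat wall).

Axis convention: perfusion flow runs along +x.  The primary (cultured)
fiber pair bulges into the unit from the top and bottom faces with axes
across the flow: its caps are circles in the (x, z) plane with chord along
x, forming the converging-diverging bumps whose downstream velocity drop
drives the design problem.  The secondary pair runs along the flow axis:
its caps are circles in the (y, z) cross-section plane with chord along z,
invariant in x, so these fibers act as rails that set the free flow
cross-section (each appears as a circular segment in every cross-section,
which is how the narrowest-section areas are reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np

__all__ = [
    "FACES",
    "UnitDesign",
    "VoxelDomain",
    "GeometryMetrics",
    "OccludedDomainError",
    "diameter_from_delta",
    "delta_from_diameter",
    "attachment_area",
    "voxelize",
    "min_cross_section",
    "design_metrics",
]

#: Face names of the unit cube that can carry a fiber cap.
FACES = ("top", "bottom", "front", "back")

UM_TO_M = 1e-6
UM2_TO_M2 = 1e-12


class OccludedDomainError(RuntimeError):
    """The fiber caps block every flow path through the unit."""


def diameter_from_delta(delta: float, r: float) -> float:
    """Fiber diameter [um] from an indicator-point displacement [um].

    Sagitta relation D = (r^2 + delta^2)/delta for a cap of chord 2r and
    sagitta delta.  ``delta = 0`` is the flat-wall sentinel and returns
    ``math.inf``; values outside [0, r] are rejected.
    """
    if r <= 0:
        raise ValueError("half-edge r must be positive")
    if delta == 0:
        return math.inf
    if delta < 0 or delta > r:
        raise ValueError(f"displacement must lie in [0, r]; got {delta}")
    return (r * r + delta * delta) / delta


def delta_from_diameter(D: float, r: float) -> float:
    """Displacement [um] whose cap of chord 2r has diameter ``D`` [um].

    Inverse sagitta relation; returns the smaller root
    ``(D - sqrt(D^2 - 4 r^2)) / 2`` so that
    ``diameter_from_delta(delta_from_diameter(D)) == D``.
    ``D = inf`` maps back to the flat-wall sentinel 0.
    """
    if r <= 0:
        raise ValueError("half-edge r must be positive")
    if math.isinf(D):
        return 0.0
    if D < 2 * r:
        raise ValueError(
            f"no real sagitta for D < 2r (D={D}, r={r}); the cap cannot "
            "fit a chord of 2r")
    disc = D * D - 4.0 * r * r
    # smaller quadratic root in cancellation-free form
    return 2.0 * r * r / (D + math.sqrt(disc))


def attachment_area(D: float, chord: float, span: float) -> float:
    """Cultured surface area [m^2] of one cap exposed inside the unit.

    The cap is a cylindrical surface of diameter ``D`` [um] cut by a chord
    ``chord`` [um] and extruded over ``span`` [um] along the fiber axis:
    area = arc * span with arc = D * asin(chord / D).  For the flat-wall
    limit (``D = inf``) the arc degenerates to the chord.
    """
    if chord <= 0 or span <= 0:
        raise ValueError("chord and span must be positive")
    if math.isinf(D):
        return chord * span * UM2_TO_M2
    if D < chord:
        raise ValueError(f"diameter {D} shorter than chord {chord}")
    arc = D * math.asin(chord / D)
    return arc * span * UM2_TO_M2


@dataclass(frozen=True)
class UnitDesign:
    """Parametric four-fiber scaffold unit.

    Parameters
    ----------
    r : half-edge of the imaginary cube [um].
    delta_y : shared displacement of indicator points 1 and 2 [um];
        controls the primary (top/bottom) fiber pair.  0 = flat wall.
    delta_z : shared displacement of indicator points 3 and 4 [um];
        controls the secondary (front/back) pair.
    cultured_surfaces : faces whose cap carries the initial cell monolayer.
    """

    r: float = 100.0
    delta_y: float = 0.0
    delta_z: float = 0.0
    cultured_surfaces: tuple = ("bottom",)

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("half-edge r must be positive")
        for name, d in (("delta_y", self.delta_y), ("delta_z", self.delta_z)):
            if d < 0 or d > self.r:
                raise ValueError(f"{name} must lie in [0, r]; got {d}")
        bad = set(self.cultured_surfaces) - set(FACES)
        if bad:
            raise ValueError(f"unknown cultured surfaces: {sorted(bad)}")
        object.__setattr__(self, "cultured_surfaces",
                           tuple(self.cultured_surfaces))

    @property
    def edge(self) -> float:
        """Cube edge 2r [um]."""
        return 2.0 * self.r

    @property
    def d_primary(self) -> float:
        """Diameter of the top/bottom fiber pair [um] (inf = flat wall)."""
        return diameter_from_delta(self.delta_y, self.r)

    @property
    def d_secondary(self) -> float:
        """Diameter of the front/back fiber pair [um] (inf = flat wall)."""
        return diameter_from_delta(self.delta_z, self.r)

    @property
    def alpha(self) -> float:
        """Approximate attachment angle [degrees] between touching fibers.

        Reported as the tangent-chord angle of the primary cap at the cube
        edge where the two fiber families meet, asin(2r / D1).  Descriptive
        output only; it enters no downstream computation.
        """
        D = self.d_primary
        if math.isinf(D):
            return 0.0
        return math.degrees(math.asin(self.edge / D))

    def delta_of(self, face: str) -> float:
        if face in ("top", "bottom"):
            return self.delta_y
        if face in ("front", "back"):
            return self.delta_z
        raise ValueError(f"unknown face {face!r}")


# voxel phase labels
FLUID, SOLID, BIOMASS = 0, 1, 2


@dataclass
class VoxelDomain:
    """Uniformly voxelized simulation domain for one scaffold unit.

    ``labels`` holds one phase tag per voxel (0 fluid, 1 solid, 2 biomass);
    ``spacing_um`` is the voxel edge per axis [um]; flow runs along axis 0
    (+x).  ``occluded`` is set when some cross-section normal to the flow
    axis is completely solid (no through-path exists).
    """

    labels: np.ndarray
    spacing_um: tuple
    design: UnitDesign | None = None
    flow_axis: int = 0
    occluded: bool = False

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def spacing_m(self) -> tuple:
        return tuple(s * UM_TO_M for s in self.spacing_um)

    @property
    def fluid(self) -> np.ndarray:
        return self.labels == FLUID

    @property
    def solid(self) -> np.ndarray:
        return self.labels == SOLID

    @property
    def biomass(self) -> np.ndarray:
        return self.labels == BIOMASS

    @property
    def flow(self) -> np.ndarray:
        """Voxels the medium can occupy (fluid + biomass)."""
        return self.labels != SOLID

    def cell_centers_um(self):
        """Voxel-center coordinate arrays (1-D per axis), in um."""
        return tuple(
            (np.arange(n) + 0.5) * h
            for n, h in zip(self.labels.shape, self.spacing_um))

    def voxel_volume_m3(self) -> float:
        hx, hy, hz = self.spacing_m
        return hx * hy * hz

    def free_area_profile_m2(self) -> np.ndarray:
        """Open (non-solid) area of each cross-section normal to the flow."""
        _, hy, hz = self.spacing_m
        free = np.count_nonzero(self.labels != SOLID, axis=(1, 2))
        return free * hy * hz


def _cap_mask(U, V, r, delta, side):
    """Solid mask of one cap in its cross-section plane.

    ``U`` is the coordinate along the chord (the flow direction), ``V`` the
    coordinate along the sagitta; ``side`` is -1 for the cap on the low-V
    face, +1 for the high-V face.  Coordinates in um.
    """
    if delta == 0:
        return np.zeros(np.broadcast(U, V).shape, dtype=bool)
    D = diameter_from_delta(delta, r)
    R = D / 2.0
    L = 2.0 * r
    vc = (delta - R) if side < 0 else (L - delta + R)
    return (U - r) ** 2 + (V - vc) ** 2 <= R * R


def _shell_mask(U, V, r, delta, side, dc):
    """Mask of the dc-thick layer over one cap surface (outside the solid)."""
    L = 2.0 * r
    if delta == 0:
        v = V if side < 0 else (L - V)
        return v <= dc
    D = diameter_from_delta(delta, r)
    R = D / 2.0
    vc = (delta - R) if side < 0 else (L - delta + R)
    rho2 = (U - r) ** 2 + (V - vc) ** 2
    return (rho2 > R * R) & (rho2 <= (R + dc) ** 2)


def voxelize(design: UnitDesign, resolution: int, dc_um: float = 13.0,
             on_occluded: str = "flag") -> VoxelDomain:
    """Discretise a unit design onto a uniform cubic voxel grid.

    Parameters
    ----------
    design : the parametric unit.
    resolution : voxels per cube edge (>= 8).
    dc_um : thickness of the initial biomass monolayer shell [um], laid
        over the caps named in ``design.cultured_surfaces``.
    on_occluded : ``"flag"`` records a blocked unit in ``domain.occluded``;
        ``"error"`` raises :class:`OccludedDomainError` instead.  A unit is
        blocked when some cross-section normal to the flow is fully solid,
        which happens e.g. for tangent inscribed fibers (delta = r on both
        opposite faces).

    A voxel is solid when its center lies inside any cap; biomass when it
    lies in the dc shell of a cultured cap (and is not solid); fluid
    otherwise.
    """
    if resolution < 8:
        raise ValueError("resolution must be at least 8 voxels per edge")
    if on_occluded not in ("flag", "error"):
        raise ValueError("on_occluded must be 'flag' or 'error'")
    r = design.r
    L = design.edge
    h = L / resolution
    c = (np.arange(resolution) + 0.5) * h
    X = c[:, None, None]
    Y = c[None, :, None]
    Z = c[None, None, :]

    solid = np.zeros((resolution,) * 3, dtype=bool)
    # primary pair (axes across the flow): caps in (x, z), chord along x;
    # bottom = low z, top = high z.  These are the converging-diverging
    # bumps the flow passes over.
    solid |= _cap_mask(X, Z, r, design.delta_y, -1)
    solid |= _cap_mask(X, Z, r, design.delta_y, +1)
    # secondary pair (axes along the flow): caps in (y, z), chord along z,
    # invariant in x.  These rails set the free cross-section; a single
    # such cap appears as a circular segment in every cross-section.
    solid |= _cap_mask(Z, Y, r, design.delta_z, -1)
    solid |= _cap_mask(Z, Y, r, design.delta_z, +1)

    shell = np.zeros_like(solid)
    for face in design.cultured_surfaces:
        d = design.delta_of(face)
        if face == "bottom":
            shell |= _shell_mask(X, Z, r, d, -1, dc_um)
        elif face == "top":
            shell |= _shell_mask(X, Z, r, d, +1, dc_um)
        elif face == "back":
            shell |= _shell_mask(Z, Y, r, d, -1, dc_um)
        elif face == "front":
            shell |= _shell_mask(Z, Y, r, d, +1, dc_um)
    shell &= ~solid

    labels = np.zeros(solid.shape, dtype=np.int8)
    labels[solid] = SOLID
    labels[shell] = BIOMASS

    blocked = bool(np.any(np.all(solid, axis=(1, 2))))
    if blocked and on_occluded == "error":
        raise OccludedDomainError(
            "occluded domain: a cross-section normal to the flow axis is "
            "completely solid")
    return VoxelDomain(labels=labels, spacing_um=(h, h, h), design=design,
                       flow_axis=0, occluded=blocked)


def min_cross_section(domain: VoxelDomain) -> float:
    """Minimum open flow area [m^2] over cross-sections normal to the flow."""
    return float(domain.free_area_profile_m2().min())


@dataclass(frozen=True)
class GeometryMetrics:
    """Reported geometric indicators of one unit design."""

    attachment_area: float      # cultured cap surface area [m^2]
    min_cross_section: float    # narrowest open flow area [m^2]
    effective_curvature: float  # 1/D of the cultured (primary) fiber [1/um]


def design_metrics(design: UnitDesign,
                   domain: VoxelDomain | None = None,
                   resolution: int = 64) -> GeometryMetrics:
    """Compute the geometric indicators of a design.

    The attachment area sums the cap-arc areas of all cultured faces
    (chord = span = cube edge).  The minimum cross-section is measured on
    the voxelized domain (built at ``resolution`` when not supplied).
    Effective curvature is 1/D of the primary fiber (0 for a flat wall).
    """
    L = design.edge
    area = 0.0
    for face in design.cultured_surfaces:
        D = diameter_from_delta(design.delta_of(face), design.r)
        area += attachment_area(D, L, L)
    if domain is None:
        domain = voxelize(design, resolution)
    D1 = design.d_primary
    curvature = 0.0 if math.isinf(D1) else 1.0 / D1
    return GeometryMetrics(attachment_area=area,
                           min_cross_section=min_cross_section(domain),
                           effective_curvature=curvature)
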