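"""Geometry of the frontal-plane lumbar spine plant.

The spine is a chain of two-node beam elements from a clamped sacrum node up
to L1.  Coordinates are planar: X vertical (gravity acts -X), Z lateral.
User-facing units are millimetres; the solvers work in SI internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["REFERENCE_NODES_MM", "EI_DEFAULT", "AREA_MM2_DEFAULT",
           "SpineGeometry", "PlantState", "SectionLoads", "build_geometry"]

#: default lumbar node coordinates (L5 .. L1), mm, in the laterally bent
#: reference posture the controllers defend
REFERENCE_NODES_MM = np.array(
    [[38.0, 0.4], [80.0, 1.7], [105.0, 3.0], [150.0, 6.2], [190.0, 10.0]]
)

EI_DEFAULT = 1.9          # flexural rigidity, N m^2
AREA_MM2_DEFAULT = 1225.0  # cross-section area, mm^2 (35 x 35 square)

#: level labels for the five intervertebral sections, bottom-up
LEVELS = ("L5-S1", "L4-L5", "L3-L4", "L2-L3", "L1-L2")


@dataclass
class SpineGeometry:
    """Beam-column geometry: sacrum base plus the lumbar nodes in order.

    ``node_coords_mm`` has shape (n_nodes, 2) with the base first; elements
    connect consecutive nodes.  ``lumbar_nodes`` maps each physical lumbar
    level (L5 .. L1, bottom-up) to its node index, so a refined mesh keeps
    track of where muscles insert and where loads act.
    """

    node_coords_mm: np.ndarray
    EI: float = EI_DEFAULT
    area_mm2: float = AREA_MM2_DEFAULT
    base_fixed: bool = True
    lumbar_nodes: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.node_coords_mm = np.atleast_2d(np.asarray(self.node_coords_mm, float))
        if self.lumbar_nodes is None:
            self.lumbar_nodes = np.arange(1, self.n_nodes)
        self.lumbar_nodes = np.asarray(self.lumbar_nodes, dtype=int)
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_coords_mm)

    @property
    def n_elements(self) -> int:
        return self.n_nodes - 1

    @property
    def coords_m(self) -> np.ndarray:
        return self.node_coords_mm * 1e-3

    @property
    def area_m2(self) -> float:
        return self.area_mm2 * 1e-6

    @property
    def EA(self) -> float:
        """Axial rigidity, N.  The section's second moment follows from a
        square of the stated area, and E = EI / I; only the product EA is
        ever used."""
        side = np.sqrt(self.area_m2)
        inertia = side**4 / 12.0
        return (self.EI / inertia) * self.area_m2

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("geometry needs at least a base and one node")
        if not (self.EI > 0.0):
            raise ValueError("EI must be positive")
        if not (self.area_mm2 > 0.0):
            raise ValueError("cross-section area must be positive")
        x = self.node_coords_mm[:, 0]
        if np.any(np.diff(x) <= 0.0):
            raise ValueError("node X coordinates must strictly increase from base to L1")
        if not self.base_fixed:
            raise ValueError("the sacrum node must be clamped")
        if np.any(self.lumbar_nodes <= 0) or np.any(self.lumbar_nodes >= self.n_nodes):
            raise ValueError("lumbar node indices out of range")

    # -- mesh refinement ----------------------------------------------------
    def refine(self, nsub: int = 2) -> "SpineGeometry":
        """Split every element into ``nsub`` equal parts (straight
        subdivision of the chord).  Lumbar node indices are remapped so
        loads, muscles and controllers stay attached to the same physical
        vertebrae."""
        if nsub < 1:
            raise ValueError("nsub must be >= 1")
        pts = [self.node_coords_mm[0]]
        new_lumbar = []
        for e in range(self.n_elements):
            p, q = self.node_coords_mm[e], self.node_coords_mm[e + 1]
            for s in range(1, nsub + 1):
                pts.append(p + (q - p) * s / nsub)
            if e + 1 in self.lumbar_nodes:
                new_lumbar.append(len(pts) - 1)
        return SpineGeometry(
            node_coords_mm=np.array(pts),
            EI=self.EI,
            area_mm2=self.area_mm2,
            lumbar_nodes=np.array(new_lumbar, dtype=int),
        )


def build_geometry(config: dict | None = None) -> SpineGeometry:
    """Construct a validated geometry from a configuration mapping.

    Recognised keys (all optional): ``nodes_mm`` - lumbar coordinates
    bottom-up excluding the base, ``EI``, ``area_mm2``.  Defaults are the
    reference laterally bent posture with EI = 1.9 N m^2 and a 1225 mm^2
    section.
    """
    config = dict(config or {})
    nodes = np.atleast_2d(np.asarray(config.pop("nodes_mm", REFERENCE_NODES_MM), float))
    ei = config.pop("EI", EI_DEFAULT)
    if ei is None:
        raise ValueError("EI missing from geometry configuration")
    area = config.pop("area_mm2", AREA_MM2_DEFAULT)
    if config:
        raise ValueError(f"unknown geometry keys: {sorted(config)}")
    coords = np.vstack([[0.0, 0.0], nodes])
    return SpineGeometry(node_coords_mm=coords, EI=float(ei), area_mm2=float(area))


@dataclass
class PlantState:
    """Kinematic state of the plant: per-node (uX, uZ, theta) displacement
    and velocity triplets relative to the reference posture, SI units.
    The base triplet is identically zero (clamped)."""

    displacements: np.ndarray
    velocities: np.ndarray
    time: float = 0.0

    @classmethod
    def zeros(cls, geometry: SpineGeometry) -> "PlantState":
        n = 3 * geometry.n_nodes
        return cls(np.zeros(n), np.zeros(n), 0.0)

    def node_positions_m(self, geometry: SpineGeometry) -> np.ndarray:
        return geometry.coords_m + self.displacements.reshape(-1, 3)[:, :2]

    def node_velocities_m(self) -> np.ndarray:
        return self.velocities.reshape(-1, 3)[:, :2]


@dataclass
class SectionLoads:
    """Internal force transmitted across one intervertebral section,
    decomposed in the local deformed frame: compression along the local
    tangent (positive = compressive) and shear perpendicular to it
    (positive toward +Z)."""

    level: str
    compression: float
    shear: float

    @property
    def follower_angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(abs(self.shear), self.compression)))
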