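"""Port-wall geometry for the multi-directional orienting task.

The behavioural arena is a vertical wall of 7 operant ports: one central port
(id 0) at the origin and six ports (ids 1-6) at the vertices of a regular
hexagon around it.  Movements between ports define six possible movement
directions (angles 0, 60, ..., 300 degrees, 0 = rightward, counterclockwise
positive).  The task uses 30 of the 42 ordered start-target pairs: every
ordered pair of adjacent ports (24 "short" trajectories) plus the six
vertex-to-opposite-vertex movements that pass through the central port
("long" trajectories).  Each direction is therefore shared by exactly five
trajectories (4 short + 1 long) but up to four different target ports, which
is what dissociates direction tuning from position tuning.

Distances are in mm.  The inter-port spacing is configurable (only relative
geometry matters downstream); the port radius is 11 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PORT_RADIUS_MM = 11.0
DEFAULT_SPACING_MM = 50.0

#: the six movement-direction labels, degrees CCW from rightward
DIRECTIONS = (0, 60, 120, 180, 240, 300)

#: the four oblique directions used by the four-direction session design
OBLIQUE_DIRECTIONS = (60, 120, 240, 300)


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Port:
    id: int
    x: float
    y: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass(frozen=True)
class PortWall:
    """Seven ports: center (id 0) at the origin plus a regular hexagon."""

    ports: tuple[Port, ...]
    port_radius: float = PORT_RADIUS_MM
    spacing: float = DEFAULT_SPACING_MM

    def port_xy(self, port_id: int) -> np.ndarray:
        return self.ports[port_id].xy

    def coordinates(self) -> np.ndarray:
        """(7, 2) array of port coordinates, row index = port id."""
        return np.array([[p.x, p.y] for p in self.ports])

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Unordered port pairs separated by exactly one spacing."""
        xy = self.coordinates()
        out = []
        for i in range(7):
            for j in range(i + 1, 7):
                d = np.linalg.norm(xy[i] - xy[j])
                if np.isclose(d, self.spacing):
                    out.append((i, j))
        return out

    def to_dict(self) -> dict:
        return {
            "spacing": self.spacing,
            "port_radius": self.port_radius,
            "ports": [{"id": p.id, "x": p.x, "y": p.y} for p in self.ports],
        }


@dataclass(frozen=True)
class Trajectory:
    start_port: int
    target_port: int
    direction: int          # degrees, one of DIRECTIONS
    distance_class: str     # "short" | "long"

    def __post_init__(self):
        if self.start_port == self.target_port:
            raise GeometryError("start and target ports must differ")


@dataclass(frozen=True)
class SessionDesign:
    name: str
    trajectories: tuple[Trajectory, ...]
    min_trials_per_condition: int = 8

    @property
    def directions(self) -> tuple[int, ...]:
        return tuple(sorted({t.direction for t in self.trajectories}))


def build_port_wall(spacing: float = DEFAULT_SPACING_MM) -> PortWall:
    """Center port at the origin plus six ports on a hexagon of radius ``spacing``."""
    if spacing <= 2 * PORT_RADIUS_MM:
        raise GeometryError(
            f"spacing {spacing} mm must exceed twice the port radius "
            f"({2 * PORT_RADIUS_MM} mm)"
        )
    ports = [Port(0, 0.0, 0.0)]
    for k in range(6):
        ang = np.deg2rad(60 * k)
        ports.append(Port(k + 1, spacing * np.cos(ang), spacing * np.sin(ang)))
    return PortWall(ports=tuple(ports), spacing=spacing)


def _direction_label(disp: np.ndarray) -> int:
    ang = np.rad2deg(np.arctan2(disp[1], disp[0])) % 360.0
    label = int(np.round(ang / 60.0)) % 6 * 60
    if not np.isclose((ang - label + 180) % 360 - 180, 0, atol=1e-6):
        raise GeometryError(f"displacement angle {ang} is not a task direction")
    return label


def enumerate_trajectories(wall: PortWall) -> list[Trajectory]:
    """All 30 legal trajectories: 24 ordered adjacent pairs + 6 long movements.

    Long movements connect opposite hexagon vertices and pass through the
    central port.
    """
    xy = wall.coordinates()
    out = []
    for i, j in wall.adjacent_pairs():
        for a, b in ((i, j), (j, i)):
            out.append(
                Trajectory(a, b, _direction_label(xy[b] - xy[a]), "short")
            )
    # opposite-vertex pairs: vertices k and k+3 (ids 1..6)
    for k in range(1, 7):
        opp = (k - 1 + 3) % 6 + 1
        out.append(Trajectory(k, opp, _direction_label(xy[opp] - xy[k]), "long"))
    return sorted(out, key=lambda t: (t.direction, t.distance_class, t.start_port))


def all_ordered_pairs(wall: PortWall) -> list[tuple[int, int]]:
    """The 42 ordered (start, target) pairs available before trajectory selection."""
    return [(i, j) for i in range(7) for j in range(7) if i != j]


def session_design(name: str, wall: PortWall | None = None) -> SessionDesign:
    """Build one of the three session designs.

    - ``reference``: all 24 short trajectories (4 per direction).
    - ``distance``: per direction, the two collinear spoke movements
      (center->vertex, vertex->center) plus the long vertex-to-vertex
      movement: 18 trajectories.
    - ``four_direction``: the 16 short trajectories of the four oblique
      directions.
    """
    wall = wall or build_port_wall()
    trajs = enumerate_trajectories(wall)
    if name == "reference":
        chosen = [t for t in trajs if t.distance_class == "short"]
    elif name == "distance":
        chosen = [
            t for t in trajs
            if t.distance_class == "long" or 0 in (t.start_port, t.target_port)
        ]
    elif name == "four_direction":
        chosen = [
            t for t in trajs
            if t.distance_class == "short" and t.direction in OBLIQUE_DIRECTIONS
        ]
    else:
        raise ValueError(f"unknown session design {name!r}")
    return SessionDesign(name=name, trajectories=tuple(chosen))


def variable_coordinates(
    start_port: int, target_port: int, wall: PortWall | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(start_xy, direction_xy, target_xy) in mm; target = start + direction."""
    wall = wall or build_port_wall()
    start_xy = wall.port_xy(start_port)
    target_xy = wall.port_xy(target_port)
    return start_xy, target_xy - start_xy, target_xy


def direction_unit(direction: int) -> np.ndarray:
    ang = np.deg2rad(direction)
    return np.array([np.cos(ang), np.sin(ang)])
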