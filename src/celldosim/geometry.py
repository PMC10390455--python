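"""Cell and micrometastasis geometry.

The cellular model is the standard MIRD concentric-sphere cell: a 10 µm
diameter cell with a concentric 8 µm diameter nucleus, unit-density water.
A micrometastasis is modelled as 13 such cells: a central cell plus the 12
equidistant nearest neighbours of a hexagonal close-packed (HCP) lattice
with 10 µm spacing, i.e. touching cells.

Radionuclide source compartments follow the MIRD cellular convention:
``cell_surface`` (zero-thickness membrane sphere), ``cytoplasm``,
``nucleus`` or ``whole_cell``; sampling is uniform by area or volume.
Coordinates are Cartesian µm with the (central) cell centred at the origin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Compartment",
    "CellModel",
    "ClusterModel",
    "hcp_neighbor_centers",
    "sample_source_points",
    "ray_sphere_intersect",
]


class Compartment(str, enum.Enum):
    CELL_SURFACE = "cell_surface"
    CYTOPLASM = "cytoplasm"
    NUCLEUS = "nucleus"
    WHOLE_CELL = "whole_cell"


@dataclass(frozen=True)
class CellModel:
    """Concentric-sphere cell (radii in µm, density in g/cm³)."""

    cell_radius: float = 5.0
    nucleus_radius: float = 4.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    density: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")
        if not self.density > 0:
            raise ValueError("density must be positive")

    @property
    def nucleus_mass_kg(self) -> float:
        """Mass of the nucleus: (4/3)π r³ × density."""
        volume_cm3 = 4.0 / 3.0 * np.pi * (self.nucleus_radius * 1e-4) ** 3
        return volume_cm3 * self.density * 1e-3

    def with_center(self, center) -> "CellModel":
        return CellModel(self.cell_radius, self.nucleus_radius,
                         tuple(float(c) for c in center), self.density)


def hcp_neighbor_centers(d: float = 10.0) -> np.ndarray:
    """The 12 nearest-neighbour sites of an HCP lattice, spacing ``d`` [µm].

    Canonical orientation: 6 hexagon sites in the z = 0 plane, plus two
    triangles of 3 at z = ±d·√(2/3) rotated 30° from the hexagon vertices.
    All 12 sit at distance d from the origin and the minimum distance among
    them is d.
    """
    if not d > 0:
        raise ValueError("lattice spacing must be positive")
    centers = []
    for k in range(6):
        phi = np.pi / 3.0 * k
        centers.append([np.cos(phi), np.sin(phi), 0.0])
    z = np.sqrt(2.0 / 3.0)
    rho = 1.0 / np.sqrt(3.0)
    for sign in (+1.0, -1.0):
        for k in range(3):
            phi = np.pi / 6.0 + 2.0 * np.pi / 3.0 * k
            centers.append([rho * np.cos(phi), rho * np.sin(phi), sign * z])
    return d * np.asarray(centers)


@dataclass(frozen=True)
class ClusterModel:
    """13-cell micrometastasis: central cell + 12 HCP nearest neighbours."""

    cells: tuple[CellModel, ...]
    lattice_spacing: float = 10.0

    @classmethod
    def hcp(cls, cell: CellModel | None = None, spacing: float = 10.0) -> "ClusterModel":
        cell = cell or CellModel()
        centers = np.vstack([[0.0, 0.0, 0.0], hcp_neighbor_centers(spacing)])
        return cls(tuple(cell.with_center(c) for c in centers), spacing)

    def __post_init__(self) -> None:
        if len(self.cells) != 13:
            raise ValueError("cluster must hold exactly 13 cells")
        centers = np.array([c.center for c in self.cells])
        dist = np.linalg.norm(centers[1:] - centers[0], axis=1)
        if not np.allclose(dist, self.lattice_spacing, rtol=1e-9):
            raise ValueError("neighbours must be equidistant from the centre")
        # no overlap: pairwise centre separation >= spacing
        diff = centers[:, None, :] - centers[None, :, :]
        pd = np.linalg.norm(diff, axis=-1)
        pd[np.diag_indices(13)] = np.inf
        if pd.min() < self.lattice_spacing * (1 - 1e-9):
            raise ValueError("cells overlap")

    @property
    def central_cell(self) -> CellModel:
        return self.cells[0]


def _isotropic_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    z = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - z**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def sample_source_points(
    cell: CellModel,
    compartment: Compartment | str,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """Uniform source positions [µm] in a compartment of ``cell``.

    Surface points are uniform on the membrane sphere; volume compartments
    use inverse-CDF radius sampling r = (a³ + u·(b³−a³))^(1/3) with
    isotropic directions.
    """
    compartment = Compartment(compartment)
    u = _isotropic_unit_vectors(rng, n)
    if compartment is Compartment.CELL_SURFACE:
        r = np.full(n, cell.cell_radius)
    else:
        lo, hi = {
            Compartment.NUCLEUS: (0.0, cell.nucleus_radius),
            Compartment.CYTOPLASM: (cell.nucleus_radius, cell.cell_radius),
            Compartment.WHOLE_CELL: (0.0, cell.cell_radius),
        }[compartment]
        r = np.cbrt(lo**3 + rng.random(n) * (hi**3 - lo**3))
    return np.asarray(cell.center) + u * r[:, None]


def ray_sphere_intersect(origin, direction, center, radius):
    """Forward half-line vs sphere: path lengths ``(s_in, s_out)`` or None.

    ``direction`` must be unit length.  The entry length is clipped to 0 for
    origins inside the sphere; tangent rays (zero discriminant) count as a
    miss, which is measure-zero for any continuous source.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if abs(np.dot(direction, direction) - 1.0) > 1e-9:
        raise ValueError("direction must be a unit vector")
    oc = origin - np.asarray(center, dtype=float)
    b = np.dot(oc, direction)
    c = np.dot(oc, oc) - radius * radius
    disc = b * b - c
    if disc <= 0.0:
        return None
    sq = np.sqrt(disc)
    s_in, s_out = -b - sq, -b + sq
    if s_out <= 0.0:
        return None
    return max(s_in, 0.0), s_out


def ray_sphere_intersect_many(origins, directions, center, radius):
    """Vectorised :func:`ray_sphere_intersect` (misses give s_in = s_out = 0)."""
    oc = np.asarray(origins, dtype=float) - np.asarray(center, dtype=float)
    d = np.asarray(directions, dtype=float)
    b = np.einsum("ij,ij->i", oc, d)
    c = np.einsum("ij,ij->i", oc, oc) - radius * radius
    disc = b * b - c
    hit = disc > 0.0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    s_in = np.clip(-b - sq, 0.0, None)
    s_out = np.clip(-b + sq, 0.0, None)
    s_in = np.where(hit, s_in, 0.0)
    s_out = np.where(hit, np.maximum(s_out, s_in), s_in)
    return s_in, s_out
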