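"""Elongated Kelvin-cell (tetrakaidecahedron) open-cell foam geometry.

The idealized foam cell is an elongated tetrakaidecahedron: 14 faces
(8 hexagons, 4 diamonds, 2 squares), 24 vertices and 36 edges.  The cell is
parametrized by the rise half-angle ``theta`` of the inclined hexagon edges,
the hexagon edge length ``L`` and a ligament section radius ``r``.  The two
square faces are normal to the global x axis (the rise / elongation
direction); the cell proportions follow

    b = sqrt(2) * L * cos(theta)        (square/diamond edge length)
    H = 4 * L * sin(theta)              (cell height along x)

Ligaments carry a plateau-border cross-section (three touching circular
arcs), for which the area and second moments of area have the closed forms

    A        = (sqrt(3) - pi/2) * r**2
    Iy = Iz  = (20*sqrt(3) - 11*pi) / 24 * r**4

Cells tile space on a body-centred lattice with transverse period
``D = 4*L*cos(theta)`` and axial period ``H``; each edge of the tiling is
shared by three cells, which is what the closed-form relative density
(:func:`relative_density`) assumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "LigamentSection",
    "KelvinCell",
    "FoamLattice",
    "ligament_section_properties",
    "build_kelvin_cell",
    "tile_lattice",
    "relative_density",
    "relative_density_numeric",
]

#: area factor of the plateau-border section, A = _AREA_COEF * r**2
_AREA_COEF = math.sqrt(3.0) - math.pi / 2.0
#: bending factor, Iy = Iz = _INERTIA_COEF * r**4
_INERTIA_COEF = (20.0 * math.sqrt(3.0) - 11.0 * math.pi) / 24.0


@dataclass(frozen=True)
class LigamentSection:
    """Plateau-border ligament cross-section.

    Parameters are all in SI units (m, m**2, m**4).  ``Jt`` is a torsion
    constant; no closed form is available for the plateau-border shape, so it
    is taken as ``torsion_factor * (Iy + Iz)`` (see :func:`ligament_section_properties`).
    """

    r: float
    A: float
    Iy: float
    Iz: float
    Jt: float


def ligament_section_properties(r: float, torsion_factor: float = 1.0) -> LigamentSection:
    """Closed-form section properties of a plateau-border ligament.

    Parameters
    ----------
    r : float
        Section radius parameter (m), ``r >= 0``.
    torsion_factor : float
        Multiplier c in ``Jt = c * (Iy + Iz)``.  The effective-stiffness
        formulas contain no torsion term, so results of interest are
        insensitive to it; any positive value regularizes a 3-D frame.
    """
    if not np.isfinite(r) or r < 0.0:
        raise ValueError(f"section radius must be finite and >= 0, got {r!r}")
    if torsion_factor <= 0.0:
        raise ValueError("torsion_factor must be positive")
    A = _AREA_COEF * r * r
    I = _INERTIA_COEF * r ** 4
    return LigamentSection(r=r, A=A, Iy=I, Iz=I, Jt=torsion_factor * 2.0 * I)


def _signed_permutations():
    """Integer vertices of the tetrakaidecahedron: signed permutations of (0, 1, 2)."""
    verts = set()
    for perm in permutations((0, 1, 2)):
        for s1 in (1, -1):
            for s2 in (1, -1):
                v = tuple(c * (s1 if abs(c) == 1 else s2 if abs(c) == 2 else 1) for c in perm)
                verts.add(v)
    return sorted(verts)


@dataclass(frozen=True)
class KelvinCell:
    """One elongated tetrakaidecahedron with derived node/edge/face sets.

    ``nodes`` are 24 vertex coordinates (m) centred on the origin, with the
    elongation along +x.  ``edges`` are 36 index pairs; ``faces`` is a list of
    vertex-index loops (8 hexagons, 4 diamonds, 2 squares).
    """

    theta_deg: float
    L: float
    b: float
    H: float
    D: float
    section: LigamentSection
    ligament_length: float  # the symbol l of the cell tables: edge length L
    nodes: np.ndarray = field(repr=False)
    edges: np.ndarray = field(repr=False)
    faces: tuple = field(repr=False)

    @property
    def theta_rad(self) -> float:
        return math.radians(self.theta_deg)

    def face_multiset(self) -> dict:
        """Face sizes as a histogram, e.g. ``{4: 6, 6: 8}``."""
        out: dict = {}
        for f in self.faces:
            out[len(f)] = out.get(len(f), 0) + 1
        return out

    def edge_lengths(self) -> np.ndarray:
        d = self.nodes[self.edges[:, 0]] - self.nodes[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)


def build_kelvin_cell(theta_deg: float, L: float, r: float,
                      torsion_factor: float = 1.0) -> KelvinCell:
    """Construct an elongated Kelvin cell from (theta, L, r).

    The integer model is the truncated octahedron with vertices at the signed
    permutations of (0, 1, 2); anisotropic scaling by ``L*sin(theta)`` along x
    and ``L*cos(theta)`` transversally produces the elongated cell.  Edges
    connect integer vertices at squared distance 2 (each vertex has exactly
    three neighbours, 36 edges total).
    """
    if not (0.0 < theta_deg < 90.0):
        raise ValueError(f"theta must lie in (0, 90) degrees, got {theta_deg!r}")
    if L <= 0.0:
        raise ValueError(f"edge length L must be positive, got {L!r}")
    th = math.radians(theta_deg)
    b = math.sqrt(2.0) * L * math.cos(th)
    H = 4.0 * L * math.sin(th)
    D = 4.0 * L * math.cos(th)
    section = ligament_section_properties(r, torsion_factor)

    iverts = _signed_permutations()
    index = {v: i for i, v in enumerate(iverts)}
    sx = L * math.sin(th)   # scale per unit integer x
    st = L * math.cos(th)   # transverse scale per unit integer y/z
    nodes = np.array([(v[0] * sx, v[1] * st, v[2] * st) for v in iverts])

    edges = []
    for i, u in enumerate(iverts):
        for j in range(i + 1, len(iverts)):
            v = iverts[j]
            d2 = sum((a - c) ** 2 for a, c in zip(u, v))
            if d2 == 2:
                edges.append((i, j))
    edges = np.array(sorted(edges))

    faces = []
    # squares: integer planes x = +-2
    for s in (2, -2):
        loop = [v for v in iverts if v[0] == s]
        faces.append(tuple(index[v] for v in _order_loop(loop)))
    # diamonds: integer planes y = +-2 and z = +-2
    for axis in (1, 2):
        for s in (2, -2):
            loop = [v for v in iverts if v[axis] == s]
            faces.append(tuple(index[v] for v in _order_loop(loop)))
    # hexagons: planes +-x +- y +- z = 3
    for a in (1, -1):
        for bb in (1, -1):
            for c in (1, -1):
                loop = [v for v in iverts if a * v[0] + bb * v[1] + c * v[2] == 3]
                faces.append(tuple(index[v] for v in _order_loop(loop)))

    return KelvinCell(theta_deg=theta_deg, L=L, b=b, H=H, D=D, section=section,
                      ligament_length=L, nodes=nodes, edges=edges, faces=tuple(faces))


def _order_loop(loop):
    """Order the vertices of a planar convex face by angle about its centroid."""
    arr = np.array(loop, dtype=float)
    c = arr.mean(axis=0)
    rel = arr - c
    # build a 2-D basis in the face plane
    n = np.cross(rel[0], rel[1])
    if np.allclose(n, 0.0):
        n = np.cross(rel[0], rel[2])
    n = n / np.linalg.norm(n)
    e1 = rel[0] / np.linalg.norm(rel[0])
    e2 = np.cross(n, e1)
    ang = np.arctan2(rel @ e2, rel @ e1)
    return [loop[i] for i in np.argsort(ang)]


@dataclass(frozen=True)
class FoamLattice:
    """Open-cell foam lattice: deduplicated nodes + ligament connectivity."""

    nodes: np.ndarray
    ligaments: np.ndarray           # (n_lig, 2) node indices
    section: LigamentSection
    cell: KelvinCell
    tiling: tuple
    periodic: bool = False
    n_cells: int = 0
    periods: np.ndarray | None = None

    def ligament_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Geometric edge vectors (node_j - node_i) and their image translations.

        For a periodic lattice the vectors follow the minimum-image
        convention; the second array holds the box translation added to the
        second endpoint (zero for non-wrapping edges and aperiodic lattices).
        """
        d = self.nodes[self.ligaments[:, 1]] - self.nodes[self.ligaments[:, 0]]
        t = np.zeros_like(d)
        if self.periodic and self.periods is not None:
            t = -self.periods * np.round(d / self.periods)
            d = d + t
        return d, t

    def ligament_lengths(self) -> np.ndarray:
        d, _ = self.ligament_vectors()
        return np.linalg.norm(d, axis=1)

    def is_connected(self) -> bool:
        n = len(self.nodes)
        i, j = self.ligaments[:, 0], self.ligaments[:, 1]
        g = coo_matrix((np.ones(len(i)), (i, j)), shape=(n, n))
        ncomp, _ = connected_components(g, directed=False)
        return ncomp == 1

    def bounding_box(self):
        return self.nodes.min(axis=0), self.nodes.max(axis=0)


def tile_lattice(cell: KelvinCell, nx: int, ny: int, nz: int,
                 merge_tol: float | None = None,
                 include_body_centers: bool = True,
                 periodic: bool = False,
                 jitter_frac: float = 0.0,
                 rng: np.random.Generator | None = None) -> FoamLattice:
    """Tile translated Kelvin cells into an open-cell lattice.

    Cells sit on a body-centred arrangement: corner sites ``(i*H, j*D, k*D)``
    and, when ``include_body_centers``, interstitial sites offset by
    ``(H/2, D/2, D/2)``.  Coincident vertices of neighbouring cells are merged
    within ``merge_tol`` and duplicated ligaments dropped, so shared faces are
    represented once.

    With ``periodic=True`` node coordinates are wrapped modulo the box periods
    ``(nx*H, ny*D, nz*D)`` before merging; every ligament is then interior,
    which is the configuration the closed-form relative density refers to.

    ``jitter_frac`` optionally perturbs the merged nodes by a uniform random
    offset of amplitude ``jitter_frac * L`` (seeded via ``rng``); the regular
    lattice (default) is what the closed-form effective properties assume.
    """
    if min(nx, ny, nz) < 1:
        raise ValueError("tiling counts must be >= 1")
    if merge_tol is None:
        merge_tol = 1e-9 * cell.L
    shortest = min(cell.L, cell.b)
    if merge_tol >= shortest:
        raise ValueError(
            f"merge_tol {merge_tol!r} >= shortest edge {shortest!r}: would collapse geometry")
    if merge_tol <= 0.0:
        raise ValueError("merge_tol must be positive")

    H, D = cell.H, cell.D
    offsets = [(i * H, j * D, k * D)
               for i in range(nx) for j in range(ny) for k in range(nz)]
    if include_body_centers:
        if periodic:
            bi, bj, bk = nx, ny, nz
        else:
            bi, bj, bk = nx - 1, ny - 1, nz - 1
        offsets += [((i + 0.5) * H, (j + 0.5) * D, (k + 0.5) * D)
                    for i in range(bi) for j in range(bj) for k in range(bk)]

    periods = np.array([nx * H, ny * D, nz * D])
    all_nodes = []
    all_edges = []
    base = 0
    for off in offsets:
        pts = cell.nodes + np.asarray(off)
        if periodic:
            # wrap into [-H/2, periods - H/2) so the single-cell box is stable
            lo = cell.nodes.min(axis=0)
            pts = (pts - lo) % periods
            # float residue can leave a boundary point at period - eps
            pts = np.where(pts > periods - merge_tol, pts - periods, pts) + lo
        all_nodes.append(pts)
        all_edges.append(cell.edges + base)
        base += len(cell.nodes)
    pts = np.vstack(all_nodes)
    raw_edges = np.vstack(all_edges)

    # deduplicate nodes on a tolerance grid, deterministic lexicographic order
    key = np.round(pts / merge_tol).astype(np.int64)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    remap = np.empty(len(pts), dtype=np.int64)
    uniq_pts = []
    seen: dict = {}
    for idx in order:
        k = tuple(key[idx])
        if k not in seen:
            seen[k] = len(uniq_pts)
            uniq_pts.append(pts[idx])
        remap[idx] = seen[k]
    nodes = np.array(uniq_pts)

    e = remap[raw_edges]
    e = np.sort(e, axis=1)
    e = e[e[:, 0] != e[:, 1]]                       # drop collapsed edges
    e = np.unique(e, axis=0)

    if jitter_frac:
        if rng is None:
            raise ValueError("jitter requires an explicit seeded rng")
        nodes = nodes + rng.uniform(-jitter_frac * cell.L, jitter_frac * cell.L,
                                    size=nodes.shape)

    lat = FoamLattice(nodes=nodes, ligaments=e, section=cell.section, cell=cell,
                      tiling=(nx, ny, nz), periodic=periodic, n_cells=len(offsets),
                      periods=periods if periodic else None)
    lengths = lat.ligament_lengths()
    if np.any(lengths < merge_tol):
        raise RuntimeError("zero-length ligament survived merging")
    return lat


def relative_density(cell: KelvinCell) -> float:
    """Closed-form relative density gamma = rho_foam / rho_solid.

    gamma = 2 A (2L + b) / ( L sin(theta) * (2 L cos(theta) + sqrt(2) b)**2 )

    Valid for slender ligaments; a warning is emitted when the formula leaves
    the open-cell regime (gamma >= 1).
    """
    th = cell.theta_rad
    A, L, b = cell.section.A, cell.L, cell.b
    gamma = 2.0 * A * (2.0 * L + b) / (
        L * math.sin(th) * (2.0 * L * math.cos(th) + math.sqrt(2.0) * b) ** 2)
    if gamma >= 1.0:
        warnings.warn("relative density >= 1: outside open-cell validity",
                      stacklevel=2)
    return gamma


def relative_density_numeric(cell: KelvinCell, n: int = 2) -> float:
    """Mesh-based relative density estimate: ligament volume over box volume.

    Tiles an ``n**3`` periodic body-centred block (``2 n**3`` cells), sums the
    deduplicated ligament lengths and divides ``A * total_length`` by the box
    volume.  Serves as an independent check of :func:`relative_density`
    (it ignores the double counting of material where ligaments meet, which is
    negligible for slender ligaments).
    """
    lat = tile_lattice(cell, n, n, n, periodic=True)
    total = lat.ligament_lengths().sum()
    vol = (n * cell.H) * (n * cell.D) * (n * cell.D)
    return cell.section.A * total / vol
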