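"""Cell geometry: outlines, triangular meshes, anchors, fibers, line-scans.

The cell is modelled as a 2D domain in the (x, y) plane with x the
longitudinal axis (origin at the leftmost point of the cell) and all
lengths in micrometres.  Meshes are plain conforming triangulations with
per-element unit fiber directions (longitudinal by default) and an ordered
set of line-scan sample positions along the mid-axis, mirroring confocal
line-scan acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon


class MeshError(ValueError):
    """Raised for invalid or unsupported mesh content."""


# ---------------------------------------------------------------------------
# CellMesh
# ---------------------------------------------------------------------------

@dataclass
class CellMesh:
    """Triangulated 2D cell domain.

    Attributes
    ----------
    nodes : (n_nodes, 2) float array, micrometres.
    triangles : (n_elems, 3) int array, counter-clockwise node triples.
    boundary_edges : (n_bedges, 2) int array forming one closed loop.
    anchor_nodes : int array, nodes with zero prescribed displacement.
    fiber_direction : (n_elems, 2) unit vectors in the reference
        configuration (default: the longitudinal axis everywhere).
    linescan : strictly increasing sample positions (um) along the
        longitudinal mid-axis.
    long_axis : unit 2-vector of the cell's longitudinal direction.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    anchor_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fiber_direction: np.ndarray | None = None
    linescan: np.ndarray = field(default_factory=lambda: np.array([]))
    long_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.fiber_direction is None:
            self.fiber_direction = np.tile(self.long_axis, (len(self.triangles), 1))
        self.fiber_direction = np.asarray(self.fiber_direction, dtype=float)

    # -- derived quantities -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * (v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def validate(self, require_anchor: bool = False) -> None:
        """Check mesh invariants; raise :class:`MeshError` on violation."""
        if np.any(self.element_areas() <= 0):
            raise MeshError("mesh contains non-positively oriented or degenerate triangles")
        norms = np.linalg.norm(self.fiber_direction, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise MeshError("fiber_direction must be unit vectors")
        if len(self.linescan) and np.any(np.diff(self.linescan) <= 0):
            raise MeshError("linescan positions must be strictly increasing")
        if require_anchor and len(self.anchor_nodes) == 0:
            raise MeshError(
                "anchor_nodes is empty: the equilibrium problem is only "
                "Robin-constrained; select an anchor region first"
            )
        # boundary edges must form one closed loop
        _order_boundary_loop(self.boundary_edges)

    def rotated(self, angle_rad: float) -> "CellMesh":
        """Return a rigidly rotated copy (fibers and axes co-rotate)."""
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        Q = np.array([[c, -s], [s, c]])
        return replace(
            self,
            nodes=self.nodes @ Q.T,
            fiber_direction=self.fiber_direction @ Q.T,
            long_axis=Q @ self.long_axis,
        )


# ---------------------------------------------------------------------------
# Outline generation
# ---------------------------------------------------------------------------

def build_synthetic_outline(length: float, width: float,
                            corner_rounding: float = 0.4,
                            points_per_arc: int = 16) -> np.ndarray:
    """Closed stadium-like polygon with bounding box ``length x width``.

    ``corner_rounding`` is the corner radius expressed as a fraction of the
    cell width; 0 gives a rectangle and 0.5 fully rounded (stadium) ends,
    mimicking the rounded shape of an adult rat cardiomyocyte.

    Returns an (n, 2) CCW polygon (first point not repeated).  The origin is
    the leftmost point of the bounding box at mid-height, i.e. the domain is
    [0, length] x [-width/2, width/2].
    """
    if not (length > width > 0):
        raise ValueError("require length > width > 0")
    if not (0.0 <= corner_rounding <= 0.5):
        raise ValueError("corner_rounding must lie in [0, 0.5]")
    r = corner_rounding * width
    hw = width / 2.0
    if r == 0.0:
        poly = np.array([[0, -hw], [length, -hw], [length, hw], [0, hw]], float)
    else:
        pts = []
        # corner centers, CCW starting bottom-left
        corners = [
            (r, -hw + r, np.pi, 1.5 * np.pi),            # bottom-left
            (length - r, -hw + r, 1.5 * np.pi, 2 * np.pi),  # bottom-right
            (length - r, hw - r, 0.0, 0.5 * np.pi),      # top-right
            (r, hw - r, 0.5 * np.pi, np.pi),             # top-left
        ]
        for cx, cy, a0, a1 in corners:
            ang = np.linspace(a0, a1, points_per_arc)
            pts.append(np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)]))
        poly = np.vstack(pts)
        # drop consecutive duplicates
        keep = np.r_[True, np.linalg.norm(np.diff(poly, axis=0), axis=1) > 1e-12]
        poly = poly[keep]
    shp = Polygon(poly)
    if not shp.is_valid or not shp.is_simple:
        raise ValueError("degenerate rounding produced a non-simple polygon")
    return poly


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def mesh_outline(polygon: np.ndarray, target_edge_length: float,
                 long_axis=(1.0, 0.0)) -> CellMesh:
    """Triangulate the interior of a (convex) cell outline.

    Boundary vertices are resampled at the target edge length, the interior
    is filled with a hexagonal point lattice, and the point cloud is
    Delaunay-triangulated.  Triangles whose centroid falls outside the
    outline are discarded (for the convex outlines used here none are).
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    h = float(target_edge_length)
    shp = Polygon(polygon)
    if not shp.is_valid:
        raise MeshError("invalid polygon outline")

    # resample boundary at spacing ~h
    ring = np.vstack([polygon, polygon[:1]])
    seg = np.linalg.norm(np.diff(ring, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    per = arclen[-1]
    n_b = max(8, int(round(per / h)))
    s = np.linspace(0.0, per, n_b, endpoint=False)
    bx = np.interp(s, arclen, ring[:, 0])
    by = np.interp(s, arclen, ring[:, 1])
    boundary_pts = np.column_stack([bx, by])

    # hexagonal interior lattice, kept clear of the boundary
    xmin, ymin, xmax, ymax = shp.bounds
    dy = h * np.sqrt(3) / 2
    rows = np.arange(ymin + 0.5 * dy, ymax, dy)
    interior = []
    inset = shp.buffer(-0.55 * h)
    for i, y in enumerate(rows):
        x0 = xmin + (0.25 if i % 2 else 0.75) * h
        xs = np.arange(x0, xmax, h)
        for x in xs:
            if inset.contains(Point(x, y)):
                interior.append((x, y))
    pts = np.vstack([boundary_pts, np.asarray(interior).reshape(-1, 2)])

    tri = Delaunay(pts)
    simplices = tri.simplices
    cent = pts[simplices].mean(axis=1)
    shp_eps = shp.buffer(1e-9)
    inside = np.fromiter(
        (shp_eps.contains(Point(*c)) for c in cent), bool, count=len(cent)
    )
    simplices = simplices[inside]
    if len(simplices) == 0:
        raise MeshError("meshing failed: no interior triangles")

    # enforce CCW orientation
    p = pts[simplices]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]

    # drop unreferenced points
    used = np.unique(simplices)
    remap = -np.ones(len(pts), dtype=int)
    remap[used] = np.arange(len(used))
    mesh = CellMesh(
        nodes=pts[used],
        triangles=remap[simplices],
        boundary_edges=_boundary_edges(remap[simplices]),
        long_axis=np.asarray(long_axis, float),
    )
    mesh.validate()
    return mesh


def _boundary_edges(triangles: np.ndarray) -> np.ndarray:
    """Edges belonging to exactly one triangle."""
    edges = np.vstack([
        triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]],
    ])
    key = np.sort(edges, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return edges[idx[counts == 1]]


def _order_boundary_loop(bedges: np.ndarray) -> np.ndarray:
    """Order boundary edges into a single closed loop of node indices."""
    if len(bedges) == 0:
        raise MeshError("mesh has no boundary edges")
    nxt = dict(zip(bedges[:, 0].tolist(), bedges[:, 1].tolist()))
    start = int(bedges[0, 0])
    loop = [start]
    node = nxt.get(start)
    for _ in range(len(bedges) + 1):
        if node is None:
            raise MeshError("boundary edges do not form a closed loop")
        if node == start:
            break
        loop.append(node)
        node = nxt.get(node)
    else:
        raise MeshError("boundary edges do not form a single closed loop")
    if len(loop) != len(bedges):
        raise MeshError("boundary edges do not form a single closed loop")
    return np.asarray(loop, dtype=int)


def boundary_loop_length(mesh: CellMesh) -> float:
    e = mesh.boundary_edges
    return float(np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1).sum())


# ---------------------------------------------------------------------------
# Anchors and line-scan
# ---------------------------------------------------------------------------

def select_anchor(mesh: CellMesh, strain_profile=None, interval=None) -> np.ndarray:
    """Select zero-displacement (Dirichlet) nodes.

    Either an explicit longitudinal ``interval`` ``(x0, x1)`` is given, or a
    measured strain profile at maximum contraction: in that case the anchor
    is the longest contiguous run of profile positions with strain >= 0
    (the observed non-shortening region, interpreted as an adhesion site or
    the nucleus).
    """
    x = mesh.nodes @ mesh.long_axis
    if interval is not None:
        x0, x1 = float(interval[0]), float(interval[1])
    elif strain_profile is not None:
        pos = np.asarray(strain_profile.positions, float)
        val = np.asarray(strain_profile.strain, float)
        runs = _nonneg_runs(val)
        if not runs:
            raise ValueError(
                "no zero/positive-strain region in profile; "
                "pass an explicit anchor interval"
            )
        i0, i1 = max(runs, key=lambda r: r[1] - r[0])
        x0, x1 = pos[i0], pos[i1]
    else:
        raise ValueError("provide either strain_profile or interval")
    sel = np.nonzero((x >= x0 - 1e-12) & (x <= x1 + 1e-12))[0]
    if len(sel) == 0:
        raise ValueError(
            f"anchor interval [{x0}, {x1}] contains no mesh nodes; "
            "pass a wider explicit interval"
        )
    return sel


def default_anchor(mesh: CellMesh, band_width: float = 2.0) -> np.ndarray:
    """Default synthetic-cell anchor: transverse band at mid-length."""
    x = mesh.nodes @ mesh.long_axis
    mid = 0.5 * (x.min() + x.max())
    return select_anchor(mesh, interval=(mid - band_width / 2, mid + band_width / 2))


def _nonneg_runs(values: np.ndarray):
    """Index ranges [i0, i1] (inclusive) of contiguous non-negative runs."""
    runs = []
    start = None
    for i, v in enumerate(values):
        if v >= 0 and start is None:
            start = i
        elif v < 0 and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(values) - 1))
    return runs


def sample_linescan(mesh: CellMesh, n_points: int) -> np.ndarray:
    """Equispaced line-scan positions along the longitudinal mid-axis."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    x = mesh.nodes @ mesh.long_axis
    return np.linspace(x.min(), x.max(), n_points)


def linescan_from_spacing(mesh: CellMesh, spacing: float) -> np.ndarray:
    """Line-scan sampled at a fixed pixel spacing (um), e.g. 0.28 um."""
    x = mesh.nodes @ mesh.long_axis
    n = int(np.floor((x.max() - x.min()) / spacing)) + 1
    return x.min() + spacing * np.arange(n)


# ---------------------------------------------------------------------------
# Gmsh MSH v2.2 ASCII I/O
# ---------------------------------------------------------------------------

_MSH_TRIANGLE = 2
_MSH_NNODES = {1: 2, 2: 3, 3: 4, 4: 4, 5: 8, 6: 6, 7: 5, 8: 3, 9: 6, 15: 1}
_MSH_NAMES = {3: "quadrangle", 4: "tetrahedron", 5: "hexahedron",
              6: "prism", 7: "pyramid", 9: "6-node triangle"}


def write_mesh(mesh: CellMesh, path) -> None:
    """Write a CellMesh as Gmsh MSH v2.2 ASCII (triangles only)."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            f.write(f"{i} {x:.17g} {y:.17g} 0\n")
        f.write("$EndNodes\n")
        f.write(f"$Elements\n{mesh.n_elements}\n")
        for i, (a, b, c) in enumerate(mesh.triangles + 1, start=1):
            f.write(f"{i} 2 2 0 1 {a} {b} {c}\n")
        f.write("$EndElements\n")


def read_mesh(path, long_axis=(1.0, 0.0)) -> CellMesh:
    """Read a Gmsh MSH v2.2 ASCII mesh.

    Only triangular (type 2) elements define the domain; point and line
    elements (boundary markers) are skipped; any other element type is
    rejected.  The boundary loop is recomputed from the triangulation.
    """
    with open(path) as f:
        lines = f.read().split("\n")
    it = iter(range(len(lines)))
    sections = {}
    i = 0
    while i < len(lines):
        token = lines[i].strip()
        if token.startswith("$") and not token.startswith("$End"):
            name = token[1:]
            j = i + 1
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                j += 1
            if j >= len(lines):
                raise MeshError(f"unterminated section ${name}")
            sections[name] = lines[i + 1:j]
            i = j
        i += 1
    if "MeshFormat" not in sections:
        raise MeshError("not a Gmsh MSH file (missing $MeshFormat)")
    version = sections["MeshFormat"][0].split()[0]
    if not version.startswith("2"):
        raise MeshError(f"unsupported MSH format version {version!r} (need v2.x ASCII)")
    if "Nodes" not in sections or "Elements" not in sections:
        raise MeshError("MSH file missing $Nodes or $Elements")

    node_lines = sections["Nodes"]
    n_nodes = int(node_lines[0])
    ids = np.empty(n_nodes, dtype=int)
    coords = np.empty((n_nodes, 2), dtype=float)
    for k in range(n_nodes):
        parts = node_lines[1 + k].split()
        ids[k] = int(parts[0])
        coords[k] = [float(parts[1]), float(parts[2])]
    id2row = {int(i_): k for k, i_ in enumerate(ids)}

    elem_lines = sections["Elements"]
    n_elems = int(elem_lines[0])
    tris = []
    for k in range(n_elems):
        parts = elem_lines[1 + k].split()
        etype = int(parts[1])
        ntags = int(parts[2])
        conn = parts[3 + ntags:]
        if etype == _MSH_TRIANGLE:
            tris.append([id2row[int(c)] for c in conn])
        elif etype in (1, 15):
            continue  # boundary line / point markers
        else:
            name = _MSH_NAMES.get(etype, f"type {etype}")
            raise MeshError(
                f"non-triangular element in mesh: element {parts[0]} is a {name}"
            )
    if not tris:
        raise MeshError("MSH file contains no triangles")
    triangles = np.asarray(tris, dtype=int)
    # enforce CCW
    p = coords[triangles]
    areas = 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                   - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = areas < 0
    triangles[flip] = triangles[flip][:, ::-1]
    return CellMesh(
        nodes=coords,
        triangles=triangles,
        boundary_edges=_boundary_edges(triangles),
        long_axis=np.asarray(long_axis, float),
    )


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII)
# ---------------------------------------------------------------------------

def write_vtk(mesh: CellMesh, path, point_data=None, cell_data=None) -> None:
    """Write mesh (+ optional nodal/element fields) as legacy ASCII VTK."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncardiomech mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.10g} {y:.10g} 0\n")
        ne = mesh.n_elements
        f.write(f"CELLS {ne} {4 * ne}\n")
        for a, b, c in mesh.triangles:
            f.write(f"3 {a} {b} {c}\n")
        f.write(f"CELL_TYPES {ne}\n")
        f.write("5\n" * ne)
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                _write_vtk_field(f, name, np.asarray(arr))
        if cell_data:
            f.write(f"CELL_DATA {ne}\n")
            for name, arr in cell_data.items():
                _write_vtk_field(f, name, np.asarray(arr))


def _write_vtk_field(f, name, arr):
    if arr.ndim == 1:
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in arr:
            f.write(f"{v:.10g}\n")
    else:
        f.write(f"VECTORS {name} double\n")
        for row in arr:
            vx, vy = row[:2]
            f.write(f"{vx:.10g} {vy:.10g} 0\n")
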