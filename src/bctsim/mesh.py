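"""Triangular meshing of the virtual breast.

Builds a conforming 2D triangle mesh from a tissue label map, carves the
"virtual lumpectomy" cavity (tumor bed plus negative margin, as an
ellipse), and remeshes as the wound boundary moves during healing.  The
mesh is a structured right-triangle grid whose boundary nodes are snapped
onto the sub-pixel tissue silhouette (and onto the exact cavity ellipse /
wound polyline), which keeps areas accurate while guaranteeing element
quality.

Boundary markers: ``skin_surface`` (air interface), ``chest_wall``
(pectoral interface, clamped in the mechanics), ``cavity_wall`` (the
lumpectomy wound).  Boundary edges are oriented with tissue on the left,
so the outward normal of edge (u, v) is (dy, -dx)/|..|.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import Point, Polygon

from .phantom import BACKGROUND, CHEST, FAT, GLANDULAR, SKIN, TissueLabelMap

__all__ = ["SCAR", "INFLAMED", "MATERIAL_NAMES", "CavitySpec", "BreastMesh",
           "build_mesh", "apply_virtual_lumpectomy", "remesh_from_wound",
           "mark_inflamed_ring", "min_angle_deg", "element_areas",
           "write_msh", "read_msh", "write_vtk"]

SCAR, INFLAMED = 5, 6
MATERIAL_NAMES = {FAT: "fat", GLANDULAR: "glandular", SKIN: "skin",
                  SCAR: "scar", INFLAMED: "inflamed"}

_MIN_ANGLE_GUARD = 20.0     # deg, quality floor enforced when snapping nodes


@dataclass
class CavitySpec:
    """Lumpectomy cavity: elliptical tumor bed plus surgical margin.

    The margin is added radially (to each semi-axis), so a 12 x 9 mm bed
    with a 5 mm negative margin yields a 22 x 19 mm cavity ellipse.
    """

    center: tuple[float, float]          # mm
    bed_axes: tuple[float, float] = (12.0, 9.0)   # full axes, mm
    margin: float = 5.0                  # mm
    orientation: float = 0.0             # radians, major-axis tilt

    def __post_init__(self) -> None:
        if min(self.bed_axes) <= 0:
            raise ValueError("bed axes must be positive")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")

    @property
    def semi_axes(self) -> tuple[float, float]:
        return (self.bed_axes[0] / 2 + self.margin,
                self.bed_axes[1] / 2 + self.margin)

    def polygon(self, resolution: int = 96) -> Polygon:
        a, b = self.semi_axes
        e = affinity.scale(Point(self.center).buffer(1.0, quad_segs=resolution), a, b)
        return affinity.rotate(e, self.orientation, origin=self.center,
                               use_radians=True)


@dataclass
class BreastMesh:
    """Conforming triangle mesh with material labels and marked boundaries."""

    nodes: np.ndarray                 # (N, 2) mm
    tris: np.ndarray                  # (M, 3) CCW node triplets
    material: np.ndarray              # (M,) tissue codes
    boundary: dict = field(default_factory=dict)  # marker -> (K, 2) edges
    h: float = 0.0                    # characteristic element size, mm
    label_map: TissueLabelMap | None = None
    cavity: Polygon | None = None             # current wound/cavity polygon
    original_cavity: Polygon | None = None    # the surgical cavity ellipse

    def boundary_nodes(self, marker: str) -> np.ndarray:
        edges = self.boundary.get(marker, np.empty((0, 2), int))
        return np.unique(edges)

    def area(self) -> float:
        return float(element_areas(self.nodes, self.tris).sum())

    def cavity_area(self) -> float:
        return 0.0 if self.cavity is None else float(self.cavity.area)


def element_areas(nodes: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = nodes[tris]
    return 0.5 * ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                  - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1]))


def min_angle_deg(nodes: np.ndarray, tris: np.ndarray) -> float:
    """Smallest interior angle over all elements (degrees)."""
    p = nodes[tris]
    angles = []
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cosv = (a * b).sum(1) / (np.linalg.norm(a, axis=1)
                                 * np.linalg.norm(b, axis=1) + 1e-30)
        angles.append(np.degrees(np.arccos(np.clip(cosv, -1, 1))))
    return float(np.min(angles))


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def _boundary_edges_oriented(tris: np.ndarray) -> np.ndarray:
    """Edges owned by exactly one triangle, oriented tissue-on-left."""
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(e, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    return e[counts[inv] == 1]


def _edge_outward_normals(nodes: np.ndarray, edges: np.ndarray) -> np.ndarray:
    d = nodes[edges[:, 1]] - nodes[edges[:, 0]]
    n = np.column_stack([d[:, 1], -d[:, 0]])
    return n / (np.linalg.norm(n, axis=1, keepdims=True) + 1e-30)


def _nearest_tissue_label(label_map: TissueLabelMap, pts: np.ndarray) -> np.ndarray:
    """Label lookup falling back to the nearest breast-tissue pixel."""
    from scipy import ndimage
    lab = label_map.label_at(pts[:, 0], pts[:, 1]).copy()
    bad = ~np.isin(lab, (FAT, GLANDULAR, SKIN))
    if bad.any():
        mask = label_map.foreground_mask()
        _, (iy, ix) = ndimage.distance_transform_edt(~mask, return_indices=True)
        ny, nx = mask.shape
        jx = np.clip(((pts[bad, 0] - label_map.origin[0]) / label_map.pixel_pitch
                      - 0.5).round().astype(int), 0, nx - 1)
        jy = np.clip(((pts[bad, 1] - label_map.origin[1]) / label_map.pixel_pitch
                      - 0.5).round().astype(int), 0, ny - 1)
        lab[bad] = label_map.grid[iy[jy, jx], ix[jy, jx]]
    return lab


def _snap_nodes(nodes: np.ndarray, tris: np.ndarray, node_ids: np.ndarray,
                target_line, max_dist: float) -> np.ndarray:
    """Project nodes onto a shapely line, guarding element quality.

    Each move is accepted only if every incident triangle keeps positive
    orientation and a minimum angle above the quality floor; otherwise the
    node stays put.
    """
    out = nodes.copy()
    incident: dict[int, list[int]] = {}
    for t, tri in enumerate(tris):
        for n in tri:
            incident.setdefault(int(n), []).append(t)
    for nid in node_ids:
        p = Point(out[nid])
        q = target_line.interpolate(target_line.project(p))
        if p.distance(q) > max_dist:
            continue
        trial = out[nid].copy()
        out[nid] = (q.x, q.y)
        tids = incident.get(int(nid), [])
        sub = tris[tids]
        if (element_areas(out, sub) <= 1e-9).any() or \
                min_angle_deg(out, sub) < _MIN_ANGLE_GUARD:
            out[nid] = trial
    return out


def _main_component(tris: np.ndarray) -> np.ndarray:
    """Mask of elements in the largest edge-connected component.

    Carving a cavity can strand single elements (or hinged slivers) that
    would carry rigid-body modes into the mechanics; only the main body
    of tissue is kept.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    owners = np.full((len(uniq), 2), -1, dtype=int)
    tids = np.tile(np.arange(len(tris)), 3)
    for edge_id, t in zip(inv, tids):
        if owners[edge_id, 0] < 0:
            owners[edge_id, 0] = t
        else:
            owners[edge_id, 1] = t
    pair = owners[(owners >= 0).all(axis=1)]
    g = coo_matrix((np.ones(len(pair)), (pair[:, 0], pair[:, 1])),
                   shape=(len(tris), len(tris)))
    _, lab = connected_components(g, directed=False)
    return lab == np.bincount(lab).argmax()


def _compact(nodes: np.ndarray, tris: np.ndarray,
             boundary: dict) -> tuple[np.ndarray, np.ndarray, dict]:
    """Drop nodes referenced by no triangle and renumber."""
    used = np.unique(tris)
    remap = -np.ones(len(nodes), dtype=int)
    remap[used] = np.arange(len(used))
    new_boundary = {m: remap[e] for m, e in boundary.items()}
    return nodes[used], remap[tris], new_boundary


def _classify_boundary(nodes, tris, label_map, cavity: Polygon | None,
                       probe_dist: float):
    edges = _boundary_edges_oriented(tris)
    mids = 0.5 * (nodes[edges[:, 0]] + nodes[edges[:, 1]])
    normals = _edge_outward_normals(nodes, edges)
    probes = mids + normals * probe_dist
    markers = np.full(len(edges), "skin_surface", dtype=object)
    if cavity is not None and not cavity.is_empty:
        grown = cavity.buffer(probe_dist)
        inside = shapely.contains(grown, shapely.points(probes))
        markers[inside] = "cavity_wall"
    lab = label_map.label_at(probes[:, 0], probes[:, 1])
    markers[(markers == "skin_surface") & (lab == CHEST)] = "chest_wall"
    return {m: edges[markers == m] for m in np.unique(markers)}


def build_mesh(label_map: TissueLabelMap, target_size: float = 2.0) -> BreastMesh:
    """Structured triangle mesh of the breast tissue in a label map.

    The grid spacing is ``target_size / sqrt(2)`` so no edge exceeds
    ``target_size``; cells whose center lies in breast tissue are kept and
    split into two triangles (alternating diagonals).  Element materials
    come from the label at the element centroid; outer boundary nodes are
    snapped onto the sub-pixel silhouette extracted by marching squares.
    """
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    mask = label_map.foreground_mask()
    if not mask.any():
        raise ValueError("label map has no breast tissue")
    pitch = label_map.pixel_pitch
    hg = target_size / np.sqrt(2.0)

    iy, ix = np.nonzero(mask)
    x0 = label_map.origin[0] + ix.min() * pitch
    x1 = label_map.origin[0] + (ix.max() + 1) * pitch
    y0 = label_map.origin[1] + iy.min() * pitch
    y1 = label_map.origin[1] + (iy.max() + 1) * pitch
    x0, y0 = np.floor(x0 / hg) * hg, np.floor(y0 / hg) * hg
    ncx = int(np.ceil((x1 - x0) / hg)) + 1
    ncy = int(np.ceil((y1 - y0) / hg)) + 1

    gx = x0 + np.arange(ncx + 1) * hg
    gy = y0 + np.arange(ncy + 1) * hg
    # cell centers and keep mask (points beyond the map are background)
    cx, cy = np.meshgrid(gx[:-1] + hg / 2, gy[:-1] + hg / 2)
    ny, nx = label_map.grid.shape
    ox, oy = label_map.origin
    in_map = ((cx >= ox) & (cx <= ox + nx * pitch)
              & (cy >= oy) & (cy <= oy + ny * pitch))
    keep = np.isin(label_map.label_at(cx.ravel(), cy.ravel()),
                   (FAT, GLANDULAR, SKIN)).reshape(cx.shape) & in_map

    def nid(i, j):                      # i along x, j along y
        return j * (ncx + 1) + i
    tris = []
    jj, ii = np.nonzero(keep)
    for j, i in zip(jj, ii):
        n00, n10 = nid(i, j), nid(i + 1, j)
        n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
        if (i + j) % 2 == 0:
            tris += [(n00, n10, n11), (n00, n11, n01)]
        else:
            tris += [(n00, n10, n01), (n10, n11, n01)]
    tris = np.array(tris, dtype=int)
    X, Y = np.meshgrid(gx, gy)
    nodes_all = np.column_stack([X.ravel(), Y.ravel()])
    used = np.unique(tris)
    remap = -np.ones(len(nodes_all), dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes_all[used]
    tris = remap[tris]

    centroids = nodes[tris].mean(axis=1)
    material = _nearest_tissue_label(label_map, centroids)

    boundary = _classify_boundary(nodes, tris, label_map, None,
                                  probe_dist=0.5 * hg)

    # snap the outer boundary (skin and chest interface) onto the
    # sub-pixel silhouette so mesh area tracks the label-map area
    from .image_ops import extract_contour
    sil = extract_contour((mask, pitch, label_map.origin))
    line = shapely.LinearRing(sil)
    outer = np.unique(np.vstack([boundary.get(m, np.empty((0, 2), int))
                                 for m in ("skin_surface", "chest_wall")]))
    nodes = _snap_nodes(nodes, tris, outer.astype(int), line,
                        max_dist=0.9 * hg)

    return BreastMesh(nodes=nodes, tris=tris, material=material,
                      boundary=boundary, h=target_size, label_map=label_map)


def apply_virtual_lumpectomy(mesh: BreastMesh, cavity: CavitySpec) -> BreastMesh:
    """Carve the lumpectomy cavity (bed + margin ellipse) out of a mesh.

    Elements whose centroid falls inside the effective ellipse are removed,
    the new boundary is marked ``cavity_wall``, and its nodes are snapped
    onto the exact ellipse.  Raises if the ellipse (plus 1 mm clearance)
    reaches the skin or the chest wall.
    """
    if mesh.label_map is None:
        raise ValueError("mesh lacks its source label map")
    poly = cavity.polygon()
    probe = np.asarray(poly.buffer(1.0).exterior.coords)
    lab = mesh.label_map.label_at(probe[:, 0], probe[:, 1])
    if np.isin(lab, (SKIN, CHEST, BACKGROUND)).any():
        raise ValueError("cavity ellipse (with margin) breaches skin or "
                         "chest wall")

    centroids = mesh.nodes[mesh.tris].mean(axis=1)
    inside = shapely.contains(poly, shapely.points(centroids))
    tris = mesh.tris[~inside]
    material = mesh.material[~inside]
    main = _main_component(tris)
    tris, material = tris[main], material[main]

    boundary = _classify_boundary(mesh.nodes, tris, mesh.label_map, poly,
                                  probe_dist=0.35 * mesh.h / np.sqrt(2.0))
    nodes, tris, boundary = _compact(mesh.nodes, tris, boundary)
    cav_nodes = np.unique(boundary.get("cavity_wall", np.empty((0, 2), int)))
    nodes = _snap_nodes(nodes, tris, cav_nodes, shapely.LinearRing(
        np.asarray(poly.exterior.coords)), max_dist=0.9 * mesh.h / np.sqrt(2))

    return replace(mesh, nodes=nodes, tris=tris, material=material,
                   boundary=boundary, cavity=poly, original_cavity=poly)


def remesh_from_wound(mesh: BreastMesh, wound: Polygon | np.ndarray | None
                      ) -> BreastMesh:
    """Rebuild the mesh for a healed (shrunken) wound boundary.

    The base grid is regenerated from the stored label map, the current
    wound polygon is carved out, and elements lying in the original
    surgical cavity but outside the wound become scar tissue.  ``wound``
    may be a polygon, a closed polyline, or None/empty for a fully closed
    wound.
    """
    if mesh.label_map is None or mesh.original_cavity is None:
        raise ValueError("mesh lacks lumpectomy provenance")
    if wound is not None and not isinstance(wound, Polygon):
        arr = np.asarray(wound, dtype=float)
        wound = None if arr.size == 0 else Polygon(arr)
    if wound is not None and (wound.is_empty or wound.area < 1e-9):
        wound = None
    if wound is not None:
        if not wound.is_valid:
            raise ValueError("wound polygon is self-intersecting")
        if not wound.within(mesh.original_cavity.buffer(0.75 * mesh.h)):
            raise ValueError("wound polygon must lie inside the previous "
                             "cavity")

    base = build_mesh(mesh.label_map, mesh.h)
    centroids = base.nodes[base.tris].mean(axis=1)
    pts = shapely.points(centroids)
    if wound is not None:
        inside = shapely.contains(wound, pts)
    else:
        inside = np.zeros(len(base.tris), dtype=bool)
    tris = base.tris[~inside]
    material = base.material[~inside].copy()
    main = _main_component(tris)
    tris, material = tris[main], material[main]
    cent2 = base.nodes[tris].mean(axis=1)
    in_orig = shapely.contains(mesh.original_cavity, shapely.points(cent2))
    material[in_orig] = SCAR

    boundary = _classify_boundary(base.nodes, tris, mesh.label_map, wound,
                                  probe_dist=0.35 * mesh.h / np.sqrt(2.0))
    nodes, tris, boundary = _compact(base.nodes, tris, boundary)
    if wound is not None:
        cav_nodes = np.unique(boundary.get("cavity_wall",
                                           np.empty((0, 2), int)))
        ring = shapely.LinearRing(np.asarray(wound.exterior.coords))
        nodes = _snap_nodes(nodes, tris, cav_nodes, ring,
                            max_dist=0.9 * mesh.h / np.sqrt(2))
    return replace(mesh, nodes=nodes, tris=tris, material=material,
                   boundary=boundary, cavity=wound)


def mark_inflamed_ring(mesh: BreastMesh, width: float = 5.0) -> BreastMesh:
    """Label the tissue ring of given width around the cavity as inflamed.

    Mirrors the early-phase local inflammation: elements (other than skin)
    whose centroid lies within ``width`` of the cavity wall are given the
    stiff ``inflamed`` material.
    """
    if mesh.cavity is None:
        raise ValueError("mesh has no cavity")
    centroids = mesh.nodes[mesh.tris].mean(axis=1)
    d = shapely.distance(shapely.points(centroids), mesh.cavity.exterior)
    material = mesh.material.copy()
    ring = (d <= width) & (material != SKIN)
    material[ring] = INFLAMED
    return replace(mesh, material=material)


# ---------------------------------------------------------------------------
# mesh I/O: Gmsh MSH (ASCII v2.2) and legacy VTK
# ---------------------------------------------------------------------------

_MARKER_TAGS = {"skin_surface": 101, "chest_wall": 102, "cavity_wall": 103}


def write_msh(path: str | Path, mesh: BreastMesh) -> None:
    lines = ["$MeshFormat\n2.2 0 8\n$EndMeshFormat\n$Nodes\n",
             f"{len(mesh.nodes)}\n"]
    for i, (x, y) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i} {x:.9g} {y:.9g} 0\n")
    lines.append("$EndNodes\n$Elements\n")
    n_edges = sum(len(e) for e in mesh.boundary.values())
    lines.append(f"{n_edges + len(mesh.tris)}\n")
    eid = 1
    for marker, edges in sorted(mesh.boundary.items()):
        tag = _MARKER_TAGS[marker]
        for a, b in edges:
            lines.append(f"{eid} 1 2 {tag} {tag} {a + 1} {b + 1}\n")
            eid += 1
    for t, (a, b, c) in enumerate(mesh.tris):
        m = int(mesh.material[t])
        lines.append(f"{eid} 2 2 {m} {m} {a + 1} {b + 1} {c + 1}\n")
        eid += 1
    lines.append("$EndElements\n")
    Path(path).write_text("".join(lines))


def read_msh(path: str | Path) -> BreastMesh:
    """Minimal reader for meshes written by :func:`write_msh`."""
    text = Path(path).read_text().splitlines()
    it = iter(text)
    nodes, tris, mats = [], [], []
    boundary: dict[str, list] = {}
    tag_to_marker = {v: k for k, v in _MARKER_TAGS.items()}
    for line in it:
        if line.strip() == "$Nodes":
            n = int(next(it))
            for _ in range(n):
                parts = next(it).split()
                nodes.append((float(parts[1]), float(parts[2])))
        elif line.strip() == "$Elements":
            n = int(next(it))
            for _ in range(n):
                parts = [int(p) for p in next(it).split()]
                etype, ntags = parts[1], parts[2]
                tags = parts[3:3 + ntags]
                conn = [c - 1 for c in parts[3 + ntags:]]
                if etype == 1:
                    boundary.setdefault(tag_to_marker[tags[0]], []).append(conn)
                elif etype == 2:
                    tris.append(conn)
                    mats.append(tags[0])
    return BreastMesh(nodes=np.array(nodes), tris=np.array(tris, dtype=int),
                      material=np.array(mats, dtype=np.uint8),
                      boundary={k: np.array(v, dtype=int)
                                for k, v in boundary.items()})


def write_vtk(path: str | Path, mesh: BreastMesh,
              point_data: dict[str, np.ndarray] | None = None,
              cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with material + optional fields."""
    out = ["# vtk DataFile Version 3.0\nbctsim mesh\nASCII\n"
           "DATASET UNSTRUCTURED_GRID\n",
           f"POINTS {len(mesh.nodes)} double\n"]
    for x, y in mesh.nodes:
        out.append(f"{x:.9g} {y:.9g} 0\n")
    m = len(mesh.tris)
    out.append(f"CELLS {m} {4 * m}\n")
    for a, b, c in mesh.tris:
        out.append(f"3 {a} {b} {c}\n")
    out.append(f"CELL_TYPES {m}\n" + "5\n" * m)
    cell_data = dict(cell_data or {})
    cell_data.setdefault("material", mesh.material.astype(float))
    out.append(f"CELL_DATA {m}\n")
    for name, arr in cell_data.items():
        out.append(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        out.extend(f"{v:.9g}\n" for v in np.asarray(arr, dtype=float))
    if point_data:
        out.append(f"POINT_DATA {len(mesh.nodes)}\n")
        for name, arr in point_data.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                out.append(f"VECTORS {name} double\n")
                out.extend(f"{v[0]:.9g} {v[1]:.9g} 0\n" for v in arr)
            else:
                out.append(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                out.extend(f"{v:.9g}\n" for v in arr)
    Path(path).write_text("".join(out))
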