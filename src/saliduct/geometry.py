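"""Branched duct geometry: centreline tree, lumen segments, cells and the
cell ↔ segment apical-strip map.

The duct is a tree rooted at the outlet.  Each acinus feeds an intercalated
duct (ID) branch; the ID branches merge into a single striated duct (SD).
The lumen is discretised into nominally 1 µm segments; each epithelial
cell's apical membrane is split into strips, one per lumen segment it
faces, so the strip areas of a cell always sum to its total apical area.

A statistical generator builds synthetic ducts from measured spatial
statistics (SD inner diameter 8 µm, ID 1.6 µm, SD ≈ 80 µm long, longest ID
branch ≈ 45 µm).  Real surface meshes can be ingested through
:func:`classify_apical_triangles`, which labels mesh triangles apical when
their centroid lies within ``radius_factor`` times the local duct radius of
the centreline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "SpatialStats",
    "Branch",
    "CentrelineTree",
    "LumenSegment",
    "CellGeometry",
    "DuctGeometry",
    "generate_synthetic_duct",
    "discretise_centreline",
    "classify_apical_triangles",
    "geometry_to_json",
    "geometry_from_json",
]


@dataclass
class SpatialStats:
    """Spatial statistics of the mouse submandibular duct.

    Radii and lengths in µm, volumes in µm³, areas in µm².  ``cv`` is the
    coefficient of variation applied (lognormally) to per-cell volumes and
    basolateral areas by the synthetic generator.
    """

    id_radius: float = 0.8
    sd_radius: float = 4.0
    id_length: float = 45.0
    sd_length: float = 80.0
    id_cell_length: float = 5.0
    sd_cell_length: float = 5.0
    id_cell_volume: float = 400.0
    sd_cell_volume: float = 700.0
    id_cell_basal_area: float = 200.0
    sd_cell_basal_area: float = 500.0
    cv: float = 0.05

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if name != "cv" and v <= 0:
                raise ValueError(f"spatial statistic {name} must be positive")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")


@dataclass
class Branch:
    """One straight run of duct between branch points.

    ``start``/``end`` are 3-D node positions (µm); flow runs start → end.
    """

    index: int
    start: np.ndarray
    end: np.ndarray
    radius: float
    duct_type: str                  # "ID" | "SD"
    children_of: list = field(default_factory=list)  # upstream branch indices

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class CentrelineTree:
    """Node–segment tree of the duct centreline, rooted at the outlet."""

    branches: list            # list[Branch], topologically ordered leaves→root

    def validate(self) -> None:
        if not self.branches:
            raise ValueError("empty centreline tree")
        consumers = {}
        for b in self.branches:
            if b.radius <= 0:
                raise ValueError("branch radii must be positive")
            for up in b.children_of:
                if up in consumers:
                    raise ValueError("branch feeds two downstream branches")
                consumers[up] = b.index
        roots = [b for b in self.branches if b.index not in consumers]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one outlet")
        leaves = [b for b in self.branches if not b.children_of]
        for b in leaves:
            if b.duct_type != "ID":
                raise ValueError("every leaf must be an ID branch")

    def outlet(self) -> Branch:
        consumed = {up for b in self.branches for up in b.children_of}
        return next(b for b in self.branches if b.index not in consumed)


@dataclass
class LumenSegment:
    """One well-mixed lumen compartment of nominal length Δx."""

    index: int
    length: float                 # Δx, µm
    radius: float
    duct_type: str
    upstream: list                # indices of parent segments (may be empty)
    x: float = 0.0                # arc length from the farthest acinus
    is_leaf: bool = False         # receives primary-saliva inflow
    branch: int = -1              # owning branch of the centreline tree
    inflow_weight: float = 1.0    # number of acini feeding a leaf segment

    @property
    def area(self) -> float:
        """Cross-sectional area, µm²."""
        return float(np.pi * self.radius ** 2)

    @property
    def lateral_per_length(self) -> float:
        """Lateral surface area per unit length, µm."""
        return float(2.0 * np.pi * self.radius)

    @property
    def volume(self) -> float:
        return self.area * self.length


@dataclass
class CellGeometry:
    """One duct cell: areas, resting volume and its apical strips."""

    index: int
    cell_type: str
    apical_area: float
    basal_area: float
    volume: float                  # resting volume w0, µm³
    strips: list                   # list[(segment index, strip area µm²)]

    def validate(self) -> None:
        if min(self.apical_area, self.basal_area, self.volume) <= 0:
            raise ValueError("cell areas and volume must be positive")
        total = sum(a for _, a in self.strips)
        if abs(total - self.apical_area) > 1e-9 * self.apical_area:
            raise ValueError("strip areas must sum to the apical area")


@dataclass
class DuctGeometry:
    """Canonical simulator input: segments plus cells with strip maps."""

    segments: list                 # list[LumenSegment], topological order
    cells: list                    # list[CellGeometry]

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def leaf_indices(self) -> list:
        return [s.index for s in self.segments if s.is_leaf]


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

def generate_synthetic_duct(stats: SpatialStats | None = None,
                            n_acini: int = 4, seed: int = 0,
                            dx: float = 1.0):
    """Build a synthetic branching duct and its cells.

    Returns ``(tree, cells)`` where the cells are tiled along each branch
    with volumes and basolateral areas drawn lognormally around the
    spatial statistics.  Deterministic for a fixed seed.
    """
    stats = stats or SpatialStats()
    stats.validate()
    if n_acini < 1:
        raise ValueError("need at least one acinus")
    rng = np.random.default_rng(seed)

    branches = []
    # SD runs along +x from the junction (x=stats.id_length) to the outlet
    junction = np.array([stats.id_length, 0.0, 0.0])
    outlet = junction + np.array([stats.sd_length, 0.0, 0.0])
    # ID branches fan out upstream of the junction
    for a in range(n_acini):
        angle = 2.0 * np.pi * a / max(n_acini, 1)
        tip = junction - np.array([stats.id_length, 0.0, 0.0])
        # fan the tips out in the y-z plane while keeping branch length fixed
        lateral = 0.3 * stats.id_length * np.array(
            [0.0, np.cos(angle), np.sin(angle)])
        tip = junction - np.array(
            [np.sqrt(max(stats.id_length ** 2 - lateral @ lateral, 1e-12)),
             0.0, 0.0]) - lateral
        branches.append(Branch(a, tip, junction.copy(), stats.id_radius, "ID"))
    branches.append(Branch(n_acini, junction.copy(), outlet,
                           stats.sd_radius, "SD",
                           children_of=list(range(n_acini))))
    tree = CentrelineTree(branches)
    tree.validate()

    segments = discretise_centreline(tree, dx)
    cells = _tile_cells(tree, segments, stats, rng)
    return tree, cells


def _draw(rng, mean, cv):
    """Lognormal draw with given mean and coefficient of variation."""
    if cv == 0:
        return mean
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return float(mean * rng.lognormal(-0.5 * sigma ** 2, sigma))


def _tile_cells(tree: CentrelineTree, segments, stats: SpatialStats, rng):
    """Tile cells along every branch, splitting apical membrane into strips."""
    by_branch = {}
    for seg in segments:
        by_branch.setdefault(seg.branch, []).append(seg)

    cells = []
    for b in tree.branches:
        segs = by_branch[b.index]
        cell_len = (stats.id_cell_length if b.duct_type == "ID"
                    else stats.sd_cell_length)
        mean_vol = (stats.id_cell_volume if b.duct_type == "ID"
                    else stats.sd_cell_volume)
        mean_ab = (stats.id_cell_basal_area if b.duct_type == "ID"
                   else stats.sd_cell_basal_area)
        n_cells = max(1, int(round(b.length / cell_len)))
        bounds = np.linspace(0.0, b.length, n_cells + 1)
        # per-segment start positions along the branch
        pos = 0.0
        seg_spans = []
        for seg in segs:
            seg_spans.append((pos, pos + seg.length))
            pos += seg.length
        for c in range(n_cells):
            lo, hi = bounds[c], bounds[c + 1]
            strips = []
            for seg, (s0, s1) in zip(segs, seg_spans):
                overlap = min(hi, s1) - max(lo, s0)
                if overlap > 1e-12:
                    strips.append((seg.index,
                                   overlap * seg.lateral_per_length))
            a_a = sum(a for _, a in strips)
            cell = CellGeometry(
                index=len(cells),
                cell_type=b.duct_type,
                apical_area=a_a,
                basal_area=_draw(rng, mean_ab, stats.cv),
                volume=_draw(rng, mean_vol, stats.cv),
                strips=strips,
            )
            cell.validate()
            cells.append(cell)
    return cells


def discretise_centreline(tree: CentrelineTree, dx: float = 1.0):
    """Split every branch into segments of length ``dx`` (terminal partial
    segments keep their true length), ordered topologically leaves→outlet.

    Junction segments (the first segment of a branch with upstream
    branches) list the last segment of every parent branch as upstream.
    """
    if dx <= 0:
        raise ValueError("dx must be positive")
    for b in tree.branches:
        if dx > b.length:
            raise ValueError("dx exceeds the shortest branch length")
    tree.validate()

    # topological order of branches, leaves first
    order, seen = [], set()

    def visit(b: Branch):
        for up in b.children_of:
            visit(tree.branches[up])
        if b.index not in seen:
            seen.add(b.index)
            order.append(b)

    visit(tree.outlet())

    # distance from a branch's downstream end to the outlet
    depth_to_outlet = {}

    def walk(b: Branch, acc):
        depth_to_outlet[b.index] = acc
        for up in b.children_of:
            walk(tree.branches[up], acc + b.length)

    walk(tree.outlet(), 0.0)
    total_len = max(depth_to_outlet[b.index] + b.length for b in tree.branches)

    segments = []
    last_of_branch = {}
    for b in order:
        n_full = int(np.floor(b.length / dx + 1e-9))
        rem = b.length - n_full * dx
        lengths = [dx] * n_full + ([rem] if rem > 1e-9 else [])
        upstream_first = ([last_of_branch[up] for up in b.children_of]
                          if b.children_of else [])
        x0 = total_len - (depth_to_outlet[b.index] + b.length)
        pos = 0.0
        prev = None
        for k, ell in enumerate(lengths):
            seg = LumenSegment(
                index=len(segments),
                length=ell,
                radius=b.radius,
                duct_type=b.duct_type,
                upstream=(upstream_first if k == 0 else [prev]),
                x=x0 + pos + ell / 2.0,
                is_leaf=(k == 0 and not b.children_of),
                branch=b.index,
            )
            segments.append(seg)
            prev = seg.index
            pos += ell
        last_of_branch[b.index] = prev
    return segments


# ---------------------------------------------------------------------------
# Mesh characterisation
# ---------------------------------------------------------------------------

def classify_apical_triangles(mesh, tree: CentrelineTree,
                              radius_factor: float = 1.2):
    """Label surface triangles apical/basolateral by centreline distance.

    ``mesh`` is either an object with ``vertices``/``faces`` attributes
    (e.g. a trimesh.Trimesh) or a ``(vertices, faces)`` tuple.  A triangle
    is apical iff the distance from its centroid to the nearest centreline
    branch is ≤ ``radius_factor`` × that branch's radius.

    Returns ``(labels, areas)`` where labels is a boolean array (True =
    apical) and areas a dict with total apical and basolateral areas.
    """
    if hasattr(mesh, "vertices"):
        vertices = np.asarray(mesh.vertices, dtype=float)
        faces = np.asarray(mesh.faces, dtype=int)
    else:
        vertices, faces = mesh
        vertices = np.asarray(vertices, dtype=float)
        faces = np.asarray(faces, dtype=int)
    if len(faces) == 0:
        raise ValueError("empty mesh")

    tri = vertices[faces]                       # (n, 3, 3)
    centroids = tri.mean(axis=1)                # (n, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_areas = 0.5 * np.linalg.norm(cross, axis=1)

    apical = np.zeros(len(faces), dtype=bool)
    for b in tree.branches:
        d = _point_segment_distance(centroids, b.start, b.end)
        apical |= d <= radius_factor * b.radius
    areas = {
        "apical": float(tri_areas[apical].sum()),
        "basolateral": float(tri_areas[~apical].sum()),
    }
    return apical, areas


def _point_segment_distance(points, a, b):
    """Distance from each point to the line segment a–b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def geometry_to_json(geom: DuctGeometry, path=None) -> str:
    """Serialise a duct geometry to JSON (optionally writing to ``path``)."""
    doc = {
        "segments": [
            {
                "index": s.index, "length": s.length, "radius": s.radius,
                "duct_type": s.duct_type, "upstream": list(s.upstream),
                "x": s.x, "is_leaf": s.is_leaf,
            }
            for s in geom.segments
        ],
        "cells": [
            {
                "index": c.index, "cell_type": c.cell_type,
                "apical_area": c.apical_area, "basal_area": c.basal_area,
                "volume": c.volume,
                "strips": [[int(i), float(a)] for i, a in c.strips],
            }
            for c in geom.cells
        ],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def geometry_from_json(source) -> DuctGeometry:
    """Load a duct geometry from a JSON string or file path."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    segments = [
        LumenSegment(index=s["index"], length=s["length"], radius=s["radius"],
                     duct_type=s["duct_type"], upstream=list(s["upstream"]),
                     x=s.get("x", 0.0), is_leaf=s.get("is_leaf", False))
        for s in doc["segments"]
    ]
    cells = [
        CellGeometry(index=c["index"], cell_type=c["cell_type"],
                     apical_area=c["apical_area"], basal_area=c["basal_area"],
                     volume=c["volume"],
                     strips=[(int(i), float(a)) for i, a in c["strips"]])
        for c in doc["cells"]
    ]
    return DuctGeometry(segments=segments, cells=cells)
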