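"""Surface templates, synthetic icospheres and mesh utilities.

A surface template is a pair of triangulated hemisphere meshes in a common
space.  Real cortical templates (fsaverage5/6, fsLR32k) and the CIT168
hippocampal template are loaded from user-supplied geometry files; for fully
self-contained work and for all tests, nested subdivided-icosahedron spheres
("icospheres") stand in for the cortical hemispheres and small open grid
meshes stand in for the unfolded hippocampal sheets.

Icospheres at subdivision level L have ``10 * 4**L + 2`` vertices, so a pair
of level-5 spheres carries 20,484 vertices — the same total as fsaverage5 —
and a level-6 pair carries 81,924, matching fsaverage6.  Subdivision is
*nested*: the vertices of level ``L-1`` appear, with identical coordinates
and indices, as the first vertices of level ``L``.  This nesting is what
makes exact fsaverage5 <-> fsaverage6 resampling possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "TemplateRegistry",
    "build_icosphere",
    "hemisphere_pair",
    "make_grid_mesh",
    "vertex_adjacency",
    "pair_adjacency",
    "unique_edges",
    "mean_edge_length",
    "mesh_area",
    "vertex_areas",
    "TEMPLATE_HEMI_COUNTS",
]

#: Per-hemisphere vertex counts (left, right) of the named supported spaces.
#: The hippocampal CIT168 split is assumed symmetric (total 14,524 is the
#: published figure; the per-side split is not).
TEMPLATE_HEMI_COUNTS: dict[str, tuple[int, int]] = {
    "fsaverage5": (10242, 10242),
    "fsaverage6": (40962, 40962),
    "fsLR32k": (32492, 32492),
    "CIT168": (7262, 7262),
}


class MeshError(ValueError):
    """Raised for invalid mesh geometry or registry lookups."""


@dataclass
class SurfaceMesh:
    """One hemisphere's triangulated geometry.

    Parameters
    ----------
    coords
        ``(V, 3)`` float array of vertex coordinates in mm (template space).
    faces
        ``(F, 3)`` integer array of vertex indices, 0-based.
    hemisphere
        ``"left"`` or ``"right"``.
    space_tag
        Name of the template space, e.g. ``"fsaverage5"`` or
        ``"synthetic-ico5"``.
    parents
        Optional ``(V - n_base, 2)`` array: for meshes produced by one
        subdivision step, the two parent-vertex indices of each appended
        edge-midpoint vertex.  Used for nested upsampling.
    n_base
        Number of leading vertices inherited from the previous subdivision
        level (``parents`` describes vertices ``n_base:``).
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: str
    space_tag: str
    parents: np.ndarray | None = field(default=None, repr=False)
    n_base: int | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise MeshError("coords must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (F, 3)")
        if self.hemisphere not in ("left", "right"):
            raise MeshError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def validate(self, require_connected: bool = True) -> None:
        """Check structural invariants; raise :class:`MeshError` on failure.

        Face indices must lie in ``[0, V)``, no face may repeat a vertex,
        and (optionally) the mesh must be edge-connected.
        """
        v = self.n_vertices
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= v):
            raise MeshError("face index out of range")
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise MeshError("degenerate face (repeated vertex)")
        if require_connected and v > 1:
            n_comp, _ = connected_components(vertex_adjacency(self), directed=False)
            if n_comp != 1:
                raise MeshError(f"mesh is not edge-connected ({n_comp} components)")


# ---------------------------------------------------------------------------
# icosphere construction


def _icosahedron(radius: float) -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    coords = raw * (radius / np.linalg.norm(raw[0]))
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return coords, faces


def _subdivide(
    coords: np.ndarray, faces: np.ndarray, radius: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One 4-way subdivision; returns (coords, faces, midpoint parent pairs).

    Existing vertex coordinates are left untouched (nestedness is exact);
    only the new midpoints are projected onto the sphere.
    """
    n0 = coords.shape[0]
    cache: dict[tuple[int, int], int] = {}
    new_pts: list[np.ndarray] = []
    parents: list[tuple[int, int]] = []

    def midpoint(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = cache.get(key)
        if idx is None:
            m = (coords[i] + coords[j]) / 2.0
            m *= radius / np.linalg.norm(m)
            idx = n0 + len(new_pts)
            new_pts.append(m)
            parents.append(key)
            cache[key] = idx
        return idx

    new_faces = np.empty((faces.shape[0] * 4, 3), dtype=np.int64)
    for k, (a, b, c) in enumerate(faces):
        ab = midpoint(a, b)
        bc = midpoint(b, c)
        ca = midpoint(c, a)
        new_faces[4 * k + 0] = (a, ab, ca)
        new_faces[4 * k + 1] = (b, bc, ab)
        new_faces[4 * k + 2] = (c, ca, bc)
        new_faces[4 * k + 3] = (ab, bc, ca)

    all_coords = np.vstack([coords, np.array(new_pts)])
    return all_coords, new_faces, np.array(parents, dtype=np.int64)


_MAX_ICOSPHERE_LEVEL = 7


def build_icosphere(
    subdivision_level: int,
    radius: float = 100.0,
    hemisphere: str = "left",
    space_tag: str | None = None,
) -> SurfaceMesh:
    """Build a closed icosphere by recursive 4-way subdivision.

    Vertex count is ``10 * 4**level + 2``; subdivision is nested, so the
    first ``10 * 4**(level-1) + 2`` vertices coincide exactly with the
    level ``level-1`` mesh.  The default 100 mm radius gives a mean edge
    length of ~3.8 mm at level 5, comparable to fsaverage5 vertex spacing.

    Raises
    ------
    MeshError
        If ``subdivision_level`` exceeds the memory guard (7) or is
        negative, or ``radius`` is not positive.
    """
    if not 0 <= subdivision_level <= _MAX_ICOSPHERE_LEVEL:
        raise MeshError(
            f"subdivision level must be in [0, {_MAX_ICOSPHERE_LEVEL}], "
            f"got {subdivision_level}"
        )
    if radius <= 0:
        raise MeshError("radius must be positive")
    coords, faces = _icosahedron(radius)
    parents = None
    n_base = None
    for _ in range(subdivision_level):
        n_base = coords.shape[0]
        coords, faces, parents = _subdivide(coords, faces, radius)
    tag = space_tag if space_tag is not None else f"synthetic-ico{subdivision_level}"
    return SurfaceMesh(coords, faces, hemisphere, tag, parents=parents, n_base=n_base)


def hemisphere_pair(
    subdivision_level: int, radius: float = 100.0, space_tag: str | None = None
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """A left/right pair of identical icospheres under one space tag.

    The right hemisphere is offset along +x so peak coordinates are
    distinguishable; there are no cross-hemisphere edges.
    """
    tag = space_tag if space_tag is not None else f"synthetic-ico{subdivision_level}"
    left = build_icosphere(subdivision_level, radius, "left", tag)
    right = build_icosphere(subdivision_level, radius, "right", tag)
    right.coords = right.coords + np.array([3.0 * radius, 0.0, 0.0])
    return left, right


def make_grid_mesh(
    n_rows: int,
    n_cols: int,
    spacing: float = 0.5,
    hemisphere: str = "left",
    space_tag: str = "synthetic-hipp",
) -> SurfaceMesh:
    """Open rectangular grid mesh — stand-in for an unfolded hippocampal sheet.

    ``n_rows * n_cols`` vertices on a planar lattice with the given spacing
    (mm), triangulated by splitting each grid cell into two triangles.
    """
    if n_rows < 2 or n_cols < 2:
        raise MeshError("grid mesh needs at least 2x2 vertices")
    r, c = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    coords = np.column_stack(
        [c.ravel() * spacing, r.ravel() * spacing, np.zeros(n_rows * n_cols)]
    )
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    f1 = np.column_stack(
        [idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(), idx[:-1, 1:].ravel()]
    )
    f2 = np.column_stack(
        [idx[1:, :-1].ravel(), idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()]
    )
    faces = np.vstack([f1, f2])
    mesh = SurfaceMesh(coords, faces, hemisphere, space_tag)
    if hemisphere == "right":
        mesh.coords = mesh.coords + np.array([2.0 * n_cols * spacing, 0.0, 0.0])
    return mesh


# ---------------------------------------------------------------------------
# mesh measurements


def unique_edges(faces: np.ndarray) -> np.ndarray:
    """Unique undirected edges ``(E, 2)`` with i < j, from a face array."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0)


def vertex_adjacency(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Sparse symmetric V x V edge indicator (1 iff the vertices share an edge)."""
    e = unique_edges(mesh.faces)
    v = mesh.n_vertices
    data = np.ones(len(e), dtype=np.int8)
    a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(v, v))
    a = a + a.T
    return a.tocsr()


def pair_adjacency(left: SurfaceMesh, right: SurfaceMesh) -> sp.csr_matrix:
    """Block-diagonal adjacency of a hemisphere pair (no cross-hemisphere edges)."""
    return sp.block_diag(
        [vertex_adjacency(left), vertex_adjacency(right)], format="csr"
    )


def _edge_lengths(mesh: SurfaceMesh) -> np.ndarray:
    e = unique_edges(mesh.faces)
    return np.linalg.norm(mesh.coords[e[:, 0]] - mesh.coords[e[:, 1]], axis=1)


def mean_edge_length(mesh: SurfaceMesh) -> float:
    """Arithmetic mean of the unique edge lengths (mm)."""
    return float(_edge_lengths(mesh).mean())


def _triangle_areas(mesh: SurfaceMesh) -> np.ndarray:
    p = mesh.coords[mesh.faces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mesh_area(mesh: SurfaceMesh) -> float:
    """Total surface area (mm^2)."""
    return float(_triangle_areas(mesh).sum())


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Per-vertex area: one third of the area of each incident triangle."""
    tri = _triangle_areas(mesh)
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], tri / 3.0)
    return out


# ---------------------------------------------------------------------------
# registry


@lru_cache(maxsize=8)
def _cached_pair(level: int, radius: float) -> tuple[SurfaceMesh, SurfaceMesh]:
    return hemisphere_pair(level, radius)


class TemplateRegistry:
    """Maps space tags to hemisphere mesh pairs.

    Synthetic tags ``synthetic-ico{L}`` are built on demand; real templates
    are registered from FreeSurfer or GIFTI geometry files (or directly as
    mesh objects).  Vertex-count bookkeeping for the named supported spaces
    is available even without geometry, via :meth:`hemi_counts`.
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[SurfaceMesh, SurfaceMesh]] = {}

    def register(self, space_tag: str, left: SurfaceMesh, right: SurfaceMesh) -> None:
        if left.n_vertices + right.n_vertices <= 0:
            raise MeshError("empty template")
        self._entries[space_tag] = (left, right)

    def register_files(
        self, space_tag: str, left_path: str | Path, right_path: str | Path
    ) -> None:
        """Register a template from two surface geometry files.

        FreeSurfer binary surfaces and GIFTI ``.surf.gii`` files are
        recognised by extension.
        """
        left = _read_geometry(Path(left_path), "left", space_tag)
        right = _read_geometry(Path(right_path), "right", space_tag)
        self.register(space_tag, left, right)

    def register_config(self, config_path: str | Path) -> None:
        """Register templates from a YAML mapping: tag -> {left: path, right: path}."""
        import yaml

        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
        for tag, paths in cfg.items():
            self.register_files(tag, paths["left"], paths["right"])

    def get(self, space_tag: str) -> tuple[SurfaceMesh, SurfaceMesh]:
        if space_tag in self._entries:
            return self._entries[space_tag]
        if space_tag.startswith("synthetic-ico"):
            level = int(space_tag.removeprefix("synthetic-ico"))
            return _cached_pair(level, 100.0)
        raise MeshError(f"unknown space tag {space_tag!r}")

    def hemi_counts(self, space_tag: str) -> tuple[int, int]:
        """(left, right) vertex counts for a tag, with or without geometry."""
        if space_tag in self._entries:
            left, right = self._entries[space_tag]
            return left.n_vertices, right.n_vertices
        if space_tag in TEMPLATE_HEMI_COUNTS:
            return TEMPLATE_HEMI_COUNTS[space_tag]
        if space_tag.startswith("synthetic-ico"):
            level = int(space_tag.removeprefix("synthetic-ico"))
            n = 10 * 4**level + 2
            return n, n
        raise MeshError(f"unknown space tag {space_tag!r}")

    def total_count(self, space_tag: str) -> int:
        lc, rc = self.hemi_counts(space_tag)
        return lc + rc


def _read_geometry(path: Path, hemisphere: str, space_tag: str) -> SurfaceMesh:
    import nibabel as nib

    if path.suffix == ".gii" or str(path).endswith(".surf.gii"):
        img = nib.load(str(path))
        coords = img.darrays[0].data
        faces = img.darrays[1].data
    else:
        coords, faces = nib.freesurfer.read_geometry(str(path))
    return SurfaceMesh(np.asarray(coords, float), np.asarray(faces, int), hemisphere, space_tag)


#: Shared default registry instance.
default_registry = TemplateRegistry()
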