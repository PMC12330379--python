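"""Surface-data manipulation: smoothing, template resampling, atlas aggregation.

Smoothing uses iterative nearest-neighbour diffusion on the mesh graph — an
approximation to a geodesic Gaussian kernel that needs only the adjacency
structure.  The number of iterations is chosen by matching the variance of
the requested Gaussian: a kernel of full width at half maximum ``f`` has
standard deviation ``f / sqrt(8 ln 2)``, and each averaging pass spreads
mass roughly one edge length, so ``n = ceil(sigma^2 / edge^2)`` passes
(minimum 1) are applied per hemisphere.

Template resampling exploits the nested vertex ordering of the subdivided
icosahedral templates: the coarse template's vertices are the leading
vertices of the fine one, and every additional fine vertex is the midpoint
of one coarse edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cohort import CohortSurface
from .templates import (
    SurfaceMesh,
    build_icosphere,
    mean_edge_length,
    vertex_adjacency,
)

__all__ = [
    "Parcellation",
    "load_parcellation",
    "smoothing_iterations",
    "smooth_surface",
    "fs5_to_fs6",
    "fs6_to_fs5",
    "surf_to_atlas",
    "atlas_to_surf",
]

_GAUSS = 8.0 * np.log(2.0)  # FWHM^2 = 8 ln2 * sigma^2


@dataclass
class Parcellation:
    """Per-vertex integer parcel labels with names (0 = unassigned/medial wall)."""

    labels: np.ndarray
    names: dict[int, str]
    space_tag: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        missing = set(np.unique(self.labels)) - {0} - set(self.names)
        if missing:
            raise ValueError(f"parcel IDs without names: {sorted(missing)}")


def load_parcellation(
    vertex_tsv: str | Path, labels_tsv: str | Path, space_tag: str
) -> Parcellation:
    """Load a parcellation from two TSVs.

    ``vertex_tsv`` columns: ``vertex_index`` (0-based), ``label_id``;
    ``labels_tsv`` columns: ``label_id``, ``name``.
    """
    vt = pd.read_csv(vertex_tsv, sep="\t")
    lt = pd.read_csv(labels_tsv, sep="\t")
    n = int(vt["vertex_index"].max()) + 1
    labels = np.zeros(n, dtype=np.int64)
    labels[vt["vertex_index"].to_numpy()] = vt["label_id"].to_numpy()
    names = dict(zip(lt["label_id"].astype(int), lt["name"].astype(str)))
    return Parcellation(labels, names, space_tag)


# ---------------------------------------------------------------------------
# smoothing


def _averaging_operator(mesh: SurfaceMesh) -> sp.csr_matrix:
    """Row-normalised (self + neighbours) averaging operator."""
    a = vertex_adjacency(mesh).astype(np.float64)
    a = a + sp.eye(mesh.n_vertices, format="csr")
    inv_deg = 1.0 / np.asarray(a.sum(axis=1)).ravel()
    return sp.diags(inv_deg) @ a


def smoothing_iterations(fwhm: float, edge: float) -> int:
    """Iteration count matching the variance of a Gaussian of the given FWHM."""
    sigma2 = fwhm**2 / _GAUSS
    return max(1, int(np.ceil(sigma2 / edge**2)))


def smooth_surface(
    c: CohortSurface, meshes: tuple[SurfaceMesh, SurfaceMesh], fwhm: float
) -> CohortSurface:
    """Smooth every subject's map by iterated neighbour averaging, per hemisphere.

    Constant fields are fixed points of the operator; smoothing never mixes
    values across the hemisphere boundary.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    left, right = meshes
    if c.n_vertices != left.n_vertices + right.n_vertices:
        raise ValueError("cohort width does not match mesh pair")
    out = c.data.copy()
    for mesh, sl in (
        (left, slice(0, c.left_count)),
        (right, slice(c.left_count, c.n_vertices)),
    ):
        op = _averaging_operator(mesh)
        n_iter = smoothing_iterations(fwhm, mean_edge_length(mesh))
        block = out[:, sl].T  # V x N
        for _ in range(n_iter):
            block = op @ block
        out[:, sl] = block.T
    return CohortSurface(
        out, list(c.subject_ids), c.space_tag, c.measure, c.left_count,
        session_ids=None if c.session_ids is None else list(c.session_ids),
    )


# ---------------------------------------------------------------------------
# nested resampling between icosahedral template resolutions


@lru_cache(maxsize=4)
def _subdivision_parents(level: int) -> tuple[int, np.ndarray]:
    """(coarse vertex count, (V_fine - V_coarse, 2) parent pairs) for one level."""
    mesh = build_icosphere(level)
    assert mesh.parents is not None and mesh.n_base is not None
    return mesh.n_base, mesh.parents


def upsample_nested(values: np.ndarray, fine_level: int) -> np.ndarray:
    """One nested upsampling step: copy coarse vertices, average edge parents."""
    n_coarse, parents = _subdivision_parents(fine_level)
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-1] != n_coarse:
        raise ValueError(f"expected {n_coarse} vertices, got {values.shape[-1]}")
    mid = (values[..., parents[:, 0]] + values[..., parents[:, 1]]) / 2.0
    return np.concatenate([values, mid], axis=-1)


def upsample_nested_nearest(values: np.ndarray, fine_level: int) -> np.ndarray:
    """Nearest-neighbour variant: new vertices copy their first parent."""
    n_coarse, parents = _subdivision_parents(fine_level)
    values = np.asarray(values, dtype=np.float64)
    if values.shape[-1] != n_coarse:
        raise ValueError(f"expected {n_coarse} vertices, got {values.shape[-1]}")
    return np.concatenate([values, values[..., parents[:, 0]]], axis=-1)


def downsample_nested(values: np.ndarray, fine_level: int) -> np.ndarray:
    """Restriction to the nested coarse vertex set (exact inverse of upsampling)."""
    n_coarse, _ = _subdivision_parents(fine_level)
    values = np.asarray(values, dtype=np.float64)
    expected = 10 * 4**fine_level + 2
    if values.shape[-1] != expected:
        raise ValueError(f"expected {expected} vertices, got {values.shape[-1]}")
    return values[..., :n_coarse]


def _split_hemis(v: np.ndarray, per_hemi: int) -> tuple[np.ndarray, np.ndarray]:
    return v[..., :per_hemi], v[..., per_hemi:]


def fs5_to_fs6(v: np.ndarray, nearest: bool = False) -> np.ndarray:
    """Remap a 20,484-vertex fsaverage5-resolution map to fsaverage6 (81,924).

    The nested 10,242 vertices per hemisphere are copied; each new vertex is
    the mean of its two parent edge endpoints (or a parent copy with
    ``nearest=True``).
    """
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != 20484:
        raise ValueError(f"expected 20484 vertices, got {v.shape[-1]}")
    up = upsample_nested_nearest if nearest else upsample_nested
    lh, rh = _split_hemis(v, 10242)
    return np.concatenate([up(lh, 6), up(rh, 6)], axis=-1)


def fs6_to_fs5(v: np.ndarray) -> np.ndarray:
    """Restrict an 81,924-vertex fsaverage6-resolution map to fsaverage5."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != 81924:
        raise ValueError(f"expected 81924 vertices, got {v.shape[-1]}")
    lh, rh = _split_hemis(v, 40962)
    return np.concatenate([downsample_nested(lh, 6), downsample_nested(rh, 6)], axis=-1)


# ---------------------------------------------------------------------------
# atlas aggregation


def surf_to_atlas(c: CohortSurface, p: Parcellation) -> pd.DataFrame:
    """Mean vertex value per parcel for each subject (label 0 excluded).

    Returns an ``N x K`` table with parcel names as columns; a named parcel
    with no vertices yields a NaN column.
    """
    if p.labels.size != c.n_vertices:
        raise ValueError("parcellation length does not match cohort width")
    cols = {}
    for label_id, name in sorted(p.names.items()):
        mask = p.labels == label_id
        if mask.any():
            cols[name] = c.data[:, mask].mean(axis=1)
        else:
            cols[name] = np.full(c.n_subjects, np.nan)
    return pd.DataFrame(cols, index=list(c.subject_ids))


def atlas_to_surf(parcel_values: dict[str, float] | pd.Series, p: Parcellation) -> np.ndarray:
    """Scatter one value per named parcel back to the vertices (label 0 -> 0)."""
    if isinstance(parcel_values, pd.Series):
        parcel_values = parcel_values.to_dict()
    missing = [name for name in p.names.values() if name not in parcel_values]
    if missing:
        raise ValueError(f"missing values for parcels: {missing}")
    out = np.zeros(p.labels.size)
    for label_id, name in p.names.items():
        out[p.labels == label_id] = parcel_values[name]
    return out
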