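"""Cluster labelling, result tables, ROI extraction and meta-analytic decoding.

A corrected analysis ends in a :class:`ClusterResults`: the thresholded
t-map, binary positive/negative masks, integer cluster-membership maps and
a tabulated summary (peak coordinates, peak t, region, corrected P).  The
binary masks are the hook for follow-up work — ROI values are obtained by
multiplying a mask into the cohort matrix, and an ROI can be "decoded"
against a database of keyword-labelled association maps by ranking the
keyword maps' correlation with the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .cohort import CohortSurface
from .glm import StatMap
from .ops import Parcellation
from .templates import SurfaceMesh, pair_adjacency

__all__ = [
    "ClusterResults",
    "DecodingDatabase",
    "label_clusters",
    "attach_regions",
    "roi_extract",
    "decode_roi",
]

_TABLE_COLUMNS = [
    "cluster_id", "sign", "n_vertices", "X", "Y", "Z", "tstat", "region", "P",
]


@dataclass
class ClusterResults:
    """Significant-cluster maps and table.

    ``pos_clusterIDmap``/``neg_clusterIDmap`` label vertices 1..K per sign
    (0 = not in a cluster), IDs ordered by descending cluster extent.  The
    table holds one row per cluster; ``P`` is the cluster-corrected
    p-value, filled by the inference routine that produced the mask.
    """

    thresholded_stat_map: np.ndarray
    pos_mask: np.ndarray
    neg_mask: np.ndarray
    pos_clusterIDmap: np.ndarray
    neg_clusterIDmap: np.ndarray
    table: pd.DataFrame
    vertex_p: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.table)


def _components_for_sign(
    mask: np.ndarray, adjacency: sp.csr_matrix
) -> list[np.ndarray]:
    """Connected components of the masked vertex set, largest first."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    comps = [idx[labels == k] for k in range(n_comp)]
    comps.sort(key=lambda a: (-a.size, a.min()))
    return comps


def label_clusters(
    stat: StatMap,
    significant: np.ndarray,
    meshes: tuple[SurfaceMesh, SurfaceMesh],
) -> ClusterResults:
    """Split a significant vertex set into sign-specific connected clusters.

    Components are taken on the hemisphere adjacency (no cross-hemisphere
    edges, so clusters never span hemispheres).  Peak = max |t| vertex of
    each cluster; its template coordinates fill X/Y/Z.  Corrected P is left
    NaN for the caller.
    """
    left, right = meshes
    adjacency = pair_adjacency(left, right)
    coords = np.vstack([left.coords, right.coords])
    t = stat.tvalues
    significant = np.asarray(significant, dtype=bool) & ~stat.degenerate

    thresholded = np.where(significant, t, 0.0)
    rows = []
    maps = {}
    masks = {}
    for sign, name in ((1, "pos"), (-1, "neg")):
        mask = significant & (np.sign(t) == sign)
        id_map = np.zeros(t.size, dtype=np.int64)
        for k, comp in enumerate(_components_for_sign(mask, adjacency), start=1):
            id_map[comp] = k
            peak = comp[np.argmax(np.abs(t[comp]))]
            rows.append(
                {
                    "cluster_id": k,
                    "sign": name,
                    "n_vertices": comp.size,
                    "X": coords[peak, 0],
                    "Y": coords[peak, 1],
                    "Z": coords[peak, 2],
                    "tstat": t[peak],
                    "region": None,
                    "P": np.nan,
                }
            )
        maps[name] = id_map
        masks[name] = mask.astype(np.int8)
    table = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    return ClusterResults(
        thresholded, masks["pos"], masks["neg"], maps["pos"], maps["neg"], table
    )


def attach_regions(cr: ClusterResults, p: Parcellation) -> ClusterResults:
    """Name each cluster after the parcel containing its peak vertex."""
    if p.labels.size != cr.thresholded_stat_map.size:
        raise ValueError("parcellation space does not match cluster maps")
    coords_needed = len(cr.table)
    if coords_needed == 0:
        return cr
    regions = []
    for _, row in cr.table.iterrows():
        id_map = cr.pos_clusterIDmap if row["sign"] == "pos" else cr.neg_clusterIDmap
        comp = np.flatnonzero(id_map == row["cluster_id"])
        t_map = np.abs(cr.thresholded_stat_map[comp])
        peak = comp[np.argmax(t_map)]
        label = int(p.labels[peak])
        regions.append(p.names.get(label, "unassigned") if label != 0 else "unassigned")
    cr.table = cr.table.assign(region=regions)
    return cr


def roi_extract(
    c: CohortSurface, mask: np.ndarray, average: bool = False
) -> np.ndarray:
    """Per-subject ROI value: ``data @ mask`` (sum), optionally divided by |mask|.

    This is the mask-times-matrix product: with a binary mask it totals the
    measure over included vertices for each subject; ``average=True``
    divides by the vertex count to give a per-vertex mean.
    """
    mask = np.asarray(mask, dtype=np.float64).ravel()
    if mask.size != c.n_vertices:
        raise ValueError("mask length does not match cohort width")
    total = c.data @ mask
    if average:
        denom = mask.sum()
        if denom == 0:
            raise ZeroDivisionError("cannot average over an empty mask")
        return total / denom
    return total


# ---------------------------------------------------------------------------
# meta-analytic decoding


@dataclass
class DecodingDatabase:
    """Keyword-labelled association maps on one decoding template.

    ``maps`` is K x V, row k being keyword ``names[k]``'s vertex-wise
    association map.  A real meta-analytic database is imported externally
    into this structure; synthetic databases come from
    :func:`vertexstats.simulate.simulate_decoding_db`.
    """

    names: list[str]
    maps: np.ndarray
    space_tag: str

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=np.float64))
        if self.maps.shape[0] != len(self.names):
            raise ValueError("map rows do not match keyword names")


def decode_roi(
    mask: np.ndarray,
    db: DecodingDatabase,
    exclude: list[str] | None = None,
    space_tag: str | None = None,
) -> pd.DataFrame:
    """Rank database keywords by Pearson correlation with an ROI mask.

    The mask must live on the database's template.  Returns a
    ``(keyword, r)`` table sorted by descending |r| (ties broken
    lexicographically by keyword).
    """
    if space_tag is not None and space_tag != db.space_tag:
        raise ValueError(
            f"mask space {space_tag!r} does not match database space {db.space_tag!r}"
        )
    mask = np.asarray(mask, dtype=np.float64).ravel()
    if mask.size != db.maps.shape[1]:
        raise ValueError("mask length does not match database maps")
    if np.std(mask) == 0:
        raise ValueError("degenerate mask (constant); cannot correlate")

    exclude_set = set(exclude or [])
    keep = [i for i, n in enumerate(db.names) if n not in exclude_set]
    maps = db.maps[keep]
    mc = mask - mask.mean()
    dm = maps - maps.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(dm, axis=1) * np.linalg.norm(mc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, dm @ mc / denom, np.nan)
    out = pd.DataFrame({"keyword": [db.names[i] for i in keep], "r": r})
    out = out.sort_values(
        by=["r", "keyword"],
        key=lambda s: -s.abs() if s.name == "r" else s,
        ascending=True,
    ).reset_index(drop=True)
    return out
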