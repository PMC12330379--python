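"""Synthetic cohorts with known ground truth.

The generator draws data that satisfy the vertex-wise model assumptions
exactly: a constant baseline field, plus covariate effects confined to a
geodesic-hop disk around a centre vertex, plus a per-subject random
intercept, plus Gaussian noise optionally smoothed on the mesh.  With more
than one session the cohort is emitted in long format (one row per
subject-session) and the planted effect enters through the session-by-group
interaction, mirroring a longitudinal intervention design.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .cohort import CohortSurface
from .ops import smooth_surface
from .reporting import DecodingDatabase
from .templates import SurfaceMesh, TemplateRegistry, default_registry, pair_adjacency

__all__ = ["SimulationConfig", "simulate_cohort", "simulate_decoding_db", "effect_region"]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate a mid-sized cross-sectional morphometry study on the
    level-5 synthetic template: 40 subjects, two groups coded -1/1, noise
    of 1 mm standard deviation.  ``effect_size`` is the change in the
    measure per unit of ``effect_covariate`` inside the effect region, so
    with -1/1 group coding a two-group Cohen's d of ``d`` (relative to the
    unsmoothed noise sd) corresponds to ``effect_size = d * noise_sd / 2``.
    """

    n_subjects: int = 40
    n_sessions: int = 1
    space_tag: str = "synthetic-ico5"
    baseline: float = 2.5
    noise_sd: float = 1.0
    noise_smooth_fwhm: float = 0.0
    effect_center: int = 0
    effect_hops: int = 7
    effect_size: float = 0.0
    effect_covariate: str = "group"
    age_range: tuple[float, float] = (20.0, 70.0)
    female_ratio: float = 0.5
    group_coding: tuple[float, float] = (-1.0, 1.0)
    random_intercept_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.random_intercept_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.effect_hops < 0:
            raise ValueError("effect region must be nonempty")


def effect_region(
    meshes: tuple[SurfaceMesh, SurfaceMesh], center: int, hops: int
) -> np.ndarray:
    """Boolean truth mask: vertices within ``hops`` mesh edges of ``center``."""
    adj = pair_adjacency(*meshes)
    dist = dijkstra(adj, directed=False, unweighted=True, indices=center, limit=hops)
    return np.isfinite(dist)


def _covariate_sheet(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_subjects
    age = rng.uniform(*cfg.age_range, size=n)
    sex = np.where(rng.random(n) < cfg.female_ratio, "F", "M")
    half = n // 2
    group = np.r_[
        np.full(half, cfg.group_coding[0]), np.full(n - half, cfg.group_coding[1])
    ]
    sheet = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "group": group,
        }
    )
    if cfg.n_sessions > 1:
        sheet = sheet.loc[sheet.index.repeat(cfg.n_sessions)].reset_index(drop=True)
        sess = np.tile(np.arange(cfg.n_sessions, dtype=float), n)
        sheet["session"] = sess
        sheet["group_x_session"] = sheet["group"] * sheet["session"]
    return sheet


def simulate_cohort(
    cfg: SimulationConfig,
    registry: TemplateRegistry | None = None,
    meshes: tuple[SurfaceMesh, SurfaceMesh] | None = None,
) -> tuple[CohortSurface, pd.DataFrame, np.ndarray]:
    """Generate (cohort, covariate sheet, truth mask) under the config.

    The planted effect multiplies ``effect_covariate`` (``group`` for
    cross-sectional designs, ``group_x_session`` by default when sessions
    are simulated) inside the truth region.  When ``effect_size`` is zero
    the truth mask is empty.
    """
    registry = registry or default_registry
    if meshes is None:
        meshes = registry.get(cfg.space_tag)
    left, right = meshes
    v = left.n_vertices + right.n_vertices
    rng = np.random.default_rng(cfg.seed)

    effect_cov = cfg.effect_covariate
    if cfg.n_sessions > 1 and effect_cov == "group":
        effect_cov = "group_x_session"
    sheet = _covariate_sheet(cfg, rng)
    n_rows = len(sheet)

    if cfg.effect_size != 0.0:
        truth = effect_region(meshes, cfg.effect_center, cfg.effect_hops)
    else:
        truth = np.zeros(v, dtype=bool)

    noise = rng.normal(0.0, cfg.noise_sd, size=(n_rows, v))
    if cfg.noise_smooth_fwhm > 0:
        carrier = CohortSurface(
            noise, [str(i) for i in range(n_rows)], cfg.space_tag, "noise",
            left.n_vertices,
        )
        noise = smooth_surface(carrier, meshes, cfg.noise_smooth_fwhm).data

    data = np.full((n_rows, v), cfg.baseline)
    data += noise
    if cfg.effect_size != 0.0:
        cov_vals = sheet[effect_cov].to_numpy(dtype=float)
        data[:, truth] += cfg.effect_size * cov_vals[:, None]
    if cfg.random_intercept_sd > 0:
        b = rng.normal(0.0, cfg.random_intercept_sd, size=cfg.n_subjects)
        subj_index = pd.factorize(sheet["subject_id"])[0]
        data += b[subj_index][:, None]

    session_ids = (
        [f"ses-{int(s) + 1}" for s in sheet["session"]] if cfg.n_sessions > 1 else None
    )
    cohort = CohortSurface(
        data,
        list(sheet["subject_id"]),
        cfg.space_tag,
        "thickness",
        left.n_vertices,
        session_ids=session_ids,
    )
    return cohort, sheet, truth


def simulate_decoding_db(
    n_keywords: int,
    meshes: tuple[SurfaceMesh, SurfaceMesh],
    planted_support: np.ndarray,
    seed: int = 0,
    space_tag: str | None = None,
    smooth_fwhm: float = 0.0,
) -> DecodingDatabase:
    """Synthetic keyword database: one planted map plus smooth noise maps.

    The first keyword, ``"planted"``, has an association map equal to the
    given support indicator; the remaining ``n_keywords - 1`` maps are
    Gaussian noise (optionally mesh-smoothed), so decoding an ROI equal to
    the support must rank ``"planted"`` first.
    """
    if n_keywords < 1:
        raise ValueError("need at least one keyword")
    left, right = meshes
    v = left.n_vertices + right.n_vertices
    planted_support = np.asarray(planted_support, dtype=np.float64).ravel()
    if planted_support.size != v:
        raise ValueError("planted support length does not match meshes")
    tag = space_tag or left.space_tag
    rng = np.random.default_rng(seed)

    maps = np.empty((n_keywords, v))
    maps[0] = planted_support
    if n_keywords > 1:
        noise = rng.normal(size=(n_keywords - 1, v))
        if smooth_fwhm > 0:
            carrier = CohortSurface(
                noise, [str(i) for i in range(n_keywords - 1)], tag, "map",
                left.n_vertices,
            )
            noise = smooth_surface(carrier, meshes, smooth_fwhm).data
        maps[1:] = noise
    names = ["planted"] + [f"kw_{i:03d}" for i in range(1, n_keywords)]
    return DecodingDatabase(names, maps, tag)
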