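"""Mass-univariate vertex-wise linear models.

One model is fitted independently at every vertex.  The fixed-effects path
is ordinary least squares; the repeated-measures path is a linear mixed
model with a single random intercept per grouping level (typically subject
ID), estimated by restricted maximum likelihood over one variance-ratio
parameter ``lambda = sigma_b^2 / sigma_e^2`` per vertex, with
generalized-least-squares fixed effects.

Both fits produce a :class:`StatMap` of t-statistics for one contrast
column, with a shared (map-wide) degrees-of-freedom value.  Vertices whose
residual variance is numerically zero are flagged degenerate and carry
``t = 0``; downstream cluster formation skips them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .cohort import CohortSurface

__all__ = [
    "ModelSpec",
    "StatMap",
    "DesignMatrix",
    "build_design",
    "fit_vertexwise_ols",
    "fit_vertexwise_mixed",
    "CollinearityError",
]

logger = logging.getLogger(__name__)

_VAR_TINY = 1e-12


class CollinearityError(ValueError):
    """Design matrix is rank deficient."""


@dataclass
class ModelSpec:
    """Covariate sheet + contrast (+ optional random-effect grouping).

    ``covariates`` rows must align with the cohort rows.  ``contrast``
    names the tested column; its coefficient's t-statistic is mapped.
    ``random_group`` names a column with repeated levels (e.g. subject ID)
    for the mixed model.
    """

    covariates: pd.DataFrame
    contrast: str
    random_group: str | None = None

    def __post_init__(self) -> None:
        if self.contrast not in self.covariates.columns:
            raise ValueError(f"contrast column {self.contrast!r} not in covariates")
        if self.random_group is not None and self.random_group not in self.covariates.columns:
            raise ValueError(f"random_group column {self.random_group!r} not in covariates")


@dataclass
class StatMap:
    """Per-vertex t-statistics for one contrast.

    Positive t means positive association with the contrast variable.
    ``degenerate`` marks zero-residual-variance vertices (t forced to 0).
    """

    tvalues: np.ndarray
    dof: float
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]
    space_tag: str | None = None
    variance_ratio: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.tvalues = np.asarray(self.tvalues, dtype=np.float64)
        if self.degenerate is None:
            self.degenerate = np.zeros(self.tvalues.shape, dtype=bool)


class DesignMatrix(NamedTuple):
    matrix: np.ndarray          # N x p, full column rank
    columns: list[str]
    contrast_vector: np.ndarray  # length p, selects the tested coefficient
    row_mask: np.ndarray         # bool, rows kept after missing-value drop


def build_design(spec: ModelSpec) -> DesignMatrix:
    """Compile the covariate sheet into an intercept-led design matrix.

    Numeric covariates pass through unchanged; categorical/text covariates
    are dummy-coded (first level dropped).  Rows with any missing covariate
    are dropped with a warning.  The random-grouping column, if any, is not
    part of the fixed design.
    """
    cov = spec.covariates
    fixed_cols = [c for c in cov.columns if c != spec.random_group]
    sheet = cov[fixed_cols]

    row_mask = ~sheet.isna().any(axis=1).to_numpy()
    if not row_mask.all():
        n_drop = int((~row_mask).sum())
        warnings.warn(f"dropping {n_drop} rows with missing covariates", stacklevel=2)
        sheet = sheet.loc[row_mask]
    if sheet.shape[0] == 0:
        raise ValueError("no rows left after dropping missing covariates")

    pieces = [pd.Series(1.0, index=sheet.index, name="intercept")]
    contrast_col = None
    for name in fixed_cols:
        col = sheet[name]
        if pd.api.types.is_numeric_dtype(col):
            pieces.append(col.astype(float))
            if name == spec.contrast:
                contrast_col = name
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            if name == spec.contrast:
                if dummies.shape[1] != 1:
                    raise ValueError(
                        f"categorical contrast {name!r} must have exactly 2 levels"
                    )
                contrast_col = dummies.columns[0]
            pieces.append(dummies)
    x = pd.concat(pieces, axis=1)
    if contrast_col is None:
        raise ValueError(f"contrast column {spec.contrast!r} produced no coefficient")

    matrix = x.to_numpy(dtype=np.float64)
    columns = list(x.columns)
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        _raise_collinear(matrix, columns)
    cvec = np.zeros(matrix.shape[1])
    cvec[columns.index(contrast_col)] = 1.0
    return DesignMatrix(matrix, columns, cvec, row_mask)


def _raise_collinear(matrix: np.ndarray, columns: list[str]) -> None:
    from scipy.linalg import qr

    _, r, piv = qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    bad = [columns[piv[i]] for i in range(len(columns)) if diag[i] <= tol]
    raise CollinearityError(f"design matrix is rank deficient; dependent columns: {bad}")


# ---------------------------------------------------------------------------
# OLS


def ols_t(y: np.ndarray, x: np.ndarray, cvec: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Vectorized per-vertex OLS t-statistics.

    Returns ``(t, dof, degenerate)`` where ``t[v]`` is the contrast
    coefficient estimate over its standard error at vertex ``v``.
    """
    n, p = x.shape
    dof = n - p
    if dof <= 0:
        raise ValueError(f"insufficient data: N={n} <= rank(X)={p}")
    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    beta = pinv @ y                          # p x V
    resid = y - x @ beta
    ssr = np.einsum("nv,nv->v", resid, resid)
    sigma2 = ssr / dof
    cvar = float(cvec @ xtx_inv @ cvec)
    yss = np.einsum("nv,nv->v", y, y)
    degenerate = ssr <= _VAR_TINY * np.maximum(yss, 1.0)
    se = np.sqrt(np.maximum(sigma2, _VAR_TINY * 1e-6) * cvar)
    t = (cvec @ beta) / se
    t[degenerate] = 0.0
    return t, float(dof), degenerate


def _aligned_data(c: CohortSurface, design: DesignMatrix) -> np.ndarray:
    y = c.data
    if y.shape[0] != design.row_mask.size:
        raise ValueError("covariate sheet rows do not match cohort rows")
    return y[design.row_mask]


def fit_vertexwise_ols(c: CohortSurface, spec: ModelSpec) -> StatMap:
    """Per-vertex ordinary least squares over the cohort matrix."""
    if spec.random_group is not None:
        raise ValueError("spec has random_group set; use fit_vertexwise_mixed")
    design = build_design(spec)
    y = _aligned_data(c, design)
    t, dof, degenerate = ols_t(y, design.matrix, design.contrast_vector)
    n_bad = int(degenerate.sum())
    if n_bad:
        logger.info("flagged %d degenerate (zero-variance) vertices", n_bad)
    return StatMap(t, dof, degenerate, space_tag=c.space_tag)


# ---------------------------------------------------------------------------
# random-intercept mixed model


class RandomInterceptModel:
    """Shared machinery for per-vertex random-intercept GLS/REML fits.

    The marginal covariance is ``sigma_e^2 (I + lambda Z Z')`` where ``Z``
    is the group-indicator matrix.  Since ``Z Z'`` depends only on the
    grouping, one eigendecomposition ``Z Z' = U diag(d) U'`` serves every
    vertex and every candidate ``lambda``: in the rotated basis the
    covariance is diagonal with weights ``1 + lambda d``.
    """

    def __init__(self, x: np.ndarray, groups: np.ndarray, cvec: np.ndarray) -> None:
        self.n, self.p = x.shape
        codes, self.group_levels = pd.factorize(groups)
        self.n_groups = len(self.group_levels)
        z = np.zeros((self.n, self.n_groups))
        z[np.arange(self.n), codes] = 1.0
        d, u = np.linalg.eigh(z @ z.T)
        self.d = np.clip(d, 0.0, None)
        self.u = u
        self.bx = u.T @ x               # rotated design
        self.cvec = cvec
        self.dof = self.n - self.p - (self.n_groups - 1)
        if self.dof <= 0:
            raise ValueError(
                f"insufficient data for mixed model: N={self.n}, p={self.p}, "
                f"groups={self.n_groups}"
            )

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.u.T @ y

    def _reml_neg2(self, lam: float, by: np.ndarray) -> float:
        w = 1.0 + lam * self.d
        wi = 1.0 / w
        m = self.bx.T @ (wi[:, None] * self.bx)
        rhs = self.bx.T @ (wi * by)
        try:
            beta = np.linalg.solve(m, rhs)
        except np.linalg.LinAlgError:
            return np.inf
        q = float(wi @ (by**2) - rhs @ beta)
        if q <= 0:
            return np.inf
        sign, logdet_m = np.linalg.slogdet(m)
        if sign <= 0:
            return np.inf
        nm = self.n - self.p
        return float(np.sum(np.log(w)) + logdet_m + nm * np.log(q / nm))

    def reml_lambda(self, by: np.ndarray) -> float:
        """REML estimate of the variance ratio for one rotated data vector."""
        at_zero = self._reml_neg2(0.0, by)
        res = minimize_scalar(
            lambda u: self._reml_neg2(10.0**u, by),
            bounds=(-6.0, 6.0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.fun < at_zero:
            return float(10.0 ** res.x)
        return 0.0

    def reml_lambda_batch(
        self, by: np.ndarray, grid: np.ndarray | None = None
    ) -> np.ndarray:
        """Grid-search REML variance ratios for all vertices at once.

        For a fixed candidate ``lambda`` the whitening weights are shared
        by every vertex, so the restricted likelihood of all vertices is
        evaluated with a handful of small matrix products per grid point.
        The default grid is 0 plus 81 log-spaced ratios in [1e-4, 1e4]
        (0.1-decade resolution; the t-statistic is flat to first order in
        ``lambda`` around the optimum).
        """
        if grid is None:
            grid = np.concatenate([[0.0], np.logspace(-4.0, 4.0, 81)])
        n_v = by.shape[1]
        nm = self.n - self.p
        best = np.full(n_v, np.inf)
        best_lam = np.zeros(n_v)
        yss_wi = by**2
        for lam in grid:
            w = 1.0 + lam * self.d
            wi = 1.0 / w
            m = self.bx.T @ (wi[:, None] * self.bx)
            sign, logdet_m = np.linalg.slogdet(m)
            if sign <= 0:
                continue
            rhs = self.bx.T @ (wi[:, None] * by)       # p x V
            beta = np.linalg.solve(m, rhs)
            q = wi @ yss_wi - np.einsum("pv,pv->v", rhs, beta)
            with np.errstate(divide="ignore", invalid="ignore"):
                crit = np.sum(np.log(w)) + logdet_m + nm * np.log(q / nm)
            better = np.isfinite(crit) & (crit < best)
            best[better] = crit[better]
            best_lam[better] = lam
        return best_lam

    def gls_t(self, by: np.ndarray, lambdas: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Batched GLS t-statistics given per-vertex variance ratios.

        ``by`` is the rotated data (N x V); returns ``(t, degenerate)``.
        """
        wi = 1.0 / (1.0 + np.outer(self.d, lambdas))      # N x V
        m = np.einsum("np,nv,nq->vpq", self.bx, wi, self.bx)
        rhs = np.einsum("np,nv,nv->vp", self.bx, wi, by)
        beta = np.linalg.solve(m, rhs[..., None])[..., 0]  # V x p
        q = np.einsum("nv,nv->v", wi * by, by) - np.einsum("vp,vp->v", rhs, beta)
        sigma2 = np.maximum(q, 0.0) / (self.n - self.p)
        cvec_b = np.broadcast_to(self.cvec, (by.shape[1], self.p))[..., None]
        minv_c = np.linalg.solve(m, cvec_b)[..., 0]
        cvar = np.einsum("p,vp->v", self.cvec, minv_c)
        yss = np.maximum(np.einsum("nv,nv->v", by, by), 1.0)
        degenerate = q <= _VAR_TINY * yss
        se = np.sqrt(np.maximum(sigma2 * cvar, _VAR_TINY * 1e-6))
        t = (beta @ self.cvec) / se
        t[degenerate] = 0.0
        return t, degenerate


def fit_vertexwise_mixed(c: CohortSurface, spec: ModelSpec) -> StatMap:
    """Per-vertex linear mixed model with a random intercept per group.

    REML estimates one variance ratio per vertex; fixed effects are GLS at
    the estimated ratio.  Degrees of freedom are the conservative
    ``N - rank(X) - (n_groups - 1)``.  If every group is a singleton the
    model collapses to OLS (with a warning).
    """
    if spec.random_group is None:
        raise ValueError("spec.random_group must be set for the mixed model")
    design = build_design(spec)
    y = _aligned_data(c, design)
    groups = spec.covariates[spec.random_group].to_numpy()[design.row_mask]

    _, counts = np.unique(groups, return_counts=True)
    if counts.max() < 2:
        warnings.warn(
            "all random-effect groups are singletons; falling back to OLS",
            stacklevel=2,
        )
        t, dof, degenerate = ols_t(y, design.matrix, design.contrast_vector)
        return StatMap(t, dof, degenerate, space_tag=c.space_tag)

    model = RandomInterceptModel(design.matrix, groups, design.contrast_vector)
    by = model.rotate(y)
    lambdas = np.array([model.reml_lambda(by[:, v]) for v in range(y.shape[1])])
    t, degenerate = model.gls_t(by, lambdas)
    return StatMap(
        t, float(model.dof), degenerate, space_tag=c.space_tag, variance_ratio=lambdas
    )
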