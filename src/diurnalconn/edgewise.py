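"""Edgewise hormone-connectome inference.

Coherence matrices from the 40 sessions are vectorized to an edges x
sessions array; each edge's coherence is z-scored across sessions and
regressed on the z-scored hormone timeseries (optionally with covariates
such as time-since-waking). Significance comes from a nonparametric
permutation null: session labels are permuted jointly for all edges,
models are refit, and the two-tailed p-value of an edge is the proportion
of permuted |t| that equal or exceed the observed |t| (floored at 1/B).
Maps carry a display mask (p < 0.001) and a strength mask (Benjamini-
Hochberg FDR at q < 0.05 across all edges) used for nodal strengths.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from diurnalconn.coherence import CoherenceMatrix

logger = logging.getLogger(__name__)


def edge_index(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edge ordering: row-major, 0-based, (0,1),(0,2),..."""
    return np.triu_indices(n_nodes, 1)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


def vectorize_edges(matrix: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique off-diagonal entries of a symmetric matrix in edge order."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(m, m.T, atol=tol):
        raise ValueError("matrix is not symmetric within tolerance")
    iu = edge_index(m.shape[0])
    return m[iu]


def devectorize_edges(vec: np.ndarray, n_nodes: int, diagonal: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize_edges`."""
    vec = np.asarray(vec, dtype=float)
    if vec.size != n_edges(n_nodes):
        raise ValueError("edge vector length does not match n_nodes")
    out = np.zeros((n_nodes, n_nodes))
    iu = edge_index(n_nodes)
    out[iu] = vec
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return out


@dataclass
class EdgeVectorSet:
    """Edges x sessions coherence with the edge-index mapping."""

    data: np.ndarray  # edges x sessions
    n_nodes: int
    session_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("edge data must be edges x sessions")
        if self.data.shape[0] != n_edges(self.n_nodes):
            raise ValueError("edge count does not match n_nodes")
        if not self.session_ids:
            self.session_ids = [f"ses-{k + 1:02d}" for k in range(self.n_sessions)]

    @property
    def n_sessions(self) -> int:
        return self.data.shape[1]

    @classmethod
    def from_matrices(cls, matrices: Sequence[CoherenceMatrix]) -> "EdgeVectorSet":
        if not matrices:
            raise ValueError("no matrices given")
        n = matrices[0].n_nodes
        if any(m.n_nodes != n for m in matrices):
            raise ValueError("matrices have mismatched sizes")
        data = np.column_stack([vectorize_edges(m.values) for m in matrices])
        return cls(data, n, [m.session_id for m in matrices])


@dataclass
class EdgewiseMap:
    """Per-edge statistics of one hormone-coherence regression."""

    n_nodes: int
    hormone: str
    beta_z: np.ndarray
    t: np.ndarray
    df: int
    p: Optional[np.ndarray] = None
    q: Optional[np.ndarray] = None
    display_mask: Optional[np.ndarray] = None
    strength_mask: Optional[np.ndarray] = None
    covariates: list[str] = field(default_factory=list)
    n_permutations: int = 0
    seed: Optional[int] = None
    exhaustive: bool = False

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.beta_z)

    def to_frame(self):
        import pandas as pd

        iu = edge_index(self.n_nodes)
        d = {
            "edge_i": iu[0],
            "edge_j": iu[1],
            "beta_z": self.beta_z,
            "t": self.t,
        }
        for name in ("p", "q"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v
        for name in ("display_mask", "strength_mask"):
            v = getattr(self, name)
            if v is not None:
                d[name] = v.astype(int)
        return pd.DataFrame(d)

    def metadata(self) -> dict:
        return {
            "hormone": self.hormone,
            "covariates": list(self.covariates),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "df": int(self.df),
            "exhaustive": bool(self.exhaustive),
            "n_nodes": int(self.n_nodes),
        }


def _zscore_rows(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row z-scores (population SD); returns (z, valid mask for sd > 0)."""
    mean = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=0, keepdims=True)
    valid = sd[:, 0] > 0
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (a - mean) / sd_safe, valid


def _design_matrix(hormone_z: np.ndarray, covariates: Optional[np.ndarray]) -> np.ndarray:
    n = len(hormone_z)
    cols = [np.ones(n), hormone_z]
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] == n and C.shape[1] != n:
            C = C.T
        elif C.shape[1] != n:
            raise ValueError("covariates must have one row/column per session")
        for row in C:
            sd = row.std(ddof=0)
            cols.append((row - row.mean()) / sd if sd > 0 else row - row.mean())
    return np.column_stack(cols)


def _fit_t(X: np.ndarray, Yz: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Hormone-coefficient estimate and t over all edges (rows of Yz).

    Yz is edges x sessions, already z-scored per row; X is the full design
    with the hormone z in column 1. Returns (beta, t, df).
    """
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("not enough sessions for the requested model")
    pinv = np.linalg.pinv(X)
    XtXinv = np.linalg.inv(X.T @ X)
    coef = Yz @ pinv.T  # edges x p
    fitted_ss = np.einsum("ep,pq,eq->e", coef, X.T @ X, coef)
    total_ss = np.einsum("es,es->e", Yz, Yz)
    resid_ss = np.maximum(total_ss - fitted_ss, 0.0)
    sigma2 = resid_ss / df
    se = np.sqrt(sigma2 * XtXinv[1, 1])
    beta = coef[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return beta, t, df


def edgewise_regression(
    edges: EdgeVectorSet,
    hormone: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    hormone_name: str = "hormone",
    covariate_names: Optional[Sequence[str]] = None,
) -> EdgewiseMap:
    """Standardized regression of each edge's coherence on the hormone.

    Both sides are z-scored across sessions, so without covariates the
    slope equals the Pearson correlation; with covariates the hormone's
    partial standardized coefficient is reported. Zero-variance edges are
    excluded (NaN statistics) and logged.
    """
    h = np.asarray(hormone, dtype=float)
    if h.ndim != 1 or len(h) != edges.n_sessions:
        raise ValueError("hormone must have one value per session")
    if edges.n_sessions < 4:
        raise ValueError("need >= 4 sessions")
    if h.std(ddof=0) == 0:
        raise ValueError("hormone timeseries has zero variance")
    hz = (h - h.mean()) / h.std(ddof=0)
    Yz, valid = _zscore_rows(edges.data)
    if not valid.all():
        logger.warning("%d zero-variance edges excluded from inference", int((~valid).sum()))
    X = _design_matrix(hz, covariates)
    beta, t, df = _fit_t(X, Yz)
    beta = np.where(valid, beta, np.nan)
    t = np.where(valid, t, np.nan)
    return EdgewiseMap(
        n_nodes=edges.n_nodes,
        hormone=hormone_name,
        beta_z=beta,
        t=t,
        df=df,
        covariates=list(covariate_names or []),
    )


def permutation_null(
    edges: EdgeVectorSet,
    hormone: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    B: int = 10_000,
    seed: int = 0,
    hormone_name: str = "hormone",
    covariate_names: Optional[Sequence[str]] = None,
    chunk: int = 512,
) -> EdgewiseMap:
    """Edgewise permutation test of the hormone-coherence association.

    One session permutation per iteration is applied jointly to all edges
    (equivalent to permuting the session order of the design), preserving
    the cross-edge dependence structure. p(edge) = #{b : |t_b| >= |t_obs|}
    / B, floored at 1/B. When B is at least the number of distinct session
    permutations the test switches to exhaustive enumeration (including the
    identity), with a warning.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    emap = edgewise_regression(edges, hormone, covariates, hormone_name, covariate_names)
    h = np.asarray(hormone, dtype=float)
    hz = (h - h.mean()) / h.std(ddof=0)
    Yz, valid = _zscore_rows(edges.data)
    n = edges.n_sessions

    n_distinct = math.factorial(n) if n <= 20 else None
    exhaustive = n_distinct is not None and B >= n_distinct
    if exhaustive:
        warnings.warn(
            f"B={B} >= {n_distinct} distinct permutations at n={n}; "
            "switching to exhaustive enumeration",
            stacklevel=2,
        )
        perms = np.array(list(_iter_permutations(range(n))))
        B_eff = n_distinct
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(B)])
        B_eff = B

    t_obs = emap.t
    abs_obs = np.abs(np.where(valid, t_obs, np.inf))
    exceed = np.zeros(edges.data.shape[0], dtype=np.int64)
    # Permuting the edge data's session labels by sigma is equivalent to
    # evaluating the unpermuted data against the design re-ordered by sigma.
    if covariates is None:
        # slope equals the Pearson r here, so t_b comes from r in closed form
        df = n - 2
        for start in range(0, B_eff, chunk):
            block = perms[start : start + chunk]
            R = Yz @ hz[block].T / n  # edges x chunk
            with np.errstate(divide="ignore", invalid="ignore"):
                T = R * np.sqrt(df / np.maximum(1.0 - R**2, 0.0))
                T = np.where(np.abs(R) >= 1.0 - 1e-15, np.where(R >= 0, np.inf, -np.inf), T)
            exceed += (np.abs(T) >= abs_obs[:, None] - 1e-12).sum(axis=1)
    else:
        for perm in perms:
            X = _design_matrix(hz[perm], _permute_cov(covariates, perm))
            _, t_b, _ = _fit_t(X, Yz)
            exceed += np.abs(t_b) >= abs_obs - 1e-12
    p = np.maximum(exceed / B_eff, 1.0 / B_eff)
    p = np.where(valid, p, np.nan)
    emap.p = p
    emap.n_permutations = B_eff
    emap.seed = seed
    emap.exhaustive = exhaustive
    return emap


def _permute_cov(covariates: np.ndarray, perm: np.ndarray) -> np.ndarray:
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[1] == len(perm):
        return C[:, perm]
    return C[perm]


def threshold_map(emap: EdgewiseMap, p_alpha: float = 0.001, q: float = 0.05) -> EdgewiseMap:
    """Attach display (p < alpha) and strength (BH FDR q) masks to a map."""
    if emap.p is None:
        raise ValueError("permutation p-values required before thresholding")
    p = emap.p
    valid = np.isfinite(p)
    display = np.zeros_like(valid)
    display[valid] = p[valid] < p_alpha
    qvals = np.full_like(p, np.nan)
    strength = np.zeros_like(valid)
    if valid.any():
        reject, q_adj, _, _ = multipletests(p[valid], alpha=q, method="fdr_bh")
        qvals[valid] = q_adj
        strength[valid] = reject
    emap.q = qvals
    emap.display_mask = display
    emap.strength_mask = strength
    return emap


def compare_maps(a: EdgewiseMap, b: EdgewiseMap) -> tuple[float, int, float]:
    """Spearman correlation between two unthresholded edge maps.

    Returns (rho, df, p) with df = n_edges - 2 over the jointly finite
    edges; requires identical edge sets (same parcellation size).
    """
    if a.n_nodes != b.n_nodes:
        raise ValueError("maps have mismatched edge sets")
    ok = np.isfinite(a.t) & np.isfinite(b.t)
    rho, p = stats.spearmanr(a.t[ok], b.t[ok])
    return float(rho), int(ok.sum() - 2), float(p)
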