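"""Timeseries-level nuisance processing.

Framewise displacement from six rigid-body parameters, the Friston-24
motion expansion (parameters, their squares, one-frame lags, and lagged
squares), binary spike regressors for high-motion frames, and least-squares
residualization of regional timeseries against an assembled design
(median-1000 scaling, linear detrend, then OLS projection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import detrend as _detrend

from diurnalconn.coherence import RegionalTimeseries

logger = logging.getLogger(__name__)

DEFAULT_HEAD_RADIUS_MM = 50.0
DEFAULT_SPIKE_THRESHOLD_MM = 0.5  # 500 microns


@dataclass
class NuisanceDesign:
    """Per-frame nuisance regressors with column labels."""

    matrix: np.ndarray  # frames x columns
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.size == 0:
            self.matrix = self.matrix.reshape(0, 0)
        if not self.labels:
            self.labels = [f"reg{k}" for k in range(self.n_columns)]
        if len(self.labels) != self.n_columns:
            raise ValueError("labels must match design columns")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1] if self.matrix.ndim == 2 else 0

    @property
    def is_empty(self) -> bool:
        return self.n_columns == 0

    def drop_zero_columns(self, tol: float = 1e-12) -> "NuisanceDesign":
        if self.is_empty:
            return self
        keep = np.abs(self.matrix).max(axis=0) > tol
        return NuisanceDesign(self.matrix[:, keep], [l for l, k in zip(self.labels, keep) if k])

    def detrended(self) -> "NuisanceDesign":
        """Linearly detrend every column (matching the treatment of BOLD)."""
        if self.is_empty:
            return self
        return NuisanceDesign(_detrend(self.matrix, axis=0, type="linear"), list(self.labels)).drop_zero_columns()

    def to_tsv(self, path) -> None:
        header = "\t".join(self.labels)
        np.savetxt(path, self.matrix, delimiter="\t", header=header, comments="")


def empty_design(n_frames: int) -> NuisanceDesign:
    return NuisanceDesign(np.zeros((n_frames, 0)), [])


def combine_designs(*designs: NuisanceDesign, detrend: bool = True) -> NuisanceDesign:
    """Concatenate designs column-wise; optionally detrend all regressors."""
    designs = [d for d in designs if not d.is_empty]
    if not designs:
        raise ValueError("no non-empty designs to combine")
    n = designs[0].n_frames
    if any(d.n_frames != n for d in designs):
        raise ValueError("designs have mismatched frame counts")
    combined = NuisanceDesign(
        np.hstack([d.matrix for d in designs]),
        [l for d in designs for l in d.labels],
    )
    return combined.detrended() if detrend else combined.drop_zero_columns()


def read_motion(path) -> np.ndarray:
    """Read a six-column motion trace (translations mm, rotations rad)."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion trace must have six columns")
    return m


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Per-frame framewise displacement (mm).

    FWD(t) = sum |delta translation| + radius * sum |delta rotation|, with
    rotations converted to arc length on a sphere of the given radius; the
    first frame is 0 by convention.
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be frames x 6")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    d = np.abs(np.diff(m, axis=0))
    fwd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fwd])


def friston24(motion: np.ndarray) -> NuisanceDesign:
    """Friston-24 Volterra expansion of the six motion parameters.

    Columns: R (6), R squared (6), R lagged one frame (6, first frame
    zero-padded), and the lagged squares (6).
    """
    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion must be frames x 6")
    if m.shape[0] < 2:
        raise ValueError("need >= 2 frames")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    mat = np.hstack([m, m**2, lag, lag**2])
    names = [f"mp{k + 1}" for k in range(6)]
    labels = names + [f"{n}_sq" for n in names] + [f"{n}_lag" for n in names] + [f"{n}_lag_sq" for n in names]
    return NuisanceDesign(mat, labels)


def spike_regressors(fwd: np.ndarray, threshold_mm: float = DEFAULT_SPIKE_THRESHOLD_MM) -> NuisanceDesign:
    """One binary indicator column per frame with FWD strictly above threshold."""
    fwd = np.asarray(fwd, dtype=float)
    flagged = np.flatnonzero(fwd > threshold_mm)
    if flagged.size == 0:
        return empty_design(len(fwd))
    mat = np.zeros((len(fwd), flagged.size))
    mat[flagged, np.arange(flagged.size)] = 1.0
    return NuisanceDesign(mat, [f"spike_frame{f}" for f in flagged])


def clean_timeseries(ts: RegionalTimeseries, design: NuisanceDesign) -> RegionalTimeseries:
    """Scale, detrend, and residualize a session's regional timeseries.

    The session is globally scaled so the median over all nodes and frames
    is 1,000 (skipped, with a log record, when the median is ~0 as for
    already-residualized input), each node linearly detrended, and then
    residualized by OLS against the (detrended) design columns. Residuals
    are orthogonal to every retained design column. Rank-deficient designs
    have redundant columns dropped with a warning.
    """
    X = ts.data.astype(float)
    if not design.is_empty and design.n_frames != ts.n_frames:
        raise ValueError("design frames do not match timeseries frames")
    med = np.median(X)
    # Median-1000 scaling targets raw data sitting on a positive baseline.
    # Centered (already cleaned) data have a median near zero relative to
    # their spread; rescaling those would blow them up, so skip instead.
    spread = X.std()
    if abs(med) > 0.1 * spread and med != 0:
        X = X * (1000.0 / med)
    else:
        logger.info("session median ~0 relative to spread; skipping median-1000 scaling")
    X = _detrend(X, axis=1, type="linear")
    if not design.is_empty:
        D = design.detrended()
        if not D.is_empty:
            M = D.matrix
            rank = np.linalg.matrix_rank(M)
            if rank < M.shape[1]:
                logger.warning("rank-deficient design (%d < %d); dropping redundant columns", rank, M.shape[1])
                q, r, piv = _qr_column_pivot(M)
                keep = sorted(piv[:rank])
                M = M[:, keep]
            beta, *_ = np.linalg.lstsq(M, X.T, rcond=None)
            X = X - (M @ beta).T
    return RegionalTimeseries(X, ts.tr_seconds, ts.session_id)


def _qr_column_pivot(M: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(M, mode="economic", pivoting=True)
    return q, r, piv
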