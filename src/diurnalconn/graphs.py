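"""Session-level graph topology on thresholded coherence matrices.

Within-network global efficiency (average inverse shortest-path length over
ordered node pairs, edge length = 1/coherence, averaged across the nine
networks) indexes within-network integration; the participation coefficient
P_i = 1 - sum_s (k_is / k_i)^2 over network modules, averaged over connected
nodes, indexes between-network integration. Morning/evening differences use
Welch's two-sample t-test with Cohen's d (pooled SD).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import shortest_path

from diurnalconn.coherence import CoherenceMatrix
from diurnalconn.parcellation import Parcellation

logger = logging.getLogger(__name__)


def _weighted_efficiency(weights: np.ndarray) -> float:
    """Average inverse shortest-path length over ordered pairs.

    Edge length is 1/weight; absent edges (weight 0) have no direct
    connection, and disconnected pairs contribute 0.
    """
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    with np.errstate(divide="ignore"):
        lengths = np.where(weights > 0, 1.0 / weights, 0.0)
    np.fill_diagonal(lengths, 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & (d > 0)
    inv[off & finite] = 1.0 / d[off & finite]
    return float(inv[off].mean())


def global_efficiency(m: CoherenceMatrix, parc: Parcellation, within_networks: bool = True) -> float:
    """Session efficiency: mean weighted efficiency across network subgraphs.

    With ``within_networks=False`` the whole-graph weighted efficiency is
    returned instead. Networks with fewer than two nodes are skipped.
    """
    W = m.values.copy()
    np.fill_diagonal(W, 0.0)
    if W.min() < 0 or W.max() > 1:
        raise ValueError("weights must be in [0, 1]")
    if not within_networks:
        return _weighted_efficiency(W)
    if parc.n_nodes != m.n_nodes:
        raise ValueError("parcellation does not match matrix")
    effs = []
    for net, idx in parc.network_indices().items():
        if len(idx) < 2:
            logger.warning("network %r has < 2 nodes; skipped", net)
            continue
        effs.append(_weighted_efficiency(W[np.ix_(idx, idx)]))
    if not effs:
        raise ValueError("no network with >= 2 nodes")
    return float(np.mean(effs))


def participation(m: CoherenceMatrix, parc: Parcellation) -> float:
    """Session participation: mean coefficient over connected nodes.

    P_i = 1 - sum_s (k_is / k_i)^2 with k_is the coherence-weighted strength
    of node i into network s. Nodes with zero total strength are excluded;
    an entirely disconnected graph is undefined.
    """
    if parc.n_nodes != m.n_nodes:
        raise ValueError("parcellation does not match matrix")
    W = m.values.copy()
    np.fill_diagonal(W, 0.0)
    nets = parc.networks
    onehot = np.stack([(parc.network_of_node == net) for net in nets]).astype(float)
    k_is = W @ onehot.T  # nodes x networks
    k = k_is.sum(axis=1)
    connected = k > 0
    if not connected.any():
        raise ValueError("all nodes isolated; participation undefined")
    frac = k_is[connected] / k[connected, None]
    p = 1.0 - (frac**2).sum(axis=1)
    return float(p.mean())


def node_participation(m: CoherenceMatrix, parc: Parcellation) -> np.ndarray:
    """Per-node participation coefficients (NaN for isolated nodes)."""
    W = m.values.copy()
    np.fill_diagonal(W, 0.0)
    onehot = np.stack([(parc.network_of_node == net) for net in parc.networks]).astype(float)
    k_is = W @ onehot.T
    k = k_is.sum(axis=1)
    out = np.full(m.n_nodes, np.nan)
    conn = k > 0
    frac = k_is[conn] / k[conn, None]
    out[conn] = 1.0 - (frac**2).sum(axis=1)
    return out


def session_metrics(
    matrices: list[CoherenceMatrix],
    parc: Parcellation,
    session_table: pd.DataFrame,
) -> pd.DataFrame:
    """Efficiency and participation per session, joined with AM/PM labels."""
    rows = []
    labels = dict(zip(session_table["session_id"], session_table["time_label"]))
    for m in matrices:
        try:
            part = participation(m, parc)
        except ValueError:
            logger.warning("session %r: all nodes isolated; participation NaN", m.session_id)
            part = float("nan")
        rows.append(
            {
                "session_id": m.session_id,
                "time_label": labels.get(m.session_id, ""),
                "efficiency": global_efficiency(m, parc),
                "participation": part,
            }
        )
    return pd.DataFrame(rows)


def am_pm_compare(metrics: pd.DataFrame, field: str) -> dict:
    """Welch two-sample t-test of a session metric, morning minus evening.

    Returns the Welch t and Welch-Satterthwaite df, two-tailed p, and
    Cohen's d with the pooled SD (positive values mean AM > PM). When the
    metric is constant within both groups the test statistic is undefined;
    the result then carries the raw mean difference with NaN t/p and a
    ``degenerate`` flag instead of raising, since a constant metric is a
    legitimate outcome (e.g. participation is identically zero when no
    between-network edge survives thresholding in any session).
    """
    am = metrics.loc[metrics["time_label"] == "AM", field].to_numpy(dtype=float)
    pm = metrics.loc[metrics["time_label"] == "PM", field].to_numpy(dtype=float)
    am = am[np.isfinite(am)]  # sessions with an undefined metric are dropped
    pm = pm[np.isfinite(pm)]
    if len(am) < 2 or len(pm) < 2:
        raise ValueError("need >= 2 sessions per group")
    v1, v2 = am.var(ddof=1), pm.var(ddof=1)
    n1, n2 = len(am), len(pm)
    if v1 == 0 and v2 == 0:
        logger.warning("metric %r constant within AM and PM; Welch test undefined", field)
        return {
            "t": float("nan"), "df_welch": float("nan"), "p": float("nan"),
            "cohens_d": float("nan"), "n_am": n1, "n_pm": n2,
            "mean_diff": float(am.mean() - pm.mean()), "degenerate": True,
        }
    t, p = stats.ttest_ind(am, pm, equal_var=False)
    df = (v1 / n1 + v2 / n2) ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    pooled_sd = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = (am.mean() - pm.mean()) / pooled_sd if pooled_sd > 0 else np.nan
    return {"t": float(t), "df_welch": float(df), "p": float(p), "cohens_d": float(d),
            "n_am": n1, "n_pm": n2, "mean_diff": float(am.mean() - pm.mean()),
            "degenerate": False}
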