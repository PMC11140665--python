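"""Study-scale validation harnesses with known ground truth.

The real study's brain-hormone maps cannot be recomputed without its data,
so the pipeline is validated on synthetic studies instead: permutation
p-value calibration under null coupling, recovery of known hormone-coupled
edges at the study's sample size, exhaustive-permutation equivalence at
tiny n, the analytic small-sample bias of the Welch coherence estimator on
independent noise, and the handshake identity linking nodal strengths to
edge sums. These functions are shared by the test suite and the acceptance
script.
"""

from __future__ import annotations

import math
from itertools import permutations as _iter_permutations

import numpy as np
from scipy import stats

from diurnalconn.config import CoupledEdge, RunConfig, StudyConfig, derive_seeds
from diurnalconn.edgewise import (
    EdgeVectorSet,
    edgewise_regression,
    permutation_null,
    threshold_map,
)
from diurnalconn.pipeline import run_pipeline


def null_uniformity(seed: int = 0, n_nodes: int = 46, B: int = 500) -> dict:
    """KS test of permutation-p uniformity under null coupling.

    Runs the full pipeline (simulate, clean, connectomes, permutation
    regression) on a study with no hormone-coupled edges; under the null
    the edgewise permutation p-values are uniform on {1/B, ..., 1}, so a
    Kolmogorov-Smirnov test against U(0, 1) should not reject. ``n_nodes``
    of 46 yields 1,035 edges.
    """
    cfg = RunConfig(
        study=StudyConfig(n_nodes=n_nodes, seed=seed),
        hormones=("testosterone_saliva",),
        n_permutations=B,
        seed=seed,
    )
    run = run_pipeline(cfg)
    emap = run["results"]["maps"]["testosterone_saliva"]
    p = emap.p[np.isfinite(emap.p)]
    ks = stats.kstest(p, "uniform")
    return {
        "n_edges": int(p.size),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "B": B,
    }


def default_coupled_edges(n_edges: int = 10, beta: float = 0.15) -> list[CoupledEdge]:
    """Disjoint coupled edges (2k, 2k+1) with alternating coupling signs."""
    return [
        CoupledEdge(2 * k, 2 * k + 1, beta if k % 2 == 0 else -beta)
        for k in range(n_edges)
    ]


def edge_recovery(
    seed: int = 0,
    n_seeds: int = 20,
    n_nodes: int = 40,
    n_coupled: int = 10,
    beta: float = 0.15,
    B: int = 2000,
) -> dict:
    """Recovery of known hormone-coupled edges across replicate studies.

    For each replicate, a 40-session study with ``n_coupled`` coupled edges
    (|beta| in coherence units per hormone SD) is simulated and analyzed
    end to end; edges surviving BH FDR at q = 0.05 are compared with the
    ground truth. Returns mean sensitivity and mean empirical false
    discovery proportion over replicates.
    """
    child = derive_seeds(seed, n_seeds)
    sens, fdr = [], []
    for s in child:
        cfg = RunConfig(
            study=StudyConfig(
                n_nodes=n_nodes,
                coupled_edges=default_coupled_edges(n_coupled, beta),
                seed=s,
            ),
            hormones=("testosterone_saliva",),
            n_permutations=B,
            seed=s,
        )
        run = run_pipeline(cfg)
        rec = run["report"]["ground_truth_recovery"]
        sens.append(rec["sensitivity"])
        fdr.append(rec["empirical_fdr"])
    return {
        "n_seeds": n_seeds,
        "mean_sensitivity": float(np.mean(sens)),
        "mean_empirical_fdr": float(np.mean(fdr)),
        "per_seed_sensitivity": [float(v) for v in sens],
        "per_seed_fdr": [float(v) for v in fdr],
    }


def exhaustive_permutation_check(seed: int = 0, n_sessions: int = 5, n_edges: int = 12) -> dict:
    """Exact-permutation equivalence at tiny n.

    With n = 5 sessions there are 120 distinct session permutations; the
    permutation engine switches to exhaustive enumeration, and its p-values
    must equal a direct brute-force enumeration of |t| exceedances edge by
    edge. Returns the maximum absolute p difference (0 when exact).
    """
    rng = np.random.default_rng(seed)
    n_nodes = int(np.ceil((1 + math.sqrt(1 + 8 * n_edges)) / 2))
    m = n_nodes * (n_nodes - 1) // 2
    data = rng.standard_normal((m, n_sessions))
    hormone = rng.standard_normal(n_sessions)
    edges = EdgeVectorSet(data, n_nodes)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emap = permutation_null(edges, hormone, B=math.factorial(n_sessions), seed=seed)
    # independent brute force: enumerate all session orderings of the hormone
    hz = (hormone - hormone.mean()) / hormone.std(ddof=0)
    Yz = (data - data.mean(axis=1, keepdims=True)) / data.std(axis=1, ddof=0, keepdims=True)
    n = n_sessions
    t_obs = _t_from_r(Yz @ hz / n, n)
    count = np.zeros(m)
    total = 0
    for perm in _iter_permutations(range(n)):
        t_b = _t_from_r(Yz @ hz[list(perm)] / n, n)
        count += np.abs(t_b) >= np.abs(t_obs) - 1e-12
        total += 1
    p_brute = np.maximum(count / total, 1.0 / total)
    return {
        "n_permutations": total,
        "max_abs_p_diff": float(np.max(np.abs(emap.p - p_brute))),
    }


def _t_from_r(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    return np.where(np.abs(r) >= 1.0 - 1e-15, np.where(r >= 0, np.inf, -np.inf), t)


def msc_estimator_bias(seed: int = 0, L: int = 8, window: int = 64, n_trials: int = 200) -> dict:
    """Small-sample bias of the Welch MSC on independent white noise.

    With L non-overlapping segments, the expected magnitude-squared
    coherence of two independent series is approximately 1/L at interior
    frequency bins. Returns the empirical mean (averaged over bins and
    trials) and its ratio to 1/L.
    """
    from diurnalconn.coherence import ms_coherence

    rng = np.random.default_rng(seed)
    n_frames = L * window
    band = (1.0 / window, 0.5 - 1.0 / window)  # interior bins: no DC/Nyquist
    vals = []
    for _ in range(n_trials):
        x = rng.standard_normal((2, n_frames))
        vals.append(ms_coherence(x[0], x[1], 1.0, band=band, window=window, overlap=0.0))
    mean = float(np.mean(vals))
    return {"L": L, "mean_msc": mean, "expected": 1.0 / L, "ratio": mean * L}


def handshake_identity(seed: int = 0, n_nodes: int = 30) -> dict:
    """Nodal strengths double-count each edge once per endpoint.

    Sum over nodes of positive strength must equal exactly twice the sum of
    the masked positive edge statistics (and likewise for magnitudes of
    negative edges). Exercised on a random masked map.
    """
    from diurnalconn.networks import nodal_strengths
    from diurnalconn.parcellation import build_parcellation
    from diurnalconn.edgewise import EdgewiseMap, n_edges as _n_edges

    rng = np.random.default_rng(seed)
    m = _n_edges(n_nodes)
    t = rng.standard_normal(m) * 3
    p = rng.uniform(size=m)
    emap = EdgewiseMap(n_nodes=n_nodes, hormone="synthetic", beta_z=t / 4, t=t, df=38, p=p)
    emap = threshold_map(emap, p_alpha=0.05, q=0.5)
    parc = build_parcellation(n_nodes)
    strengths = nodal_strengths(emap, parc)
    pos_sum = float(strengths["positive_strength"].sum())
    neg_sum = float(strengths["negative_strength"].sum())
    masked = emap.t[emap.strength_mask]
    edge_pos = float(masked[masked > 0].sum())
    edge_neg = float(np.abs(masked[masked < 0]).sum())
    return {
        "node_positive_sum": pos_sum,
        "edge_positive_sum_x2": 2 * edge_pos,
        "node_negative_sum": neg_sum,
        "edge_negative_sum_x2": 2 * edge_neg,
        "positive_ratio": pos_sum / (2 * edge_pos) if edge_pos else float("nan"),
    }
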