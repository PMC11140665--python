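"""End-to-end orchestration: simulate -> clean -> connect -> regress -> summarize.

``run_pipeline`` runs the whole analysis in memory from a ``RunConfig`` and
returns a JSON-serializable report of the headline numbers (diurnal percent
decreases, edgewise survivor counts, network ANOVA statistics, map
similarity, and morning/evening topology comparisons) together with the
intermediate artifacts. A single master seed drives independent child
streams for the hormone, BOLD, motion, and permutation stages so partial
reruns are reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from diurnalconn import graphs, hormones as hormod, networks, nuisance
from diurnalconn.coherence import CoherenceMatrix, coherence_matrix, fdr_threshold_matrix
from diurnalconn.config import RunConfig, derive_seeds
from diurnalconn.edgewise import (
    EdgeVectorSet,
    compare_maps,
    permutation_null,
    threshold_map,
)
from diurnalconn.parcellation import build_parcellation
from diurnalconn.synthetic import (
    generate_bold,
    generate_hormones,
    generate_motion_and_mood,
)

logger = logging.getLogger(__name__)


def simulate_study(config: RunConfig) -> dict:
    """Generate the synthetic study (hormones, BOLD, motion, mood, truth)."""
    s_h, s_b, s_m, _ = derive_seeds(config.seed, 4)
    hormone_table = generate_hormones(config.study, s_h)
    sessions, truth = generate_bold(config.study, hormone_table, s_b)
    motion, mood = generate_motion_and_mood(config.study, s_m)
    parc = build_parcellation(config.study.n_nodes)
    return {
        "hormones": hormone_table,
        "sessions": sessions,
        "truth": truth,
        "motion": motion,
        "mood": mood,
        "parcellation": parc,
    }


def clean_sessions(sessions, motion) -> tuple[list, pd.DataFrame]:
    """Nuisance-clean each session; returns cleaned series and an FWD table."""
    cleaned = []
    fwd_rows = []
    for ts, mo in zip(sessions, motion):
        fwd = nuisance.framewise_displacement(mo)
        spikes = nuisance.spike_regressors(fwd)
        designs = [nuisance.friston24(mo)]
        if not spikes.is_empty:
            designs.append(spikes)
        design = nuisance.combine_designs(*designs)
        cleaned.append(nuisance.clean_timeseries(ts, design))
        fwd_rows.append(
            {
                "session_id": ts.session_id,
                "mean_fwd_mm": float(fwd.mean()),
                "max_fwd_mm": float(fwd.max()),
                "n_spike_frames": int(spikes.n_columns),
            }
        )
    return cleaned, pd.DataFrame(fwd_rows)


def build_connectomes(cleaned, config: RunConfig) -> tuple[list[CoherenceMatrix], list[CoherenceMatrix]]:
    """Per-session coherence matrices, raw and per-session FDR-thresholded."""
    raw = [
        coherence_matrix(
            ts,
            window=config.welch_window,
            overlap=config.welch_overlap,
            wavelet=config.wavelet,
            levels=config.wavelet_levels,
        )
        for ts in cleaned
    ]
    thresholded = [fdr_threshold_matrix(m, config.fdr_q) for m in raw]
    return raw, thresholded


def analyze_connectomes(
    matrices: list[CoherenceMatrix],
    hormone_table: pd.DataFrame,
    parc,
    config: RunConfig,
) -> dict:
    """Edgewise permutation regression per hormone, strengths, and summaries."""
    _, _, _, s_perm = derive_seeds(config.seed, 4)
    perm_seeds = derive_seeds(s_perm, len(config.hormones))
    maps = {}
    strengths = {}
    summaries = {}
    for seed, hormone in zip(perm_seeds, config.hormones):
        h = hormone_table[hormone].to_numpy(dtype=float)
        keep = np.isfinite(h)
        sub = [m for m, k in zip(matrices, keep) if k]
        edges = EdgeVectorSet.from_matrices(sub)
        cov = None
        cov_names: list[str] = []
        if config.covariates:
            cov = hormone_table.loc[keep, list(config.covariates)].to_numpy(dtype=float).T
            cov_names = list(config.covariates)
        emap = permutation_null(
            edges,
            h[keep],
            covariates=cov,
            B=config.n_permutations,
            seed=seed,
            hormone_name=hormone,
            covariate_names=cov_names,
        )
        emap = threshold_map(emap, config.p_alpha, config.fdr_q)
        maps[hormone] = emap
        strengths[hormone] = networks.nodal_strengths(emap, parc)
        summaries[hormone] = networks.network_summary(strengths[hormone], parc)
    return {"maps": maps, "strengths": strengths, "network_summaries": summaries}


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-study analysis; returns artifacts and a report."""
    config.validate()
    t0 = time.time()
    timings = {}
    artifacts = simulate_study(config)
    timings["simulate_s"] = round(time.time() - t0, 2)

    t1 = time.time()
    cleaned, fwd_table = clean_sessions(artifacts["sessions"], artifacts["motion"])
    timings["clean_s"] = round(time.time() - t1, 2)

    t2 = time.time()
    raw, thresholded = build_connectomes(cleaned, config)
    timings["connectomes_s"] = round(time.time() - t2, 2)

    t3 = time.time()
    matrices = thresholded if config.threshold_session_matrices else raw
    results = analyze_connectomes(matrices, artifacts["hormones"], artifacts["parcellation"], config)
    timings["edgewise_s"] = round(time.time() - t3, 2)

    t4 = time.time()
    metrics = graphs.session_metrics(thresholded, artifacts["parcellation"], artifacts["hormones"])
    topo = {}
    for metric_name in ("efficiency", "participation"):
        try:
            topo[metric_name] = graphs.am_pm_compare(metrics, metric_name)
        except ValueError as exc:
            logger.warning("AM/PM comparison of %r undefined: %s", metric_name, exc)
            topo[metric_name] = {"degenerate": True, "reason": str(exc)}
    timings["graph_metrics_s"] = round(time.time() - t4, 2)

    diurnal = hormod.diurnal_summary_table(artifacts["hormones"])
    report = build_report(config, artifacts, results, diurnal, topo, fwd_table, timings)
    return {
        "config": config,
        "report": report,
        "artifacts": artifacts,
        "cleaned": cleaned,
        "matrices_raw": raw,
        "matrices_thresholded": thresholded,
        "fwd_table": fwd_table,
        "results": results,
        "session_metrics": metrics,
    }


def build_report(config, artifacts, results, diurnal, topo, fwd_table, timings) -> dict:
    maps = results["maps"]
    survivors = {
        h: {
            "display_p": int(m.display_mask.sum()),
            "strength_fdr": int(m.strength_mask.sum()),
            "n_valid_edges": int(m.valid.sum()),
        }
        for h, m in maps.items()
    }
    similarity = {}
    names = list(maps)
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rho, df, p = compare_maps(maps[names[a]], maps[names[b]])
            similarity[f"{names[a]}__{names[b]}"] = {"rho": round(rho, 4), "df": df, "p": p}
    truth = artifacts["truth"]
    recovery = None
    if truth.coupled_edges:
        recovery = recovery_metrics(maps.get(truth.coupling_analyte), truth)
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_nodes": config.study.n_nodes,
        "n_sessions": config.study.n_sessions,
        "diurnal_pct_decrease": {
            r["analyte"]: round(float(r["pct_decrease"]), 2) for _, r in diurnal.iterrows()
        },
        "edgewise_survivors": survivors,
        "map_similarity": similarity,
        "am_pm_topology": topo,
        "mean_fwd_mm": round(float(fwd_table["mean_fwd_mm"].mean()), 5),
        "sessions_with_spikes": int((fwd_table["n_spike_frames"] > 0).sum()),
        "ground_truth_recovery": recovery,
        "stage_timings": timings,
    }
    return report


def recovery_metrics(emap, truth) -> Optional[dict]:
    """Sensitivity and false-discovery rate against the generator's truth."""
    if emap is None or emap.strength_mask is None:
        return None
    from diurnalconn.edgewise import edge_index

    iu = edge_index(emap.n_nodes)
    detected = {
        (int(i), int(j))
        for i, j, keep in zip(iu[0], iu[1], emap.strength_mask)
        if keep
    }
    true_edges = truth.edge_set()
    tp = len(detected & true_edges)
    fp = len(detected - true_edges)
    sens = tp / len(true_edges) if true_edges else np.nan
    fdr = fp / max(len(detected), 1)
    return {
        "n_true_edges": len(true_edges),
        "n_detected": len(detected),
        "true_positives": tp,
        "sensitivity": round(float(sens), 4),
        "empirical_fdr": round(float(fdr), 4),
    }


def write_outputs(out_dir, run: dict) -> None:
    """Write the pipeline's tables and the JSON report under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = run["config"]
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    run["artifacts"]["hormones"].to_csv(out / "sessions.tsv", sep="\t", index=False)
    run["artifacts"]["parcellation"].to_tsv(out / "parcellation.tsv")
    run["fwd_table"].to_csv(out / "fwd.tsv", sep="\t", index=False)
    run["session_metrics"].to_csv(out / "session_metrics.tsv", sep="\t", index=False)
    for hormone, emap in run["results"]["maps"].items():
        df = emap.to_frame()
        df.to_csv(out / f"edgewise_{hormone}.tsv", sep="\t", index=False)
        meta = {**emap.metadata(), **stamp}
        with open(out / f"edgewise_{hormone}.json", "w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
        run["results"]["strengths"][hormone].to_csv(
            out / f"strengths_{hormone}.tsv", sep="\t", index=False
        )
        run["results"]["network_summaries"][hormone].to_csv(
            out / f"network_summary_{hormone}.tsv", sep="\t", index=False
        )
    with open(out / "report.json", "w") as fh:
        json.dump(run["report"], fh, indent=2, sort_keys=True)
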