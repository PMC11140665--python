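"""Synthetic dense-sampling study generator with known ground truth.

Emulates a 40-session / 30-day single-subject design: 20 morning sessions
at 7 A.M. and 20 evening sessions at 8 P.M., diurnal hormone draws around
per-analyte morning/evening means, serum analytes available on 30 of the 40
sessions, regional BOLD-like timeseries with network-block structure in the
0.01-0.17 Hz band, and a configurable set of edges whose band coherence
varies linearly with a z-scored hormone. The generator records the coupling
as ground truth so the downstream edgewise pipeline can be tested for
parameter recovery.

Signal model per session. Every node mixes unit-variance band-limited
latent components plus white measurement noise. A global latent (weight a,
a^2 = sqrt(global_coherence)) gives every pair a coherence floor of a^4; a
network-block latent tops within-network pairs up to the block baseline
(a^2 + b^2 = sqrt(baseline_block_coherence)); a node-private latent absorbs
the remaining variance. Coupled-edge endpoints carry no block latent: their
pair latent's weight w(s) solves a^2 + w(s)^2 = sqrt(rho(s)) with target
rho(s) = clip(baseline + beta * z_s), and their private weight shrinks to
keep unit variance. Because each node's global/block weights are constant
across sessions, only the listed edges' coherence tracks the hormone; the
realized coherence is an emergent quantity the estimator can check.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from diurnalconn.coherence import RegionalTimeseries, modwt_bandlimit
from diurnalconn.config import ConfigError, StudyConfig
from diurnalconn.parcellation import Parcellation, build_parcellation

logger = logging.getLogger(__name__)

MOOD_SCALES = {
    # scale: (min, max, mean, sd)
    "stress_pss": (0, 40, 10.0, 3.0),
    "anxiety_stai": (20, 80, 30.0, 5.0),
    "poms_total": (-32, 200, 10.0, 8.0),
    "poms_vigor": (0, 32, 18.0, 4.0),
    "poms_fatigue": (0, 28, 6.0, 3.0),
    "aggression_aq": (29, 145, 60.0, 8.0),
    "sleep_psqi": (0, 21, 3.0, 1.5),
}


@dataclass
class GroundTruth:
    """The coupling the generator injected, stored apart from the data."""

    coupled_edges: list[dict]  # {"i", "j", "beta", "baseline"}
    session_hormone_z: dict[str, list[float]]
    coupling_analyte: str

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "coupled_edges": self.coupled_edges,
                    "session_hormone_z": self.session_hormone_z,
                    "coupling_analyte": self.coupling_analyte,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["coupled_edges"], d["session_hormone_z"], d["coupling_analyte"])

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(e["i"], e["j"]), max(e["i"], e["j"])) for e in self.coupled_edges}


def session_schedule(config: StudyConfig) -> pd.DataFrame:
    """Session calendar: 20 AM + 20 PM over 30 days, serum on 30 sessions.

    Single-session days open (AM) and close (PM) the study; the middle days
    carry both a morning and an evening session with one blood draw per day,
    alternating AM/PM, so serum sessions split evenly by time of day.
    """
    n = config.n_sessions
    n_days = config.n_days
    n_double_days = n - n_days
    if not 0 <= n_double_days <= n_days:
        raise ConfigError("n_sessions incompatible with n_days (need n_days <= n_sessions <= 2*n_days)")
    n_single = n_days - n_double_days
    n_am_single = n_single // 2 + n_single % 2
    rows = []
    # leading AM-only days
    for d in range(1, n_am_single + 1):
        rows.append({"day": d, "time_label": "AM"})
    # double-session days in the middle
    for d in range(n_am_single + 1, n_am_single + n_double_days + 1):
        rows.append({"day": d, "time_label": "AM"})
        rows.append({"day": d, "time_label": "PM"})
    # trailing PM-only days
    for d in range(n_am_single + n_double_days + 1, n_days + 1):
        rows.append({"day": d, "time_label": "PM"})
    df = pd.DataFrame(rows)
    df["session_id"] = [f"ses-{k + 1:02d}" for k in range(len(df))]
    df["clock_time"] = np.where(df["time_label"] == "AM", "07:00", "20:00")
    df["wake_hours"] = np.where(df["time_label"] == "AM", 1.0, 14.0)
    # serum draws: all single-session days, plus one per double day alternating
    serum = np.zeros(len(df), dtype=bool)
    double_days = sorted(set(df.loc[df.duplicated("day", keep=False), "day"]))
    singles = df.loc[~df["day"].isin(double_days)].index
    serum[singles] = True
    budget = config.n_serum_sessions - len(singles)
    for k, d in enumerate(double_days):
        if budget <= 0:
            break
        pick = "AM" if k % 2 == 0 else "PM"
        idx = df.index[(df["day"] == d) & (df["time_label"] == pick)][0]
        serum[idx] = True
        budget -= 1
    df["serum"] = serum
    if serum.sum() != config.n_serum_sessions:
        # fall back: fill remaining serum slots in calendar order
        need = config.n_serum_sessions - int(serum.sum())
        free = df.index[~df["serum"]][:max(need, 0)]
        df.loc[free, "serum"] = True
    cols = ["session_id", "day", "time_label", "clock_time", "wake_hours", "serum"]
    return df[cols]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws redrawn (not clipped) until non-negative."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    for _ in range(1000):
        bad = out < 0
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    out[out < 0] = 0.0
    return out


def generate_hormones(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Per-session hormone concentrations with the configured diurnal profile.

    AM rows draw from (mean_am, sd_am) and PM rows from (mean_pm, sd_pm)
    per analyte, redrawn at zero to stay non-negative; serum-only analytes
    are missing (NaN) outside the blood-draw sessions.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    table = session_schedule(config)
    am = (table["time_label"] == "AM").to_numpy()
    for name, hp in config.hormone_params.items():
        vals = np.empty(len(table))
        vals[am] = _truncated_normal(rng, hp.mean_am, hp.sd_am, int(am.sum()))
        vals[~am] = _truncated_normal(rng, hp.mean_pm, hp.sd_pm, int((~am).sum()))
        if hp.serum_only:
            vals = np.where(table["serum"].to_numpy(), vals, np.nan)
        table[name] = vals
    return table


def _standardize_band_latents(rng: np.random.Generator, n: int, n_frames: int) -> np.ndarray:
    """n unit-variance band-limited latent signals (wavelet-filtered noise)."""
    if n == 0:
        return np.zeros((0, n_frames))
    x = modwt_bandlimit(rng.standard_normal((n, n_frames)))
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_bold(
    config: StudyConfig, hormones: pd.DataFrame, seed: int
) -> tuple[list[RegionalTimeseries], GroundTruth]:
    """Per-session regional timeseries with hormone-coupled edge coherence.

    Returns one nodes x frames matrix per session plus the ground-truth
    coupling record (per-edge betas and the session hormone z-scores).
    """
    config.validate()
    if len(hormones) != config.n_sessions:
        raise ValueError("hormone table must have one row per session")
    min_frames = 4 * 64 + 128 - 64  # at least 4 Welch windows at 50% overlap
    if config.frames_per_session < min_frames:
        raise ConfigError(
            f"frames_per_session={config.frames_per_session} too short for spectral "
            f"estimation (need >= {min_frames})"
        )
    parc = build_parcellation(config.n_nodes)
    networks = parc.networks
    net_of = parc.network_of_node
    net_index = {n: k for k, n in enumerate(networks)}
    node_net = np.array([net_index[n] for n in net_of])

    h = hormones[config.coupling_analyte].to_numpy(dtype=float)
    if np.isnan(h).any():
        raise ValueError("coupling analyte has missing sessions; use a salivary analyte")
    hz = (h - h.mean()) / h.std(ddof=0) if h.std(ddof=0) > 0 else np.zeros_like(h)

    # Latent mixing weights: a global latent shared by all nodes sets the
    # cross-network floor (coherence a^4 = global_coherence) and a block
    # latent tops within-network pairs up to the block baseline, so the
    # within-block cross-spectral fraction is a^2 + b^2 = sqrt(baseline).
    a2 = math.sqrt(config.global_coherence)
    b2 = math.sqrt(config.baseline_block_coherence) - a2
    a, b = math.sqrt(a2), math.sqrt(b2)
    edges = [
        {
            "i": int(min(e.i, e.j)),
            "j": int(max(e.i, e.j)),
            "beta": float(e.beta),
            "baseline": float(config.edge_baseline(e)),
        }
        for e in config.coupled_edges
    ]
    coupled_mask = np.zeros(config.n_nodes, dtype=bool)
    for e in edges:
        coupled_mask[e["i"]] = coupled_mask[e["j"]] = True

    rng = np.random.default_rng(seed)
    sessions: list[RegionalTimeseries] = []
    clipped = 0
    for s in range(config.n_sessions):
        lat = _standardize_band_latents(
            rng, 1 + len(networks) + len(edges) + config.n_nodes, config.frames_per_session
        )
        global_lat = lat[0]
        block_lat = lat[1 : 1 + len(networks)]
        pair_lat = lat[1 + len(networks) : 1 + len(networks) + len(edges)]
        private = lat[1 + len(networks) + len(edges) :]
        # Per-node pair weights for this session. Coupled-edge endpoints do
        # not carry the network-block latent: their background is the global
        # latent plus a private latent whose variance absorbs the session's
        # pair-weight variation. This keeps the cross-spectral fraction of
        # every NON-listed edge constant across sessions (= a^2, or a^2+b^2
        # within a block of regular nodes), so only the listed edges track
        # the hormone. Coupled-edge coherence: a^2 + w(s)^2 = sqrt(rho(s)).
        c2 = np.zeros(config.n_nodes)  # total pair-latent variance per node
        pair_w = np.zeros((len(edges), config.n_nodes))
        for k, e in enumerate(edges):
            rho = e["baseline"] + e["beta"] * hz[s]
            if rho < 0.0 or rho > 0.97:
                clipped += 1
                rho = float(np.clip(rho, 0.0, 0.97))
            w2 = max(math.sqrt(rho) - a2, 0.0)
            w = math.sqrt(w2)
            pair_w[k, e["i"]] = w
            pair_w[k, e["j"]] = w
            c2[e["i"]] += w2
            c2[e["j"]] += w2
        priv_var = 1.0 - a2 - c2 - np.where(coupled_mask, 0.0, b2)
        if np.any(priv_var < -1e-12):
            raise ConfigError(
                "coupled-edge weights exceed unit node variance; reduce betas/baselines "
                "or spread coupled edges over more nodes"
            )
        priv_w = np.sqrt(np.clip(priv_var, 0.0, 1.0))
        block_w = np.where(coupled_mask, 0.0, b)
        data = (
            pair_w.T @ pair_lat
            + a * global_lat
            + block_w[:, None] * block_lat[node_net]
            + priv_w[:, None] * private
            + config.noise_sd * rng.standard_normal((config.n_nodes, config.frames_per_session))
            + config.baseline_intensity
        )
        sid = hormones.iloc[s]["session_id"] if "session_id" in hormones else f"ses-{s + 1:02d}"
        sessions.append(RegionalTimeseries(data, config.tr_seconds, str(sid)))
    if clipped:
        logger.warning("coherence target clipped to [0, 0.97] on %d edge-sessions", clipped)

    gt_z = {config.coupling_analyte: [float(v) for v in hz]}
    truth = GroundTruth(edges, gt_z, config.coupling_analyte)
    return sessions, truth


def generate_motion_and_mood(
    config: StudyConfig, seed: int
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Six-parameter motion traces per session and a per-session mood table.

    Motion is a random walk in the three translations (mm) and three
    rotations (rad; step SD scaled by 1/50 so rotations and translations
    contribute comparably to framewise displacement), with evening sessions
    allowed a larger step SD and occasional large spikes.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    schedule = session_schedule(config)
    traces: list[np.ndarray] = []
    mood_rows = []
    for _, row in schedule.iterrows():
        step_sd = (
            config.motion_step_sd_am_mm
            if row["time_label"] == "AM"
            else config.motion_step_sd_pm_mm
        )
        steps = rng.normal(0.0, step_sd, (config.frames_per_session, 6))
        steps[:, 3:] /= 50.0  # rotations in rad, FWD-equivalent scale
        spikes = rng.random(config.frames_per_session) < config.motion_spike_prob_per_frame
        steps[spikes, 0] += config.motion_spike_size_mm * rng.choice(
            [-1.0, 1.0], int(spikes.sum())
        )
        trace = np.cumsum(steps, axis=0)
        trace[0] = 0.0
        traces.append(trace)
        scores = {}
        for scale, (lo, hi, mean, sd) in MOOD_SCALES.items():
            scores[scale] = float(np.clip(rng.normal(mean, sd), lo, hi))
        mood_rows.append({"session_id": row["session_id"], **scores})
    return traces, pd.DataFrame(mood_rows)


def write_study(
    out_dir,
    hormones: pd.DataFrame,
    sessions: list[RegionalTimeseries],
    truth: GroundTruth,
    parcellation: Parcellation | None = None,
    motion: list[np.ndarray] | None = None,
    mood: pd.DataFrame | None = None,
) -> None:
    """Write a generated study to disk as plain-text tables plus JSON truth."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hormones.to_csv(out / "sessions.tsv", sep="\t", index=False)
    truth.to_json(out / "ground_truth.json")
    if parcellation is not None:
        parcellation.to_tsv(out / "parcellation.tsv")
    ts_dir = out / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    for ts in sessions:
        ts.to_tsv(ts_dir / f"{ts.session_id}_bold.tsv")
    if motion is not None:
        mo_dir = out / "motion"
        mo_dir.mkdir(exist_ok=True)
        for ts, tr in zip(sessions, motion):
            np.savetxt(mo_dir / f"rp_{ts.session_id}.txt", tr)
    if mood is not None:
        mood.to_csv(out / "mood.tsv", sep="\t", index=False)
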