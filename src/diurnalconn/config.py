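"""Study and run configuration.

``StudyConfig`` describes the synthetic dense-sampling study: 40 sessions
over 30 consecutive days (20 at 7 A.M., 20 at 8 P.M.), per-analyte diurnal
means/SDs, a 415-node / nine-network parcellation, and an optional set of
edges whose band-limited coherence varies linearly with a z-scored hormone.
``RunConfig`` adds the analysis-side knobs (permutations, thresholds, paths).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a study or run configuration is internally inconsistent."""


@dataclass
class HormoneParams:
    """Diurnal sampling parameters for one analyte.

    ``mean_am``/``sd_am`` parameterize 7 A.M. draws, ``mean_pm``/``sd_pm``
    the 8 P.M. draws, in the analyte's own units. ``serum_only`` analytes
    are measured only on sessions with a blood draw (30 of 40 by default).
    """

    mean_am: float
    sd_am: float
    mean_pm: float
    sd_pm: float
    units: str
    serum_only: bool = False

    def validate(self, name: str) -> None:
        if self.sd_am < 0 or self.sd_pm < 0:
            raise ConfigError(f"negative SD for analyte {name!r}")
        if self.mean_am < 0 or self.mean_pm < 0:
            raise ConfigError(f"negative mean for analyte {name!r}")


def default_hormone_params() -> dict[str, HormoneParams]:
    """Morning/evening means (SD) per analyte for the densely sampled male.

    Salivary analytes are measured at all 40 sessions; serum analytes only
    on the 30 blood-draw sessions.
    """
    return {
        "testosterone_saliva": HormoneParams(101.6, 10.20, 37.9, 11.50, "pg/ml"),
        "testosterone_serum": HormoneParams(513.4, 47.00, 286.4, 79.00, "ng/dl", serum_only=True),
        "free_testosterone": HormoneParams(3.5, 0.40, 2.6, 0.30, "%FT", serum_only=True),
        "estradiol": HormoneParams(23.8, 3.60, 14.5, 2.90, "pg/ml", serum_only=True),
        "cortisol_saliva": HormoneParams(0.5, 0.10, 0.04, 0.02, "ug/dl"),
        "cortisol_serum": HormoneParams(15.9, 2.10, 2.6, 0.90, "ug/dl", serum_only=True),
    }


@dataclass
class CoupledEdge:
    """An edge whose in-band coherence varies linearly with a hormone z-score.

    ``beta`` is in coherence units per hormone SD; ``baseline`` is the
    coherence at hormone z = 0 (defaults to the study-level coupled-edge
    baseline when None).
    """

    i: int
    j: int
    beta: float
    baseline: Optional[float] = None


@dataclass
class StudyConfig:
    """Parameters of the synthetic dense-sampling study."""

    n_nodes: int = 415
    n_networks: int = 9
    n_sessions: int = 40
    n_days: int = 30
    frames_per_session: int = 1250
    tr_seconds: float = 0.72
    hormone_params: dict[str, HormoneParams] = field(default_factory=default_hormone_params)
    coupled_edges: list[CoupledEdge] = field(default_factory=list)
    coupling_analyte: str = "testosterone_saliva"
    baseline_block_coherence: float = 0.4
    global_coherence: float = 0.12
    coupled_edge_baseline: float = 0.5
    noise_sd: float = 0.5
    baseline_intensity: float = 1000.0
    n_serum_sessions: int = 30
    # motion generator: random-walk step SDs chosen so mean FWD is a few
    # microns in the morning and slightly larger in the evening
    motion_step_sd_am_mm: float = 0.00125
    motion_step_sd_pm_mm: float = 0.00210
    motion_spike_prob_per_frame: float = 4.4e-4
    motion_spike_size_mm: float = 0.9
    seed: int = 0

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    def edge_baseline(self, edge: CoupledEdge) -> float:
        return self.coupled_edge_baseline if edge.baseline is None else edge.baseline

    def validate(self) -> None:
        if self.n_nodes < 2:
            raise ConfigError("need at least 2 nodes")
        if not 1 <= self.n_networks <= self.n_nodes:
            raise ConfigError("n_networks must be in [1, n_nodes]")
        if self.n_sessions % 2 != 0:
            raise ConfigError("n_sessions must be even for balanced AM/PM sampling")
        if self.frames_per_session < 2:
            raise ConfigError("frames_per_session too small")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        if not 0.0 <= self.baseline_block_coherence < 1.0:
            raise ConfigError("baseline_block_coherence must be in [0, 1)")
        if not 0.0 <= self.global_coherence < 1.0:
            raise ConfigError("global_coherence must be in [0, 1)")
        if self.global_coherence > self.baseline_block_coherence:
            raise ConfigError("global_coherence cannot exceed baseline_block_coherence")
        if not 0.0 <= self.coupled_edge_baseline < 1.0:
            raise ConfigError("coupled_edge_baseline must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not 0 <= self.n_serum_sessions <= self.n_sessions:
            raise ConfigError("n_serum_sessions out of range")
        for name, hp in self.hormone_params.items():
            hp.validate(name)
        if self.coupling_analyte not in self.hormone_params:
            raise ConfigError(f"unknown coupling analyte {self.coupling_analyte!r}")
        seen = set()
        for e in self.coupled_edges:
            i, j = min(e.i, e.j), max(e.i, e.j)
            if i == j:
                raise ConfigError("coupled edge endpoints must differ")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ConfigError("coupled-edge endpoint exceeds n_nodes")
            if (i, j) in seen:
                raise ConfigError(f"coupled edge ({i},{j}) listed twice")
            seen.add((i, j))
            base = self.edge_baseline(e)
            # implied coherence must remain a valid coherence over +/-3 SD
            lo = base - 3.0 * abs(e.beta)
            hi = base + 3.0 * abs(e.beta)
            if lo < -1e-12 or hi > 1.0 + 1e-12:
                raise ConfigError(
                    f"coupled edge ({i},{j}): baseline {base} with beta {e.beta} "
                    f"implies coherence outside [0,1] over +/-3 hormone SD"
                )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunConfig:
    """Analysis-side parameters for the end-to-end pipeline."""

    study: StudyConfig = field(default_factory=StudyConfig)
    hormones: Sequence[str] = ("testosterone_saliva", "estradiol", "cortisol_saliva")
    covariates: Sequence[str] = ()
    n_permutations: int = 10_000
    p_alpha: float = 0.001
    fdr_q: float = 0.05
    welch_window: int = 128
    welch_overlap: float = 0.5
    wavelet: str = "sym8"
    wavelet_levels: tuple[int, ...] = (3, 4, 5, 6)
    # Regress on unthresholded matrices by default: zeroing sub-threshold
    # edges per session censors edge values in a hormone-dependent way once
    # any edge is hormone-coupled, biasing the edgewise null. Thresholded
    # matrices are still used for the graph-topology metrics.
    threshold_session_matrices: bool = False
    seed: int = 0
    out_dir: Optional[str] = None

    def validate(self) -> None:
        self.study.validate()
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if not 0 < self.p_alpha <= 1 or not 0 < self.fdr_q <= 1:
            raise ConfigError("thresholds must be in (0, 1]")
        unknown = set(self.hormones) - set(self.study.hormone_params)
        if unknown:
            raise ConfigError(f"unknown hormones requested: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def derive_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from a master seed."""
    import numpy as np

    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
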