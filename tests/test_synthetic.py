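"""Synthetic study generator: schedule, hormones, BOLD coupling, motion."""

import numpy as np
import pandas as pd
import pytest

from conftest import tiny_study
from diurnalconn.config import ConfigError, CoupledEdge, StudyConfig, default_hormone_params
from diurnalconn.synthetic import (
    generate_bold,
    generate_hormones,
    generate_motion_and_mood,
    session_schedule,
)
from diurnalconn.coherence import coherence_matrix, nominal_band


class TestSchedule:
    def test_default_calendar(self):
        cfg = StudyConfig()
        table = session_schedule(cfg)
        assert len(table) == 40
        assert (table["time_label"] == "AM").sum() == 20
        assert (table["time_label"] == "PM").sum() == 20
        assert table["day"].min() == 1 and table["day"].max() == 30
        assert table["serum"].sum() == 30

    def test_serum_split_by_time_of_day(self):
        table = session_schedule(StudyConfig())
        serum = table[table["serum"]]
        assert (serum["time_label"] == "AM").sum() == 15
        assert (serum["time_label"] == "PM").sum() == 15

    def test_wake_hours(self):
        table = session_schedule(StudyConfig())
        assert (table.loc[table["time_label"] == "AM", "wake_hours"] == 1.0).all()
        assert (table.loc[table["time_label"] == "PM", "wake_hours"] == 14.0).all()

    def test_incompatible_days(self):
        with pytest.raises(ConfigError):
            session_schedule(StudyConfig(n_sessions=40, n_days=10))


class TestHormones:
    def test_zero_sd_reproduces_configured_means(self):
        cfg = StudyConfig()
        for hp in cfg.hormone_params.values():
            hp.sd_am = hp.sd_pm = 0.0
        table = generate_hormones(cfg, seed=1)
        am = table["time_label"] == "AM"
        assert (table.loc[am, "testosterone_saliva"] == 101.6).all()
        assert (table.loc[~am, "testosterone_saliva"] == 37.9).all()

    def test_constant_analyte_zero_decrease(self):
        from diurnalconn.hormones import summarize_diurnal

        cfg = StudyConfig()
        hp = cfg.hormone_params["testosterone_saliva"]
        hp.sd_am = hp.sd_pm = 0.0
        hp.mean_am = hp.mean_pm = 50.0
        table = generate_hormones(cfg, seed=1)
        assert summarize_diurnal(table, "testosterone_saliva")["pct_decrease"] == 0.0

    def test_monte_carlo_mean_within_2_se(self):
        cfg = StudyConfig(n_sessions=10_000, n_days=5_000, n_serum_sessions=10_000)
        table = generate_hormones(cfg, seed=3)
        am = table.loc[table["time_label"] == "AM", "cortisol_saliva"]
        se = 0.1 / np.sqrt(len(am))
        assert abs(am.mean() - 0.5) < 2 * se

    def test_non_negative_and_serum_missingness(self):
        cfg = StudyConfig()
        table = generate_hormones(cfg, seed=5)
        for name, hp in default_hormone_params().items():
            vals = table[name]
            assert (vals.dropna() >= 0).all()
            expected_missing = 10 if hp.serum_only else 0
            assert vals.isna().sum() == expected_missing

    def test_deterministic(self):
        cfg = StudyConfig()
        a = generate_hormones(cfg, seed=11)
        b = generate_hormones(cfg, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sd_rejected(self):
        cfg = StudyConfig()
        cfg.hormone_params["estradiol"].sd_am = -1.0
        with pytest.raises(ConfigError):
            generate_hormones(cfg, seed=0)


def _edge_coherence(ts, i, j):
    band = nominal_band(ts.tr_seconds)
    m = coherence_matrix(ts, band=band)
    return m.values[i, j]


class TestBold:
    def test_deterministic(self):
        cfg = tiny_study(seed=2)
        horm = generate_hormones(cfg, seed=2)
        a, _ = generate_bold(cfg, horm, seed=9)
        b, _ = generate_bold(cfg, horm, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.data, y.data)

    def test_coupled_edge_tracks_hormone(self):
        # strong coupling, low noise: top-5 hormone sessions must have higher
        # estimated band coherence on the coupled edge than the bottom-5
        cfg = tiny_study(
            seed=4,
            n_sessions=12,
            n_days=8,
            n_serum_sessions=8,
            coupled_edges=[CoupledEdge(0, 1, 0.15)],
            noise_sd=0.1,
        )
        horm = generate_hormones(cfg, seed=4)
        sessions, truth = generate_bold(cfg, horm, seed=4)
        z = np.array(truth.session_hormone_z[truth.coupling_analyte])
        coh = np.array([_edge_coherence(ts, 0, 1) for ts in sessions])
        order = np.argsort(z)
        assert coh[order[-5:]].mean() > coh[order[:5]].mean()

    def test_null_coupling_no_slope(self):
        # with no coupled edges, edge coherence is uncorrelated with the
        # hormone beyond sampling noise
        cfg = tiny_study(seed=6)
        horm = generate_hormones(cfg, seed=6)
        sessions, truth = generate_bold(cfg, horm, seed=6)
        assert truth.coupled_edges == []
        z = horm["testosterone_saliva"].to_numpy()
        z = (z - z.mean()) / z.std()
        coh = np.array([_edge_coherence(ts, 0, 1) for ts in sessions])
        r = np.corrcoef(z, coh)[0, 1]
        assert abs(r) < 0.95  # not systematically coupled

    def test_uncoupled_edges_constant_cross_spectral_weights(self):
        # edges incident to a coupled node but not listed must NOT track the
        # hormone: their coherence-hormone correlation stays small on average
        cfg = tiny_study(
            seed=8,
            n_sessions=16,
            n_days=10,
            n_serum_sessions=12,
            coupled_edges=[CoupledEdge(0, 1, 0.15)],
            noise_sd=0.1,
        )
        horm = generate_hormones(cfg, seed=8)
        sessions, truth = generate_bold(cfg, horm, seed=8)
        z = np.array(truth.session_hormone_z[truth.coupling_analyte])
        neighbors = [(0, j) for j in range(2, 8)]
        rs = []
        for i, j in neighbors:
            coh = np.array([_edge_coherence(ts, i, j) for ts in sessions])
            rs.append(np.corrcoef(z, coh)[0, 1])
        assert abs(np.mean(rs)) < 0.5

    def test_short_series_rejected(self):
        cfg = tiny_study(frames_per_session=200)
        horm_cfg = tiny_study()
        horm = generate_hormones(horm_cfg, seed=0)
        with pytest.raises(ConfigError):
            generate_bold(cfg, horm, seed=0)

    def test_infeasible_coupling_rejected(self):
        # two high-baseline coupled edges sharing a node exceed unit variance
        cfg = tiny_study(
            coupled_edges=[
                CoupledEdge(0, 1, 0.15, baseline=0.5),
                CoupledEdge(0, 2, 0.15, baseline=0.5),
            ]
        )
        horm = generate_hormones(cfg, seed=0)
        with pytest.raises(ConfigError):
            generate_bold(cfg, horm, seed=0)

    def test_out_of_range_beta_rejected_by_config(self):
        with pytest.raises(ConfigError):
            tiny_study(coupled_edges=[CoupledEdge(0, 1, 0.4)]).validate()


class TestMotionMood:
    def test_zero_amplitude_zero_fwd(self):
        from diurnalconn.nuisance import framewise_displacement

        cfg = tiny_study(
            motion_step_sd_am_mm=0.0,
            motion_step_sd_pm_mm=0.0,
            motion_spike_prob_per_frame=0.0,
        )
        traces, _ = generate_motion_and_mood(cfg, seed=0)
        for tr in traces:
            assert framewise_displacement(tr).max() == 0.0

    def test_pm_motion_exceeds_am(self):
        from diurnalconn.nuisance import framewise_displacement

        cfg = StudyConfig(motion_spike_prob_per_frame=0.0, frames_per_session=1250)
        traces, _ = generate_motion_and_mood(cfg, seed=1)
        sched = session_schedule(cfg)
        fwd = np.array([framewise_displacement(t).mean() for t in traces])
        am = (sched["time_label"] == "AM").to_numpy()
        assert fwd[~am].mean() > fwd[am].mean()

    def test_deterministic_and_mood_ranges(self):
        from diurnalconn.synthetic import MOOD_SCALES

        cfg = tiny_study()
        t1, m1 = generate_motion_and_mood(cfg, seed=3)
        t2, m2 = generate_motion_and_mood(cfg, seed=3)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a, b)
        pd.testing.assert_frame_equal(m1, m2)
        for scale, (lo, hi, *_rest) in MOOD_SCALES.items():
            assert m1[scale].between(lo, hi).all()
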