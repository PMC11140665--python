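"""Nodal strengths, network summaries, two-way ANOVAs, top nodes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from diurnalconn.edgewise import EdgewiseMap, edge_index, n_edges
from diurnalconn.networks import (
    hormone_network_anova,
    network_summary,
    nodal_strengths,
    sex_network_anova,
    top_nodes,
)
from diurnalconn.parcellation import NINE_NETWORKS, build_parcellation


def _masked_map(n_nodes, entries, hormone="h"):
    """Map with t set on given (i, j): t edges, all in the strength mask."""
    m = n_edges(n_nodes)
    t = np.zeros(m)
    mask = np.zeros(m, dtype=bool)
    iu = edge_index(n_nodes)
    lookup = {(int(i), int(j)): k for k, (i, j) in enumerate(zip(*iu))}
    for (i, j), val in entries.items():
        k = lookup[(min(i, j), max(i, j))]
        t[k] = val
        mask[k] = True
    return EdgewiseMap(n_nodes, hormone, t / 3, t, 8, p=np.full(m, 0.5),
                       strength_mask=mask, display_mask=mask)


class TestNodalStrengths:
    def test_hand_worked_four_node_case(self):
        emap = _masked_map(4, {(0, 1): 2.0, (0, 2): -3.0, (2, 3): 1.0})
        from diurnalconn.parcellation import Parcellation

        parc = Parcellation(pd.DataFrame({
            "node_id": range(4), "label": list("wxyz"),
            "network": ["A", "A", "B", "B"], "hemisphere": ["LH"] * 4,
        }))
        out = nodal_strengths(emap, parc).set_index("node_id")
        assert out.loc[0, "positive_strength"] == 2.0
        assert out.loc[0, "negative_strength"] == 3.0
        assert out.loc[2, "positive_strength"] == 1.0
        assert out.loc[2, "negative_strength"] == 3.0
        assert out.loc[3, "positive_strength"] == 1.0
        assert out.loc[3, "negative_strength"] == 0.0

    def test_empty_mask_all_zero(self):
        emap = _masked_map(6, {})
        parc = build_parcellation(6, networks=NINE_NETWORKS[:3])
        out = nodal_strengths(emap, parc)
        assert (out["positive_strength"] == 0).all()
        assert (out["negative_strength"] == 0).all()

    def test_handshake_identity(self, rng):
        from diurnalconn.validation import handshake_identity

        out = handshake_identity(seed=2, n_nodes=25)
        assert out["node_positive_sum"] == out["edge_positive_sum_x2"]
        assert out["node_negative_sum"] == out["edge_negative_sum_x2"]

    def test_size_mismatch_errors(self):
        emap = _masked_map(4, {})
        with pytest.raises(ValueError):
            nodal_strengths(emap, build_parcellation(10))

    def test_requires_strength_mask(self):
        emap = EdgewiseMap(4, "h", np.zeros(6), np.zeros(6), 8)
        with pytest.raises(ValueError):
            nodal_strengths(emap, build_parcellation(4, networks=NINE_NETWORKS[:2]))


def _strength_table(values, networks):
    return pd.DataFrame({
        "node_id": range(len(values)),
        "label": [f"n{k}" for k in range(len(values))],
        "network": networks,
        "positive_strength": values,
        "negative_strength": np.zeros(len(values)),
        "hormone": "h",
    })


class TestNetworkSummary:
    def test_constant_strengths(self):
        t = _strength_table([3.0] * 6, ["A"] * 3 + ["B"] * 3)
        out = network_summary(t)
        pos = out[out["direction"] == "positive"]
        assert (pos["mean"] == 3.0).all()
        np.testing.assert_allclose(pos["ci95_lo"], 3.0)
        np.testing.assert_allclose(pos["ci95_hi"], 3.0)

    def test_t_interval_oracle(self):
        t = _strength_table([1.0, 2.0, 3.0], ["A"] * 3)
        out = network_summary(t)
        row = out[(out["network"] == "A") & (out["direction"] == "positive")].iloc[0]
        se = np.std([1, 2, 3], ddof=1) / np.sqrt(3)
        tcrit = stats.t.ppf(0.975, df=2)
        assert row["mean"] == pytest.approx(2.0)
        assert row["ci95_lo"] == pytest.approx(2.0 - tcrit * se)
        assert row["ci95_hi"] == pytest.approx(2.0 + tcrit * se)

    def test_singleton_flagged(self):
        t = _strength_table([1.0, 2.0, 5.0], ["A", "A", "B"])
        out = network_summary(t)
        b = out[(out["network"] == "B") & (out["direction"] == "positive")].iloc[0]
        assert bool(b["degenerate"]) and np.isnan(b["ci95_lo"])


class TestAnovas:
    def _tables(self, n_nodes, hormones=("T", "E", "C"), seed=0):
        parc = build_parcellation(n_nodes)
        rng = np.random.default_rng(seed)
        return {
            h: _strength_table(rng.normal(size=n_nodes) ** 2, parc.network_of_node)
            for h in hormones
        }

    def test_residual_df_formula(self):
        tables = self._tables(45)
        out = hormone_network_anova(tables)
        assert out["residual_df"] == 3 * 45 - 3 * 9

    def test_full_scale_dfs(self):
        tables = self._tables(415)
        out = hormone_network_anova(tables)
        assert out["residual_df"] == 1218
        a, b = self._tables(415, hormones=("x", "y"), seed=1).values()
        out2 = sex_network_anova(a, b)
        assert out2["residual_df"] == 812

    def test_constructed_contrast(self):
        parc = build_parcellation(45)
        nets = parc.network_of_node
        tables = {
            "T": _strength_table(np.full(45, 1.0), nets),
            "E": _strength_table(np.full(45, 5.0), nets),
            "C": _strength_table(np.full(45, 9.0), nets),
        }
        # add tiny noise so the residual variance is nonzero
        rng = np.random.default_rng(0)
        for t in tables.values():
            t["positive_strength"] += rng.normal(scale=1e-3, size=45)
        out = hormone_network_anova(tables)
        table = out["anova"]
        f_h = float(table.loc["C(hormone)", "F"])
        f_n = float(table.loc["C(network)", "F"])
        assert f_h > 1e4 and f_n < 10

    def test_balanced_two_by_two_oracle(self):
        # 2 hormones x 2 networks, 2 nodes per cell: compare against a
        # hand-computed balanced two-way ANOVA (type II == classic here)
        vals = {
            ("T", "A"): [1.0, 2.0],
            ("T", "B"): [3.0, 4.0],
            ("E", "A"): [2.0, 3.0],
            ("E", "B"): [6.0, 7.0],
        }
        rows = []
        for (h, n), vs in vals.items():
            for v in vs:
                rows.append({"strength": v, "hormone": h, "network": n})
        df = pd.DataFrame(rows)
        from diurnalconn.networks import _two_way_anova

        out = _two_way_anova(df, "hormone", "network", "strength")
        table = out["anova"]
        # hand SS: grand mean 3.5; hormone means T=2.5, E=4.5; network A=2, B=5
        ss_h = 4 * ((2.5 - 3.5) ** 2 + (4.5 - 3.5) ** 2)
        ss_n = 4 * ((2.0 - 3.5) ** 2 + (5.0 - 3.5) ** 2)
        cell_means = {k: np.mean(v) for k, v in vals.items()}
        ss_resid = sum((v - cell_means[k]) ** 2 for k, vs in vals.items() for v in vs)
        ss_int = sum(
            2 * (cell_means[(h, n)] - hm - nm + 3.5) ** 2
            for (h, n), hm, nm in [
                (("T", "A"), 2.5, 2.0), (("T", "B"), 2.5, 5.0),
                (("E", "A"), 4.5, 2.0), (("E", "B"), 4.5, 5.0),
            ]
        )
        assert float(table.loc["C(hormone)", "sum_sq"]) == pytest.approx(ss_h)
        assert float(table.loc["C(network)", "sum_sq"]) == pytest.approx(ss_n)
        assert float(table.loc["C(hormone):C(network)", "sum_sq"]) == pytest.approx(ss_int)
        assert float(table.loc["Residual", "sum_sq"]) == pytest.approx(ss_resid)
        assert out["residual_df"] == 4

    def test_identical_participants_sex_f_near_zero(self):
        parc = build_parcellation(45)
        rng = np.random.default_rng(3)
        t = _strength_table(rng.normal(size=45) ** 2, parc.network_of_node)
        out = sex_network_anova(t, t.copy())
        assert float(out["anova"].loc["C(sex)", "F"]) == pytest.approx(0.0, abs=1e-8)

    def test_mismatched_node_sets_error(self):
        tables = self._tables(45)
        tables["E"] = tables["E"].iloc[:-1]
        with pytest.raises(ValueError):
            hormone_network_anova(tables)


class TestTopNodes:
    def test_ordering(self):
        t = _strength_table([5.0, 1.0, 9.0], ["A", "A", "B"])
        out = top_nodes(t, k=3)
        assert list(out["node_id"]) == [2, 0, 1]

    def test_tie_break_by_node_id(self):
        t = _strength_table([4.0, 7.0, 7.0, 1.0], ["A", "A", "B", "B"])
        out = top_nodes(t, k=2)
        assert list(out["node_id"]) == [1, 2]

    def test_all_zero_degenerate_but_deterministic(self):
        t = _strength_table([0.0, 0.0, 0.0], ["A", "A", "B"])
        a = top_nodes(t, k=3)
        b = top_nodes(t, k=3)
        assert list(a["node_id"]) == list(b["node_id"]) == [0, 1, 2]
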