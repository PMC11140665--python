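"""Signed nodal association strengths and network-level inference.

From an FDR-masked edgewise map, each node's positive strength is the sum
of suprathreshold positive edge statistics incident to it, and its negative
strength the summed magnitudes of suprathreshold negative edges (signed,
weighted graph treatment). Network means carry t-based 95% confidence
intervals, and two-way fixed-effects ANOVAs (hormone x network, or sex x
network) with Tukey HSD compare strengths across factors, treating nodes
as observations.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from diurnalconn.edgewise import EdgewiseMap, devectorize_edges
from diurnalconn.parcellation import Parcellation

logger = logging.getLogger(__name__)


def nodal_strengths(emap: EdgewiseMap, parc: Parcellation) -> pd.DataFrame:
    """Per-node positive/negative association strengths from a masked map.

    Only edges in the strength (FDR) mask contribute; node i's positive
    strength sums t(i, j) > 0 over masked edges at i, and its negative
    strength sums |t(i, j)| over masked negative edges.
    """
    if emap.strength_mask is None:
        raise ValueError("edgewise map has no strength mask; run threshold_map first")
    if parc.n_nodes != emap.n_nodes:
        raise ValueError("parcellation size does not match the edgewise map")
    t = np.where(emap.strength_mask & np.isfinite(emap.t), emap.t, 0.0)
    tmat = devectorize_edges(t, emap.n_nodes)
    pos = np.clip(tmat, 0, None).sum(axis=1)
    neg = np.abs(np.clip(tmat, None, 0)).sum(axis=1)
    out = parc.table[["node_id", "label", "network"]].copy()
    out["positive_strength"] = pos
    out["negative_strength"] = neg
    out["hormone"] = emap.hormone
    return out


def network_summary(strengths: pd.DataFrame, parc: Parcellation | None = None) -> pd.DataFrame:
    """Per-network mean strength with t-based 95% CI, each direction.

    Singleton networks get an undefined (NaN) CI and a degenerate flag.
    """
    rows = []
    for net, grp in strengths.groupby("network", sort=False):
        for direction in ("positive", "negative"):
            v = grp[f"{direction}_strength"].to_numpy(dtype=float)
            mean = float(v.mean())
            if len(v) >= 2:
                se = v.std(ddof=1) / np.sqrt(len(v))
                tcrit = stats.t.ppf(0.975, df=len(v) - 1)
                lo, hi = mean - tcrit * se, mean + tcrit * se
                degenerate = False
            else:
                logger.warning("singleton network %r: CI undefined", net)
                lo = hi = np.nan
                degenerate = True
            rows.append(
                {
                    "network": net,
                    "direction": direction,
                    "mean": mean,
                    "ci95_lo": float(lo),
                    "ci95_hi": float(hi),
                    "n_nodes": int(len(v)),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def _two_way_anova(df: pd.DataFrame, factor_a: str, factor_b: str, response: str) -> dict:
    """Fixed-effects two-way ANOVA with interaction; Type II main effects."""
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    if (counts == 0).any() or counts.size < df[factor_a].nunique() * df[factor_b].nunique():
        raise ValueError(f"empty {factor_a} x {factor_b} cell")
    model = smf.ols(f"{response} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    tukey = {
        factor_a: pairwise_tukeyhsd(df[response], df[factor_a], alpha=0.05),
        factor_b: pairwise_tukeyhsd(df[response], df[factor_b], alpha=0.05),
    }
    return {
        "anova": table,
        "tukey": tukey,
        "residual_df": int(model.df_resid),
        "model": model,
    }


def hormone_network_anova(
    strengths_by_hormone: dict[str, pd.DataFrame],
    direction: str = "positive",
) -> dict:
    """Two-way ANOVA of nodal strengths: hormone (3) x network (9).

    Node-level strengths of each hormone map are stacked (N = n_hormones x
    n_nodes observations); negative strengths are analyzed as magnitudes.
    Tukey HSD is run on both margins.
    """
    frames = []
    node_sets = None
    for hormone, df in strengths_by_hormone.items():
        ids = tuple(df["node_id"])
        if node_sets is None:
            node_sets = ids
        elif ids != node_sets:
            raise ValueError("hormone strength tables must share the same node set")
        frames.append(
            pd.DataFrame(
                {
                    "strength": df[f"{direction}_strength"].to_numpy(dtype=float),
                    "hormone": hormone,
                    "network": df["network"].to_numpy(),
                }
            )
        )
    longdf = pd.concat(frames, ignore_index=True)
    return _two_way_anova(longdf, "hormone", "network", "strength")


def sex_network_anova(
    strengths_a: pd.DataFrame,
    strengths_b: pd.DataFrame,
    labels: tuple[str, str] = ("participant_a", "participant_b"),
    direction: str = "positive",
) -> dict:
    """Two-way ANOVA of nodal strengths: participant/sex (2) x network (9)."""
    if list(strengths_a["network"]) != list(strengths_b["network"]):
        raise ValueError("participants must share the same parcellation")
    frames = []
    for label, df in zip(labels, (strengths_a, strengths_b)):
        frames.append(
            pd.DataFrame(
                {
                    "strength": df[f"{direction}_strength"].to_numpy(dtype=float),
                    "sex": label,
                    "network": df["network"].to_numpy(),
                }
            )
        )
    longdf = pd.concat(frames, ignore_index=True)
    return _two_way_anova(longdf, "sex", "network", "strength")


def top_nodes(strengths: pd.DataFrame, k: int = 10, direction: str = "positive") -> pd.DataFrame:
    """Top-k nodes by strength, descending, ties broken by lower node_id."""
    col = f"{direction}_strength"
    out = strengths.sort_values([col, "node_id"], ascending=[False, True], kind="mergesort")
    out = out.head(k).reset_index(drop=True)
    if (out[col] == 0).all():
        logger.warning("all requested strengths are zero; ranking is degenerate")
    return out
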