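"""Endocrine and behavioral session-table analysis.

Diurnal summaries (morning/evening means, SDs, percent decrease) and a
Pearson correlation screen between hormone and mood columns with Bonferroni
correction, using pairwise-complete observations so missing serum sessions
are dropped per pair rather than imputed.
"""

from __future__ import annotations

import itertools
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ANALYTE_COLUMNS = (
    "testosterone_saliva",
    "testosterone_serum",
    "free_testosterone",
    "estradiol",
    "cortisol_saliva",
    "cortisol_serum",
)


class HormoneError(ValueError):
    pass


def read_session_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_session_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def summarize_diurnal(table: pd.DataFrame, analyte: str) -> dict:
    """Morning/evening summary of one analyte with the percent decrease.

    pct_decrease = 100 * (mean_am - mean_pm) / mean_am; rows with a missing
    concentration are skipped. Requires at least two AM and two PM values.
    """
    if analyte not in table.columns:
        raise HormoneError(f"unknown analyte {analyte!r}")
    sub = table[["time_label", analyte]].dropna()
    am = sub.loc[sub["time_label"] == "AM", analyte].to_numpy(dtype=float)
    pm = sub.loc[sub["time_label"] == "PM", analyte].to_numpy(dtype=float)
    if len(am) < 2 or len(pm) < 2:
        raise HormoneError(f"analyte {analyte!r} needs >= 2 AM and >= 2 PM sessions")
    mean_am, mean_pm = float(am.mean()), float(pm.mean())
    if mean_am == 0:
        raise HormoneError(f"percent decrease undefined: AM mean of {analyte!r} is zero")
    return {
        "mean_am": mean_am,
        "sd_am": float(am.std(ddof=1)),
        "mean_pm": mean_pm,
        "sd_pm": float(pm.std(ddof=1)),
        "pct_decrease": 100.0 * (mean_am - mean_pm) / mean_am,
        "n_am": int(len(am)),
        "n_pm": int(len(pm)),
    }


def diurnal_summary_table(table: pd.DataFrame, analytes: Sequence[str] = ANALYTE_COLUMNS) -> pd.DataFrame:
    rows = []
    for a in analytes:
        if a in table.columns:
            rows.append({"analyte": a, **summarize_diurnal(table, a)})
    return pd.DataFrame(rows)


def correlation_screen(
    table: pd.DataFrame,
    x_vars: Sequence[str],
    y_vars: Sequence[str],
    subset: str = "all",
    alpha: float = 0.05,
    n_comparisons: Optional[int] = None,
) -> pd.DataFrame:
    """Pearson correlation screen with Bonferroni correction.

    Tests every (x, y) pair over pairwise-complete rows of the requested
    subset ("all", "AM", or "PM"). The Bonferroni divisor defaults to the
    number of correlations actually computed but can be overridden when the
    family is defined externally. Zero-variance columns are flagged with an
    undefined correlation rather than an error.
    """
    if subset not in ("all", "AM", "PM"):
        raise HormoneError(f"subset must be all|AM|PM, got {subset!r}")
    df = table if subset == "all" else table.loc[table["time_label"] == subset]
    pairs = list(itertools.product(x_vars, y_vars))
    rows = []
    for x, y in pairs:
        sub = df[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            raise HormoneError(f"fewer than 3 complete pairs for ({x}, {y})")
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            logger.warning("zero-variance column in pair (%s, %s); correlation undefined", x, y)
            rows.append({"var_x": x, "var_y": y, "subset": subset, "n": n,
                         "r": np.nan, "p": np.nan, "degenerate": True})
            continue
        if x == y:
            r, p = 1.0, 0.0
        else:
            r, p = stats.pearsonr(xv, yv)
        rows.append({"var_x": x, "var_y": y, "subset": subset, "n": n,
                     "r": float(r), "p": float(p), "degenerate": False})
    out = pd.DataFrame(rows)
    m = n_comparisons if n_comparisons is not None else int((~out["degenerate"]).sum())
    out["bonferroni_threshold"] = alpha / max(m, 1)
    out["significant"] = (out["p"] < out["bonferroni_threshold"]) & ~out["degenerate"]
    return out
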