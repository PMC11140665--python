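"""Stage 5: edgewise hormone regression with a permutation null.

Regresses every edge's session coherence on each z-scored hormone, builds
the permutation null by reshuffling sessions, applies the BH FDR strength
mask and the p < alpha display mask, and derives signed nodal strengths,
network summaries, and the hormone x network / sex x network ANOVAs.
Checks detections against the generator's ground truth. Tables go to
results/, full edge maps to results/edgewise_<hormone>.tsv.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.coherence import CoherenceMatrix
from diurnalconn.hormones import read_session_table
from diurnalconn.networks import hormone_network_anova
from diurnalconn.parcellation import Parcellation
from diurnalconn.pipeline import analyze_connectomes, recovery_metrics
from diurnalconn.synthetic import GroundTruth


def load_matrices(kind: str) -> list[CoherenceMatrix]:
    with open(_common.CONNECTOME_DIR / "meta.json") as fh:
        meta = json.load(fh)
    sessions_table = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    return [
        CoherenceMatrix(
            np.loadtxt(_common.CONNECTOME_DIR / kind / f"{sid}.tsv", delimiter="\t"),
            meta["n_segments"],
            meta["tr_seconds"],
            sid,
            thresholded=(kind == "fdr"),
        )
        for sid in sessions_table["session_id"]
    ]


def main() -> None:
    args = _common.parse_args(__doc__)
    cfg = _common.load(args)
    kind = "fdr" if cfg.threshold_session_matrices else "raw"
    matrices = load_matrices(kind)
    hormones = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    parc = Parcellation.from_tsv(_common.STUDY_DIR / "parcellation.tsv")

    results = analyze_connectomes(matrices, hormones, parc, cfg)

    _common.RESULTS.mkdir(parents=True, exist_ok=True)
    _common.TABLES.mkdir(parents=True, exist_ok=True)
    survivors = {}
    for hormone, emap in results["maps"].items():
        emap.to_frame().to_csv(_common.RESULTS / f"edgewise_{hormone}.tsv", sep="\t", index=False)
        results["strengths"][hormone].to_csv(
            _common.TABLES / f"strengths_{hormone}.tsv", sep="\t", index=False
        )
        results["network_summaries"][hormone].to_csv(
            _common.TABLES / f"network_summary_{hormone}.tsv", sep="\t", index=False
        )
        survivors[hormone] = {
            "strength_fdr": int(emap.strength_mask.sum()),
            "display_p": int(emap.display_mask.sum()),
        }

    anova = hormone_network_anova(results["strengths"])
    atab = anova["anova"]
    anova_summary = {
        row.replace("C(", "").replace(")", ""): {
            "F": None if np.isnan(atab.loc[row, "F"]) else round(float(atab.loc[row, "F"]), 3),
            "p": None if np.isnan(atab.loc[row, "PR(>F)"]) else float(atab.loc[row, "PR(>F)"]),
            "df": int(atab.loc[row, "df"]),
        }
        for row in atab.index
    }
    truth = GroundTruth.from_json(_common.STUDY_DIR / "ground_truth.json")
    recovery = (
        recovery_metrics(results["maps"].get(truth.coupling_analyte), truth)
        if truth.coupled_edges
        else None
    )
    summary = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "survivors": survivors,
        "hormone_network_anova": {**anova_summary, "residual_df": anova["residual_df"]},
        "ground_truth_recovery": recovery,
    }
    with open(_common.RESULTS / "edgewise_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    print(json.dumps(summary, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
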