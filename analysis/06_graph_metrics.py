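"""Stage 6: session graph topology and the morning/evening comparison.

Computes weighted global efficiency and mean between-network participation
on each FDR-thresholded connectome, then Welch-tests AM versus PM sessions
on both metrics. Writes results/tables/session_metrics.tsv and
results/topology.json.
"""

import importlib
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.graphs import am_pm_compare, session_metrics
from diurnalconn.hormones import read_session_table
from diurnalconn.parcellation import Parcellation

load_matrices = importlib.import_module("05_edgewise").load_matrices


def main() -> None:
    _common.parse_args(__doc__)
    matrices = load_matrices("fdr")
    sessions = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    parc = Parcellation.from_tsv(_common.STUDY_DIR / "parcellation.tsv")

    metrics = session_metrics(matrices, parc, sessions)
    _common.TABLES.mkdir(parents=True, exist_ok=True)
    metrics.to_csv(_common.TABLES / "session_metrics.tsv", sep="\t", index=False)

    topo = {}
    for metric in ("efficiency", "participation"):
        try:
            topo[metric] = am_pm_compare(metrics, metric)
        except ValueError as exc:
            topo[metric] = {"degenerate": True, "reason": str(exc)}
    with open(_common.RESULTS / "topology.json", "w") as fh:
        json.dump(topo, fh, indent=2, sort_keys=True)
    print(json.dumps(topo, indent=2, sort_keys=True))


if __name__ == "__main__":
    main()
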