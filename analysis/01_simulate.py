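"""Stage 1: generate the synthetic dense-sampling study.

Writes the session calendar with hormone concentrations, per-session BOLD
timeseries and motion traces, mood scores, the parcellation, and the
generator's ground-truth coupling record to scratch/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.pipeline import simulate_study
from diurnalconn.synthetic import write_study


def main() -> None:
    args = _common.parse_args(__doc__)
    cfg = _common.load(args)
    artifacts = simulate_study(cfg)
    write_study(
        _common.STUDY_DIR,
        artifacts["hormones"],
        artifacts["sessions"],
        artifacts["truth"],
        parcellation=artifacts["parcellation"],
        motion=artifacts["motion"],
        mood=artifacts["mood"],
    )
    print(
        f"wrote {cfg.study.n_sessions} sessions x {cfg.study.n_nodes} nodes "
        f"(seed {cfg.seed}, config {cfg.config_hash()}) to {_common.STUDY_DIR}"
    )


if __name__ == "__main__":
    main()
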