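"""Stage 3: nuisance regression of the session timeseries.

For each session, builds the Friston-24 motion expansion plus spike
regressors from framewise displacement, regresses them (with a linear
detrend) out of the median-scaled BOLD, and writes the cleaned timeseries
to scratch/cleaned/ and the per-session motion summary to results/tables/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.coherence import RegionalTimeseries
from diurnalconn.hormones import read_session_table
from diurnalconn.pipeline import clean_sessions


def main() -> None:
    args = _common.parse_args(__doc__)
    cfg = _common.load(args)
    sessions_table = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    sessions, motion = [], []
    for sid in sessions_table["session_id"]:
        sessions.append(
            RegionalTimeseries.from_tsv(
                _common.STUDY_DIR / "timeseries" / f"{sid}_bold.tsv",
                cfg.study.tr_seconds,
                sid,
            )
        )
        motion.append(np.loadtxt(_common.STUDY_DIR / "motion" / f"rp_{sid}.txt"))

    cleaned, fwd_table = clean_sessions(sessions, motion)

    _common.CLEANED_DIR.mkdir(parents=True, exist_ok=True)
    for ts in cleaned:
        ts.to_tsv(_common.CLEANED_DIR / f"{ts.session_id}_cleaned.tsv")
    _common.TABLES.mkdir(parents=True, exist_ok=True)
    fwd_table.to_csv(_common.TABLES / "fwd.tsv", sep="\t", index=False)

    print(f"cleaned {len(cleaned)} sessions; mean FWD "
          f"{fwd_table['mean_fwd_mm'].mean():.4f} mm, "
          f"{int((fwd_table['n_spike_frames'] > 0).sum())} sessions with spike frames")


if __name__ == "__main__":
    main()
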