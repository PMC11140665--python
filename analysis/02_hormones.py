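"""Stage 2: endocrine summaries and the hormone-mood correlation screen.

Reads the session table and mood scores written by stage 1 and writes the
diurnal summary (AM/PM means, SDs, percent decrease per analyte) and the
Bonferroni-corrected Pearson screen of hormones against mood scales
(overall plus AM-only and PM-only subsets) to results/tables/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.hormones import (
    ANALYTE_COLUMNS,
    correlation_screen,
    diurnal_summary_table,
    read_session_table,
)
from diurnalconn.synthetic import MOOD_SCALES


def main() -> None:
    _common.parse_args(__doc__)
    sessions = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    mood = pd.read_csv(_common.STUDY_DIR / "mood.tsv", sep="\t")
    table = sessions.merge(mood, on="session_id")

    _common.TABLES.mkdir(parents=True, exist_ok=True)
    diurnal = diurnal_summary_table(sessions)
    diurnal.to_csv(_common.TABLES / "diurnal_summary.tsv", sep="\t", index=False)

    analytes = [a for a in ANALYTE_COLUMNS if a in table.columns]
    scales = list(MOOD_SCALES)
    screens = [
        correlation_screen(table, analytes, scales, subset=s) for s in ("all", "AM", "PM")
    ]
    screen = pd.concat(screens, ignore_index=True)
    screen.to_csv(_common.TABLES / "hormone_mood_screen.tsv", sep="\t", index=False)

    print(diurnal[["analyte", "mean_am", "mean_pm", "pct_decrease"]].round(2).to_string(index=False))
    print(f"\ncorrelation screen: {int(screen['significant'].sum())} of {len(screen)} "
          f"pairs significant after Bonferroni")


if __name__ == "__main__":
    main()
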