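"""Stage 4: per-session wavelet-coherence connectomes.

Band-limits each cleaned session to the 0.01-0.17 Hz MODWT detail band
(levels 3-6, sym8), estimates the Welch magnitude-squared coherence for
every node pair, and applies the per-session FDR threshold against the
independence null. Raw and thresholded matrices go to scratch/connectomes/.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
import _common

from diurnalconn.coherence import RegionalTimeseries
from diurnalconn.hormones import read_session_table
from diurnalconn.pipeline import build_connectomes


def main() -> None:
    args = _common.parse_args(__doc__)
    cfg = _common.load(args)
    sessions_table = read_session_table(_common.STUDY_DIR / "sessions.tsv")
    cleaned = [
        RegionalTimeseries.from_tsv(
            _common.CLEANED_DIR / f"{sid}_cleaned.tsv", cfg.study.tr_seconds, sid
        )
        for sid in sessions_table["session_id"]
    ]
    raw, thresholded = build_connectomes(cleaned, cfg)

    for kind, mats in (("raw", raw), ("fdr", thresholded)):
        out = _common.CONNECTOME_DIR / kind
        out.mkdir(parents=True, exist_ok=True)
        for m in mats:
            np.savetxt(out / f"{m.session_id}.tsv", m.values, delimiter="\t")
    meta = {
        "n_segments": raw[0].n_segments,
        "tr_seconds": raw[0].tr_seconds,
        "fdr_q": cfg.fdr_q,
        "config_hash": cfg.config_hash(),
        **raw[0].meta,
    }
    with open(_common.CONNECTOME_DIR / "meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)

    density = float(np.mean([(m.values > 0).mean() for m in thresholded]))
    print(f"{len(raw)} connectomes, L = {raw[0].n_segments} Welch segments; "
          f"mean post-FDR density {density:.3f}")


if __name__ == "__main__":
    main()
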