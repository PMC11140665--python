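"""Shared locations and config loading for the numbered analysis scripts.

Run the scripts from the repository root in order:

    python analysis/01_simulate.py
    python analysis/02_hormones.py
    ...

Large intermediates (timeseries, per-session connectomes) go to scratch/;
small result tables and JSON summaries go to results/. Both are gitignored.
"""

from __future__ import annotations

import argparse
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DEFAULT_CONFIG = ROOT / "analysis" / "config.yaml"
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

STUDY_DIR = SCRATCH / "study"
CLEANED_DIR = SCRATCH / "cleaned"
CONNECTOME_DIR = SCRATCH / "connectomes"
TABLES = RESULTS / "tables"


def parse_args(description: str, seed_default: int = 0) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--config", default=str(DEFAULT_CONFIG))
    ap.add_argument("--seed", type=int, default=seed_default)
    return ap.parse_args()


def load(args: argparse.Namespace):
    from diurnalconn.cli import load_config

    return load_config(args.config, seed=args.seed)
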