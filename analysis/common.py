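"""Shared constants for the numbered analysis drivers."""

from pathlib import Path

STUDY_SEED = 2021
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SIM_DIR = RESULTS / "simulated"
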