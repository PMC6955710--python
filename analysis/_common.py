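"""Shared constants for the analysis drivers."""

from pathlib import Path

SEED = 0
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
PIPELINE_DIR = RESULTS / "pipeline"

RESULTS.mkdir(exist_ok=True)
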