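"""Shared paths and configuration for the numbered analysis scripts.

All scripts use the same seeded study configuration, so each step can be
rerun independently and reproduces the same inputs deterministically.
"""

from pathlib import Path

from pcoskg.config import PipelineConfig, SimConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 11


def study_config() -> PipelineConfig:
    cfg = PipelineConfig(seed=SEED, sim=SimConfig(seed=SEED))
    cfg.validate()
    return cfg
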