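"""Shared configuration for the analysis scripts: one study seed, one
cohort definition (21 NT + 20 ASD, 80-sentence sessions, 600
reverse-correlation trials), and the output locations."""

from pathlib import Path

from vocalsmile.pipeline import RunConfig

SEED = 2026
CONFIG = RunConfig(seed=SEED)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def get_cohort(**overrides):
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return CONFIG.simulate(**overrides)
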