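"""Shared run configuration for the numbered analysis scripts.

One study, one seed, one output directory: every script works on
results/study so later stages reuse the fixtures written by earlier ones.
"""

from kidbioage.pipeline import RunConfig
from kidbioage.synth import SimConfig

STUDY_SEED = 20
OUTPUT_DIR = "results/study"


def build_config(stages: tuple[str, ...]) -> RunConfig:
    return RunConfig(
        sim=SimConfig(n_children=1000, seed=STUDY_SEED),
        output_dir=OUTPUT_DIR,
        seed=STUDY_SEED,
        stages=stages,
    )
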