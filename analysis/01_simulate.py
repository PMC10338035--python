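"""Generate the default synthetic cohort and write its fixtures.

Simulates ~1000 children aged 5-12 across six centres with four omic
blocks, qPCR telomere wells, outcomes tied to a latent delta age, and a
follow-up panel subset; writes everything under results/study/fixtures.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_config  # noqa: E402

from kidbioage.pipeline import run_pipeline


def main() -> None:
    cfg = build_config(stages=("simulate",))
    manifest = run_pipeline(cfg)
    rec = manifest["stages"]["simulate"]
    print(f"simulated {rec['n_children']} children; wrote {len(rec['files'])} fixture files")
    print(f"fixtures under {cfg.output_dir}/fixtures")


if __name__ == "__main__":
    main()
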