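"""Quantify relative telomere length (T/S) from the triplicate qPCR wells.

Estimates per-target PCR efficiencies from the serial-dilution standards,
computes calibrator-referenced relative quantities per run, and reports
each child's T/S ratio relative to the cohort average (mean = 1).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_config  # noqa: E402

from kidbioage.pipeline import run_pipeline


def main() -> None:
    cfg = build_config(stages=("telomere",))
    manifest = run_pipeline(cfg)
    rec = manifest["stages"]["telomere"]
    print(f"relative T/S for {rec['n']} children (cohort mean {rec['cohort_mean_relative_ts']:.6f})")
    print(f"median triplicate T/S CV: {rec['median_cv_ts_pct']:.2f}%")
    print(f"results: {cfg.output_dir}/telomere.csv")


if __name__ == "__main__":
    main()
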