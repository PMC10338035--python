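"""Apply the assay-specific QC, batch-correction and normalization chain.

Proteins: linear-range filter, plate-mean correction, truncated-normal
imputation of out-of-range values. Serum metabolites: CV/LOD exclusion,
log2. Urinary metabolites: median fold-change dilution normalization with
a half-minimum offset and log2. Transcripts: call-rate filters.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_config  # noqa: E402

from kidbioage.pipeline import run_pipeline


def main() -> None:
    cfg = build_config(stages=("preprocess",))
    manifest = run_pipeline(cfg)
    for label, rec in manifest["stages"]["preprocess"].items():
        if label == "status":
            continue
        print(
            f"{label}: {rec['n_samples']} samples x {rec['n_features']} features "
            f"({rec['dropped']} features dropped by QC)"
        )
    print(f"QC report: {cfg.output_dir}/qc_report.json")


if __name__ == "__main__":
    main()
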